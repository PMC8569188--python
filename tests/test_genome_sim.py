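import math

import numpy as np
import pytest

import clonebench as cb
from clonebench.genome_sim import (
    AneuploidyEvent,
    CNAEvent,
    Variant,
    WGDEvent,
)
from conftest import diploid_config


class TestLognormalLength:
    def test_degenerate_variance_is_deterministic(self, rng):
        # exp(-1) * 1e6 rounds to 367879 regardless of the RNG
        assert cb.sample_lognormal_length(-1, 0, 1e6, rng) == 367879

    def test_median_matches_closed_form(self):
        rng = np.random.default_rng(5)
        draws = [cb.sample_lognormal_length(-1, 3, 1e6, rng) for _ in range(100_000)]
        median = np.median(draws)
        # median of a lognormal is exp(mean) * multiplier; order-statistic
        # noise at n=1e5 with sigma=sqrt(3) stays well within 5%
        assert median == pytest.approx(math.exp(-1) * 1e6, rel=0.05)

    def test_floor_at_one(self):
        rng = np.random.default_rng(5)
        assert all(cb.sample_lognormal_length(-2, 2, 1, rng) >= 1
                   for _ in range(2000))

    def test_negative_variance_errors(self, rng):
        with pytest.raises(ValueError):
            cb.sample_lognormal_length(0, -1, 1, rng)


class TestGermlineVariants:
    def test_zero_rates_give_empty_set(self, toy_ref, rng):
        cfg = diploid_config()
        assert cb.simulate_germline_variants(cfg, toy_ref, None, rng) == []

    def test_snv_rate_matches_config(self, toy_ref):
        cfg = diploid_config(snvgermline=0.0014, dbsnpsnvproportion=0.0)
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            counts.append(len(cb.simulate_germline_variants(cfg, toy_ref, None, rng)))
        rate = np.mean(counts) / toy_ref.total_length
        se = np.std(counts, ddof=1) / math.sqrt(len(counts)) / toy_ref.total_length
        assert abs(rate - 0.0014) < 3 * se + 1e-5

    def test_all_snvs_from_known_sites_at_proportion_one(self, toy_ref, rng):
        known = cb.toy_known_sites(toy_ref, 0.005, seed=3, indel_fraction=0.0)
        cfg = diploid_config(snvgermline=0.0005, dbsnpsnvproportion=1.0)
        variants = cb.simulate_germline_variants(cfg, toy_ref, known, rng)
        known_keys = {(c, p, r, a) for c, p, r, a in known.snvs}
        assert variants
        assert all((v.chrom, v.pos, v.ref, v.alt) in known_keys for v in variants)

    def test_nonzero_dbsnp_with_empty_known_errors(self, toy_ref, rng):
        cfg = diploid_config(snvgermline=0.0005, dbsnpsnvproportion=0.9)
        with pytest.raises(ValueError):
            cb.simulate_germline_variants(cfg, toy_ref, None, rng)

    def test_germline_cnv_event_counts_are_exact(self, toy_ref, rng):
        cfg = diploid_config(cnvrepgermline=7, cnvdelgermline=13)
        events = cb.simulate_germline_cnas(cfg, toy_ref, rng)
        kinds = [e.kind for e in events]
        assert kinds.count("replication") == 7
        assert kinds.count("deletion") == 13


class TestSomaticEvents:
    def test_zero_config_gives_no_events(self, eight_clone_tree, toy_ref, rng):
        cfg = diploid_config(snvsomatic_total=0, indsomatic_total=0)
        events = cb.simulate_somatic_events(cfg, eight_clone_tree, toy_ref, rng)
        assert all(not evs for evs in events.values())

    def test_wgdprob_one_gives_exactly_one_wgd(self, eight_clone_tree, toy_ref):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cfg = diploid_config(snvsomatic_total=0, indsomatic_total=0, wgdprob=1.0)
            events = cb.simulate_somatic_events(cfg, eight_clone_tree, toy_ref, rng)
            wgds = [e for evs in events.values() for e in evs
                    if isinstance(e, WGDEvent)]
            assert len(wgds) == 1

    def test_aneuploid_count_is_exact(self, eight_clone_tree, toy_ref, rng):
        cfg = diploid_config(snvsomatic_total=0, indsomatic_total=0, aneuploid=4)
        events = cb.simulate_somatic_events(cfg, eight_clone_tree, toy_ref, rng)
        aneu = [e for evs in events.values() for e in evs
                if isinstance(e, AneuploidyEvent)]
        assert len(aneu) == 4

    def test_multinomial_split_follows_branch_weights(self, toy_ref):
        tree = cb.parse_structure("A,2,germline,B,1,A")
        cfg = diploid_config(snvsomatic_total=3000, indsomatic_total=0)
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            events = cb.simulate_somatic_events(cfg, tree, toy_ref, rng)
            counts.append(len(events["A"]))
        mean_a = np.mean(counts)
        se = math.sqrt(3000 * (2 / 3) * (1 / 3) / len(counts))
        assert abs(mean_a - 2000) < 3 * se


class TestCloneProfiles:
    def test_no_events_is_diploid_everywhere(self, toy_ref, rng):
        tree = cb.parse_structure("A,1,germline,B,1,A")
        profiles = cb.build_clone_profiles(tree, [], {}, toy_ref, rng)
        for clone in ("A", "B", "germline"):
            total, per = profiles[clone].cn("chr1", 1234)
            assert total == 2 and per == {"A": 1, "B": 1}
            assert profiles[clone].ploidy() == pytest.approx(2.0)

    def test_diploid_simulation_has_m1_n2(self, diploid_profiles, eight_clone_tree):
        registry = diploid_profiles["clone1"].variants
        somatic = [v for v in registry.values() if v.origin != "germline"]
        assert somatic
        for var in somatic:
            prof = diploid_profiles[var.origin]
            assert prof.multiplicity(var) == 1
            assert prof.locus_total(var) == 2

    def test_wgd_doubles_clone_and_descendants_only(self, toy_ref, rng):
        tree = cb.parse_structure("A,1,germline,B,1,A,C,1,B,D,1,A")
        events = {"B": [WGDEvent(clone="B", time=0.5)]}
        profiles = cb.build_clone_profiles(tree, [], events, toy_ref, rng)
        for pos in (0, 25_000, 49_999):
            assert profiles["B"].cn("chr1", pos)[0] == 4
            assert profiles["C"].cn("chr1", pos)[0] == 4
            assert profiles["A"].cn("chr1", pos)[0] == 2
            assert profiles["D"].cn("chr1", pos)[0] == 2

    def test_snv_then_replication_raises_multiplicity(self, toy_ref, rng):
        # an SNV at t=0.2 whose allele copy is replicated (+1) at t=0.7
        tree = cb.parse_structure("A,1,germline")
        var = Variant(chrom="chr1", pos=1000, ref="A", alt="T", var_class="SNV",
                      origin="A", time=0.2)
        profiles = cb.build_clone_profiles(tree, [], {"A": [var]}, toy_ref, rng)
        prof = profiles["A"]
        rep = CNAEvent(chrom="chr1", start=500, end=2000, kind="replication",
                       added_copies=1, origin="A", time=0.7,
                       target_allele_copy=var.allele_copy_id)
        prof.apply_cna(rep, rng)
        assert prof.multiplicity(var) == 2
        assert prof.locus_total(var) == 3

    def test_replication_before_snv_keeps_multiplicity_one(self, toy_ref, rng):
        tree = cb.parse_structure("A,1,germline")
        var = Variant(chrom="chr1", pos=1000, ref="A", alt="T", var_class="SNV",
                      origin="A", time=0.9)
        rep = CNAEvent(chrom="chr1", start=500, end=2000, kind="replication",
                       added_copies=2, origin="A", time=0.1)
        profiles = cb.build_clone_profiles(tree, [], {"A": [rep, var]}, toy_ref, rng)
        assert profiles["A"].multiplicity(var) == 1
        assert profiles["A"].locus_total(var) == 4

    def test_deletion_removes_copy_and_its_variants(self, toy_ref, rng):
        tree = cb.parse_structure("A,1,germline")
        var = Variant(chrom="chr1", pos=1000, ref="A", alt="T", var_class="SNV",
                      origin="A", time=0.2)
        profiles = cb.build_clone_profiles(tree, [], {"A": [var]}, toy_ref, rng)
        prof = profiles["A"]
        deletion = CNAEvent(chrom="chr1", start=900, end=1100, kind="deletion",
                            origin="A", time=0.8,
                            target_allele_copy=var.allele_copy_id)
        prof.apply_cna(deletion, rng)
        assert prof.multiplicity(var) == 0
        assert prof.locus_total(var) == 1

    def test_deletion_of_zero_copy_region_is_skipped(self, toy_ref, rng, caplog):
        tree = cb.parse_structure("A,1,germline")
        profiles = cb.build_clone_profiles(tree, [], {}, toy_ref, rng)
        prof = profiles["A"]
        for _ in range(2):  # remove both copies
            prof.apply_cna(CNAEvent(chrom="chr1", start=100, end=200,
                                    kind="deletion", origin="A"), rng)
        assert prof.cn("chr1", 150)[0] == 0
        with caplog.at_level("WARNING"):
            ok = prof.apply_cna(CNAEvent(chrom="chr1", start=120, end=180,
                                         kind="deletion", origin="A"), rng)
        assert not ok
        assert "skipped" in caplog.text

    def test_copy_conservation_under_branch_events(self, toy_ref, rng):
        tree = cb.parse_structure("A,1,germline,B,1,A")
        rep = CNAEvent(chrom="chr2", start=10_000, end=20_000, kind="replication",
                       added_copies=3, origin="B", time=0.4)
        profiles = cb.build_clone_profiles(tree, [], {"B": [rep]}, toy_ref, rng)
        assert profiles["B"].cn("chr2", 15_000)[0] == \
            profiles["A"].cn("chr2", 15_000)[0] + 3
        assert profiles["B"].cn("chr2", 25_000)[0] == \
            profiles["A"].cn("chr2", 25_000)[0]

    def test_inheritance_is_monotone(self, diploid_profiles, eight_clone_tree):
        # without deletions, each clone carries every ancestor-branch variant
        tree = eight_clone_tree
        registry = diploid_profiles["clone1"].variants
        for clone in tree.clones:
            path = [clone]
            while tree.parent(path[-1]) != "germline":
                path.append(tree.parent(path[-1]))
            for var in registry.values():
                if var.origin in path and var.allele_copy_id is not None:
                    assert diploid_profiles[clone].multiplicity(var) >= 1

    def test_segment_table_tiles_contigs(self, toy_ref, rng):
        tree = cb.parse_structure("A,1,germline")
        rep = CNAEvent(chrom="chr1", start=5_000, end=9_000, kind="replication",
                       added_copies=1, origin="A", time=0.3)
        profiles = cb.build_clone_profiles(tree, [], {"A": [rep]}, toy_ref, rng)
        seg = profiles["A"].segment_table()
        for chrom, grp in seg.groupby("chrom"):
            assert grp["start"].iloc[0] == 0
            assert grp["end"].iloc[-1] == toy_ref.lengths[chrom]
            assert (grp["start"].values[1:] == grp["end"].values[:-1]).all()
        mid = seg[(seg.chrom == "chr1") & (seg.start <= 6000) & (seg.end > 6000)]
        assert mid["total"].iloc[0] == 3


def test_wgd_fraction_converges_to_probability(eight_clone_tree, toy_ref):
    cfg = diploid_config(snvsomatic_total=0, indsomatic_total=0, wgdprob=0.333)
    n = 600
    rng = np.random.default_rng(99)
    hits = 0
    for _ in range(n):
        events = cb.simulate_somatic_events(cfg, eight_clone_tree, toy_ref, rng)
        hits += any(isinstance(e, WGDEvent) for evs in events.values() for e in evs)
    se = math.sqrt(0.333 * 0.667 / n)
    assert abs(hits / n - 0.333) < 3 * se
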