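import math

import numpy as np
import pytest

import clonebench as cb
from clonebench.bulk_sim import clone_snv_haplotype, emit_toy_reads
from clonebench.genome_sim import CNAEvent, CloneGenomeProfile, Variant


def _chain_with_deletion(rng):
    """germline -> A -> B -> C; variant arises in B, deleted again in C."""
    tree = cb.parse_structure("A,1,germline,B,1,A,C,1,B")
    var = Variant(chrom="chr1", pos=500, ref="A", alt="G", var_class="SNV",
                  origin="B", time=0.3)
    profiles = cb.build_clone_profiles(
        tree, [], {"B": [var]},
        cb.Reference({"chr1": "A" * 2000}), rng)
    deletion = CNAEvent(chrom="chr1", start=400, end=600, kind="deletion",
                        origin="C", time=0.5, target_allele_copy=var.allele_copy_id)
    profiles["C"].apply_cna(deletion, rng)
    comp = cb.BulkComposition(clone_fractions={"A": 0.1, "B": 0.2, "C": 0.7},
                              normal_fraction=0.0)
    return tree, var, profiles, comp


class TestTrueCCF:
    def test_founding_clone_variant_is_clonal(self, eight_clone_tree):
        var = Variant(chrom="chr1", pos=10, ref="A", alt="C", var_class="SNV",
                      origin="clone1")
        comp = cb.BulkComposition.from_weights(
            {c: 1.0 for c in eight_clone_tree.clones}, purity=0.6)
        assert cb.true_ccf(var, eight_clone_tree, comp) == pytest.approx(1.0)

    def test_leaf_private_variant(self):
        tree = cb.parse_structure("A,1,germline,B,1,A")
        var = Variant(chrom="chr1", pos=10, ref="A", alt="C", var_class="SNV",
                      origin="B")
        comp = cb.BulkComposition(clone_fractions={"A": 0.92, "B": 0.08},
                                  normal_fraction=0.0)
        assert cb.true_ccf(var, tree, comp) == pytest.approx(0.08)

    def test_deletion_in_descendant_shrinks_ccf(self, rng):
        tree, var, profiles, comp = _chain_with_deletion(rng)
        assert cb.true_ccf(var, tree, comp, profiles) == pytest.approx(0.2)
        # the switch restores the subtree sum
        assert cb.true_ccf(var, tree, comp, profiles,
                           account_deletions=False) == pytest.approx(0.9)

    def test_germline_variant_errors(self, eight_clone_tree):
        var = Variant(chrom="chr1", pos=10, ref="A", alt="C", var_class="SNV",
                      origin="germline")
        comp = cb.BulkComposition.from_weights({"clone1": 1.0}, purity=1.0)
        with pytest.raises(ValueError):
            cb.true_ccf(var, eight_clone_tree, comp)


class TestExpectedVAF:
    def _single_clone(self, rng):
        tree = cb.parse_structure("A,1,germline")
        var = Variant(chrom="chr1", pos=100, ref="A", alt="T", var_class="SNV",
                      origin="A", time=0.2)
        ref = cb.Reference({"chr1": "A" * 1000})
        profiles = cb.build_clone_profiles(tree, [], {"A": [var]}, ref, rng)
        return var, profiles

    def test_clonal_het_diploid_pure(self, rng):
        var, profiles = self._single_clone(rng)
        comp = cb.BulkComposition.from_weights({"A": 1.0}, purity=1.0)
        assert cb.expected_vaf(var, profiles, comp) == pytest.approx(0.5)

    def test_purity_dilutes_vaf(self, rng):
        var, profiles = self._single_clone(rng)
        comp = cb.BulkComposition.from_weights({"A": 1.0}, purity=0.75)
        assert cb.expected_vaf(var, profiles, comp) == pytest.approx(0.375)

    def test_two_of_three_copies(self, rng):
        var, profiles = self._single_clone(rng)
        rep = CNAEvent(chrom="chr1", start=0, end=1000, kind="replication",
                       added_copies=1, origin="A", time=0.8,
                       target_allele_copy=var.allele_copy_id)
        profiles["A"].apply_cna(rep, rng)
        comp = cb.BulkComposition.from_weights({"A": 1.0}, purity=1.0)
        assert cb.expected_vaf(var, profiles, comp) == pytest.approx(2 / 3)

    def test_fully_deleted_locus_is_nan(self, rng):
        var, profiles = self._single_clone(rng)
        for _ in range(2):
            profiles["A"].apply_cna(
                CNAEvent(chrom="chr1", start=0, end=1000, kind="deletion",
                         origin="A", time=0.9), rng)
        comp = cb.BulkComposition.from_weights({"A": 1.0}, purity=1.0)
        assert math.isnan(cb.expected_vaf(var, profiles, comp))


class TestSampleObservation:
    def test_zero_vaf_zero_alt(self, rng):
        for _ in range(100):
            depth, alt = cb.sample_observation(0.0, 80, rng)
            assert alt == 0 and depth >= 0

    def test_zero_depth_is_uncovered(self, rng):
        assert cb.sample_observation(0.3, 0, rng) == (0, 0)

    def test_vaf_out_of_range_errors(self, rng):
        with pytest.raises(ValueError):
            cb.sample_observation(1.5, 100, rng)

    def test_mean_vaf_converges(self):
        rng = np.random.default_rng(17)
        vafs = []
        for _ in range(10_000):
            depth, alt = cb.sample_observation(0.25, 250, rng)
            if depth:
                vafs.append(alt / depth)
        se = np.std(vafs, ddof=1) / math.sqrt(len(vafs))
        assert abs(np.mean(vafs) - 0.25) < 3 * se

    def test_overdispersion_widens_spread(self):
        rng = np.random.default_rng(17)
        plain = [cb.sample_observation(0.3, 200, rng)[1] for _ in range(4000)]
        noisy = [cb.sample_observation(0.3, 200, rng, overdispersion=0.2)[1]
                 for _ in range(4000)]
        assert np.std(noisy) > 1.5 * np.std(plain)


class TestComposeBulk:
    def test_pure_single_clone_is_all_clonal(self, rng):
        tree = cb.parse_structure("A,1,germline")
        ref = cb.Reference({"chr1": "ACGT" * 2500})
        cfg = cb.SimulationConfig(
            snvgermline=0, indgermline=0, snvsomatic_total=50, indsomatic_total=0,
            aneuploid=0, wgdprob=0, cnvrepgermline=0, cnvdelgermline=0,
            cnvsomatic_rep=0, cnvsomatic_del=0,
            dbsnpsnvproportion=0, dbsnpindelproportion=0)
        events = cb.simulate_somatic_events(cfg, tree, ref, rng)
        profiles = cb.build_clone_profiles(tree, [], events, ref, rng)
        comp = cb.BulkComposition.from_weights({"A": 1.0}, purity=1.0)
        _, truth = cb.compose_bulk(profiles, tree, comp, 100, rng)
        assert (truth["true_ccf"] == 1.0).all()
        assert (truth["expected_vaf"] == 0.5).all()

    def test_truth_table_is_seed_invariant(self, diploid_profiles,
                                           eight_clone_tree):
        comp = cb.BulkComposition.from_weights(
            {c: 1.0 for c in eight_clone_tree.clones}, purity=0.75)
        _, t1 = cb.compose_bulk(diploid_profiles, eight_clone_tree, comp, 60,
                                np.random.default_rng(1))
        _, t2 = cb.compose_bulk(diploid_profiles, eight_clone_tree, comp, 60,
                                np.random.default_rng(2))
        assert t1.equals(t2)

    def test_zero_depth_keeps_truth_complete(self, diploid_profiles,
                                             eight_clone_tree, rng):
        comp = cb.BulkComposition.from_weights(
            {c: 1.0 for c in eight_clone_tree.clones}, purity=1.0)
        sample, truth = cb.compose_bulk(diploid_profiles, eight_clone_tree,
                                        comp, 0, rng)
        assert len(truth) > 0
        assert (sample.observations["depth"] == 0).all()
        assert sample.observations["vaf"].isna().all()

    def test_missing_profile_errors(self, eight_clone_tree, diploid_profiles, rng):
        comp = cb.BulkComposition.from_weights({"cloneX": 1.0}, purity=1.0)
        with pytest.raises(KeyError):
            cb.compose_bulk(diploid_profiles, eight_clone_tree, comp, 10, rng)

    def test_doubled_vaf_identity_on_diploid_truth(self, diploid_bulk):
        # 2 * expected_vaf / purity == true CCF exactly when m=1, n=2 everywhere
        _, truth, comp = diploid_bulk
        est = cb.doubled_vaf_baseline(truth["expected_vaf"].to_numpy(), comp.purity)
        np.testing.assert_allclose(est, truth["true_ccf"].to_numpy(), atol=1e-12)


class TestToyReads:
    def _setup(self, rng):
        ref = cb.Reference({"chr1": "".join(
            "ACGT"[i] for i in np.random.default_rng(3).integers(0, 4, 20_000))})
        tree = cb.parse_structure("A,1,germline")
        var = Variant(chrom="chr1", pos=5_000, ref=ref.base("chr1", 5_000),
                      alt="A" if ref.base("chr1", 5_000) != "A" else "C",
                      var_class="SNV", origin="A", time=0.5)
        profiles = cb.build_clone_profiles(tree, [], {"A": [var]}, ref, rng)
        haps = {"A": clone_snv_haplotype(ref, profiles["A"]),
                "germline": ref.sequences}
        return ref, haps

    def test_error_free_reads_are_haplotype_substrings(self, rng, tmp_path):
        ref, haps = self._setup(rng)
        fq1, fq2 = str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq")
        n = emit_toy_reads(haps, {"A": 0.5, "germline": 0.5},
                           [("chr1", 1000, 16_100)], depth=5, read_len=151,
                           error_rate=0.0, rng=rng, fastq1=fq1, fastq2=fq2)
        assert n > 0
        lines = open(fq1).read().splitlines()
        assert len(lines) == 4 * n
        comp = str.maketrans("ACGTN", "TGCAN")
        for i in range(0, len(lines), 4):
            read = lines[i + 1]
            assert (read in haps["A"]["chr1"] or read in haps["germline"]["chr1"])

    def test_pair_count_matches_coverage_arithmetic(self, rng, tmp_path):
        ref, haps = self._setup(rng)
        n = emit_toy_reads(haps, {"germline": 1.0}, [("chr1", 100, 15_200)],
                           depth=10, read_len=151, error_rate=0.0, rng=rng,
                           fastq1=str(tmp_path / "a.fq"),
                           fastq2=str(tmp_path / "b.fq"))
        assert n == 500  # 10 * 15100 / (2 * 151)

    def test_zero_depth_writes_empty_files(self, rng, tmp_path):
        ref, haps = self._setup(rng)
        n = emit_toy_reads(haps, {"germline": 1.0}, [("chr1", 0, 10_000)],
                           depth=0, read_len=151, error_rate=0.0, rng=rng,
                           fastq1=str(tmp_path / "a.fq"),
                           fastq2=str(tmp_path / "b.fq"))
        assert n == 0
        assert (tmp_path / "a.fq").read_text() == ""
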