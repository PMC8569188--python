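"""Bulk-sample composition: truth tables, expected VAFs and sampled counts.

A bulk sample mixes reads from tumour clones and normal cells at a given
purity and mean depth.  Rather than realising reads, the primary path here
works at count level: each somatic variant gets an expected variant allele
frequency (VAF) from the mixture's copy states, a Poisson depth and a
binomial (or beta-binomial) alternate-read count.  A toy paired-FASTQ
emitter is provided for pipelines that want sequence-shaped input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clone_tree import BulkComposition, CloneTree, ROOT_MARKER, subtree_ccf
from .genome_sim import CloneGenomeProfile, Reference, Variant

logger = logging.getLogger(__name__)

__all__ = [
    "BulkSample",
    "true_ccf",
    "expected_vaf",
    "sample_observation",
    "compose_bulk",
    "clone_snv_haplotype",
    "emit_toy_reads",
]

TRUTH_COLUMNS = [
    "chrom", "pos", "ref", "alt", "var_class", "origin_clone",
    "true_ccf", "expected_vaf", "m", "n",
]


@dataclass
class BulkSample:
    """One composed bulk sample: composition, target depth and observations.

    ``observations`` has one row per truth variant with columns
    chrom, pos (1-based), ref, alt, depth, alt_count, vaf (NaN when depth 0).
    """

    sample_id: str
    composition: BulkComposition
    target_depth: float
    observations: pd.DataFrame

    @property
    def purity(self) -> float:
        return self.composition.purity


def true_ccf(
    variant: Variant,
    tree: CloneTree,
    comp: BulkComposition,
    profiles: Mapping[str, CloneGenomeProfile] | None = None,
    account_deletions: bool = True,
) -> float:
    """True cancer cell fraction of a somatic variant.

    The sum of tumour proportions of the clones that contain the variant:
    the origin clone's subtree, minus (when ``account_deletions`` and
    profiles are given) clones in which every mutated copy was subsequently
    deleted.
    """
    if variant.origin == ROOT_MARKER:
        raise ValueError("CCF is defined for somatic variants only")
    if profiles is None or not account_deletions:
        return subtree_ccf(tree, comp, variant.origin)
    proportions = comp.tumour_proportions
    return sum(
        proportions.get(clone, 0.0)
        for clone in tree.subtree(variant.origin)
        if profiles[clone].multiplicity(variant) > 0
    )


def expected_vaf(
    variant: Variant,
    profiles: Mapping[str, CloneGenomeProfile],
    comp: BulkComposition,
) -> float:
    """Expected bulk VAF of a variant under read-fraction mixing.

    ``sum_c f_c * m_c / (sum_c f_c * n_c + f_normal * n_germline)`` where
    ``f_c`` are clone read fractions, ``m_c``/``n_c`` the clone's mutated-copy
    multiplicity and locus total, and ``n_germline`` the germline copy number
    at the locus (2 at autosomal loci without germline CNVs).  Returns NaN
    when the locus is deleted in every cell.
    """
    num = 0.0
    den = 0.0
    for clone, frac in comp.clone_fractions.items():
        if clone not in profiles:
            raise KeyError(f"no genome profile for clone {clone!r}")
        prof = profiles[clone]
        num += frac * prof.multiplicity(variant)
        den += frac * prof.locus_total(variant)
    germ = profiles.get(ROOT_MARKER)
    germ_total = germ.locus_total(variant) if germ is not None else 2
    den += comp.normal_fraction * germ_total
    if den == 0:
        logger.warning("locus %s:%d deleted in all cells; VAF undefined",
                       variant.chrom, variant.pos)
        return float("nan")
    return num / den


def sample_observation(
    exp_vaf: float,
    mean_depth: float,
    rng: np.random.Generator,
    overdispersion: float = 0.0,
) -> tuple[int, int]:
    """Sample (depth, alt_count) for one variant.

    Depth is Poisson(``mean_depth``); given depth, the alternate count is
    Binomial(depth, vaf), or beta-binomial with dispersion ``rho`` in (0, 1)
    (concentration ``(1 - rho) / rho``) when ``overdispersion`` > 0.
    """
    if not 0 <= exp_vaf <= 1:
        raise ValueError(f"expected VAF must be in [0, 1], got {exp_vaf}")
    if mean_depth < 0:
        raise ValueError("mean depth must be >= 0")
    depth = int(rng.poisson(mean_depth))
    if depth == 0:
        return 0, 0
    p = exp_vaf
    if overdispersion > 0 and 0 < exp_vaf < 1:
        s = (1 - overdispersion) / overdispersion
        p = float(rng.beta(exp_vaf * s, (1 - exp_vaf) * s))
    return depth, int(rng.binomial(depth, p))


def compose_bulk(
    profiles: Mapping[str, CloneGenomeProfile],
    tree: CloneTree,
    comp: BulkComposition,
    target_depth: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
    overdispersion: float = 0.0,
    account_deletions: bool = True,
) -> tuple[BulkSample, pd.DataFrame]:
    """Compose a bulk sample and its ground-truth table.

    One truth record per somatic variant present in at least one clone of the
    composition, with the origin clone's multiplicity ``m`` and locus total
    ``n``; one sampled observation per record.  The truth table depends only
    on profiles and composition, not on the RNG.
    """
    missing = [c for c in comp.clone_fractions if c not in profiles]
    if missing:
        raise KeyError(f"composition clones without genome profiles: {missing}")
    registry = next(iter(profiles.values())).variants
    somatic = sorted(
        (v for v in registry.values() if v.origin != ROOT_MARKER),
        key=lambda v: v.vid,
    )
    comp_clones = list(comp.clone_fractions)
    truth_rows = []
    obs_rows = []
    for var in somatic:
        if not any(profiles[c].multiplicity(var) > 0 for c in comp_clones):
            continue
        origin_prof = profiles[var.origin]
        evaf = expected_vaf(var, profiles, comp)
        truth_rows.append((
            var.chrom, var.pos + 1, var.ref, var.alt, var.var_class, var.origin,
            true_ccf(var, tree, comp, profiles, account_deletions),
            evaf, origin_prof.multiplicity(var), origin_prof.locus_total(var),
        ))
        if math.isnan(evaf):
            depth, alt = int(rng.poisson(target_depth)), 0
        else:
            depth, alt = sample_observation(evaf, target_depth, rng, overdispersion)
        obs_rows.append((
            var.chrom, var.pos + 1, var.ref, var.alt, depth, alt,
            alt / depth if depth > 0 else float("nan"),
        ))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    obs = pd.DataFrame(
        obs_rows,
        columns=["chrom", "pos", "ref", "alt", "depth", "alt_count", "vaf"],
    )
    sample = BulkSample(sample_id=sample_id, composition=comp,
                        target_depth=target_depth, observations=obs)
    return sample, truth


# ---------------------------------------------------------------------------
# Toy read emission
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def clone_snv_haplotype(ref: Reference, profile: CloneGenomeProfile) -> dict[str, str]:
    """Reference sequences with the clone's SNVs substituted in.

    A single consensus haplotype per contig (indels and copy-number structure
    are not realised at sequence level): enough for a toy read emitter.
    """
    seqs = {chrom: list(seq) for chrom, seq in ref.sequences.items()}
    for var in profile.present_variants():
        if var.var_class == "SNV" and var.chrom in seqs:
            seqs[var.chrom][var.pos] = var.alt
    return {chrom: "".join(chars) for chrom, chars in seqs.items()}


def emit_toy_reads(
    haplotypes: Mapping[str, Mapping[str, str]],
    weights: Mapping[str, float],
    targets: Sequence[tuple[str, int, int]],
    depth: float,
    read_len: int,
    error_rate: float,
    rng: np.random.Generator,
    fastq1: str,
    fastq2: str,
) -> int:
    """Write paired 4-line FASTQ reads drawn from target regions.

    Sources (clones/germline) are picked in proportion to ``weights``,
    targets in proportion to length; per-base substitution errors are added
    at ``error_rate``.  The pair count is chosen so that the mean coverage
    over the targets is approximately ``depth``.  Returns the number of pairs
    written.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    targets = [t for t in targets if t[2] - t[1] >= read_len]
    total_len = sum(e - s for _, s, e in targets)
    n_pairs = int(round(depth * total_len / (2 * read_len))) if total_len else 0
    if not targets or n_pairs == 0:
        logger.warning("no usable targets or zero depth: writing empty FASTQ files")
        open(fastq1, "w").close()
        open(fastq2, "w").close()
        return 0
    sources = list(weights)
    w = np.array([weights[s] for s in sources], dtype=float)
    w /= w.sum()
    t_p = np.array([e - s for _, s, e in targets], dtype=float)
    t_p /= t_p.sum()
    src_idx = rng.choice(len(sources), size=n_pairs, p=w)
    tgt_idx = rng.choice(len(targets), size=n_pairs, p=t_p)

    def with_errors(seq: str) -> str:
        if error_rate <= 0:
            return seq
        chars = list(seq)
        for i in np.flatnonzero(rng.random(len(chars)) < error_rate):
            chars[i] = _BASES_EMIT[(_BASES_EMIT.index(chars[i]) + 1 +
                                    int(rng.integers(3))) % 4] \
                if chars[i] in _BASES_EMIT else chars[i]
        return "".join(chars)

    qual = "I" * read_len
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for i, (si, ti) in enumerate(zip(src_idx, tgt_idx)):
            source = sources[int(si)]
            chrom, s, e = targets[int(ti)]
            frag = min(2 * read_len, e - s)
            start = int(rng.integers(s, e - frag + 1))
            seq = haplotypes[source][chrom][start:start + frag]
            r1 = with_errors(seq[:read_len])
            r2 = with_errors(_revcomp(seq[-read_len:]))
            name = f"toyread_{i}_{source}_{chrom}_{start}"
            f1.write(f"@{name}/1\n{r1}\n+\n{qual[:len(r1)]}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{qual[:len(r2)]}\n")
    return n_pairs


_BASES_EMIT = "ACGT"
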