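"""Seeded toy-input generators.

Everything the toolkit consumes can be generated here with no downloads: a
random reference genome, a known-germline-sites panel (a dbSNP stand-in) and
a synthetic "caller" that perturbs a truth table into an imperfect call set
with known error labels.  All outputs are byte-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_sim import KnownSites, Reference, _BASES
from .io_formats import CallSet, KEY_COLUMNS

__all__ = [
    "EIGHT_CLONE_STRUCTURE",
    "FixtureSpec",
    "toy_reference",
    "toy_known_sites",
    "perturbed_callset",
]

#: An eight-clone demonstration architecture: a founding clone with two
#: lineages, one of which splits twice more.  Used throughout the examples
#: and tests as a realistically branched tumour.
EIGHT_CLONE_STRUCTURE = (
    "clone1,2,germline,clone2,1,clone1,clone3,3,clone1,clone4,1,clone2,"
    "clone5,1,clone2,clone6,1,clone4,clone7,1,clone5,clone8,1,clone5"
)


@dataclass
class FixtureSpec:
    """Scale and perturbation knobs for toy fixtures.

    The toy genome defaults (2 x 100 kb) keep a full
    simulate-compose-evaluate chain sub-minute while leaving room for
    hundreds of copy-number bins.
    """

    n_contigs: int = 2
    contig_length: int = 100_000
    seed: int = 0
    known_density: float = 0.002
    fn_rate: float = 0.0
    fp_count: int = 0
    vaf_noise: float = 0.0
    ccf_noise: float = 0.0
    depth: int = 100

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("need at least one contig of length >= 1")
        for name in ("known_density", "fn_rate", "vaf_noise", "ccf_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fp_count < 0 or self.depth < 0:
            raise ValueError("fp_count and depth must be >= 0")


def toy_reference(spec: FixtureSpec) -> Reference:
    """A uniform-random reference: ``n_contigs`` contigs named chr1, chr2, ...

    Identical for identical seeds.
    """
    rng = np.random.default_rng(spec.seed)
    seqs = {}
    for i in range(spec.n_contigs):
        idx = rng.integers(0, 4, size=spec.contig_length)
        seqs[f"chr{i + 1}"] = "".join(_BASES[j] for j in idx)
    return Reference(seqs)


def toy_known_sites(ref: Reference, density: float, seed: int,
                    indel_fraction: float = 0.1) -> KnownSites:
    """~density * genome-length biallelic known sites at uniform positions.

    A fraction ``indel_fraction`` of sites are short (1-5 bp) indels so that
    germline simulation with a nonzero known-indel proportion has a panel to
    draw from.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    known = KnownSites()
    n = int(rng.binomial(ref.total_length, density))
    if n == 0:
        return known
    offsets = rng.choice(ref.total_length, size=n, replace=False)
    is_indel = rng.random(n) < indel_fraction
    for (chrom, pos), indel in zip(ref.locate(np.sort(offsets)), is_indel):
        base = ref.base(chrom, pos)
        if base not in _BASES:
            continue
        if not indel:
            alt = _BASES[(_BASES.index(base) + 1 + int(rng.integers(3))) % 4]
            known.snvs.append((chrom, pos, base, alt))
        else:
            length = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                ins = "".join(_BASES[j] for j in rng.integers(0, 4, size=length))
                known.indels.append((chrom, pos, base, base + ins))
            else:
                end = min(pos + 1 + length, ref.lengths[chrom])
                if end > pos + 1:
                    known.indels.append(
                        (chrom, pos, base + ref.fetch(chrom, pos + 1, end), base))
    return known


def perturbed_callset(
    truth: pd.DataFrame,
    spec: FixtureSpec,
    rng: np.random.Generator,
    reference: Reference | None = None,
) -> tuple[CallSet, pd.DataFrame]:
    """A synthetic caller: truth with dropouts, false positives and VAF noise.

    Drops each truth variant with probability ``fn_rate``, injects
    ``fp_count`` novel calls at random positions, jitters VAFs with Gaussian
    noise truncated to [0, 1], and attaches plausible caller scores (true
    calls score higher on average than artefacts).  Returns the call set and
    a per-call TP/FP label table.
    """
    keep = rng.random(len(truth)) >= spec.fn_rate
    kept = truth[keep]
    vaf = kept["expected_vaf"].to_numpy(dtype=float)
    if spec.vaf_noise > 0:
        vaf = np.clip(vaf + rng.normal(0, spec.vaf_noise, size=len(vaf)), 0, 1)
    depth = max(spec.depth, 1)
    alt = np.round(np.nan_to_num(vaf) * depth).astype(int)
    rows = pd.DataFrame({
        "chrom": kept["chrom"].to_numpy(),
        "pos": kept["pos"].to_numpy(),
        "ref": kept["ref"].to_numpy(),
        "alt": kept["alt"].to_numpy(),
        "score": rng.uniform(0.4, 1.0, size=len(kept)),
        "ref_count": depth - alt,
        "alt_count": alt,
        "is_tp": True,
    })
    truth_keys = set(map(tuple, truth[KEY_COLUMNS].itertuples(index=False, name=None)))
    fp_rows = []
    chroms = (list(reference.contigs) if reference is not None
              else sorted(set(truth["chrom"])))
    guard = 0
    while len(fp_rows) < spec.fp_count and guard < 50 * (spec.fp_count + 1):
        guard += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        if reference is not None:
            pos1 = int(rng.integers(1, reference.lengths[chrom] + 1))
            base = reference.base(chrom, pos1 - 1)
            if base not in _BASES:
                continue
        else:
            pos1 = int(rng.integers(1, int(truth["pos"].max()) + 1))
            base = _BASES[int(rng.integers(4))]
        alt_b = _BASES[(_BASES.index(base) + 1 + int(rng.integers(3))) % 4]
        if (chrom, pos1, base, alt_b) in truth_keys:
            continue
        fvaf = float(rng.uniform(0.02, 0.5))
        falt = int(round(fvaf * depth))
        fp_rows.append((chrom, pos1, base, alt_b,
                        float(rng.uniform(0.0, 0.6)), depth - falt, falt, False))
    fp_df = pd.DataFrame(fp_rows, columns=["chrom", "pos", "ref", "alt", "score",
                                           "ref_count", "alt_count", "is_tp"])
    parts = [df for df in (rows, fp_df) if not df.empty]
    all_rows = (pd.concat(parts, ignore_index=True) if parts
                else rows)
    labels = all_rows[KEY_COLUMNS + ["is_tp"]].copy()
    calls = CallSet(all_rows.drop(columns=["is_tp"]), label="perturbed-truth")
    return calls, labels
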