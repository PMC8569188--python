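"""Germline and somatic event simulation on a reference genome.

Simulates single-nucleotide variants (SNVs), short indels, copy-number
variants (CNVs), single-chromosome aneuploidy and whole-genome duplication
(WGD), distributes somatic events across the branches of a clone tree, and
propagates them into per-clone genome profiles.

The genome of a clone is modelled as a set of *copy instances* per
chromosome: independent lineages of an original parental allele copy, each
covering a (possibly fragmented) set of intervals and carrying the point
variants that arose on it.  Replications clone an instance over a region
(duplicating the variants it carries there), deletions remove a region from
one instance, WGD clones every instance, and aneuploidy adds or removes one
whole-chromosome instance.  Variant multiplicity and locus copy number then
fall out by counting instances, and timestamp ordering of events on a branch
gives the intended semantics (an SNV followed by a replication of its copy
has multiplicity 2).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import re
from bisect import bisect_right
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clone_tree import ROOT_MARKER, CloneTree, branch_weights, parse_structure

logger = logging.getLogger(__name__)

__all__ = [
    "Reference",
    "SimulationConfig",
    "Variant",
    "CNAEvent",
    "AneuploidyEvent",
    "WGDEvent",
    "KnownSites",
    "CopyInstance",
    "CloneGenomeProfile",
    "sample_lognormal_length",
    "simulate_germline_variants",
    "simulate_germline_cnas",
    "simulate_somatic_events",
    "build_clone_profiles",
]

_BASES = "ACGT"
_vid_counter = itertools.count()


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


class Reference:
    """An in-memory reference genome (uppercase sequences, 0-based coords)."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("reference has no contigs")
        self.sequences: dict[str, str] = {
            name: str(seq).upper() for name, seq in sequences.items()
        }
        for name, seq in self.sequences.items():
            if len(seq) == 0:
                raise ValueError(f"contig {name!r} is empty")
        self.lengths: dict[str, int] = {n: len(s) for n, s in self.sequences.items()}
        self._contigs = list(self.sequences)
        self._cum = np.cumsum([self.lengths[c] for c in self._contigs])

    @classmethod
    def from_fasta(cls, path: str) -> "Reference":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def contigs(self) -> list[str]:
        return list(self._contigs)

    @property
    def total_length(self) -> int:
        return int(self._cum[-1])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]

    def locate(self, offsets: np.ndarray) -> list[tuple[str, int]]:
        """Map flat genome offsets to (contig, position) pairs."""
        idx = np.searchsorted(self._cum, offsets, side="right")
        starts = np.concatenate([[0], self._cum[:-1]])
        return [
            (self._contigs[i], int(off - starts[i])) for i, off in zip(idx, offsets)
        ]

    def random_positions(self, n: int, rng: np.random.Generator) -> list[tuple[str, int]]:
        """``n`` positions uniform over the whole genome."""
        if n == 0:
            return []
        return self.locate(rng.integers(0, self.total_length, size=n))

    def random_contigs(self, n: int, rng: np.random.Generator) -> list[str]:
        """``n`` contigs drawn with probability proportional to length."""
        p = np.array([self.lengths[c] for c in self._contigs], dtype=float)
        p /= p.sum()
        idx = rng.choice(len(self._contigs), size=n, p=p)
        return [self._contigs[i] for i in idx]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Event rates and distribution parameters for one simulated tumour.

    Germline SNV/indel rates are per-base; somatic SNV/indel/CNV burdens are
    tumour-wide totals distributed over clone-tree branches by branch weight.
    CNV and indel lengths are lognormal: ``round(exp(N(mean, variance)) *
    multiply)``, floored at 1 bp.  ``aneuploid`` is the per-tumour count of
    single-chromosome gain/loss events, and ``wgdprob`` the probability that
    the tumour contains one whole-genome duplication.
    """

    snvgermline: float = 0.0014
    indgermline: float = 0.00014
    snvsomatic_total: int = 1000
    indsomatic_total: int = 100
    aneuploid: int = 4
    wgdprob: float = 0.333
    cnvrepgermline: int = 160
    cnvdelgermline: int = 1000
    cnvsomatic_rep: int = 20
    cnvsomatic_del: int = 20
    cnvgermlinemean: float = -10.0
    cnvgermlinevariance: float = 3.0
    cnvgermlinemultiply: float = 1_000_000.0
    cnvsomaticmean: float = -1.0
    cnvsomaticvariance: float = 3.0
    cnvsomaticmultiply: float = 1_000_000.0
    indmean: float = -2.0
    indvariance: float = 2.0
    indmultiply: float = 1.0
    cnvcopiesmean: float = 1.0
    cnvcopiesvariance: float = 0.5
    dbsnpsnvproportion: float = 0.9
    dbsnpindelproportion: float = 0.5
    structure: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("snvgermline", "indgermline", "wgdprob",
                     "dbsnpsnvproportion", "dbsnpindelproportion"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("snvsomatic_total", "indsomatic_total", "aneuploid",
                     "cnvrepgermline", "cnvdelgermline",
                     "cnvsomatic_rep", "cnvsomatic_del"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))
        for name in ("cnvgermlinevariance", "cnvsomaticvariance",
                     "indvariance", "cnvcopiesvariance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cnvgermlinemultiply", "cnvsomaticmultiply", "indmultiply"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def tree(self) -> CloneTree:
        if self.structure is None:
            raise ValueError("config has no structure string")
        return parse_structure(self.structure)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "SimulationConfig":
        known = {f.name for f in dc_fields(cls)}
        kwargs = {k: v for k, v in mapping.items() if k in known}
        extra = set(mapping) - known - {"chromosomes"}
        if extra:
            logger.warning("ignoring unknown config keys: %s", sorted(extra))
        return cls(**kwargs)  # type: ignore[arg-type]

    @classmethod
    def from_json(cls, path: str) -> "SimulationConfig":
        text = open(path).read()
        # Tolerate typographic quotes in hand-pasted configs.
        text = re.sub(r"[“”]", '"', text)
        return cls.from_mapping(json.loads(text))


# ---------------------------------------------------------------------------
# Events and variants
# ---------------------------------------------------------------------------


@dataclass
class Variant:
    """A point variant (SNV or short indel).

    Positions are 0-based internally; ``ref``/``alt`` follow the VCF anchor
    convention for indels (shared left anchor base).  ``haplotype`` records
    the parental allele copy (``"A"``/``"B"``) a germline variant was placed
    on; ``allele_copy_id`` is filled in with the copy-instance id when the
    variant is applied to a genome profile.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str  # "SNV" | "insertion" | "deletion"
    origin: str = ROOT_MARKER
    haplotype: str | None = None
    time: float = 0.0
    allele_copy_id: int | None = None
    vid: int = field(default_factory=lambda: next(_vid_counter))

    def __post_init__(self) -> None:
        if self.var_class == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(f"malformed SNV {self.ref}>{self.alt}")
        elif self.var_class not in ("insertion", "deletion"):
            raise ValueError(f"unknown variant class {self.var_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, 1-based pos, ref, alt) — the matching key used throughout."""
        return (self.chrom, self.pos + 1, self.ref, self.alt)


@dataclass
class CNAEvent:
    """A segmental copy-number event (replication or deletion of one copy)."""

    chrom: str
    start: int
    end: int  # half-open
    kind: str  # "replication" | "deletion"
    added_copies: int = 1
    origin: str = ROOT_MARKER
    time: float = 0.0
    target_allele_copy: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("CNA requires start < end")
        if self.kind not in ("replication", "deletion"):
            raise ValueError(f"unknown CNA kind {self.kind!r}")
        if self.kind == "replication" and self.added_copies < 1:
            raise ValueError("replication requires added_copies >= 1")


@dataclass
class AneuploidyEvent:
    chrom: str
    gain: bool
    clone: str
    time: float = 0.0


@dataclass
class WGDEvent:
    clone: str
    time: float = 0.0


@dataclass
class KnownSites:
    """Known germline variant sites (a dbSNP stand-in).

    ``snvs`` and ``indels`` are lists of (chrom, 0-based pos, ref, alt).
    """

    snvs: list[tuple[str, int, str, str]] = field(default_factory=list)
    indels: list[tuple[str, int, str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Interval helpers (sorted, disjoint, half-open)
# ---------------------------------------------------------------------------


def _point_covered(intervals: list[tuple[int, int]], pos: int) -> bool:
    i = bisect_right(intervals, (pos, math.inf))
    return i > 0 and intervals[i - 1][1] > pos


def _intersect(intervals: list[tuple[int, int]], s: int, e: int) -> list[tuple[int, int]]:
    out = []
    for a, b in intervals:
        lo, hi = max(a, s), min(b, e)
        if lo < hi:
            out.append((lo, hi))
    return out


def _subtract(intervals: list[tuple[int, int]], s: int, e: int) -> list[tuple[int, int]]:
    out = []
    for a, b in intervals:
        if b <= s or a >= e:
            out.append((a, b))
            continue
        if a < s:
            out.append((a, s))
        if b > e:
            out.append((e, b))
    return out


def _total_length(intervals: list[tuple[int, int]]) -> int:
    return sum(b - a for a, b in intervals)


# ---------------------------------------------------------------------------
# Copy instances and clone genome profiles
# ---------------------------------------------------------------------------


class CopyInstance:
    """One lineage of a parental allele copy on one chromosome."""

    __slots__ = ("iid", "haplotype", "intervals", "variant_ids")

    def __init__(
        self,
        iid: int,
        haplotype: str,
        intervals: list[tuple[int, int]],
        variant_ids: set[int] | None = None,
    ):
        self.iid = iid
        self.haplotype = haplotype
        self.intervals = intervals
        self.variant_ids: set[int] = variant_ids if variant_ids is not None else set()

    def covers(self, pos: int) -> bool:
        return _point_covered(self.intervals, pos)

    def overlaps(self, s: int, e: int) -> bool:
        return bool(_intersect(self.intervals, s, e))

    def clone(self, iid: int) -> "CopyInstance":
        return CopyInstance(iid, self.haplotype, list(self.intervals), set(self.variant_ids))


class CloneGenomeProfile:
    """Allele-specific copy state and variant content of one clone's genome.

    Exposes ``cn(chrom, pos)`` (total and per-parental-allele copy counts),
    per-variant ``multiplicity`` (mutated copies *m*) and ``locus_total``
    (total copies *n* at the variant's locus), and an allele-specific
    segment table.
    """

    def __init__(self, clone: str, chrom_lengths: Mapping[str, int],
                 variants: dict[int, Variant] | None = None):
        self.clone = clone
        self.chrom_lengths = dict(chrom_lengths)
        #: shared registry of every variant simulated for this tumour
        self.variants: dict[int, Variant] = variants if variants is not None else {}
        self._next_iid = 0
        self.instances: dict[str, list[CopyInstance]] = {}
        for chrom, length in self.chrom_lengths.items():
            self.instances[chrom] = [
                self._new_instance(hap, [(0, length)]) for hap in ("A", "B")
            ]

    def _new_instance(self, haplotype: str, intervals: list[tuple[int, int]],
                      variant_ids: set[int] | None = None) -> CopyInstance:
        inst = CopyInstance(self._next_iid, haplotype, intervals, variant_ids)
        self._next_iid += 1
        return inst

    def copy(self, clone: str) -> "CloneGenomeProfile":
        """A deep copy for a daughter clone (shares the variant registry)."""
        new = CloneGenomeProfile.__new__(CloneGenomeProfile)
        new.clone = clone
        new.chrom_lengths = self.chrom_lengths
        new.variants = self.variants
        new._next_iid = self._next_iid
        new.instances = {
            chrom: [inst.clone(inst.iid) for inst in insts]
            for chrom, insts in self.instances.items()
        }
        return new

    # -- event application -------------------------------------------------

    def apply_variant(self, var: Variant, rng: np.random.Generator) -> bool:
        """Place a point variant on one allele copy covering its position.

        Germline variants go to the instance of their assigned parental
        haplotype; somatic variants pick a covering instance uniformly.
        Returns False (variant absent) if no copy covers the position.
        """
        self.variants[var.vid] = var
        candidates = [i for i in self.instances.get(var.chrom, []) if i.covers(var.pos)]
        if var.origin == ROOT_MARKER and var.haplotype is not None:
            candidates = [i for i in candidates if i.haplotype == var.haplotype]
        if not candidates:
            logger.debug("variant %s at %s:%d lands on a zero-copy region; lost",
                         var.vid, var.chrom, var.pos)
            return False
        inst = candidates[int(rng.integers(len(candidates)))]
        inst.variant_ids.add(var.vid)
        var.allele_copy_id = inst.iid
        return True

    def apply_cna(self, ev: CNAEvent, rng: np.random.Generator) -> bool:
        insts = self.instances.get(ev.chrom)
        if insts is None:
            raise KeyError(f"CNA on unknown contig {ev.chrom!r}")
        end = min(ev.end, self.chrom_lengths[ev.chrom])
        candidates = [i for i in insts if i.overlaps(ev.start, end)]
        if ev.target_allele_copy is not None:
            candidates = [i for i in candidates if i.iid == ev.target_allele_copy]
        if not candidates:
            logger.warning("%s at %s:%d-%d hits a zero-copy region; skipped",
                           ev.kind, ev.chrom, ev.start, end)
            return False
        target = candidates[int(rng.integers(len(candidates)))]
        if ev.target_allele_copy is None:
            ev.target_allele_copy = target.iid
        if ev.kind == "replication":
            region = _intersect(target.intervals, ev.start, end)
            vids = {
                vid for vid in target.variant_ids
                if _point_covered(region, self.variants[vid].pos)
            }
            for _ in range(ev.added_copies):
                insts.append(self._new_instance(target.haplotype, list(region), set(vids)))
        else:  # deletion of one copy over the region
            target.intervals = _subtract(target.intervals, ev.start, end)
            target.variant_ids = {
                vid for vid in target.variant_ids
                if _point_covered(target.intervals, self.variants[vid].pos)
            }
            if not target.intervals:
                insts.remove(target)
        return True

    def apply_wgd(self) -> None:
        """Double every allele copy (and the variants each carries)."""
        for chrom, insts in self.instances.items():
            insts.extend([inst.clone(self._bump_iid()) for inst in list(insts)])

    def _bump_iid(self) -> int:
        iid = self._next_iid
        self._next_iid += 1
        return iid

    def apply_aneuploidy(self, ev: AneuploidyEvent, rng: np.random.Generator) -> bool:
        insts = self.instances.get(ev.chrom)
        if insts is None:
            raise KeyError(f"aneuploidy on unknown contig {ev.chrom!r}")
        if not insts:
            logger.warning("aneuploidy on zero-copy chromosome %s; skipped", ev.chrom)
            return False
        inst = insts[int(rng.integers(len(insts)))]
        if ev.gain:
            insts.append(inst.clone(self._bump_iid()))
        else:
            insts.remove(inst)
        return True

    def apply_event(self, event, rng: np.random.Generator) -> None:
        if isinstance(event, Variant):
            self.apply_variant(event, rng)
        elif isinstance(event, CNAEvent):
            self.apply_cna(event, rng)
        elif isinstance(event, AneuploidyEvent):
            self.apply_aneuploidy(event, rng)
        elif isinstance(event, WGDEvent):
            self.apply_wgd()
        else:  # pragma: no cover - defensive
            raise TypeError(f"unknown event type {type(event)!r}")

    # -- queries -------------------------------------------------------------

    def cn(self, chrom: str, pos: int) -> tuple[int, dict[str, int]]:
        """(total copies, per-parental-allele copy counts) at a position."""
        per: dict[str, int] = {"A": 0, "B": 0}
        for inst in self.instances.get(chrom, []):
            if inst.covers(pos):
                per[inst.haplotype] = per.get(inst.haplotype, 0) + 1
        return sum(per.values()), per

    def multiplicity(self, var: Variant) -> int:
        """Number of allele copies in this clone that carry the variant."""
        return sum(
            1 for inst in self.instances.get(var.chrom, [])
            if var.vid in inst.variant_ids
        )

    def locus_total(self, var: Variant) -> int:
        return self.cn(var.chrom, var.pos)[0]

    def has_variant(self, var: Variant) -> bool:
        return self.multiplicity(var) > 0

    def present_variants(self) -> list[Variant]:
        vids: set[int] = set()
        for insts in self.instances.values():
            for inst in insts:
                vids |= inst.variant_ids
        return [self.variants[v] for v in sorted(vids)]

    def segment_table(self):
        """Allele-specific copy-number segments as a DataFrame.

        Columns: chrom, start, end (0-based half-open), total, major, minor.
        Covers each contig completely (zero-copy regions get total 0).
        """
        import pandas as pd

        rows = []
        for chrom, length in self.chrom_lengths.items():
            bps = {0, length}
            for inst in self.instances.get(chrom, []):
                for a, b in inst.intervals:
                    bps.add(a)
                    bps.add(min(b, length))
            edges = sorted(bps)
            prev = None
            for s, e in zip(edges[:-1], edges[1:]):
                total, per = self.cn(chrom, s)
                major, minor = max(per.values()), min(per.values())
                if prev is not None and prev[3:] == (total, major, minor):
                    prev = (chrom, prev[1], e, total, major, minor)
                    rows[-1] = prev
                else:
                    prev = (chrom, s, e, total, major, minor)
                    rows.append(prev)
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "total", "major", "minor"]
        )

    def ploidy(self) -> float:
        """Length-weighted mean total copy number over the genome."""
        seg = self.segment_table()
        lengths = seg["end"] - seg["start"]
        return float((seg["total"] * lengths).sum() / lengths.sum())


# ---------------------------------------------------------------------------
# Simulation operations
# ---------------------------------------------------------------------------


def sample_lognormal_length(
    mean: float, variance: float, multiplier: float, rng: np.random.Generator
) -> int:
    """Draw a lognormal length: ``round(exp(N(mean, variance)) * multiplier)``,
    floored at 1 bp."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    g = rng.normal(mean, math.sqrt(variance))
    return max(1, round(math.exp(g) * multiplier))


def _sample_added_copies(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    g = rng.normal(cfg.cnvcopiesmean, math.sqrt(cfg.cnvcopiesvariance))
    return max(1, round(math.exp(g)))


def _random_alt(ref_base: str, rng: np.random.Generator) -> str:
    i = _BASES.index(ref_base)
    return _BASES[(i + 1 + int(rng.integers(3))) % 4]


def _random_snvs(
    ref: Reference, n: int, rng: np.random.Generator, origin: str,
    used: set[tuple[str, int]], times: bool,
) -> list[Variant]:
    out: list[Variant] = []
    for chrom, pos in ref.random_positions(n, rng):
        if (chrom, pos) in used:
            continue
        base = ref.base(chrom, pos)
        if base not in _BASES:
            continue
        used.add((chrom, pos))
        out.append(Variant(
            chrom=chrom, pos=pos, ref=base, alt=_random_alt(base, rng),
            var_class="SNV", origin=origin,
            time=float(rng.random()) if times else 0.0,
        ))
    return out


def _random_indels(
    ref: Reference, n: int, rng: np.random.Generator, origin: str,
    cfg: SimulationConfig, used: set[tuple[str, int]], times: bool,
) -> list[Variant]:
    out: list[Variant] = []
    for chrom, pos in ref.random_positions(n, rng):
        if (chrom, pos) in used:
            continue
        anchor = ref.base(chrom, pos)
        if anchor not in _BASES:
            continue
        length = sample_lognormal_length(cfg.indmean, cfg.indvariance,
                                         cfg.indmultiply, rng)
        if rng.random() < 0.5:  # insertion
            ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
            ref_a, alt_a, cls = anchor, anchor + ins, "insertion"
        else:  # deletion
            end = min(pos + 1 + length, ref.lengths[chrom])
            if end <= pos + 1:
                continue
            ref_a, alt_a, cls = anchor + ref.fetch(chrom, pos + 1, end), anchor, "deletion"
        used.add((chrom, pos))
        out.append(Variant(
            chrom=chrom, pos=pos, ref=ref_a, alt=alt_a, var_class=cls,
            origin=origin, time=float(rng.random()) if times else 0.0,
        ))
    return out


def simulate_germline_variants(
    cfg: SimulationConfig,
    ref: Reference,
    known: KnownSites | None,
    rng: np.random.Generator,
) -> list[Variant]:
    """Simulate germline SNVs and indels on the reference.

    SNV count is Binomial(genome length, ``snvgermline``); a
    ``dbsnpsnvproportion`` share of them is drawn (position + alleles,
    without replacement) from the known-sites list and the rest placed
    uniformly with a random alternate allele.  Indels are analogous, with
    lognormal lengths.  Each variant is assigned a parental haplotype
    uniformly.
    """
    L = ref.total_length
    n_snv = int(rng.binomial(L, cfg.snvgermline)) if cfg.snvgermline > 0 else 0
    n_ind = int(rng.binomial(L, cfg.indgermline)) if cfg.indgermline > 0 else 0
    if n_snv and cfg.dbsnpsnvproportion > 0 and (known is None or not known.snvs):
        raise ValueError("dbsnpsnvproportion > 0 but no known SNV sites supplied")
    if n_ind and cfg.dbsnpindelproportion > 0 and (known is None or not known.indels):
        raise ValueError("dbsnpindelproportion > 0 but no known indel sites supplied")

    used: set[tuple[str, int]] = set()
    variants: list[Variant] = []

    def from_known(sites: list[tuple[str, int, str, str]], count: int) -> None:
        if count > len(sites):
            logger.warning("requested %d known sites but only %d available",
                           count, len(sites))
            count = len(sites)
        idx = rng.choice(len(sites), size=count, replace=False) if count else []
        for i in idx:
            chrom, pos, ref_a, alt_a = sites[int(i)]
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            cls = ("SNV" if len(ref_a) == len(alt_a) == 1
                   else "insertion" if len(alt_a) > len(ref_a) else "deletion")
            variants.append(Variant(chrom=chrom, pos=pos, ref=ref_a, alt=alt_a,
                                    var_class=cls, origin=ROOT_MARKER))

    n_known_snv = int(rng.binomial(n_snv, cfg.dbsnpsnvproportion)) if n_snv else 0
    from_known(known.snvs if known else [], n_known_snv)
    variants.extend(_random_snvs(ref, n_snv - n_known_snv, rng, ROOT_MARKER,
                                 used, times=False))
    n_known_ind = int(rng.binomial(n_ind, cfg.dbsnpindelproportion)) if n_ind else 0
    from_known(known.indels if known else [], n_known_ind)
    variants.extend(_random_indels(ref, n_ind - n_known_ind, rng, ROOT_MARKER,
                                   cfg, used, times=False))
    haps = rng.integers(0, 2, size=len(variants))
    for var, h in zip(variants, haps):
        var.haplotype = "AB"[int(h)]
    return variants


def _random_cnas(
    ref: Reference, n: int, kind: str, origin: str,
    mean: float, variance: float, multiply: float,
    cfg: SimulationConfig, rng: np.random.Generator,
) -> list[CNAEvent]:
    out: list[CNAEvent] = []
    for chrom in ref.random_contigs(n, rng):
        length = sample_lognormal_length(mean, variance, multiply, rng)
        clen = ref.lengths[chrom]
        start = int(rng.integers(0, clen))
        end = min(start + length, clen)
        if end <= start:
            start, end = max(0, clen - 1), clen
        out.append(CNAEvent(
            chrom=chrom, start=start, end=end, kind=kind,
            added_copies=_sample_added_copies(cfg, rng) if kind == "replication" else 1,
            origin=origin, time=float(rng.random()),
        ))
    return out


def simulate_germline_cnas(
    cfg: SimulationConfig, ref: Reference, rng: np.random.Generator
) -> list[CNAEvent]:
    """Exactly ``cnvrepgermline`` replications and ``cnvdelgermline`` deletions
    with germline lognormal length parameters."""
    events = _random_cnas(ref, cfg.cnvrepgermline, "replication", ROOT_MARKER,
                          cfg.cnvgermlinemean, cfg.cnvgermlinevariance,
                          cfg.cnvgermlinemultiply, cfg, rng)
    events += _random_cnas(ref, cfg.cnvdelgermline, "deletion", ROOT_MARKER,
                           cfg.cnvgermlinemean, cfg.cnvgermlinevariance,
                           cfg.cnvgermlinemultiply, cfg, rng)
    return events


def simulate_somatic_events(
    cfg: SimulationConfig,
    tree: CloneTree,
    ref: Reference,
    rng: np.random.Generator,
) -> dict[str, list]:
    """Distribute the tumour-wide somatic burden over clone-tree branches.

    SNV/indel/CNV totals are split multinomially with branch-weight
    probabilities; ``aneuploid`` single-chromosome events get a uniform clone,
    uniform chromosome and equiprobable gain/loss; with probability
    ``wgdprob`` exactly one WGD is assigned to a uniform clone.  Every event
    carries a uniform timestamp on its branch.
    """
    weights = branch_weights(tree)
    clones = tree.clones
    p = np.array([weights[c] for c in clones])
    snv_counts = rng.multinomial(cfg.snvsomatic_total, p)
    ind_counts = rng.multinomial(cfg.indsomatic_total, p)
    rep_counts = rng.multinomial(cfg.cnvsomatic_rep, p)
    del_counts = rng.multinomial(cfg.cnvsomatic_del, p)

    events: dict[str, list] = {c: [] for c in clones}
    used: set[tuple[str, int]] = set()
    for clone, n_snv, n_ind, n_rep, n_del in zip(
        clones, snv_counts, ind_counts, rep_counts, del_counts
    ):
        events[clone].extend(_random_snvs(ref, int(n_snv), rng, clone, used, times=True))
        events[clone].extend(_random_indels(ref, int(n_ind), rng, clone, cfg,
                                            used, times=True))
        events[clone].extend(_random_cnas(
            ref, int(n_rep), "replication", clone, cfg.cnvsomaticmean,
            cfg.cnvsomaticvariance, cfg.cnvsomaticmultiply, cfg, rng))
        events[clone].extend(_random_cnas(
            ref, int(n_del), "deletion", clone, cfg.cnvsomaticmean,
            cfg.cnvsomaticvariance, cfg.cnvsomaticmultiply, cfg, rng))

    for _ in range(cfg.aneuploid):
        clone = clones[int(rng.integers(len(clones)))]
        events[clone].append(AneuploidyEvent(
            chrom=ref.random_contigs(1, rng)[0],
            gain=bool(rng.random() < 0.5),
            clone=clone, time=float(rng.random()),
        ))
    if rng.random() < cfg.wgdprob:
        clone = clones[int(rng.integers(len(clones)))]
        events[clone].append(WGDEvent(clone=clone, time=float(rng.random())))
    return events


def build_clone_profiles(
    tree: CloneTree,
    germline_variants: Iterable[Variant],
    branch_events: Mapping[str, Sequence],
    ref: Reference,
    rng: np.random.Generator,
    germline_cnas: Iterable[CNAEvent] = (),
) -> dict[str, CloneGenomeProfile]:
    """Propagate events down the clone tree into per-clone genome profiles.

    The germline profile is built first (variants, then germline CNAs in
    timestamp order); each clone copies its parent's profile and applies its
    own branch events in timestamp order, so every clone inherits all
    ancestor events.  The returned map includes a ``"germline"`` entry.
    """
    unknown = set(branch_events) - set(tree.clones)
    if unknown:
        raise KeyError(f"branch events reference unknown clones: {sorted(unknown)}")
    base = CloneGenomeProfile(ROOT_MARKER, ref.lengths)
    for var in germline_variants:
        base.apply_variant(var, rng)
    for ev in sorted(germline_cnas, key=lambda e: e.time):
        base.apply_cna(ev, rng)
    profiles: dict[str, CloneGenomeProfile] = {ROOT_MARKER: base}
    for clone in tree.preorder():
        parent = tree.parent(clone)
        profile = profiles[parent].copy(clone)
        for ev in sorted(branch_events.get(clone, ()), key=lambda e: e.time):
            profile.apply_event(ev, rng)
        profiles[clone] = profile
    return profiles
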