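"""Readers/writers for the interchange formats and deconvolution inputs.

Variants travel as VCF (read via cyvcf2, written via pysam), regions as BED,
segment/truth/CCF tables as TSV, references as FASTA.  Internally the package
uses 0-based half-open coordinates; VCF-facing tables (truth, calls, CCF)
carry 1-based positions.  Readers reject rather than silently coerce, and
log counts of read/dropped records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .genome_sim import KnownSites, Reference

logger = logging.getLogger(__name__)

__all__ = [
    "CallSet",
    "SegmentProfile",
    "left_normalize",
    "read_caller_vcf",
    "read_known_sites",
    "read_segments",
    "write_segments",
    "prepare_deconv_input",
    "read_bed",
    "read_truth_table",
    "write_truth_table",
    "read_ccf_table",
    "write_ccf_table",
    "write_reference_fasta",
    "write_known_sites_vcf",
    "write_truth_vcf",
    "write_observations_vcf",
]

KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# Call sets
# ---------------------------------------------------------------------------


class CallSet:
    """A set of point-mutation calls keyed by (chrom, pos, ref, alt).

    Positions are 1-based.  Optional columns: ``score`` (NaN when unscored —
    unscored calls rank below all scored calls), ``filter``, ``ref_count``,
    ``alt_count``, ``vaf``.
    """

    def __init__(self, df: pd.DataFrame, label: str = "calls"):
        missing = [c for c in KEY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"call table missing columns {missing}")
        df = df.copy().reset_index(drop=True)
        if "score" not in df.columns:
            df["score"] = np.nan
        if "vaf" not in df.columns and {"ref_count", "alt_count"} <= set(df.columns):
            depth = df["ref_count"] + df["alt_count"]
            df["vaf"] = np.where(depth > 0, df["alt_count"] / depth, np.nan)
        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            logger.warning("%s: %d duplicate call keys collapsed (best score kept)",
                           label, int(dup.sum()))
            df = (df.sort_values("score", ascending=False, na_position="last")
                    .drop_duplicates(subset=KEY_COLUMNS)
                    .reset_index(drop=True))
        self.df = df
        self.label = label

    @property
    def keys(self) -> set[tuple]:
        return set(map(tuple, self.df[KEY_COLUMNS].itertuples(index=False, name=None)))

    @property
    def scored(self) -> bool:
        return bool(self.df["score"].notna().any())

    def __len__(self) -> int:
        return len(self.df)

    def restricted(self, regions: Mapping[str, list[tuple[int, int]]]) -> "CallSet":
        mask = _in_regions(self.df, regions)
        return CallSet(self.df[mask], label=self.label)


def _in_regions(df: pd.DataFrame, regions: Mapping[str, list[tuple[int, int]]]):
    keep = np.zeros(len(df), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(df["chrom"], df["pos"])):
        for s, e in regions.get(chrom, ()):
            if s <= pos - 1 < e:
                keep[i] = True
                break
    return keep


# ---------------------------------------------------------------------------
# Normalisation and VCF reading
# ---------------------------------------------------------------------------


def left_normalize(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    fetch: Callable[[str, int, int], str] | None = None,
) -> tuple[str, int, str, str]:
    """Left-normalise a variant (1-based ``pos``; VCF allele convention).

    Trims shared trailing/leading bases (keeping the indel anchor) and, when
    a reference ``fetch(chrom, start0, end0)`` is supplied, left-shifts
    indels until uniquely placed.
    """
    changed = True
    while changed:
        changed = False
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        elif (fetch is not None and pos > 1 and ref[-1] == alt[-1]
              and (len(ref) == 1 or len(alt) == 1) and len(ref) != len(alt)):
            prev = fetch(chrom, pos - 2, pos - 1)
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def read_caller_vcf(
    path: str,
    score_field: str | None = None,
    pass_only: bool = False,
    reference: Reference | None = None,
    label: str | None = None,
) -> CallSet:
    """Read a caller's VCF into a :class:`CallSet`.

    Multiallelic records are split; indels are left-normalised (against the
    reference when given).  ``score_field`` names an INFO field, or
    ``"QUAL"``; missing scores become NaN (rank-lowest).  With ``pass_only``
    only FILTER PASS / '.' records are kept.  Allele depths are taken from
    the first sample's AD when present.
    """
    from cyvcf2 import VCF

    fetch = reference.fetch if reference is not None else None
    rows = []
    n_read = n_dropped = 0
    vcf = VCF(str(path))
    for line_no, v in enumerate(vcf, start=1):
        n_read += 1
        if pass_only and v.FILTER is not None:
            n_dropped += 1
            continue
        try:
            score = np.nan
            if score_field == "QUAL":
                score = v.QUAL if v.QUAL is not None else np.nan
            elif score_field is not None:
                raw = v.INFO.get(score_field)
                score = float(raw) if raw is not None else np.nan
            try:
                ad = v.format("AD")
            except KeyError:
                ad = None
            for i, alt in enumerate(v.ALT):
                if alt is None or alt in ("<NON_REF>", "*"):
                    continue
                chrom, pos, ref_a, alt_a = left_normalize(
                    v.CHROM, v.POS, v.REF, alt, fetch
                )
                ref_count = alt_count = np.nan
                if ad is not None and ad.shape[1] > i + 1:
                    ref_count = int(ad[0][0])
                    alt_count = int(ad[0][i + 1])
                rows.append((chrom, pos, ref_a, alt_a, score,
                             v.FILTER or "PASS", ref_count, alt_count))
        except Exception as exc:
            raise ValueError(f"{path}: unreadable record #{line_no}: {exc}") from exc
    vcf.close()
    logger.info("%s: read %d records, dropped %d by FILTER", path, n_read, n_dropped)
    df = pd.DataFrame(rows, columns=KEY_COLUMNS + ["score", "filter",
                                                   "ref_count", "alt_count"])
    return CallSet(df, label=label or str(path))


def read_known_sites(path: str) -> KnownSites:
    """Read a known-germline-sites VCF into a :class:`KnownSites`."""
    from cyvcf2 import VCF

    known = KnownSites()
    vcf = VCF(str(path))
    for v in vcf:
        for alt in v.ALT:
            site = (v.CHROM, v.POS - 1, v.REF, alt)
            if len(v.REF) == 1 and len(alt) == 1:
                known.snvs.append(site)
            else:
                known.indels.append(site)
    vcf.close()
    return known


# ---------------------------------------------------------------------------
# Segment profiles
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["chrom", "start", "end", "total_cn", "major_cn",
                   "minor_cn", "cellular_fraction"]


@dataclass
class SegmentProfile:
    """Allele-specific copy-number segments plus purity/ploidy estimates.

    ``segments`` columns: chrom, start, end (0-based half-open), total_cn,
    major_cn, minor_cn, cellular_fraction.  Segments must be non-overlapping
    per chromosome; major/minor must sum to total where all three are present.
    """

    segments: pd.DataFrame
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        df = self.segments.copy().reset_index(drop=True)
        missing = [c for c in SEGMENT_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"segment table missing columns {missing}")
        for col in ("major_cn", "minor_cn"):
            if col not in df.columns:
                df[col] = np.nan
        if "cellular_fraction" not in df.columns:
            df["cellular_fraction"] = 1.0
        if (df["start"] >= df["end"]).any():
            raise ValueError("segments require start < end")
        cf = df["cellular_fraction"]
        if ((cf < 0) | (cf > 1)).any():
            raise ValueError("cellular_fraction must be in [0, 1]")
        swapped = df["major_cn"] < df["minor_cn"]
        if swapped.any():
            logger.warning("%d segments with major < minor: swapped", int(swapped.sum()))
            maj = df["major_cn"].where(~swapped, df["minor_cn"])
            mnr = df["minor_cn"].where(~swapped, df["major_cn"])
            df["major_cn"], df["minor_cn"] = maj, mnr
        both = df["major_cn"].notna() & df["minor_cn"].notna() & df["total_cn"].notna()
        bad = both & ((df["major_cn"] + df["minor_cn"] - df["total_cn"]).abs() > 1e-9)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} segments where major + minor != total"
            )
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError(f"overlapping segments on {chrom}")
        self.segments = df[SEGMENT_COLUMNS]
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be > 0")


def read_segments(path: str) -> SegmentProfile:
    """Read a segment TSV with ``##purity=`` / ``##ploidy=`` header lines."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            key, _, value = line[2:].strip().partition("=")
            meta[key] = float(value)
    if "purity" not in meta or "ploidy" not in meta:
        raise ValueError(f"{path}: missing ##purity= / ##ploidy= header metadata")
    df = pd.read_csv(path, sep="\t", comment="#")
    return SegmentProfile(segments=df, purity=meta["purity"], ploidy=meta["ploidy"])


def write_segments(profile: SegmentProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"##purity={profile.purity:g}\n##ploidy={profile.ploidy:g}\n")
        profile.segments.to_csv(fh, sep="\t", index=False)


def prepare_deconv_input(
    calls: CallSet,
    seg: SegmentProfile,
    cf_threshold: float = 0.5,
) -> pd.DataFrame:
    """Annotate calls with allele-specific copy numbers for CCF deconvolution.

    Each variant takes its containing segment's major/minor copy number when
    the segment's cellular fraction is >= ``cf_threshold`` (inclusive);
    otherwise — including outside all segments — it is assigned the neutral
    1/1 state.  Output columns: chrom, pos, ref, alt, ref_count, alt_count,
    major_cn, minor_cn, normal_cn.
    """
    df = calls.df
    if "alt_count" not in df.columns or df["alt_count"].isna().all():
        raise ValueError("calls carry no allele depths")
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("start") for c, g in seg.segments.groupby("chrom")
    }
    majors, minors = [], []
    warned: set[str] = set()
    for chrom, pos in zip(df["chrom"], df["pos"]):
        maj = mnr = 1.0
        grp = by_chrom.get(str(chrom))
        if grp is None:
            if chrom not in warned:
                logger.warning("contig %s absent from segments: defaulting to 1/1", chrom)
                warned.add(str(chrom))
        else:
            pos0 = pos - 1
            idx = grp["start"].searchsorted(pos0, side="right") - 1
            if idx >= 0:
                row = grp.iloc[idx]
                if (pos0 < row["end"] and row["cellular_fraction"] >= cf_threshold
                        and pd.notna(row["major_cn"]) and pd.notna(row["minor_cn"])):
                    maj, mnr = float(row["major_cn"]), float(row["minor_cn"])
        majors.append(maj)
        minors.append(mnr)
    out = df[KEY_COLUMNS + ["ref_count", "alt_count"]].copy()
    out["major_cn"] = majors
    out["minor_cn"] = minors
    out["normal_cn"] = 2
    return out


# ---------------------------------------------------------------------------
# BED / TSV tables
# ---------------------------------------------------------------------------


def read_bed(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into {chrom: [(start, end), ...]} (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    regions: dict[str, list[tuple[int, int]]] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        regions[str(chrom)] = sorted(zip(grp["start"].astype(int),
                                         grp["end"].astype(int)))
    return regions


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ccf_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ccf_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in KEY_COLUMNS + ["ccf"] if c not in df.columns]
    if missing:
        raise ValueError(f"CCF table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# FASTA / VCF writers
# ---------------------------------------------------------------------------


def write_reference_fasta(ref: Reference, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _vcf_header(contigs: Mapping[str, int]):
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    return header


def write_known_sites_vcf(known: KnownSites, contigs: Mapping[str, int],
                          path: str) -> None:
    import pysam

    header = _vcf_header(contigs)
    sites = sorted(known.snvs + known.indels)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, pos, ref_a, alt_a in sites:
            rec = out.new_record(contig=chrom, start=pos, alleles=(ref_a, alt_a))
            out.write(rec)


def write_truth_vcf(truth: pd.DataFrame, contigs: Mapping[str, int],
                    path: str) -> None:
    """Write a ground-truth VCF with CCF/expected VAF/origin in INFO."""
    import pysam

    header = _vcf_header(contigs)
    header.info.add("ORIGIN", 1, "String", "Clone of origin")
    header.info.add("CCF", 1, "Float", "True cancer cell fraction")
    header.info.add("EVAF", 1, "Float", "Expected bulk variant allele frequency")
    header.info.add("MCOPY", 1, "Integer", "Mutated copies in origin clone")
    header.info.add("TOTCOPY", 1, "Integer", "Locus total copies in origin clone")
    df = truth.sort_values(["chrom", "pos"])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in df.itertuples(index=False):
            rec = out.new_record(contig=row.chrom, start=int(row.pos) - 1,
                                 alleles=(row.ref, row.alt))
            rec.info["ORIGIN"] = str(row.origin_clone)
            rec.info["CCF"] = float(row.true_ccf)
            if not np.isnan(row.expected_vaf):
                rec.info["EVAF"] = float(row.expected_vaf)
            rec.info["MCOPY"] = int(row.m)
            rec.info["TOTCOPY"] = int(row.n)
            out.write(rec)


def write_observations_vcf(observations: pd.DataFrame, contigs: Mapping[str, int],
                           path: str, sample_id: str = "TUMOR") -> None:
    """Write sampled per-variant observations as a single-sample VCF with AD/DP."""
    import pysam

    header = _vcf_header(contigs)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample_id)
    df = observations.sort_values(["chrom", "pos"])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in df.itertuples(index=False):
            rec = out.new_record(contig=row.chrom, start=int(row.pos) - 1,
                                 alleles=(row.ref, row.alt))
            depth, alt = int(row.depth), int(row.alt_count)
            rec.samples[sample_id]["DP"] = depth
            rec.samples[sample_id]["AD"] = (depth - alt, alt)
            out.write(rec)
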