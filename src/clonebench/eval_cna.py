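"""Scoring of copy-number calls: purity/ploidy accuracy and binned agreement.

Ploidy estimates are classified as accurate / halved / doubled / wrong, where
"halved" and "doubled" capture callers that miss (or hallucinate) a
whole-genome duplication but are otherwise right.  Copy-number tracks are
compared on a fixed genome bin grid with length-weighted means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .clone_tree import BulkComposition
from .genome_sim import CloneGenomeProfile
from .io_formats import SegmentProfile

logger = logging.getLogger(__name__)

__all__ = [
    "CopyNumberMatrix",
    "Agreement",
    "ploidy_class",
    "purity_error",
    "bin_copy_numbers",
    "copy_number_agreement",
    "plot_copy_number_heatmap",
]


def ploidy_class(pred: float, true: float, tol: float = 0.3) -> str:
    """Classify a ploidy estimate: accurate, halved, doubled or wrong.

    "halved" (pred ~ true/2) flags a missed whole-genome duplication,
    "doubled" (pred ~ 2*true) a spurious one; rules are tried in the order
    accurate, halved, doubled.
    """
    if pred <= 0 or true <= 0:
        raise ValueError("ploidy must be positive")
    if abs(pred - true) <= tol:
        return "accurate"
    if abs(pred - true / 2) <= tol:
        return "halved"
    if abs(pred - 2 * true) <= tol:
        return "doubled"
    return "wrong"


def purity_error(pred: float, true: float) -> float:
    """Absolute purity estimation error; both values must be in (0, 1]."""
    for name, v in (("pred", pred), ("true", true)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} purity must be in (0, 1], got {v}")
    return abs(pred - true)


@dataclass
class CopyNumberMatrix:
    """Binned copy-number tracks on a fixed genome grid.

    ``bins``: DataFrame (chrom, start, end); ``tracks``: map from track name
    to a DataFrame (total, major, minor) aligned to the bins, NaN = missing.
    """

    bins: pd.DataFrame
    tracks: dict[str, pd.DataFrame]

    def same_grid(self, other: "CopyNumberMatrix") -> bool:
        return self.bins.reset_index(drop=True).equals(
            other.bins.reset_index(drop=True))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (chrom, start, end, track, total, major, minor)."""
        frames = []
        for name, vals in self.tracks.items():
            df = pd.concat([self.bins.reset_index(drop=True),
                            vals.reset_index(drop=True)], axis=1)
            df.insert(3, "track", name)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _make_bins(genome: Mapping[str, int], bin_width: int) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.items():
        for start in range(0, length, bin_width):
            rows.append((chrom, start, min(start + bin_width, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _bin_segments(segments: pd.DataFrame, bins: pd.DataFrame,
                  cols: Mapping[str, str]) -> pd.DataFrame:
    """Length-weighted mean of segment values per bin (NaN when uncovered)."""
    out = {name: np.full(len(bins), np.nan) for name in cols}
    for chrom, grp in bins.groupby("chrom", sort=False):
        seg = segments[segments["chrom"] == chrom]
        if seg.empty:
            continue
        s_start = seg["start"].to_numpy()
        s_end = seg["end"].to_numpy()
        vals = {name: seg[col].to_numpy(dtype=float) for name, col in cols.items()}
        for i, b in zip(grp.index, grp.itertuples(index=False)):
            overlap = np.minimum(s_end, b.end) - np.maximum(s_start, b.start)
            w = np.clip(overlap, 0, None).astype(float)
            total_w = w.sum()
            if total_w <= 0:
                continue
            for name in cols:
                v = vals[name]
                ok = w > 0
                if np.isnan(v[ok]).any():
                    continue
                out[name][i] = float((w[ok] * v[ok]).sum() / total_w)
    return pd.DataFrame(out)


def bin_copy_numbers(
    source: SegmentProfile | Mapping[str, CloneGenomeProfile],
    genome: Mapping[str, int],
    bin_width: int,
    composition: BulkComposition | None = None,
    track: str = "pred",
) -> CopyNumberMatrix:
    """Bin copy-number values onto a fixed grid.

    A :class:`SegmentProfile` yields a single predicted track.  A map of
    clone genome profiles yields one true track per clone plus, when a
    composition is given, a ``"bulk"`` track: the tumour-proportion-weighted
    mean across clones (purity-independent).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    bins = _make_bins(genome, bin_width)
    cols = {"total": "total_cn", "major": "major_cn", "minor": "minor_cn"}
    if isinstance(source, SegmentProfile):
        return CopyNumberMatrix(bins, {track: _bin_segments(source.segments, bins, cols)})
    tracks: dict[str, pd.DataFrame] = {}
    clone_cols = {"total": "total", "major": "major", "minor": "minor"}
    for clone, profile in source.items():
        tracks[clone] = _bin_segments(profile.segment_table(), bins, clone_cols)
    if composition is not None:
        proportions = composition.tumour_proportions
        missing = [c for c in proportions if c not in tracks]
        if missing:
            raise KeyError(f"composition clones without profiles: {missing}")
        bulk = sum(proportions[c] * tracks[c] for c in proportions)
        tracks["bulk"] = bulk
    return CopyNumberMatrix(bins, tracks)


class Agreement(NamedTuple):
    mae_total: float
    mae_minor: float
    exact_fraction: float


def copy_number_agreement(
    pred: CopyNumberMatrix,
    true: CopyNumberMatrix,
    pred_track: str = "pred",
    true_track: str = "bulk",
) -> Agreement:
    """Agreement between a predicted and a true binned track.

    Mean absolute error of total and minor copy number, and the fraction of
    bins whose totals match exactly after rounding; all over bins non-missing
    in both tracks.
    """
    if not pred.same_grid(true):
        raise ValueError("copy-number matrices are on different bin grids")
    p = pred.tracks[pred_track]
    t = true.tracks[true_track]
    ok_total = p["total"].notna() & t["total"].notna()
    if not ok_total.any():
        raise ValueError("no bins covered in both tracks")
    dt = (p["total"][ok_total] - t["total"][ok_total]).abs()
    ok_minor = p["minor"].notna() & t["minor"].notna()
    dm = (p["minor"][ok_minor] - t["minor"][ok_minor]).abs()
    exact = (p["total"][ok_total].round() == t["total"][ok_total].round()).mean()
    return Agreement(float(dt.mean()),
                     float(dm.mean()) if ok_minor.any() else float("nan"),
                     float(exact))


def plot_copy_number_heatmap(matrix: CopyNumberMatrix, path: str,
                             value: str = "total", vmax: float | None = None):
    """Render tracks-by-bins heatmap of copy number (gains/losses along the
    genome) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(matrix.tracks)
    data = np.vstack([matrix.tracks[n][value].to_numpy(dtype=float) for n in names])
    fig, ax = plt.subplots(figsize=(10, 0.6 * len(names) + 1.5))
    im = ax.imshow(data, aspect="auto", interpolation="nearest",
                   cmap="RdBu_r", vmin=0, vmax=vmax or np.nanmax(data))
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("genome bin")
    fig.colorbar(im, ax=ax, label=f"{value} copy number")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
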