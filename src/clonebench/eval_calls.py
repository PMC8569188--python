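"""Scoring of somatic point-mutation call sets against ground truth.

Matching is allele-exact on (chrom, pos, ref, alt) after left-normalisation;
when target regions are supplied, both truth and calls are restricted to them
before matching, so truth outside the regions is removed from the recall
denominator rather than counted as missed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .io_formats import KEY_COLUMNS, CallSet, _in_regions

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "PRF",
    "match_calls",
    "precision_recall_f1",
    "pr_curve",
    "stratified_metrics",
    "callset_union",
    "callset_intersect",
]


@dataclass
class MatchResult:
    """TP/FP/FN key sets plus the (region-restricted) annotated tables."""

    tp: set
    fp: set
    fn: set
    calls: pd.DataFrame  # restricted calls + is_tp column
    truth: pd.DataFrame  # restricted truth + called column

    @property
    def n_truth(self) -> int:
        return len(self.tp) + len(self.fn)


class PRF(NamedTuple):
    precision: float
    recall: float
    f1: float


def _truth_keys(truth: pd.DataFrame) -> set[tuple]:
    return set(map(tuple, truth[KEY_COLUMNS].itertuples(index=False, name=None)))


def match_calls(
    truth: pd.DataFrame,
    calls: CallSet,
    regions: Mapping[str, list[tuple[int, int]]] | None = None,
) -> MatchResult:
    """Match calls to truth exactly on (chrom, pos, ref, alt).

    ``truth`` needs columns chrom, pos (1-based), ref, alt (e.g. the table
    from :func:`clonebench.bulk_sim.compose_bulk`).
    """
    truth = truth.copy().reset_index(drop=True)
    t_contigs = set(truth["chrom"].astype(str))
    c_contigs = set(calls.df["chrom"].astype(str))
    if t_contigs and c_contigs and not (t_contigs & c_contigs):
        raise ValueError(
            "no shared contigs between truth and calls — naming mismatch? "
            f"truth: {sorted(t_contigs)}, calls: {sorted(c_contigs)}"
        )
    only = c_contigs - t_contigs
    if only:
        logger.warning("call contigs absent from truth: %s", sorted(only))
    calls_df = calls.df
    if regions is not None:
        truth = truth[_in_regions(truth, regions)].reset_index(drop=True)
        calls_df = calls_df[_in_regions(calls_df, regions)].reset_index(drop=True)
    truth_keys = _truth_keys(truth)
    call_keys = set(map(tuple,
                        calls_df[KEY_COLUMNS].itertuples(index=False, name=None)))
    tp = truth_keys & call_keys
    calls_df = calls_df.copy()
    calls_df["is_tp"] = [
        tuple(k) in tp
        for k in calls_df[KEY_COLUMNS].itertuples(index=False, name=None)
    ]
    truth["called"] = [
        tuple(k) in tp
        for k in truth[KEY_COLUMNS].itertuples(index=False, name=None)
    ]
    return MatchResult(tp=tp, fp=call_keys - truth_keys, fn=truth_keys - call_keys,
                       calls=calls_df, truth=truth)


def precision_recall_f1(match: MatchResult) -> PRF:
    """Precision, recall and F1; zero-denominator cases return 0 by convention."""
    tp, fp, fn = len(match.tp), len(match.fp), len(match.fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return PRF(precision, recall, f1)


def pr_curve(match: MatchResult) -> pd.DataFrame:
    """Precision–recall points, one per distinct score threshold (descending).

    Ties are grouped; unscored calls rank below all scored calls, so the last
    point equals the un-thresholded precision/recall.  Returns an empty frame
    (with a warning) when no call is scored.
    """
    calls = match.calls
    if calls.empty or calls["score"].isna().all():
        logger.warning("no scored calls: PR curve is empty")
        return pd.DataFrame(columns=["threshold", "recall", "precision"])
    scores = calls["score"].fillna(-np.inf).to_numpy(dtype=float)
    is_tp = calls["is_tp"].to_numpy(dtype=bool)
    n_truth = match.n_truth
    order = np.argsort(-scores, kind="stable")
    scores, is_tp = scores[order], is_tp[order]
    rows = []
    for threshold in np.unique(scores)[::-1]:
        kept = scores >= threshold
        n_tp = int(is_tp[kept].sum())
        n_calls = int(kept.sum())
        rows.append((threshold,
                     n_tp / n_truth if n_truth else 0.0,
                     n_tp / n_calls if n_calls else 0.0))
    return pd.DataFrame(rows, columns=["threshold", "recall", "precision"])


def stratified_metrics(
    match: MatchResult,
    bins: np.ndarray | list[float],
    truth_vaf_col: str = "expected_vaf",
    call_vaf_col: str = "vaf",
) -> pd.DataFrame:
    """Per-VAF-bin recall (over truth, by true VAF) and precision (over calls,
    by called VAF).  Empty bins are NaN, not 0."""
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("bins must be a 1-D array of at least two edges")
    rows = []
    t_vaf = match.truth[truth_vaf_col].to_numpy(dtype=float)
    c_vaf = (match.calls[call_vaf_col].to_numpy(dtype=float)
             if call_vaf_col in match.calls.columns and not match.calls.empty
             else np.array([]))
    called = match.truth["called"].to_numpy(dtype=bool)
    is_tp = match.calls["is_tp"].to_numpy(dtype=bool) if len(match.calls) else np.array([], bool)
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        t_in = (t_vaf >= lo) & ((t_vaf <= hi) if last else (t_vaf < hi))
        c_in = (c_vaf >= lo) & ((c_vaf <= hi) if last else (c_vaf < hi))
        recall = called[t_in].mean() if t_in.any() else np.nan
        precision = is_tp[c_in].mean() if c_in.any() else np.nan
        rows.append((lo, hi, int(t_in.sum()), recall, int(c_in.sum()), precision))
    return pd.DataFrame(rows, columns=["vaf_lo", "vaf_hi", "n_truth", "recall",
                                       "n_calls", "precision"])


def _merge(a: CallSet, b: CallSet, keys: set, agg, label: str) -> CallSet:
    frames = [a.df, b.df]
    df = pd.concat(frames, ignore_index=True)
    df = df[[tuple(k) in keys
             for k in df[KEY_COLUMNS].itertuples(index=False, name=None)]]
    if df.empty:
        return CallSet(pd.DataFrame(columns=KEY_COLUMNS + ["score"]), label=label)
    score = df.groupby(KEY_COLUMNS, dropna=False)["score"].agg(agg).rename("score")
    out = (df.drop(columns=["score"])
             .drop_duplicates(subset=KEY_COLUMNS)
             .merge(score.reset_index(), on=KEY_COLUMNS, how="left"))
    return CallSet(out, label=label)


def callset_union(a: CallSet, b: CallSet) -> CallSet:
    """Set union on keys; a key present in both keeps the max score."""
    return _merge(a, b, a.keys | b.keys, "max", f"union({a.label},{b.label})")


def callset_intersect(a: CallSet, b: CallSet) -> CallSet:
    """Set intersection on keys; each kept key takes the min score."""
    return _merge(a, b, a.keys & b.keys, "min", f"intersect({a.label},{b.label})")
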