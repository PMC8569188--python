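"""Cancer-cell-fraction evaluation: baselines, MADif and clustering accuracy.

The headline metric is MADif: for each sample the mean absolute difference
between true and estimated CCFs over called true variants, averaged with
equal weight across samples so that samples with many variants do not
dominate:

    MADif = (1/n) * sum_i [ sum_j |T_ij - E_ij| / m_i ]

Two simplistic baselines anchor the comparisons: "doubled VAFs"
(CCF = min(2*VAF / purity, 1), i.e. assuming a purely heterozygous diploid
genome) for non-clustered estimates, and K-means (k = 3) on the doubled VAFs
for clustered ones.  Clustering accuracy is reported as the adjusted Rand
index against the true partition (variants sharing an origin clone share a
label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .eval_calls import MatchResult
from .io_formats import KEY_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "CCFComparisonSet",
    "ClusterAssignment",
    "doubled_vaf_baseline",
    "kmeans_baseline",
    "madif",
    "adjusted_rand",
    "evaluate_ccf_pipeline",
]


@dataclass
class CCFComparisonSet:
    """Paired true/estimated CCFs over called true variants, per sample."""

    samples: list[tuple[str, np.ndarray, np.ndarray]] = field(default_factory=list)

    def add_sample(self, name: str, true_ccf: Sequence[float],
                   est_ccf: Sequence[float]) -> None:
        t = np.asarray(true_ccf, dtype=float)
        e = np.asarray(est_ccf, dtype=float)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("true and estimated CCFs must be equal-length vectors")
        if t.size == 0:
            raise ValueError(f"sample {name!r} has no paired variants")
        if not (np.isfinite(t).all() and np.isfinite(e).all()):
            raise ValueError(f"sample {name!r} has non-finite CCFs")
        self.samples.append((name, t, e))

    @property
    def n(self) -> int:
        return len(self.samples)

    def madif(self) -> float:
        return madif(self)


@dataclass
class ClusterAssignment:
    """Per-variant cluster labels with per-cluster CCFs.

    ``assigned_ccf[i]`` is the CCF of variant *i*'s cluster.
    """

    labels: np.ndarray
    cluster_ccfs: np.ndarray
    assigned_ccf: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.cluster_ccfs = np.asarray(self.cluster_ccfs, dtype=float)
        self.assigned_ccf = np.asarray(self.assigned_ccf, dtype=float)
        if not np.allclose(self.assigned_ccf, self.cluster_ccfs[self.labels]):
            raise ValueError("assigned CCFs do not match cluster CCFs")


def doubled_vaf_baseline(vaf, purity: float):
    """Baseline CCF estimate: ``min(2 * vaf / purity, 1)``.

    Assumes every variant is heterozygous on a diploid background.  Accepts a
    scalar or array of VAFs.
    """
    if purity <= 0 or purity > 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    v = np.asarray(vaf, dtype=float)
    if np.nanmin(v, initial=0) < 0 or np.nanmax(v, initial=0) > 1:
        raise ValueError("VAFs must be in [0, 1]")
    out = np.minimum(2 * v / purity, 1.0)
    return float(out) if np.isscalar(vaf) else out


def kmeans_baseline(ccfs: Sequence[float], k: int = 3, seed: int = 0,
                    n_restarts: int = 10) -> ClusterAssignment:
    """K-means clustering of one-dimensional CCFs (baseline, default k = 3).

    Cluster CCF is the cluster mean.  When fewer distinct values than ``k``
    exist, k is reduced with a warning.
    """
    x = np.asarray(ccfs, dtype=float).reshape(-1, 1)
    if x.size == 0:
        raise ValueError("no CCFs to cluster")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_unique = len(np.unique(x))
    if n_unique < k:
        logger.warning("only %d distinct CCF values; reducing k from %d",
                       n_unique, k)
        k = n_unique
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(x)
    centers = km.cluster_centers_.ravel()
    labels = km.labels_
    return ClusterAssignment(labels=labels, cluster_ccfs=centers,
                             assigned_ccf=centers[labels])


def madif(cmp: CCFComparisonSet | Sequence[tuple[Sequence[float], Sequence[float]]]) -> float:
    """Equal-sample-weight mean absolute difference of true vs estimated CCFs."""
    if isinstance(cmp, CCFComparisonSet):
        pairs = [(t, e) for _, t, e in cmp.samples]
    else:
        pairs = [(np.asarray(t, dtype=float), np.asarray(e, dtype=float))
                 for t, e in cmp]
    if not pairs:
        raise ValueError("MADif needs at least one sample")
    per_sample = []
    for t, e in pairs:
        if len(t) == 0:
            raise ValueError("MADif is undefined for a sample with no variants")
        per_sample.append(float(np.mean(np.abs(np.asarray(t) - np.asarray(e)))))
    return float(np.mean(per_sample))


def adjusted_rand(labels_true: Sequence, labels_pred: Sequence) -> float:
    """Adjusted Rand index between two partitions of the same variants."""
    a, b = list(labels_true), list(labels_pred)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def evaluate_ccf_pipeline(
    truth: pd.DataFrame,
    estimates: pd.DataFrame,
    match: MatchResult,
    clusters: ClusterAssignment | None = None,
    sample_id: str = "sample",
) -> dict:
    """Score one sample's CCF estimates against truth over true-positive calls.

    ``truth`` needs chrom/pos/ref/alt/true_ccf/origin_clone; ``estimates``
    chrom/pos/ref/alt/ccf (one row per call, the order ``clusters`` is aligned
    to).  Reports MADif of the non-clustered estimates and, when a cluster
    assignment is given, MADif over assigned cluster CCFs plus the adjusted
    Rand index against origin-clone labels.
    """
    t_idx = truth.set_index(KEY_COLUMNS)
    keys = [tuple(k) for k in
            estimates[KEY_COLUMNS].itertuples(index=False, name=None)]
    in_tp = np.array([k in match.tp for k in keys])
    missing_tp = match.tp - set(keys)
    if missing_tp:
        logger.warning("%d true-positive calls missing from the CCF table",
                       len(missing_tp))
    if not in_tp.any():
        raise ValueError("no true-positive calls with CCF estimates")
    tp_keys = [k for k, ok in zip(keys, in_tp) if ok]
    true_vals = t_idx.loc[tp_keys, "true_ccf"].to_numpy(dtype=float)
    est_vals = estimates.loc[in_tp, "ccf"].to_numpy(dtype=float)
    ok = np.isfinite(true_vals) & np.isfinite(est_vals)
    if not ok.all():
        logger.warning("dropping %d pairs with non-finite CCFs", int((~ok).sum()))
    cmp = CCFComparisonSet()
    cmp.add_sample(sample_id, true_vals[ok], est_vals[ok])
    report = {
        "sample": sample_id,
        "n_pairs": int(ok.sum()),
        "madif": cmp.madif(),
    }
    if clusters is not None:
        if len(clusters.labels) != len(estimates):
            raise ValueError("cluster assignment not aligned to the CCF table")
        assigned = clusters.assigned_ccf[in_tp][ok]
        cl_cmp = CCFComparisonSet()
        cl_cmp.add_sample(sample_id, true_vals[ok], assigned)
        true_labels = t_idx.loc[tp_keys, "origin_clone"].to_numpy()[ok]
        pred_labels = clusters.labels[in_tp][ok]
        report["madif_clustered"] = cl_cmp.madif()
        report["ari"] = adjusted_rand(list(true_labels), list(pred_labels))
    return report
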