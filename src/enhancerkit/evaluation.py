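"""Evaluation surfaces: PCC / delta-PCC, K-means comparison, PPV scans,
control rejection, and the two baseline comparisons for the activity task.

The headline classifier metric is the positive predictive value
PPV = TP / (TP + FP) at a score threshold, reported as the maximum over a
threshold grid subject to a minimum number of predicted positives — a
precision-first criterion suited to selecting a handful of designs for
low-throughput in vivo validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans


class EmptySelectionError(ValueError):
    """No region passed the z-score filter."""


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance; PCC undefined", stacklevel=3)
        return np.nan
    return float(stats.pearsonr(a, b).statistic)


def regression_metrics(
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> dict:
    """Per-tissue PCC plus delta-PCC on tissue-pair differences.

    ``observed`` / ``predicted``: aligned region x tissue matrices.  The
    delta-PCC for a pair (A, B) correlates obs_A - obs_B with pred_A -
    pred_B, emphasizing performance at tissue-specific regions.
    """
    if list(observed.columns) != list(predicted.columns) or len(observed) != len(predicted):
        raise ValueError("observed and predicted must be aligned")
    tissues = list(observed.columns)
    if pairs is None:
        pairs = list(combinations(tissues, 2))
    out = {"pcc": {}, "delta_pcc": {}}
    for t in tissues:
        out["pcc"][t] = _pcc(observed[t].to_numpy(), predicted[t].to_numpy())
    for a, b in pairs:
        out["delta_pcc"][f"{a}-{b}"] = _pcc(
            (observed[a] - observed[b]).to_numpy(), (predicted[a] - predicted[b]).to_numpy()
        )
    return out


def kmeans_clusters(
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    k: int = 6,
    z_threshold: float = 1.0,
    seed: int = 0,
) -> dict:
    """K-means on z-scored observed values; predicted values are assigned to
    the *observed* centroids (no re-fitting).

    Only regions with a z-score > ``z_threshold`` in at least one tissue
    enter the clustering.
    """
    obs_z = (observed - observed.mean()) / observed.std(ddof=0)
    pred_z = (predicted - predicted.mean()) / predicted.std(ddof=0)
    selected = obs_z.index[(obs_z > z_threshold).any(axis=1)]
    if len(selected) == 0:
        raise EmptySelectionError(f"no region has z > {z_threshold} in any tissue")
    if k > len(selected):
        raise ValueError(f"k={k} exceeds the {len(selected)} selected regions")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    obs_labels = km.fit_predict(obs_z.loc[selected].to_numpy())
    d = ((pred_z.loc[selected].to_numpy()[:, None, :] - km.cluster_centers_[None]) ** 2).sum(axis=2)
    pred_labels = d.argmin(axis=1)
    return {
        "selected": list(selected),
        "observed_labels": obs_labels,
        "predicted_labels": pred_labels,
        "centroids": km.cluster_centers_,
        "agreement": float((obs_labels == pred_labels).mean()),
    }


@dataclass
class PPVCurve:
    thresholds: np.ndarray
    ppv: np.ndarray  # NaN where no sequence is predicted positive
    n_predicted_positive: np.ndarray
    max_ppv: float  # max PPV among thresholds with support >= min_support (NaN if none)
    max_ppv_threshold: float
    min_support: int

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "ppv": self.ppv.tolist(),
            "n_predicted_positive": self.n_predicted_positive.tolist(),
            "max_ppv": self.max_ppv,
            "max_ppv_threshold": self.max_ppv_threshold,
            "min_support": self.min_support,
        }


def ppv_curve(
    labels: np.ndarray,
    scores: np.ndarray,
    min_support: int = 100,
    n_grid: int = 1001,
) -> PPVCurve:
    """PPV across an even threshold grid on [0, 1]; positive iff score >= t."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    single_class = len(np.unique(labels)) < 2
    if single_class:
        warnings.warn("labels contain a single class; PPV is not informative", stacklevel=2)

    thresholds = np.linspace(0.0, 1.0, n_grid)
    order = np.argsort(scores)
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # cumulative positives from the top
    tp_from = np.concatenate([np.cumsum(sorted_labels[::-1])[::-1], [0]])
    idx = np.searchsorted(sorted_scores, thresholds, side="left")
    n_pos_pred = len(scores) - idx
    tp = tp_from[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(n_pos_pred > 0, tp / np.maximum(n_pos_pred, 1), np.nan)
    eligible = n_pos_pred >= min_support
    if single_class or not eligible.any():
        max_ppv, max_thr = np.nan, np.nan
    else:
        vals = np.where(eligible, np.nan_to_num(ppv, nan=-1.0), -1.0)
        best = int(np.argmax(vals))
        max_ppv, max_thr = float(ppv[best]), float(thresholds[best])
    return PPVCurve(thresholds, ppv, n_pos_pred, max_ppv, max_thr, min_support)


def ppv_at_threshold(labels: np.ndarray, scores: np.ndarray, threshold: float) -> float:
    """PPV of 'score >= threshold' (NaN if nothing is predicted positive)."""
    labels = np.asarray(labels)
    pred = np.asarray(scores) >= threshold
    if pred.sum() == 0:
        return np.nan
    return float(labels[pred].mean())


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; used to turn accessibility predictions into the
    no-transfer activity baseline."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def control_rejection(scores_by_set: dict[str, np.ndarray], threshold: float) -> dict[str, float]:
    """Fraction of control sequences scored below ``threshold``, per set."""
    out = {}
    for name, scores in scores_by_set.items():
        scores = np.asarray(scores)
        if len(scores) == 0:
            raise ValueError(f"control set {name!r} is empty")
        out[name] = float((scores < threshold).mean())
    return out
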