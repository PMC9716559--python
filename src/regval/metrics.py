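"""Per-residue validation metrics comparing observed and predicted geometry.

For every residue the package computes eight base metrics — a
confidence-weighted RMSD between observed and predicted inter-residue
distances (wRMSD) and seven contact-confusion metrics (Accuracy,
Precision, Sensitivity, Specificity, FP rate and the raw FP/FN counts) —
plus a five-point smoothed variant and a spatial Z-score variant of each,
for 24 metric columns in total.  The Z-score standardizes a residue's
value against all residues within 10 Å of it.

Degenerate denominators (no partners, zero weight, empty neighbourhood
variance) produce 0 together with a False entry in the validity mask;
the table never contains NaN so it can feed a classifier directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .predictions import DistancePrediction, PredictedContactMap
from .structures import ContactMap, DistanceMatrix, StructureChain

__all__ = [
    "ConfusionCounts",
    "BASE_METRICS",
    "METRIC_COLUMNS",
    "wrmsd_profile",
    "contact_confusion_profile",
    "confusion_metrics",
    "smooth_profile",
    "spatial_zscore_profile",
    "build_metric_table",
]

BASE_METRICS = ("wrmsd", "accuracy", "precision", "sensitivity",
                "specificity", "fp_rate", "fn_count", "fp_count")
METRIC_COLUMNS = tuple(list(BASE_METRICS)
                       + [f"smooth_{m}" for m in BASE_METRICS]
                       + [f"z_{m}" for m in BASE_METRICS])


@dataclass
class ConfusionCounts:
    """Per-residue contact confusion counts over the pair universe
    U(i) = {j : |i-j| >= min_sep, both residues modelled}."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    universe: np.ndarray  # |U(i)|

    @property
    def L(self) -> int:
        return len(self.tp)


def _pair_universe(L: int, min_sep: int, mask: Optional[np.ndarray]) -> np.ndarray:
    """Boolean L×L matrix of admissible partners."""
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :]) >= min_sep
    if mask is not None:
        sep &= mask
    return sep


def wrmsd_profile(obs: DistanceMatrix, pred: DistancePrediction,
                  min_sep: int = 1, per_n: bool = False):
    """Confidence-weighted RMS deviation between observed and predicted
    distances, per residue.

    wRMSD(i) = sqrt( sum_j w_ij (x_ij - xhat_ij)^2 / sum_j w_ij ) over
    partners j with |i-j| >= min_sep, both residues modelled and the
    prediction inside the binned distance range.  ``per_n=True`` divides
    by the partner count instead of the total weight.  Residues with zero
    total weight score 0 and are flagged invalid.

    Returns (values, valid) arrays of length L.
    """
    if obs.values.shape != pred.pred_dist.shape:
        raise ValueError("observed and predicted matrices differ in size")
    L = obs.L
    w = pred.confidence * _pair_universe(L, min_sep, obs.mask) * pred.in_range
    dev2 = (obs.values - pred.pred_dist) ** 2
    num = (w * dev2).sum(axis=1)
    if per_n:
        den = (w > 0).sum(axis=1).astype(float)
    else:
        den = w.sum(axis=1)
    valid = den > 0
    out = np.zeros(L)
    out[valid] = np.sqrt(num[valid] / den[valid])
    return out, valid


def contact_confusion_profile(pred_cm: ContactMap, obs_cm: ContactMap,
                              min_sep: int = 5,
                              mask: Optional[np.ndarray] = None) -> ConfusionCounts:
    """Per-residue TP/FP/TN/FN counts of predicted vs observed contacts.

    For each residue i and admissible partner j: TP if (i, j) is in both
    maps, FP if predicted only, FN if observed only, TN otherwise.
    """
    if pred_cm.L != obs_cm.L:
        raise ValueError("contact maps differ in length")
    L = pred_cm.L
    pmat = pred_cm.to_matrix() > 0
    omat = obs_cm.to_matrix() > 0
    uni = _pair_universe(L, min_sep, mask)
    tp = (pmat & omat & uni).sum(axis=1)
    fp = (pmat & ~omat & uni).sum(axis=1)
    fn = (~pmat & omat & uni).sum(axis=1)
    tn = (~pmat & ~omat & uni).sum(axis=1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, universe=uni.sum(axis=1))


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """The seven per-residue contact metrics, each as (values, valid).

    Accuracy=(TP+TN)/|U|, Precision=TP/(TP+FP), Sensitivity=TP/(TP+FN),
    Specificity=TN/(TN+FP), FP_rate=FP/(FP+TN), plus the raw FN and FP
    counts.  Zero denominators give 0 with a False validity flag.
    """
    def ratio(num, den):
        den = den.astype(float)
        valid = den > 0
        out = np.zeros(counts.L)
        out[valid] = num[valid] / den[valid]
        return out, valid

    tp, fp, tn, fn = (c.astype(float) for c in (counts.tp, counts.fp, counts.tn, counts.fn))
    always = counts.universe > 0
    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "precision": ratio(tp, tp + fp),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "fp_rate": ratio(fp, fp + tn),
        "fn_count": (fn, always.copy()),
        "fp_count": (fp, always.copy()),
    }


def smooth_profile(values: np.ndarray, window: int = 5,
                   mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Unweighted moving average with a window that shrinks at the edges.

    value(i) becomes the mean over positions [i - w//2, i + w//2]
    clipped to the chain, so no residue is lost at the ends.  Positions
    with a False mask are excluded from every window mean; a fully masked
    window yields 0.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    values = np.asarray(values, dtype=float)
    L = len(values)
    half = window // 2
    ok = np.ones(L, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    v = np.where(ok, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    ccnt = np.concatenate([[0], np.cumsum(ok.astype(int))])
    out = np.zeros(L)
    lo = np.maximum(np.arange(L) - half, 0)
    hi = np.minimum(np.arange(L) + half, L - 1) + 1
    tot = csum[hi] - csum[lo]
    cnt = ccnt[hi] - ccnt[lo]
    nz = cnt > 0
    out[nz] = tot[nz] / cnt[nz]
    return out


def spatial_zscore_profile(values: np.ndarray, chain: StructureChain,
                           radius: float = 10.0,
                           mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Standardize each residue's value against all residues within
    ``radius`` Å of it (the residue itself included).

    Uses the population standard deviation; a zero-variance (or empty)
    neighbourhood gives a Z-score of 0.
    """
    values = np.asarray(values, dtype=float)
    L = chain.L
    coords = chain.coords()
    ok = chain.modelled_mask.copy()
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    out = np.zeros(L)
    if not ok.any():
        return out
    idx = np.where(ok)[0]
    sub = coords[idx]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
    near = d2 <= radius * radius
    vals = values[idx]
    for a, i in enumerate(idx):
        sample = vals[near[a]]
        mu = sample.mean()
        sd = sample.std()  # population std
        if sd > 0:
            out[i] = (values[i] - mu) / sd
    return out


def build_metric_table(chain: StructureChain, pred: DistancePrediction,
                       pred_cm: PredictedContactMap,
                       obs: Optional[DistanceMatrix] = None,
                       obs_cm: Optional[ContactMap] = None,
                       min_sep: int = 5, wrmsd_min_sep: int = 1,
                       contact_cutoff: float = 8.0, smooth_window: int = 5,
                       z_radius: float = 10.0) -> pd.DataFrame:
    """Assemble the full 24-column per-residue metric table.

    Columns: the 8 base metrics, their 5-point smoothed versions and
    their 10 Å spatial Z-score versions (Z-scores are computed from the
    unsmoothed values), plus a boolean ``mask`` column marking residues
    whose metrics are defined.  Rows are indexed by 1-based reference
    position and cover every position in the chain.
    """
    from .structures import observed_contact_map, observed_distance_matrix

    if obs is None:
        obs = observed_distance_matrix(chain)
    if obs_cm is None:
        obs_cm = observed_contact_map(chain, cutoff=contact_cutoff, min_sep=min_sep)
    if obs.L != pred.L or obs.L != pred_cm.L:
        raise ValueError("chain, prediction and contact-map sizes differ")

    base = {}
    valid = {}
    base["wrmsd"], valid["wrmsd"] = wrmsd_profile(obs, pred, min_sep=wrmsd_min_sep)
    counts = contact_confusion_profile(pred_cm, obs_cm, min_sep=min_sep, mask=obs.mask)
    for name, (vals, ok) in confusion_metrics(counts).items():
        base[name], valid[name] = vals, ok

    modelled = chain.modelled_mask
    table = {}
    for name in BASE_METRICS:
        ok = valid[name] & modelled
        table[name] = np.where(ok, base[name], 0.0)
        table[f"smooth_{name}"] = smooth_profile(base[name], window=smooth_window, mask=ok)
        table[f"z_{name}"] = spatial_zscore_profile(base[name], chain,
                                                    radius=z_radius, mask=ok)
    df = pd.DataFrame(table, index=pd.RangeIndex(1, chain.L + 1, name="residue"))
    df = df[list(METRIC_COLUMNS)]
    df["mask"] = modelled
    return df
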