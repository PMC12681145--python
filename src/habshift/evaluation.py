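"""Model skill and transferability metrics.

Includes spatial-sorting-bias (SSB) removal by point-wise distance
sampling, the composite overall-model-skill OMS (the mean of TSS,
rescaled SSB-corrected AUC, SSB-corrected kappa and the Brier skill
score), the area of applicability (AoA) dissimilarity screening, and the
SCORE combining OMS and AoA as a normalized distance from the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.metrics import cohen_kappa_score, roc_auc_score

__all__ = ["SkillReport", "max_tss_threshold", "tss", "cohen_kappa", "auc",
           "brier_skill", "remove_ssb", "ssb_ratio", "oms", "aoa", "score",
           "skill_report"]

EARTH_RADIUS_KM = 6371.0


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


# ---------------------------------------------------------------------------
# thresholded metrics
# ---------------------------------------------------------------------------

def _confusion(labels: np.ndarray, predictions: np.ndarray,
               threshold: float) -> tuple[int, int, int, int]:
    pred = predictions >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fp, fn, tn


def max_tss_threshold(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Threshold (from the unique prediction values) maximizing
    sensitivity + specificity - 1; ties resolve to the lowest threshold."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions, dtype=float)
    _check_two_classes(labels)
    thresholds = np.unique(predictions)
    # sensitivity(t) = P(pred >= t | pos); specificity(t) = P(pred < t | neg)
    pos = predictions[labels == 1]
    neg = predictions[labels == 0]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / len(pos)
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / len(neg)
    tss_vals = sens + spec - 1.0
    best = np.max(tss_vals)
    # lowest threshold among ties
    idx = int(np.flatnonzero(tss_vals >= best - 1e-12)[0])
    return float(thresholds[idx])


def tss(labels: np.ndarray, predictions: np.ndarray,
        threshold: float) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    _check_two_classes(np.asarray(labels))
    tp, fp, fn, tn = _confusion(np.asarray(labels),
                                np.asarray(predictions, dtype=float), threshold)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return float(sens + spec - 1.0)


def cohen_kappa(labels: np.ndarray, predictions: np.ndarray,
                threshold: float) -> float:
    """Cohen's kappa of the 2x2 table at the given threshold."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pred = (np.asarray(predictions, dtype=float) >= threshold).astype(int)
    return float(cohen_kappa_score(labels.astype(int), pred))


def auc(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Rank-based AUC: probability a presence outranks an absence."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels.astype(int),
                               np.asarray(predictions, dtype=float)))


def brier_skill(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Brier skill score vs the constant base-rate reference, floored at 0."""
    labels = np.asarray(labels, dtype=float)
    _check_two_classes(labels)
    predictions = np.asarray(predictions, dtype=float)
    bs = float(np.mean((predictions - labels) ** 2))
    base = labels.mean()
    bs_ref = float(np.mean((base - labels) ** 2))
    return max(0.0, 1.0 - bs / bs_ref)


# ---------------------------------------------------------------------------
# spatial sorting bias
# ---------------------------------------------------------------------------

def _unit_sphere(lonlat: np.ndarray) -> np.ndarray:
    lon = np.radians(lonlat[:, 0])
    lat = np.radians(lonlat[:, 1])
    return np.column_stack([np.cos(lat) * np.cos(lon),
                            np.cos(lat) * np.sin(lon),
                            np.sin(lat)])


def _nearest_gc_distance(points: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Great-circle distance (km) from each point to its nearest ref point."""
    tree = cKDTree(_unit_sphere(ref))
    chord, _ = tree.query(_unit_sphere(points))
    chord = np.clip(chord, 0.0, 2.0)
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(chord / 2.0)


def ssb_ratio(test_presences: np.ndarray, test_absences: np.ndarray,
              calib_presences: np.ndarray) -> float:
    """Mean presence-distance over mean absence-distance (1 = no bias).

    All arguments are (n, 2) arrays of (lon, lat) in degrees; distances
    are to the nearest calibration presence.
    """
    dp = _nearest_gc_distance(test_presences, calib_presences)
    da = _nearest_gc_distance(test_absences, calib_presences)
    mean_da = da.mean()
    if mean_da == 0:
        return math.inf if dp.mean() > 0 else 1.0
    return float(dp.mean() / mean_da)


def remove_ssb(test_presences: np.ndarray, test_absences: np.ndarray,
               calib_presences: np.ndarray,
               tolerance: float = 0.33) -> tuple[np.ndarray, np.ndarray]:
    """Point-wise distance sampling to remove spatial sorting bias.

    Pairs each test presence with an unused test absence whose
    nearest-calibration-presence distance best matches the presence's own
    (within a relative tolerance); unmatched points are dropped. Returns
    (presence_indices, absence_indices) into the input arrays, of equal
    length.
    """
    dp = _nearest_gc_distance(np.asarray(test_presences, dtype=float),
                              calib_presences)
    da = _nearest_gc_distance(np.asarray(test_absences, dtype=float),
                              calib_presences)
    order = np.argsort(dp)
    da_order = np.argsort(da)
    da_sorted = da[da_order]
    used = np.zeros(len(da), dtype=bool)
    kept_p: list[int] = []
    kept_a: list[int] = []
    for i in order:
        target = dp[i]
        lo = target - tolerance * target
        hi = target + tolerance * target
        j0 = np.searchsorted(da_sorted, lo, side="left")
        j1 = np.searchsorted(da_sorted, hi, side="right")
        best_j, best_err = -1, np.inf
        for j in range(j0, j1):
            cand = da_order[j]
            if used[cand]:
                continue
            err = abs(da_sorted[j] - target)
            if err < best_err:
                best_err, best_j = err, cand
        if best_j >= 0:
            used[best_j] = True
            kept_p.append(int(i))
            kept_a.append(int(best_j))
    if not kept_p:
        raise ValueError("no presence/absence pairs matchable; increase the "
                         "distance tolerance")
    return np.asarray(kept_p), np.asarray(kept_a)


# ---------------------------------------------------------------------------
# composite scores
# ---------------------------------------------------------------------------

def scale_auc(auc_raw: float) -> float:
    """Feature-scale AUC from [0.5, 1] onto [0, 1], floored at 0."""
    return max(0.0, (auc_raw - 0.5) / 0.5)


def oms(tss_value: float, auc_ssb_raw: float, ck_ssb: float, bss: float,
        include_bss: bool = True) -> float:
    """Overall model skill: mean of TSS, rescaled AUC_SSB, CK_SSB (and BSS).

    The four-metric average is the default; ``include_bss=False`` selects
    the three-metric variant.
    """
    parts = [tss_value, scale_auc(auc_ssb_raw), ck_ssb]
    if include_bss:
        parts.append(bss)
    return float(np.mean(parts))


def score(oms_value: float, aoa_value: float) -> float:
    """Composite score: Euclidean distance of (OMS, AoA) from the origin,
    normalized by sqrt(2) so a perfect model scores 1."""
    return float(math.sqrt(oms_value ** 2 + aoa_value ** 2) / math.sqrt(2.0))


# ---------------------------------------------------------------------------
# area of applicability
# ---------------------------------------------------------------------------

def aoa(calib_X: np.ndarray, stack_X: np.ndarray,
        weights: np.ndarray,
        valid: np.ndarray | None = None,
        max_pairwise: int = 2000,
        seed: int = 0) -> tuple[float, np.ndarray]:
    """Area of applicability from importance-weighted dissimilarity.

    Parameters
    ----------
    calib_X : (n_calib, p) calibration predictor values.
    stack_X : (n_cells, p) prediction-domain predictor values (same order).
    weights : per-predictor importance weights (contributions / 100).
    valid : optional boolean mask over cells; AoA is the fraction of valid
        cells inside.

    Returns (aoa_fraction, inside_mask over all cells).
    """
    calib_X = np.asarray(calib_X, dtype=float)
    if calib_X.shape[0] < 10:
        raise ValueError("AoA needs at least 10 calibration points")
    stack_X = np.asarray(stack_X, dtype=float)
    weights = np.asarray(weights, dtype=float)

    mean = calib_X.mean(axis=0)
    sd = calib_X.std(axis=0)
    sd[sd == 0] = 1.0
    cw = (calib_X - mean) / sd * weights
    sw = (stack_X - mean) / sd * weights

    sub = cw
    if len(cw) > max_pairwise:
        rng = np.random.Generator(np.random.PCG64(seed))
        sub = cw[rng.choice(len(cw), size=max_pairwise, replace=False)]
    diffs = sub[:, None, :] - sub[None, :, :]
    pair = np.sqrt((diffs ** 2).sum(-1))
    iu = np.triu_indices(len(sub), k=1)
    d_bar = float(pair[iu].mean())
    if d_bar == 0:
        d_bar = 1e-12

    tree = cKDTree(cw)
    di_cells = tree.query(sw)[0] / d_bar
    # calibration DIs: leave-one-out nearest neighbour
    d_loo = tree.query(cw, k=2)[0][:, 1]
    di_calib = d_loo / d_bar
    q1, q3 = np.quantile(di_calib, [0.25, 0.75])
    threshold = q3 + 1.5 * (q3 - q1)

    inside = di_cells <= threshold
    if valid is not None:
        frac = float(inside[valid].mean()) if valid.any() else 0.0
    else:
        frac = float(inside.mean())
    return frac, inside


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class SkillReport:
    """All skill/transferability components for one model setup."""

    TSS: float
    AUC_SSB_raw: float
    AUC_SSB_scaled: float
    CK_SSB: float
    BSS: float
    OMS: float
    AoA: float
    SCORE: float
    tss_max_threshold: float
    n_eval_points: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def skill_report(labels: np.ndarray, predictions: np.ndarray,
                 eval_lonlat: np.ndarray, calib_presence_lonlat: np.ndarray,
                 aoa_value: float, include_bss: bool = True,
                 ssb_tolerance: float = 0.33) -> SkillReport:
    """Assemble a SkillReport from held-out predictions.

    AUC and kappa are computed on the SSB-corrected subsample; TSS and
    BSS on the full held-out set.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions, dtype=float)
    thr = max_tss_threshold(labels, predictions)
    tss_val = tss(labels, predictions, thr)
    bss_val = brier_skill(labels, predictions)

    p_idx = np.flatnonzero(labels == 1)
    a_idx = np.flatnonzero(labels == 0)
    try:
        kp, ka = remove_ssb(eval_lonlat[p_idx], eval_lonlat[a_idx],
                            calib_presence_lonlat, tolerance=ssb_tolerance)
        sub = np.concatenate([p_idx[kp], a_idx[ka]])
    except ValueError:
        sub = np.concatenate([p_idx, a_idx])
    auc_raw = auc(labels[sub], predictions[sub])
    ck = cohen_kappa(labels[sub], predictions[sub], thr)

    oms_val = oms(tss_val, auc_raw, ck, bss_val, include_bss=include_bss)
    return SkillReport(
        TSS=tss_val, AUC_SSB_raw=auc_raw, AUC_SSB_scaled=scale_auc(auc_raw),
        CK_SSB=ck, BSS=bss_val, OMS=oms_val, AoA=aoa_value,
        SCORE=score(oms_val, aoa_value), tss_max_threshold=thr,
        n_eval_points=int(len(sub)),
    )
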