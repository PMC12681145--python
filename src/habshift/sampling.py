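"""Presence/pseudo-absence calibration sampling.

Implements the four background-selection strategies:

* ``random`` — absences uniformly from cells with probability < 0.5;
* ``sampled`` — absences stratified so the dominant land-use class
  composition matches the domain-wide composition;
* ``buffered`` — absences only from cells with probability exactly 0
  (cells with 0 < p < 0.5 form the excluded buffer);
* ``sampled_buffered`` — both constraints combined.

If fewer presence cells exist than requested, 75% of the available
presences are used and the absence count is topped up so the total
sample size stays at twice the requested presence count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from ._rng import substream
from .stack import PredictorStack

__all__ = ["binarize", "select_background", "CalibrationSample",
           "BACKGROUND_METHODS", "dominant_class"]

log = logging.getLogger(__name__)

BACKGROUND_METHODS = ("random", "sampled", "buffered", "sampled_buffered")


def binarize(prob_map: xr.DataArray, threshold: float = 0.5) -> xr.DataArray:
    """Presence (1.0) where probability >= threshold, absence (0.0) below;
    NaN (mask) preserved."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    values = prob_map.values
    out = np.where(np.isnan(values), np.nan,
                   (values >= threshold).astype(float))
    return xr.DataArray(out, dims=prob_map.dims, coords=prob_map.coords,
                        name="presence")


@dataclass
class CalibrationSample:
    """Labelled presence/pseudo-absence cells with aligned predictor values."""

    table: pd.DataFrame          # index: cell id; cols lat, lon, label, predictors
    background_method: str
    seed: int
    predictor_names: list[str]

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate cells in calibration sample")
        labels = set(self.table["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {labels}")

    @property
    def n_presence(self) -> int:
        return int((self.table["label"] == 1).sum())

    @property
    def n_absence(self) -> int:
        return int((self.table["label"] == 0).sum())

    @property
    def X(self) -> pd.DataFrame:
        return self.table[self.predictor_names]

    @property
    def y(self) -> np.ndarray:
        return self.table["label"].values.astype(int)

    def split(self, fraction: float = 0.5, seed: int | None = None
              ) -> tuple["CalibrationSample", "CalibrationSample"]:
        """Stratified split into (calibration, holdout) parts."""
        rng = substream(self.seed if seed is None else seed, "sample/split")
        parts = []
        for label in (1, 0):
            idx = self.table.index[self.table["label"] == label].to_numpy()
            rng.shuffle(idx)
            parts.append(np.array_split(idx, [int(round(fraction * len(idx)))]))
        first = np.concatenate([parts[0][0], parts[1][0]])
        second = np.concatenate([parts[0][1], parts[1][1]])
        make = lambda ids: CalibrationSample(
            self.table.loc[ids], self.background_method, self.seed,
            list(self.predictor_names))
        return make(first), make(second)


def dominant_class(stack: PredictorStack, cells: np.ndarray) -> np.ndarray:
    """Per-cell dominant (argmax-fraction) land-use class name."""
    lu_names = stack.landuse_names
    if not lu_names:
        raise ValueError("stack has no land-use predictors")
    fracs = np.stack([stack.array(n).ravel()[cells] for n in lu_names])
    return np.asarray(lu_names, dtype=object)[np.argmax(fracs, axis=0)]


def _stratified_absences(eligible: np.ndarray, dom_eligible: np.ndarray,
                         target_composition: dict[str, float], n_needed: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw absences matching the target dominant-class composition.

    Proportional allocation with largest-remainder rounding; exhausted
    strata have their deficit reallocated proportionally (and logged).
    """
    classes = list(target_composition)
    weights = np.array([target_composition[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    raw = weights * n_needed
    counts = np.floor(raw).astype(int)
    remainder = n_needed - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1

    pools = {c: eligible[dom_eligible == c] for c in classes}
    chosen: list[np.ndarray] = []
    deficit = 0
    for c, want in zip(classes, counts):
        pool = pools[c]
        take = min(want, len(pool))
        if take < want:
            deficit += want - take
            log.info("stratum %r exhausted: wanted %d, have %d", c, want,
                     len(pool))
        if take > 0:
            chosen.append(rng.choice(pool, size=take, replace=False))
    taken = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
    if deficit > 0:
        leftovers = np.setdiff1d(eligible, taken, assume_unique=False)
        if len(leftovers) < deficit:
            raise ValueError(
                "infeasible constraint: not enough eligible absence cells to "
                f"reallocate a stratum deficit of {deficit}")
        taken = np.concatenate(
            [taken, rng.choice(leftovers, size=deficit, replace=False)])
    return taken


def select_background(prob_map: xr.DataArray, stack: PredictorStack,
                      method: str, n_presence: int = 10000,
                      n_absence: int = 10000, seed: int = 0,
                      threshold: float = 0.5) -> CalibrationSample:
    """Draw a presence/pseudo-absence calibration sample.

    Presences are drawn uniformly from cells with probability >=
    ``threshold``. Absence eligibility depends on ``method``; see the
    module docstring. Sampling is without replacement and deterministic
    given ``seed``.
    """
    if method not in BACKGROUND_METHODS:
        raise ValueError(f"unknown background method {method!r}; choose from "
                         f"{BACKGROUND_METHODS}")
    rng = substream(seed, f"background/{method}")
    prob = prob_map.values.ravel()
    valid = ~np.isnan(prob)
    cells_all = np.flatnonzero(valid)

    presence_cells = np.flatnonzero(valid & (prob >= threshold))
    if method in ("buffered", "sampled_buffered"):
        absence_pool = np.flatnonzero(valid & (prob == 0.0))
        if len(absence_pool) == 0:
            raise ValueError(
                "infeasible constraint: buffered selection requires cells "
                "with probability exactly 0, but none exist")
    else:
        absence_pool = np.flatnonzero(valid & (prob < threshold))
    if len(presence_cells) == 0:
        raise ValueError("no presence cells available")

    if len(presence_cells) >= n_presence:
        pres = rng.choice(presence_cells, size=n_presence, replace=False)
        n_abs_needed = n_absence
    else:
        n_use = int(np.floor(0.75 * len(presence_cells)))
        if n_use == 0:
            raise ValueError("too few presence cells to sample from")
        pres = rng.choice(presence_cells, size=n_use, replace=False)
        n_abs_needed = 2 * n_presence - n_use
        log.info("only %d presence cells; using 75%% (%d) and %d absences",
                 len(presence_cells), n_use, n_abs_needed)

    if len(absence_pool) < n_abs_needed:
        raise ValueError(
            f"infeasible constraint: method {method!r} has only "
            f"{len(absence_pool)} eligible absence cells, {n_abs_needed} "
            "needed")

    if method in ("sampled", "sampled_buffered"):
        dom_domain = dominant_class(stack, cells_all)
        classes, counts = np.unique(dom_domain, return_counts=True)
        target = {c: n / counts.sum() for c, n in zip(classes, counts)}
        dom_pool = dominant_class(stack, absence_pool)
        absent = _stratified_absences(absence_pool, dom_pool, target,
                                      n_abs_needed, rng)
    else:
        absent = rng.choice(absence_pool, size=n_abs_needed, replace=False)

    cells = np.concatenate([pres, absent])
    labels = np.concatenate([np.ones(len(pres)), np.zeros(len(absent))])
    frame = stack.to_frame(cells)
    frame["label"] = labels.astype(int)
    names = stack.names
    frame = frame[["lat", "lon", "label"] + names]
    return CalibrationSample(frame, method, seed, names)
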