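"""Per-grid-box most-important-predictor (MIP / MIPC) statistics.

For each cell the candidate score of predictor P is

    (CON_N + CON_N * INT_N) * R_N

where CON_N and INT_N are the model's contribution and interaction-sum,
feature-scaled across the predictors of the analyzed group, and R_N is
the feature-scaled absolute response difference between the reference
and the year of interest (scaled jointly across cells and group
predictors). The winner is the argmax; its importance percentage is its
score over the sum of all strictly positive scores at that cell. The
change-oriented variant (MIPC) additionally filters candidates by the
sign of their response delta according to the cell's change category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brt import ResponseCurve

__all__ = ["ImportanceRecord", "response_range", "compute_mip",
           "compute_mipc", "mip_summary", "GAIN_CATEGORIES", "LOSS_CATEGORIES"]

GAIN_CATEGORIES = ("PCC", "PLUC", "RPLUC")
LOSS_CATEGORIES = ("ACC", "ALUC", "RALUC")
NEUTRAL_CATEGORIES = ("P", "A")


def response_range(curve: ResponseCurve, x_ref: float, x_now: float) -> float:
    """Signed response difference f(x_now) - f(x_ref) on the curve.

    Values outside the curve's grid clamp to the end responses (np.interp
    semantics).
    """
    f_now = float(np.interp(x_now, curve.x, curve.response))
    f_ref = float(np.interp(x_ref, curve.x, curve.response))
    return f_now - f_ref


@dataclass
class ImportanceRecord:
    """Per-cell MIP winners plus the normalized terms they came from."""

    predictors: list[str]
    winner: np.ndarray            # (n_cells,) int index into predictors; -1 = no MIP
    importance_pct: np.ndarray    # (n_cells,) percent; NaN where no MIP
    scores: np.ndarray            # (n_cells, n_pred) per-candidate scores
    con_n: np.ndarray             # (n_pred,)
    int_n: np.ndarray             # (n_pred,)
    r_n: np.ndarray               # (n_cells, n_pred)
    deltas: np.ndarray            # (n_cells, n_pred) signed response deltas

    @property
    def winner_names(self) -> np.ndarray:
        names = np.asarray(self.predictors + [None], dtype=object)
        return names[self.winner]


def _feature_scale(x: np.ndarray) -> np.ndarray:
    """Feature scaling onto [0, 1] with the minimum fixed at 0.

    Dividing by the maximum (rather than min-max over the observed
    values) keeps the zero-product semantics: a zero contribution or a
    zero response change always yields a zero score, and the smallest
    nonzero term is not artificially nulled.
    """
    hi = np.max(x)
    if hi <= 1e-15:
        return np.zeros_like(np.asarray(x, dtype=float))
    return np.asarray(x, dtype=float) / hi


def _resolve_scores(scores: np.ndarray, con_n: np.ndarray,
                    predictors: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Winner per cell (ties -> higher CON_N, then name) and importance %."""
    n_cells, n_pred = scores.shape
    positive = scores > 0
    any_pos = positive.any(axis=1)
    totals = np.where(any_pos, (scores * positive).sum(axis=1), np.nan)

    # lexicographic tie-break: primary score, then con_n, then reverse name
    name_rank = np.argsort(np.argsort(predictors))  # low rank = earlier name
    winner = np.full(n_cells, -1, dtype=int)
    best = scores.max(axis=1)
    argbest = scores.argmax(axis=1)
    winner[any_pos] = argbest[any_pos]
    n_ties = (scores >= best[:, None] - 1e-15).sum(axis=1)
    for i in np.flatnonzero(any_pos & (n_ties > 1)):
        tied = np.flatnonzero(scores[i] >= best[i] - 1e-15)
        order = sorted(tied, key=lambda j: (-con_n[j], name_rank[j]))
        winner[i] = order[0]
    pct = np.full(n_cells, np.nan)
    ok = winner >= 0
    pct[ok] = 100.0 * scores[np.flatnonzero(ok), winner[ok]] / totals[ok]
    return winner, pct


def compute_mip(contribution: dict[str, float],
                interaction_sums: dict[str, float],
                deltas: np.ndarray,
                predictors: list[str]) -> ImportanceRecord:
    """Most important predictor per cell (unsigned).

    Parameters
    ----------
    contribution, interaction_sums : per-predictor scalars for the group
        being analyzed (climate or land-use predictors, never mixed).
    deltas : (n_cells, n_pred) signed response deltas, columns aligned
        with ``predictors``.
    """
    if not predictors:
        raise ValueError("empty predictor group")
    deltas = np.asarray(deltas, dtype=float)
    if deltas.shape[1] != len(predictors):
        raise ValueError("deltas shape does not match predictor list")
    con = np.array([contribution[p] for p in predictors], dtype=float)
    ints = np.array([interaction_sums[p] for p in predictors], dtype=float)
    con_n = _feature_scale(con)
    int_n = _feature_scale(ints)
    r_n = _feature_scale(np.abs(deltas))  # joint scaling over cells x predictors

    scores = (con_n + con_n * int_n)[None, :] * r_n
    winner, pct = _resolve_scores(scores, con_n, predictors)
    return ImportanceRecord(list(predictors), winner, pct, scores, con_n,
                            int_n, r_n, deltas)


def compute_mipc(contribution: dict[str, float],
                 interaction_sums: dict[str, float],
                 deltas: np.ndarray,
                 predictors: list[str],
                 categories: np.ndarray) -> ImportanceRecord:
    """Most important predictor for change: sign-filtered candidates.

    Cells in presence-gaining categories admit only predictors with a
    positive response delta, absence-gaining categories only negative;
    stable cells (P / A) rank unsigned, as in :func:`compute_mip`.
    """
    base = compute_mip(contribution, interaction_sums, deltas, predictors)
    categories = np.asarray(categories, dtype=object).ravel()
    if len(categories) != base.scores.shape[0]:
        raise ValueError("category array length does not match cell count")

    scores = base.scores.copy()
    gain = np.isin(categories, GAIN_CATEGORIES)
    loss = np.isin(categories, LOSS_CATEGORIES)
    scores[gain] = np.where(base.deltas[gain] > 0, scores[gain], 0.0)
    scores[loss] = np.where(base.deltas[loss] < 0, scores[loss], 0.0)
    winner, pct = _resolve_scores(scores, base.con_n, list(predictors))
    return ImportanceRecord(list(predictors), winner, pct, scores,
                            base.con_n, base.int_n, base.r_n, base.deltas)


def mip_summary(record: ImportanceRecord, categories: np.ndarray,
                predictor_deltas: np.ndarray | None = None) -> pd.DataFrame:
    """Per-category modal winner and win fraction (Table-style summary).

    ``predictor_deltas`` optionally supplies the raw predictor change
    (n_cells, n_pred) so the modal winner's mean raw delta can be
    reported alongside its mean response delta.
    """
    categories = np.asarray(categories, dtype=object).ravel()
    rows = []
    for cat in np.unique(categories[categories != None]):  # noqa: E711
        in_cat = categories == cat
        winners = record.winner[in_cat]
        with_mip = winners >= 0
        if not with_mip.any():
            continue
        vals, counts = np.unique(winners[with_mip], return_counts=True)
        modal = int(vals[np.argmax(counts)])
        frac = 100.0 * counts.max() / with_mip.sum()
        cells = np.flatnonzero(in_cat)[with_mip & (winners == modal)]
        row = {
            "category": str(cat),
            "mip": record.predictors[modal],
            "win_fraction_pct": float(frac),
            "mean_response_delta": float(record.deltas[cells, modal].mean()),
        }
        if predictor_deltas is not None:
            row["mean_predictor_delta"] = float(
                predictor_deltas[cells, modal].mean())
        rows.append(row)
    return pd.DataFrame(rows)
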