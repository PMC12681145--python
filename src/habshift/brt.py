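"""Boosted regression trees with cross-validated tree-count selection.

The base learner is scikit-learn's stagewise gradient boosting with
Bernoulli (log-loss) deviance and stochastic subsampling; the layers on
top — incremental cross-validated tree selection, the adaptive learning
rate / tree-complexity loop, predictor simplification, pairwise
interaction sizes and partial-dependence response curves — are
implemented here.

Tree complexity follows the gbm convention: a complexity of ``tc`` means
trees with ``tc`` splits, i.e. ``tc + 1`` leaves.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .sampling import CalibrationSample
from .stack import PredictorStack

__all__ = ["BRTConfig", "FittedBRT", "ResponseCurve", "InteractionMatrix",
           "fit_with_cv", "tune", "contributions", "interactions",
           "response_curve", "simplify", "predict_map", "bernoulli_deviance"]

log = logging.getLogger(__name__)

EPS = 1e-9


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean Bernoulli deviance -2 mean[y log p + (1-y) log(1-p)]."""
    p = np.clip(np.asarray(p, dtype=float), EPS, 1 - EPS)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass(frozen=True)
class BRTConfig:
    """Hyperparameters for boosted-tree fitting and the tuning loop."""

    learning_rate: float = 0.15
    tree_complexity: int = 5
    bag_fraction: float = 0.5
    n_folds: int = 10
    tree_step: int = 50
    tree_count_window: tuple[int, int] = (1200, 2000)
    max_trees: int = 2600
    max_loop_iterations: int = 12
    cv_patience: int = 4          # CV scan stops after this many non-improving steps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 3 <= self.tree_complexity <= 10:
            raise ValueError("tree_complexity must be in [3, 10]")
        lo, hi = self.tree_count_window
        if lo >= hi:
            raise ValueError("tree_count_window lower bound must be < upper")


@dataclass
class ResponseCurve:
    """Partial-dependence curve of one predictor on the probability scale."""

    predictor: str
    x: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        if len(self.x) != len(self.response):
            raise ValueError("x and response lengths differ")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("evaluation grid must be strictly increasing")


@dataclass
class InteractionMatrix:
    """Symmetric non-negative pairwise interaction sizes."""

    predictors: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.predictors),) * 2:
            raise ValueError("matrix shape does not match predictor list")
        if not np.allclose(m, m.T):
            raise ValueError("interaction matrix must be symmetric")

    @property
    def sums(self) -> dict[str, float]:
        """Per-predictor sum of pairwise interaction sizes."""
        totals = self.matrix.sum(axis=1)
        return {p: float(s) for p, s in zip(self.predictors, totals)}

    def size(self, p: str, q: str) -> float:
        i, j = self.predictors.index(p), self.predictors.index(q)
        return float(self.matrix[i, j])


@dataclass
class FittedBRT:
    """A tuned boosted-tree model plus the state its diagnostics need."""

    estimator: GradientBoostingClassifier
    predictors: list[str]
    n_trees: int
    learning_rate: float
    tree_complexity: int
    cv_curve: np.ndarray                 # columns: n_trees, mean held-out deviance
    cv_deviance: float                   # at the selected tree count
    cv_deviance_se: float                # SE over folds at the selected count
    train_X: pd.DataFrame
    train_y: np.ndarray
    config: BRTConfig
    flagged: bool = False
    tuning_history: list[dict] = field(default_factory=list)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.predictors].values
        return self.estimator.predict_proba(X)[:, 1]

    @property
    def fitted_values(self) -> np.ndarray:
        return self.predict(self.train_X)


def _validate_inputs(X: pd.DataFrame, y: np.ndarray) -> None:
    if X.shape[1] < 1:
        raise ValueError("at least one predictor required")
    if not np.all(np.isfinite(X.values)):
        bad = [c for c in X.columns if not np.all(np.isfinite(X[c].values))]
        raise ValueError(f"non-finite predictor values in {bad}")
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")


def _new_estimator(config: BRTConfig, lr: float, tc: int, n_trees: int,
                   warm: bool) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        loss="log_loss",
        learning_rate=lr,
        n_estimators=n_trees,
        subsample=config.bag_fraction,
        max_leaf_nodes=tc + 1,
        max_depth=None,
        random_state=config.seed,
        warm_start=warm,
    )


def _cv_folds(y: np.ndarray, config: BRTConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    n_minority = int(min(np.bincount(y.astype(int))))
    n_folds = config.n_folds
    if n_minority < n_folds:
        warnings.warn(f"minority class has {n_minority} members; reducing "
                      f"folds from {n_folds} to {max(n_minority, 2)}")
        n_folds = max(n_minority, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=config.seed)
    return list(skf.split(np.zeros(len(y)), y))


def fit_with_cv(sample: CalibrationSample, predictors: list[str] | None = None,
                config: BRTConfig = BRTConfig(),
                _lr: float | None = None, _tc: int | None = None) -> FittedBRT:
    """Fit a BRT, choosing the tree count by k-fold cross-validation.

    Trees are grown in increments of ``config.tree_step`` with the mean
    held-out Bernoulli deviance tracked across folds; the scan stops
    early once the deviance has not improved for ``config.cv_patience``
    consecutive increments. The final model is refit on the full sample
    at the deviance-minimizing tree count.
    """
    if predictors is None:
        predictors = list(sample.predictor_names)
    if len(predictors) < 1:
        raise ValueError("empty predictor list")
    lr = config.learning_rate if _lr is None else _lr
    tc = config.tree_complexity if _tc is None else _tc

    X = sample.table[predictors]
    y = sample.y
    _validate_inputs(X, y)
    Xv = X.values

    folds = _cv_folds(y, config)
    models = [_new_estimator(config, lr, tc, 0, warm=True) for _ in folds]

    counts: list[int] = []
    fold_devs: list[np.ndarray] = []
    best_dev = np.inf
    best_i = 0
    since_best = 0
    n = 0
    while n < config.max_trees:
        n = min(n + config.tree_step, config.max_trees)
        devs = np.empty(len(folds))
        for k, (tr, va) in enumerate(folds):
            models[k].set_params(n_estimators=n)
            models[k].fit(Xv[tr], y[tr])
            p = models[k].predict_proba(Xv[va])[:, 1]
            devs[k] = bernoulli_deviance(y[va], p)
        counts.append(n)
        fold_devs.append(devs)
        mean_dev = devs.mean()
        if mean_dev < best_dev - 1e-12:
            best_dev = mean_dev
            best_i = len(counts) - 1
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.cv_patience:
                break

    n_trees = counts[best_i]
    curve = np.column_stack([counts, [d.mean() for d in fold_devs]])
    se = float(fold_devs[best_i].std(ddof=1) / np.sqrt(len(folds)))

    final = _new_estimator(config, lr, tc, n_trees, warm=False)
    final.fit(Xv, y)
    return FittedBRT(
        estimator=final, predictors=list(predictors), n_trees=n_trees,
        learning_rate=lr, tree_complexity=tc, cv_curve=curve,
        cv_deviance=float(best_dev), cv_deviance_se=se,
        train_X=X.copy(), train_y=y.copy(), config=config,
    )


def tune(sample: CalibrationSample, predictors: list[str] | None = None,
         config: BRTConfig = BRTConfig()) -> FittedBRT:
    """Adapt the learning rate (and, if needed, tree complexity) until the
    CV-selected tree count falls inside ``config.tree_count_window``.

    Too few trees -> the learning rate is decreased; too many -> it is
    increased. The adjustment is proportional to the shortfall (the
    optimal tree count scales roughly inversely with the learning rate),
    clamped so a single move never changes the rate by more than 20x.
    The tree complexity is only stepped (within [3, 10]) after three
    consecutive learning-rate-only iterations fail. If the iteration
    budget is exhausted the best (closest) model is returned flagged.
    """
    lo, hi = config.tree_count_window
    target = int(math.sqrt(lo * hi))
    lr = config.learning_rate
    tc = config.tree_complexity
    history: list[dict] = []
    best: FittedBRT | None = None
    best_gap = np.inf
    lr_only_streak = 0

    for iteration in range(config.max_loop_iterations):
        model = fit_with_cv(sample, predictors, config, _lr=lr, _tc=tc)
        nt = model.n_trees
        history.append({"iteration": iteration, "learning_rate": lr,
                        "tree_complexity": tc, "n_trees": nt})
        if lo <= nt <= hi:
            model.tuning_history = history
            return model
        gap = lo - nt if nt < lo else nt - hi
        if gap < best_gap:
            best_gap = gap
            best = model
        lr_only_streak += 1
        lr *= float(np.clip(nt / target, 0.05, 20.0))
        if lr_only_streak >= 3:
            if nt < lo:
                tc = max(tc - 1, 3)
            else:
                tc = min(tc + 1, 10)
            lr_only_streak = 0

    log.warning("tuning loop exhausted %d iterations; returning best-so-far "
                "(n_trees=%d) flagged", config.max_loop_iterations,
                best.n_trees)
    best.flagged = True
    best.tuning_history = history
    return best


def contributions(model: FittedBRT) -> dict[str, float]:
    """Relative influence per predictor from split-improvement totals,
    normalized to sum to 100."""
    imp = model.estimator.feature_importances_
    total = imp.sum()
    if total <= 0:
        return {p: 0.0 for p in model.predictors}
    return {p: float(100.0 * v / total)
            for p, v in zip(model.predictors, imp)}


def _quantile_grid(x: np.ndarray, n: int) -> np.ndarray:
    grid = np.unique(np.quantile(x, np.linspace(0.01, 0.99, n)))
    return grid


def interactions(model: FittedBRT, n_grid: int = 20) -> InteractionMatrix:
    """Pairwise interaction sizes from residual variance.

    For each pair, predictions over a quantile grid of the two predictors
    (all others fixed at their training medians) are decomposed into
    additive row/column effects; the interaction size is the residual
    variance scaled by 1000. Predictions are taken on the link (log-odds)
    scale so a purely additive model has (near-)zero residual variance.
    Constant predictors get a zero row.
    """
    preds = model.predictors
    if len(preds) < 2:
        raise ValueError("interactions need at least 2 predictors")
    Xt = model.train_X
    medians = Xt.median().values
    p = len(preds)
    mat = np.zeros((p, p))
    grids = []
    for name in preds:
        x = Xt[name].values
        if np.ptp(x) == 0:
            warnings.warn(f"predictor {name!r} is constant; zero interaction "
                          "row")
            grids.append(None)
        else:
            grids.append(_quantile_grid(x, n_grid))
    for i in range(p):
        if grids[i] is None:
            continue
        for j in range(i + 1, p):
            if grids[j] is None:
                continue
            gi, gj = grids[i], grids[j]
            ni, nj = len(gi), len(gj)
            block = np.tile(medians, (ni * nj, 1))
            ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
            block[:, i] = gi[ii.ravel()]
            block[:, j] = gj[jj.ravel()]
            z = model.estimator.decision_function(block).reshape(ni, nj)
            resid = (z - z.mean(axis=1, keepdims=True)
                     - z.mean(axis=0, keepdims=True) + z.mean())
            mat[i, j] = mat[j, i] = 1000.0 * resid.var()
    return InteractionMatrix(list(preds), mat)


def response_curve(model: FittedBRT, predictor: str,
                   n_points: int = 100) -> ResponseCurve:
    """Partial dependence of one predictor on the probability scale.

    Other predictors are fixed at their training medians; the grid spans
    the training 1st-99th percentile.
    """
    if predictor not in model.predictors:
        raise KeyError(f"predictor {predictor!r} not in model")
    Xt = model.train_X
    x = Xt[predictor].values
    lo, hi = np.quantile(x, [0.01, 0.99])
    if hi <= lo:
        hi = lo + 1e-9
    grid = np.linspace(lo, hi, n_points)
    block = np.tile(Xt.median().values, (n_points, 1))
    block[:, model.predictors.index(predictor)] = grid
    resp = model.estimator.predict_proba(block)[:, 1]
    return ResponseCurve(predictor, grid, resp)


def simplify(model: FittedBRT, sample: CalibrationSample,
             config: BRTConfig | None = None,
             candidates_per_round: int = 1,
             max_drops: int | None = None) -> list[str]:
    """Iteratively drop predictors whose removal does not hurt CV deviance.

    Each round considers the ``candidates_per_round`` lowest-contribution
    predictors, refits with each candidate removed on the same folds at
    the model's tuned hyperparameters, and drops the one whose removal
    least increases the mean CV deviance — stopping as soon as the best
    increase exceeds one standard error of the original CV deviance.
    Returns the surviving predictor names (possibly all of them).
    """
    config = config or model.config
    y = sample.y
    folds = _cv_folds(y, config)
    keep = list(model.predictors)
    baseline = model.cv_deviance
    se = model.cv_deviance_se
    contrib = contributions(model)
    n_drops = 0

    def cv_dev(names: list[str]) -> float:
        Xv = sample.table[names].values
        devs = []
        for tr, va in folds:
            est = _new_estimator(config, model.learning_rate,
                                 model.tree_complexity, model.n_trees,
                                 warm=False)
            est.fit(Xv[tr], y[tr])
            devs.append(bernoulli_deviance(y[va],
                                           est.predict_proba(Xv[va])[:, 1]))
        return float(np.mean(devs))

    while len(keep) > 1:
        if max_drops is not None and n_drops >= max_drops:
            break
        order = sorted(keep, key=lambda nm: contrib.get(nm, 0.0))
        candidates = order[:candidates_per_round]
        best_name, best_val = None, np.inf
        for name in candidates:
            val = cv_dev([nm for nm in keep if nm != name])
            if val < best_val:
                best_val, best_name = val, name
        if best_val - baseline > se:
            break
        keep.remove(best_name)
        n_drops += 1
        log.info("simplify: dropped %r (CV deviance %.4f vs baseline %.4f)",
                 best_name, best_val, baseline)
    return keep


def predict_map(model: FittedBRT, stack: PredictorStack):
    """Project the model onto a predictor stack; masked cells become NaN."""
    import xarray as xr

    missing = [p for p in model.predictors if p not in stack.data]
    if missing:
        raise KeyError(f"stack is missing model predictors: {missing}")
    cols = np.column_stack([stack.array(p).ravel() for p in model.predictors])
    prob = model.estimator.predict_proba(cols)[:, 1]
    out = prob.reshape(stack.grid.shape)
    if stack.mask is not None:
        out = np.where(stack.mask, out, np.nan)
    return xr.DataArray(out, dims=("lat", "lon"),
                        coords={"lat": stack.grid.lats,
                                "lon": stack.grid.lons},
                        name="probability")
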