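"""Tuned, covariate-pruned random-forest regression for log population density.

The estimation procedure is multi-stage:

1. tune ``mtry`` (covariates sampled per split) by a stepwise search that
   minimises out-of-bag (OOB) mean squared error;
2. grow a forest of regression trees on bootstrap samples, trees grown
   until terminal nodes hold at most ``round(N/1000)`` observations (a
   single observation when N < 1000);
3. compute per-covariate OOB permutation importance, drop every covariate
   whose importance is non-positive, and repeat from step 1 on the reduced
   set until only positive importances remain.

The ensemble logic (bootstrap, OOB accounting, permutation importance,
tuning, elimination) is implemented here; individual CART regression trees
come from scikit-learn.  Forest predictions are the per-tree mean of the
log density, so they can never leave the range of training responses.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .training_table import TrainingTable

log = logging.getLogger(__name__)

_BUNDLE_VERSION = 1


def terminal_node_cap(n_units: int, divisor: int = 1000) -> int:
    """Max observations per terminal node: round(N/1000), floor 1.

    Uses round-half-to-even for the "rounded to the nearest whole number"
    rule (so N = 2500 gives 2); a single observation when N < divisor.
    """
    if n_units < divisor:
        return 1
    return max(1, round(n_units / divisor))


@dataclass
class ForestParams:
    """Tuning parameters of the density forest.

    ``n_trees`` defaults to 500 (sufficient for a stable, minimised OOB
    error).  ``node_cap`` is derived from N via :func:`terminal_node_cap`
    when left None.  ``mtry`` (split candidates per node) is tuned when
    None.  The tuning constants mirror the stepwise search of the R
    randomForest package's ``tuneRF``: start at floor(p/3), multiply or
    divide by ``tune_step_factor``, accept a step while the relative OOB
    improvement is at least ``tune_improve``.
    """

    n_trees: int = 500
    node_cap: int | None = None
    mtry: int | None = None
    seed: int = 0
    tune_step_factor: float = 2.0
    tune_improve: float = 0.05
    tune_n_trees: int | None = None  # None: tuning forests match n_trees
    node_cap_divisor: int = 1000
    #: elimination treats a covariate as zero-importance when its permutation
    #: score does not exceed this fraction of the largest score.  Fully grown
    #: regression trees give even pure-noise covariates a small positive
    #: permutation bias (they fit residual noise), so exact non-positivity
    #: under-eliminates; 2% is "zero" at the resolution of an importance plot.
    importance_rel_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.node_cap is not None and self.node_cap < 1:
            raise ValueError("node_cap must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolved(self, n_units: int, p: int) -> "ForestParams":
        """Fill derived defaults for a concrete table size."""
        node_cap = self.node_cap or terminal_node_cap(n_units, self.node_cap_divisor)
        mtry = self.mtry or max(1, p // 3)
        mtry = min(mtry, p)
        return replace(self, node_cap=node_cap, mtry=mtry)


@dataclass
class ForestModel:
    """A fitted forest with OOB statistics and importance scores."""

    trees: list
    oob_masks: np.ndarray  # (n_trees, N) bool: obs out of bag for tree t
    params: ForestParams
    covariate_names: list[str]
    importance: pd.DataFrame  # permutation, permutation_se, node_purity
    oob_mse: float
    oob_var_explained: float
    response_range: tuple[float, float]
    n_units: int
    density_unit: str = "people per km^2 (natural log)"

    def predict_log(self, X: np.ndarray) -> np.ndarray:
        """Mean over trees of the predicted log density, clipped to the
        training response range (forest means cannot extrapolate; the clip
        only removes float-summation rounding)."""
        X = np.asarray(X, dtype=np.float64)
        acc = np.zeros(len(X), dtype=np.float64)
        for tree in self.trees:
            acc += tree.predict(X)
        acc /= len(self.trees)
        return np.clip(acc, self.response_range[0], self.response_range[1])

    def predict_density(self, X: np.ndarray) -> np.ndarray:
        """Back-transformed density: exp of the mean log prediction."""
        return np.exp(self.predict_log(X))

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        joblib.dump({"version": _BUNDLE_VERSION, "model": self}, path)

    @classmethod
    def load(cls, path) -> "ForestModel":
        bundle = joblib.load(path)
        if bundle.get("version") != _BUNDLE_VERSION:
            raise ValueError(f"unsupported model bundle version {bundle.get('version')}")
        return bundle["model"]


# ---------------------------------------------------------------------------
# Forest growing
# ---------------------------------------------------------------------------

def _fit_trees(
    X: np.ndarray, y: np.ndarray, params: ForestParams, rng: np.random.Generator
):
    """Grow the ensemble; returns (trees, oob_masks)."""
    n = len(y)
    trees = []
    oob = np.zeros((params.n_trees, n), dtype=bool)
    for t in range(params.n_trees):
        boot = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = DecisionTreeRegressor(
            max_features=params.mtry,
            min_samples_split=params.node_cap + 1,
            min_samples_leaf=1,
            random_state=tree_seed,
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        mask = np.ones(n, dtype=bool)
        mask[boot] = False
        oob[t] = mask
    return trees, oob


def _oob_predictions(trees, oob_masks, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation OOB mean prediction and the count of contributing trees."""
    n = len(X)
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for tree, mask in zip(trees, oob_masks):
        if mask.any():
            acc[mask] += tree.predict(X[mask])
            cnt[mask] += 1
    with np.errstate(invalid="ignore"):
        pred = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pred, cnt


def _oob_mse(trees, oob_masks, X, y) -> float:
    pred, cnt = _oob_predictions(trees, oob_masks, X)
    covered = cnt > 0
    if not covered.any():
        return float("nan")
    return float(np.mean((y[covered] - pred[covered]) ** 2))


def _permutation_importance(
    trees, oob_masks, X, y, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """OOB permutation importance: per tree, the increase in OOB MSE after
    permuting one covariate among that tree's OOB rows, averaged over trees.
    Returns (mean, standard error) per covariate."""
    p = X.shape[1]
    deltas: list[np.ndarray] = []
    for tree, mask in zip(trees, oob_masks):
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            continue
        Xo = X[idx]
        yo = y[idx]
        base = np.mean((tree.predict(Xo) - yo) ** 2)
        row = np.empty(p)
        for j in range(p):
            perm = rng.permutation(idx.size)
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            row[j] = np.mean((tree.predict(Xp) - yo) ** 2) - base
        deltas.append(row)
    if not deltas:
        return np.zeros(p), np.zeros(p)
    D = np.vstack(deltas)
    mean = D.mean(axis=0)
    se = D.std(axis=0, ddof=1) / math.sqrt(len(D)) if len(D) > 1 else np.zeros(p)
    return mean, se


def _node_purity_importance(trees, p: int) -> np.ndarray:
    """Mean (over trees) total decrease in residual sum of squares credited
    to splits on each covariate."""
    total = np.zeros(p)
    for tree in trees:
        t = tree.tree_
        imp = np.zeros(p)
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:  # leaf
                continue
            gain = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            )
            imp[t.feature[node]] += gain
        total += imp
    return total / len(trees)


def grow_forest(table: TrainingTable, params: ForestParams | None = None) -> ForestModel:
    """Fit the regression forest on the training table.

    Each tree is fit on a bootstrap sample of size N drawn with
    replacement; splits choose among ``mtry`` randomly drawn covariates and
    trees grow until terminal nodes hold at most ``node_cap`` observations.
    OOB error is computed from per-observation averages over the trees in
    which the observation was out of bag.  Fully deterministic given
    (seed, table).
    """
    params = (params or ForestParams()).resolved(table.n_units, len(table.covariate_names))
    X, y = table.X, table.y
    if len(y) < 2:
        raise ValueError("need at least 2 training units")
    rng = np.random.default_rng(params.seed)
    trees, oob = _fit_trees(X, y, params, rng)
    oob_mse = _oob_mse(trees, oob, X, y)
    var_y = float(np.var(y))
    oob_ve = 1.0 - oob_mse / var_y if var_y > 0 else (1.0 if oob_mse == 0 else 0.0)
    perm_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xA11CE]))
    perm, perm_se = _permutation_importance(trees, oob, X, y, perm_rng)
    purity = _node_purity_importance(trees, X.shape[1])
    importance = pd.DataFrame(
        {
            "permutation": perm,
            "permutation_se": perm_se,
            "node_purity": purity,
        },
        index=pd.Index(table.covariate_names, name="covariate"),
    )
    return ForestModel(
        trees=trees,
        oob_masks=oob,
        params=params,
        covariate_names=list(table.covariate_names),
        importance=importance,
        oob_mse=oob_mse,
        oob_var_explained=oob_ve,
        response_range=(float(y.min()), float(y.max())),
        n_units=len(y),
        density_unit=table.density_unit,
    )


# ---------------------------------------------------------------------------
# mtry tuning
# ---------------------------------------------------------------------------

def tune_mtry(table: TrainingTable, params: ForestParams | None = None) -> int:
    """Stepwise OOB-error minimisation of mtry.

    Starts at max(1, floor(p/3)); steps multiply (rightward) or divide
    (leftward) by ``tune_step_factor``, and a direction keeps stepping while
    the relative OOB-MSE improvement over the best error so far is at least
    ``tune_improve``.  Returns the argmin over all evaluated values (ties
    to the smaller mtry).  Deterministic given the seed.  Tuning forests
    default to the full ``n_trees`` — with few training units a smaller
    tuning ensemble makes the OOB objective too noisy to step on; the R
    package's 50-tree shortcut remains available via ``tune_n_trees``.
    """
    params = params or ForestParams()
    p = len(table.covariate_names)
    if p < 1:
        raise ValueError("no covariates to tune over")
    if np.var(table.y) == 0:
        raise ValueError("constant response; mtry tuning is meaningless")
    if p == 1:
        return 1

    X, y = table.X, table.y
    node_cap = params.node_cap or terminal_node_cap(len(y), params.node_cap_divisor)
    errs: dict[int, float] = {}

    tune_trees = params.tune_n_trees or params.n_trees

    def oob_err(m: int) -> float:
        if m not in errs:
            sub = replace(params, mtry=m, node_cap=node_cap, n_trees=tune_trees)
            # one fixed stream per candidate keeps the search order-independent
            rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x7E5, m]))
            trees, oob = _fit_trees(X, y, sub, rng)
            errs[m] = _oob_mse(trees, oob, X, y)
        return errs[m]

    start = max(1, p // 3)
    best = oob_err(start)
    accepted = {start}
    for direction in (+1, -1):
        m, cur_best = start, best
        while True:
            nxt = (
                min(p, math.ceil(m * params.tune_step_factor))
                if direction > 0
                else max(1, math.floor(m / params.tune_step_factor))
            )
            if nxt == m:
                break
            e = oob_err(nxt)
            improve = 1.0 - e / cur_best if cur_best > 0 else 0.0
            if not (improve >= params.tune_improve):
                break
            accepted.add(nxt)
            cur_best = min(cur_best, e)
            m = nxt
    return min(accepted, key=lambda m: (errs[m], m))


# ---------------------------------------------------------------------------
# Iterative covariate elimination
# ---------------------------------------------------------------------------

def select_covariates(
    table: TrainingTable, params: ForestParams | None = None
) -> tuple[TrainingTable, ForestModel, list[dict]]:
    """Iteratively drop covariates with (effectively) zero permutation importance.

    Loop: tune mtry on the current covariate set, grow the forest, compute
    OOB permutation importance, remove every covariate whose importance is
    "zero" — non-positive, or no larger than ``importance_rel_tol`` times
    the top score (see :class:`ForestParams`) — then re-tune on the reduced
    set.  Terminates when every remaining importance clears the bound or a
    single covariate remains; if an iteration would drop everything, the
    best-ranked covariate is kept.

    Returns (reduced table, final model, elimination log).  Typically
    converges in one or two iterations.
    """
    params = params or ForestParams()
    current = table
    history: list[dict] = []
    for iteration in range(1, len(table.covariate_names) + 2):
        p = len(current.covariate_names)
        mtry = tune_mtry(current, params) if p > 1 else 1
        model = grow_forest(current, replace(params, mtry=mtry))
        imp = model.importance["permutation"]
        threshold = max(0.0, params.importance_rel_tol * float(imp.max()))
        drop = list(imp.index[imp <= threshold])
        keep = list(imp.index[imp > threshold])
        if not keep:  # termination guard: never reject every covariate
            keep = [imp.idxmax()]
            drop = [c for c in imp.index if c != keep[0]]
        history.append(
            {
                "iteration": iteration,
                "mtry": mtry,
                "oob_mse": model.oob_mse,
                "n_covariates": p,
                "dropped": drop,
            }
        )
        if not drop or p == 1:
            return current, model, history
        log.info("elimination iteration %d: dropping %s", iteration, drop)
        current = current.subset_covariates(keep)
    raise AssertionError("covariate elimination failed to terminate")  # pragma: no cover


# ---------------------------------------------------------------------------
# Self-documenting summary
# ---------------------------------------------------------------------------

def forest_summary(model: ForestModel) -> dict:
    """Metadata report: importance ranking, OOB statistics and parameters.

    JSON-serialisable; the CLI writes it next to the model bundle so each
    mapping run self-documents.
    """
    imp = model.importance.sort_values("permutation", ascending=False)
    return {
        "n_units": model.n_units,
        "n_trees": model.params.n_trees,
        "mtry": model.params.mtry,
        "node_cap": model.params.node_cap,
        "seed": model.params.seed,
        "oob_mse": model.oob_mse,
        "oob_var_explained": model.oob_var_explained,
        "response_range": list(model.response_range),
        "response_unit": model.density_unit,
        "covariates": list(model.covariate_names),
        "importance": [
            {
                "covariate": name,
                "permutation": float(row["permutation"]),
                "permutation_se": float(row["permutation_se"]),
                "node_purity": float(row["node_purity"]),
            }
            for name, row in imp.iterrows()
        ],
    }


def write_summary(model: ForestModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(forest_summary(model), fh, indent=2)
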