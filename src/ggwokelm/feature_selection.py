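"""G-GWO-driven wrapper feature selection and KELM hyperparameter tuning.

A candidate solution is a continuous wolf position over the box [-1, 2]^N
(one coordinate per feature); it is turned into a binary inclusion mask by
stochastic thresholding and scored with the wrapper fitness

    fitness = alpha * P + (1 - alpha) * (N - L) / N,

where P is the validation accuracy of a KELM trained on the selected
columns, L the number of selected features and N the total feature count.
alpha (default 0.99) trades predictive quality against subset parsimony.
Hyperparameter tuning searches (log2 C, log2 gamma) with the same machinery,
either alone or jointly appended to the feature coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kelm import kelm_fit, kelm_predict
from .metrics import confusion_counts, classification_metrics, one_vs_rest_report
from .optimizers import binarize_position, ggwo_optimize

__all__ = [
    "FlagVector",
    "SelectionResult",
    "stratified_holdout",
    "wrapper_fitness",
    "subset_fitness",
    "select_features",
    "tune_hyperparameters",
    "svd_reduce",
    "SVDTransform",
]

_WORST = 1e9  # sentinel minimized fitness for empty subsets


@dataclass(frozen=True)
class FlagVector:
    """Binary feature-inclusion mask; L = number of selected features."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.flags, dtype=np.uint8)
        if not np.all((f == 0) | (f == 1)):
            raise ValueError("flags must be binary")
        object.__setattr__(self, "flags", f)

    @property
    def L(self) -> int:
        return int(self.flags.sum())

    @property
    def N(self) -> int:
        return len(self.flags)


@dataclass
class SelectionResult:
    """Best solution of a selection/tuning run with its held-out report."""

    flags: FlagVector
    fitness: float
    holdout_metrics: Optional[dict]
    tuned_c: float
    tuned_gamma: float
    history: list
    evaluations: int
    seed: Optional[int]


def stratified_holdout(
    y: Sequence, train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index split keeping class proportions; every class lands on both
    sides (at least one training and one validation sample per class)."""
    y = np.asarray(y)
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0,1)")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def wrapper_fitness(p: float, n_selected: int, n_total: int, alpha: float = 0.99) -> float:
    """The wrapper objective alpha * P + (1 - alpha) * (N - L) / N.

    ``p`` is the classifier's validation quality in [0, 1], ``n_selected``
    (L) the subset size and ``n_total`` (N) the feature count.  Bounded in
    [0, alpha + (1 - alpha) (N - 1) / N]; at fixed P it strictly decreases
    as the subset grows.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not 1 <= n_selected <= n_total:
        raise ValueError("need 1 <= L <= N")
    return alpha * p + (1.0 - alpha) * (n_total - n_selected) / n_total


def subset_fitness(
    flags: FlagVector | np.ndarray,
    x: np.ndarray,
    y: Sequence,
    alpha: float = 0.99,
    c_reg: float = 32.0,
    gamma: float = 0.5,
    split: tuple[float, int] = (0.7, 0),
    p_metric: str = "accuracy",
) -> float:
    """Wrapper fitness alpha*P + (1-alpha)*(N-L)/N of one feature subset.

    ``P`` is by default the validation accuracy of a KELM(C, gamma) trained
    on the flagged columns; set ``p_metric="precision"`` to use the
    macro-averaged one-vs-rest precision instead.
    """
    if not isinstance(flags, FlagVector):
        flags = FlagVector(np.asarray(flags))
    if flags.L == 0:
        raise ValueError("empty feature subset")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape[1] != flags.N:
        raise ValueError("flag length does not match feature count")
    train_frac, split_seed = split
    tr, va = stratified_holdout(y, train_frac, split_seed)
    if len(set(y[tr])) < 2 or len(set(y[va])) < 1:
        raise ValueError("split leaves a side without class coverage")
    cols = np.flatnonzero(flags.flags)
    model = kelm_fit(x[np.ix_(tr, cols)], y[tr], c_reg=c_reg, gamma=gamma)
    pred = kelm_predict(model, x[np.ix_(va, cols)])
    if p_metric == "accuracy":
        p = float(np.mean(np.asarray(pred) == y[va]))
    elif p_metric == "precision":
        rep = one_vs_rest_report(list(y[va]), list(pred))
        p = rep["macro"].pre if rep["macro"].pre is not None else 0.0
    else:
        raise ValueError(f"unknown p_metric {p_metric!r}")
    return wrapper_fitness(p, flags.L, flags.N, alpha)


def _holdout_report(
    flags: FlagVector,
    x: np.ndarray,
    y: np.ndarray,
    c_reg: float,
    gamma: float,
    split: tuple[float, int],
) -> dict:
    tr, va = stratified_holdout(y, split[0], split[1])
    cols = np.flatnonzero(flags.flags)
    model = kelm_fit(x[np.ix_(tr, cols)], y[tr], c_reg=c_reg, gamma=gamma)
    pred = kelm_predict(model, x[np.ix_(va, cols)])
    if len(set(y[va])) >= 2:
        return one_vs_rest_report(list(y[va]), list(pred))
    counts = confusion_counts(list(y[va]), list(pred), positive_label=y[va][0])
    return {y[va][0]: classification_metrics(counts)}


def select_features(
    x: np.ndarray,
    y: Sequence,
    pop_size: int = 8,
    max_iter: int = 200,
    alpha: float = 0.99,
    domain: tuple[float, float] = (-1.0, 2.0),
    kelm_params: tuple[float, float] = (32.0, 0.5),
    split: tuple[float, int] = (0.7, 0),
    ga_generations: int = 10,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> SelectionResult:
    """Binary feature selection by G-GWO over the box ``domain``^N.

    Each continuous position is binarized stochastically (a coordinate j
    selects its feature when it exceeds a fresh uniform draw) and scored by
    :func:`subset_fitness`; the optimizer minimizes the negated fitness.
    An all-zero mask is assigned a sentinel worst fitness rather than
    aborting, so the pack can move away from it.  The best-ever flag vector
    is returned with its held-out one-vs-rest metric report.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n_features = x.shape[1]
    if n_features < 2:
        raise ValueError("need at least two features")
    rng = np.random.default_rng(seed) if rng is None else rng
    c_reg, gamma = kelm_params

    best: dict = {"fitness": -np.inf, "flags": None}

    def objective(pos: np.ndarray) -> float:
        flags = binarize_position(pos, rng)
        if flags.sum() == 0:
            return _WORST
        fit = subset_fitness(
            FlagVector(flags), x, y, alpha=alpha, c_reg=c_reg, gamma=gamma, split=split
        )
        if fit > best["fitness"]:
            best["fitness"] = fit
            best["flags"] = flags.copy()
        return -fit

    bounds = [domain] * n_features
    opt = ggwo_optimize(
        objective,
        bounds,
        pop_size=pop_size,
        max_iter=max_iter,
        ga_generations=ga_generations,
        rng=rng,
        seed=seed,
    )
    flags = FlagVector(best["flags"])
    report = _holdout_report(flags, x, y, c_reg, gamma, split)
    return SelectionResult(
        flags=flags,
        fitness=best["fitness"],
        holdout_metrics=report,
        tuned_c=c_reg,
        tuned_gamma=gamma,
        history=opt.history,
        evaluations=opt.evaluations,
        seed=seed,
    )


def tune_hyperparameters(
    x: np.ndarray,
    y: Sequence,
    mode: str = "hyperparams",
    c_range: tuple[float, float] = (2.0**-5, 2.0**15),
    gamma_range: tuple[float, float] = (2.0**-10, 2.0**5),
    pop_size: int = 8,
    max_iter: int = 200,
    alpha: float = 0.99,
    domain: tuple[float, float] = (-1.0, 2.0),
    split: tuple[float, int] = (0.7, 0),
    ga_generations: int = 10,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> SelectionResult:
    """Search KELM (C, gamma) on a log2 scale, optionally jointly with the
    feature mask.

    ``mode="hyperparams"`` keeps every feature (L = N) and searches the two
    continuous coordinates (log2 C, log2 gamma); ``mode="joint"`` appends
    them to the N feature coordinates so subset and hyperparameters evolve
    together under the same wrapper fitness.
    """
    if mode not in ("hyperparams", "joint"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n_features = x.shape[1]
    rng = np.random.default_rng(seed) if rng is None else rng
    log_c = (np.log2(c_range[0]), np.log2(c_range[1]))
    log_g = (np.log2(gamma_range[0]), np.log2(gamma_range[1]))

    best: dict = {"fitness": -np.inf, "flags": None, "c": None, "gamma": None}

    def score(flags: np.ndarray, c_reg: float, gamma: float) -> float:
        if flags.sum() == 0:
            return _WORST
        fit = subset_fitness(
            FlagVector(flags), x, y, alpha=alpha, c_reg=c_reg, gamma=gamma, split=split
        )
        if fit > best["fitness"]:
            best.update(fitness=fit, flags=flags.copy(), c=c_reg, gamma=gamma)
        return -fit

    if mode == "hyperparams":
        bounds = [log_c, log_g]

        def objective(pos: np.ndarray) -> float:
            return score(np.ones(n_features, dtype=np.uint8), 2.0 ** pos[0], 2.0 ** pos[1])

    else:
        bounds = [domain] * n_features + [log_c, log_g]

        def objective(pos: np.ndarray) -> float:
            flags = binarize_position(pos[:n_features], rng)
            return score(flags, 2.0 ** pos[n_features], 2.0 ** pos[n_features + 1])

    opt = ggwo_optimize(
        objective,
        bounds,
        pop_size=pop_size,
        max_iter=max_iter,
        ga_generations=ga_generations,
        rng=rng,
        seed=seed,
    )
    flags = FlagVector(best["flags"])
    report = _holdout_report(flags, x, y, best["c"], best["gamma"], split)
    return SelectionResult(
        flags=flags,
        fitness=best["fitness"],
        holdout_metrics=report,
        tuned_c=float(best["c"]),
        tuned_gamma=float(best["gamma"]),
        history=opt.history,
        evaluations=opt.evaluations,
        seed=seed,
    )


@dataclass
class SVDTransform:
    """Column means and top right-singular vectors of the training matrix;
    applies the same centered projection to new data."""

    means: np.ndarray
    components: np.ndarray  # d x rank

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.means) @ self.components


def svd_reduce(x: np.ndarray, rank: int) -> tuple[np.ndarray, SVDTransform]:
    """Project onto the top-``rank`` right singular directions of the
    column-centered matrix (truncated PCA without variance scaling)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    if not 1 <= rank <= min(n, d):
        raise ValueError(f"rank must be in [1, {min(n, d)}], got {rank}")
    means = x.mean(axis=0)
    _, _, vt = np.linalg.svd(x - means, full_matrices=False)
    transform = SVDTransform(means=means, components=vt[:rank].T)
    return transform.apply(x), transform
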