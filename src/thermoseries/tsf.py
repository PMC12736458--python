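"""Interval-based Time Series Forest (TSF) for multivariate series.

Each tree of the ensemble samples ``k`` random temporal intervals per
variable, summarizes every interval by (mean, standard deviation, slope)
and grows an entropy-gain CART tree on the resulting 3*k*V feature vector.
Interval randomness — not bagging — provides ensemble diversity, following
the interval-forest construction for time series.  Predictions are majority
votes; the fraction of trees voting for the positive (cancer) class serves
as the ROC score.  Per-tree interval bookkeeping supports a temporal
importance curve: every split's impurity decrease is credited to the time
indices covered by the split feature's interval.

Intervals are expressed 1-based inclusive, matching the usual interval
notation for series positions; array slicing converts internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "IntervalSpec",
    "ForestConfig",
    "TemporalImportance",
    "sample_intervals",
    "interval_summary",
    "tree_features",
    "TimeSeriesForest",
    "fit_forest",
    "grid_search",
    "DEFAULT_GRID",
]

#: Hyperparameter grid searched in the experiments.
DEFAULT_GRID = {"n_trees": (100, 200, 300), "min_interval": (3, 5, 7)}


@dataclass(frozen=True)
class IntervalSpec:
    """Temporal interval of one variable, 1-based inclusive endpoints."""

    variable: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end):
            raise ValueError(f"need 1 <= start < end, got [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 100
    min_interval: int = 3
    k: int | None = None  # intervals per variable; None -> round(sqrt(M))
    max_depth: int | None = None
    seed: int = 0
    margin_tiebreak: bool = False  # secondary split comparator

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        if self.min_interval < 2:
            raise ValueError("minimum interval length must be >= 2")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")

    def resolve_k(self, m: int) -> int:
        return self.k if self.k is not None else max(1, round(math.sqrt(m)))


def sample_intervals(
    m: int, k: int, min_interval: int, rng: np.random.Generator, n_vars: int = 1
) -> list[IntervalSpec]:
    """Draw ``k`` random intervals per variable along a length-``m`` axis.

    Interval length is uniform on [min_interval, m], then the start is
    uniform over the admissible positions.  Deterministic given the rng
    state.
    """
    if min_interval > m:
        raise ValueError(f"min_interval {min_interval} exceeds series length {m}")
    specs = []
    for v in range(n_vars):
        for _ in range(k):
            length = int(rng.integers(min_interval, m + 1))
            start = int(rng.integers(1, m - length + 2))
            specs.append(IntervalSpec(v, start, start + length - 1))
    return specs


def interval_summary(series: np.ndarray, spec: IntervalSpec) -> tuple[float, float, float]:
    """(mean, sd, slope) of a univariate series over one interval.

    sd uses the N-1 denominator; the slope is the least-squares regression
    coefficient of value on time index.
    """
    series = np.asarray(series, dtype=float)
    if spec.end > series.shape[0]:
        raise ValueError(f"interval {spec} exceeds series length {series.shape[0]}")
    window = series[spec.start - 1 : spec.end]
    ell = window.shape[0]
    mu = float(window.mean())
    sd = float(window.std(ddof=1))
    j = np.arange(ell, dtype=float)
    jc = j - j.mean()
    beta = float(jc @ (window - mu) / (jc @ jc))
    return mu, sd, beta


def tree_features(xi: np.ndarray, intervals: list[IntervalSpec]) -> np.ndarray:
    """Concatenated (mean, sd, slope) per interval for one M x V sequence.

    Order follows the interval list (variable-major as produced by
    :func:`sample_intervals`): length exactly 3 * len(intervals).
    """
    feats = np.empty(3 * len(intervals))
    for i, spec in enumerate(intervals):
        feats[3 * i : 3 * i + 3] = interval_summary(xi[:, spec.variable], spec)
    return feats


def _batch_features(x: np.ndarray, intervals: list[IntervalSpec]) -> np.ndarray:
    """Interval features for an N x M x V tensor -> N x 3k' matrix."""
    n = x.shape[0]
    out = np.empty((n, 3 * len(intervals)))
    j = np.arange(x.shape[1], dtype=float)
    for i, spec in enumerate(intervals):
        window = x[:, spec.start - 1 : spec.end, spec.variable]
        ell = window.shape[1]
        mu = window.mean(axis=1)
        sd = window.std(axis=1, ddof=1)
        jc = j[:ell] - j[:ell].mean()
        beta = (window - mu[:, None]) @ jc / (jc @ jc)
        out[:, 3 * i] = mu
        out[:, 3 * i + 1] = sd
        out[:, 3 * i + 2] = beta
    return out


# ---------------------------------------------------------------------------
# entropy CART on interval features


def _entropy(p1: np.ndarray) -> np.ndarray:
    """Binary entropy for positive-class fractions (vectorized, 0*log0=0)."""
    p1 = np.clip(p1, 0.0, 1.0)
    p0 = 1.0 - p1
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p1 > 0, p1 * np.log2(p1), 0.0) - np.where(
            p0 > 0, p0 * np.log2(p0), 0.0
        )
    return h


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    label: int = 0
    weighted_gain: float = 0.0  # (n_node/n_root) * information gain
    is_leaf: bool = True


def _majority(y: np.ndarray) -> int:
    """Majority label; exact ties go to the negative (control) class."""
    pos = int(y.sum())
    return 1 if pos * 2 > y.size else 0


def _best_split(x: np.ndarray, y: np.ndarray, margin_tiebreak: bool):
    """Exhaustive best entropy-gain split over all features and thresholds.

    Returns (feature, threshold, gain) or None.  Ties are broken toward the
    first feature and smallest threshold; with ``margin_tiebreak`` the gap
    between the straddling values is compared first among gain ties.
    """
    n = y.size
    parent_h = float(_entropy(np.array(y.mean()))) if 0 < y.mean() < 1 else 0.0
    best = None  # (gain, margin, feature, threshold)
    for f in range(x.shape[1]):
        col = x[:, f]
        order = np.argsort(col, kind="stable")
        xs, ys = col[order], y[order]
        valid = xs[1:] > xs[:-1]
        if not valid.any():
            continue
        cum_pos = np.cumsum(ys)[:-1]
        n_left = np.arange(1, n)
        n_right = n - n_left
        p_left = cum_pos / n_left
        p_right = (y.sum() - cum_pos) / n_right
        child_h = (n_left * _entropy(p_left) + n_right * _entropy(p_right)) / n
        gains = np.where(valid, parent_h - child_h, -np.inf)
        i = int(np.argmax(gains))
        if gains[i] <= 0:
            continue
        margin = float(xs[i + 1] - xs[i])
        thr = float((xs[i] + xs[i + 1]) / 2.0)
        cand = (float(gains[i]), margin, f, thr)
        if best is None:
            best = cand
        else:
            if cand[0] > best[0] + 1e-12:
                best = cand
            elif abs(cand[0] - best[0]) <= 1e-12 and margin_tiebreak and cand[1] > best[1]:
                best = cand
    if best is None:
        return None
    return best[2], best[3], best[0]


def _grow(
    x: np.ndarray,
    y: np.ndarray,
    depth: int,
    max_depth: int | None,
    n_root: int,
    margin_tiebreak: bool,
) -> _Node:
    node = _Node(label=_majority(y))
    if y.size < 2 or y.min() == y.max():
        return node
    if max_depth is not None and depth >= max_depth:
        return node
    split = _best_split(x, y, margin_tiebreak)
    if split is None:
        return node
    f, thr, gain = split
    mask = x[:, f] <= thr
    node.feature = f
    node.threshold = thr
    node.is_leaf = False
    node.weighted_gain = (y.size / n_root) * gain
    node.left = _grow(x[mask], y[mask], depth + 1, max_depth, n_root, margin_tiebreak)
    node.right = _grow(x[~mask], y[~mask], depth + 1, max_depth, n_root, margin_tiebreak)
    return node


def _predict_tree(node: _Node, feats: np.ndarray) -> int:
    while not node.is_leaf:
        node = node.left if feats[node.feature] <= node.threshold else node.right
    return node.label


@dataclass(frozen=True)
class TemporalImportance:
    """Split-gain mass per (variable, time index); sums to 1."""

    values: np.ndarray  # (V, M)
    feature_names: tuple[str, ...] | None = None

    def argmax(self) -> tuple[int, int]:
        return np.unravel_index(int(np.argmax(self.values)), self.values.shape)


@dataclass
class TimeSeriesForest:
    config: ForestConfig
    n_frames_: int | None = None
    n_vars_: int | None = None
    trees_: list[_Node] = field(default_factory=list)
    intervals_: list[list[IntervalSpec]] = field(default_factory=list)

    @property
    def is_fitted(self) -> bool:
        return bool(self.trees_)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "TimeSeriesForest":
        """Fit on an N x M x V tensor with binary labels."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        if x.ndim != 3:
            raise ValueError("expected an N x M x V tensor")
        if np.unique(y).size < 2:
            raise ValueError("need both classes present to fit")
        n, m, v = x.shape
        k = self.config.resolve_k(m)
        rng = np.random.default_rng(self.config.seed)
        self.n_frames_, self.n_vars_ = m, v
        self.trees_, self.intervals_ = [], []
        for _ in range(self.config.n_trees):
            intervals = sample_intervals(m, k, self.config.min_interval, rng, n_vars=v)
            feats = _batch_features(x, intervals)
            tree = _grow(
                feats, y, 0, self.config.max_depth, n, self.config.margin_tiebreak
            )
            self.trees_.append(tree)
            self.intervals_.append(intervals)
        return self

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise RuntimeError("forest is not fitted")
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1] != self.n_frames_ or x.shape[2] != self.n_vars_:
            raise ValueError(
                f"expected shape (*, {self.n_frames_}, {self.n_vars_}), got {x.shape}"
            )
        return x

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        """Fraction of trees voting for the positive (cancer) class."""
        x = self._check_input(x)
        votes = np.zeros(x.shape[0])
        for tree, intervals in zip(self.trees_, self.intervals_):
            feats = _batch_features(x, intervals)
            votes += [_predict_tree(tree, row) for row in feats]
        return votes / len(self.trees_)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Majority-vote labels; exact vote ties go to control (0)."""
        return (self.predict_scores(x) > 0.5).astype(int)

    def temporal_importance(
        self, feature_names: tuple[str, ...] | None = None
    ) -> TemporalImportance:
        """Accumulate each split's weighted gain over the time indices of
        the split feature's interval, summed over trees, normalized to 1."""
        if not self.is_fitted:
            raise RuntimeError("forest is not fitted")
        mass = np.zeros((self.n_vars_, self.n_frames_))

        def visit(node: _Node, intervals: list[IntervalSpec]) -> None:
            if node.is_leaf:
                return
            spec = intervals[node.feature // 3]
            mass[spec.variable, spec.start - 1 : spec.end] += node.weighted_gain
            visit(node.left, intervals)
            visit(node.right, intervals)

        for tree, intervals in zip(self.trees_, self.intervals_):
            visit(tree, intervals)
        total = mass.sum()
        if total > 0:
            mass /= total
        return TemporalImportance(mass, feature_names)


def fit_forest(x: np.ndarray, y: np.ndarray, config: ForestConfig) -> TimeSeriesForest:
    return TimeSeriesForest(config).fit(x, y)


def grid_search(
    x: np.ndarray,
    y: np.ndarray,
    grid: dict = None,
    folds: int = 5,
    seed: int = 0,
    base_config: ForestConfig | None = None,
) -> tuple[ForestConfig, pd.DataFrame]:
    """Stratified-CV accuracy over the hyperparameter grid.

    Returns the winning config (highest mean accuracy; ties broken toward
    fewer trees, then shorter minimum interval) and the full CV table.
    """
    grid = grid or DEFAULT_GRID
    base = base_config or ForestConfig(seed=seed)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    for _, (tr, te) in enumerate(splits):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError("a fold lost one of the classes; reduce folds")
    rows = []
    for n_trees in grid["n_trees"]:
        for min_interval in grid["min_interval"]:
            cfg = ForestConfig(
                n_trees=n_trees,
                min_interval=min_interval,
                k=base.k,
                max_depth=base.max_depth,
                seed=base.seed,
                margin_tiebreak=base.margin_tiebreak,
            )
            accs = []
            for tr, te in splits:
                forest = TimeSeriesForest(cfg).fit(x[tr], y[tr])
                accs.append(float((forest.predict(x[te]) == y[te]).mean()))
            rows.append(
                {
                    "n_trees": n_trees,
                    "min_interval": min_interval,
                    "mean_accuracy": float(np.mean(accs)),
                    "sd_accuracy": float(np.std(accs)),
                }
            )
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        ["mean_accuracy", "n_trees", "min_interval"],
        ascending=[False, True, True],
        kind="stable",
    )
    best = ranked.iloc[0]
    best_cfg = ForestConfig(
        n_trees=int(best["n_trees"]),
        min_interval=int(best["min_interval"]),
        k=base.k,
        max_depth=base.max_depth,
        seed=base.seed,
        margin_tiebreak=base.margin_tiebreak,
    )
    return best_cfg, table
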