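"""Filter-stage feature scoring: the Kendall/chi-square greedy ranker and ReliefF.

Two filters run in tandem ahead of the wrapper search:

* **MKMC** (maximum Kendall, minimum chi-square) — an mRMR-style greedy
  forward ranking.  Relevance of a feature is the absolute tie-corrected
  Kendall rank correlation (tau-b) between the feature and the
  integer-encoded label; redundancy between two features is a normalized
  chi-square association on their discretized values.  Each greedy pick
  maximizes ``relevance - redundancy_to_selected``.
* **ReliefF** — instance-based weighting: for each sampled instance, feature
  weights decrease by the mean difference to the k nearest same-class
  neighbours (hits) and increase by the prior-weighted mean difference to
  the k nearest neighbours of every other class (misses).

Both produce a :class:`FeatureRanking` (ordered indices with the scores that
ordered them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import FeatureTable, check_labels, encode_labels

__all__ = [
    "FeatureRanking",
    "ReliefFParams",
    "kendall_tau",
    "label_relevance",
    "chi2_statistic",
    "chi2_2x2",
    "feature_redundancy",
    "mkmc_rank",
    "relieff_weights",
    "relieff_rank",
]

DEFAULT_BINS = 5  # equal-frequency bins for discretizing continuous features


@dataclass
class FeatureRanking:
    """Ordered feature indices with the scores that produced the order."""

    order: list[int]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.order) != len(self.scores):
            raise ValueError("order and scores must be aligned")
        if len(set(self.order)) != len(self.order):
            raise ValueError("order must not repeat feature indices")

    def __len__(self) -> int:
        return len(self.order)

    def top(self, k: int) -> list[int]:
        return self.order[:k]


# ---------------------------------------------------------------------------
# Kendall relevance
# ---------------------------------------------------------------------------

def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Kendall rank correlation (tau-b) in [-1, 1].

    Returns 0.0 by convention when either vector is constant (tau is
    undefined there; a constant feature carries no ordering information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need 1-d vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def label_relevance(table: FeatureTable, labels: np.ndarray) -> np.ndarray:
    """Per-feature relevance |tau_b(F_i, L)| in [0, 1].

    Labels are encoded as integers in sorted label order; for more than two
    classes this reads the label ordinally.
    """
    labels = check_labels(labels, table.n_samples)
    y = encode_labels(labels)
    return np.array([abs(kendall_tau(table.values[:, j], y))
                     for j in range(table.n_features)])


# ---------------------------------------------------------------------------
# Chi-square redundancy
# ---------------------------------------------------------------------------

def chi2_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """Goodness-of-fit statistic sum((O - E)^2 / E) over aligned count cells."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must be aligned")
    if np.any(expected <= 0):
        raise ValueError("expected frequencies must be strictly positive")
    if np.any(observed < 0):
        raise ValueError("observed frequencies must be nonnegative")
    return float(np.sum((observed - expected) ** 2 / expected))


def chi2_2x2(x: float, y: float, z: float, w: float, *, mode: str = "literal") -> float:
    """Association of a 2x2 contingency table (cells x, y / z, w).

    ``mode="literal"``: (xw - yz)^2 / ((x+y)(z+w)(x+z)(y+w)) — a phi-squared
    style quantity in [0, 1].  ``mode="standard"`` multiplies by the grand
    total N, giving the textbook uncorrected 2x2 chi-square statistic.
    A zero margin makes the association degenerate; 0 is returned with a
    warning.
    """
    if mode not in {"literal", "standard"}:
        raise ValueError(f"unknown mode {mode!r}")
    cells = np.array([x, y, z, w], dtype=float)
    if np.any(cells < 0):
        raise ValueError("contingency cells must be nonnegative")
    n = cells.sum()
    if n <= 0:
        raise ValueError("contingency table must have a positive total")
    margins = np.array([x + y, z + w, x + z, y + w], dtype=float)
    if np.any(margins == 0):
        warnings.warn("2x2 table has a zero margin; association undefined, returning 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    value = (x * w - y * z) ** 2 / np.prod(margins)
    return float(n * value) if mode == "standard" else float(value)


def _equal_frequency_codes(column: np.ndarray, bins: int) -> tuple[np.ndarray, int]:
    """Discretize into (at most) ``bins`` equal-frequency codes 0..n_codes-1."""
    qs = np.quantile(column, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(qs)
    codes = np.searchsorted(edges, column, side="left")
    # compact the code range (some bins may be empty after deduplication)
    _, codes = np.unique(codes, return_inverse=True)
    return codes, int(codes.max()) + 1


def feature_redundancy(f: np.ndarray, g: np.ndarray,
                       bins: int = DEFAULT_BINS) -> tuple[float, float]:
    """Chi-square redundancy between two feature columns.

    Continuous columns are discretized into equal-frequency bins, a
    contingency table is built, and the Pearson chi-square statistic is
    computed together with its Cramer's-V-squared normalization
    ``chi2 / (N * (min(r, c) - 1))`` so that redundancy lies in [0, 1] and
    is commensurate with an absolute rank correlation.  Constant columns
    have redundancy 0 by convention.

    Returns ``(chi2, normalized)``.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape or f.ndim != 1:
        raise ValueError("need two aligned 1-d columns")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.all(f == f[0]) or np.all(g == g[0]):
        return 0.0, 0.0
    cf, rf = _equal_frequency_codes(f, bins)
    cg, rg = _equal_frequency_codes(g, bins)
    if rf < 2 or rg < 2:
        return 0.0, 0.0
    n = len(f)
    counts = np.zeros((rf, rg))
    np.add.at(counts, (cf, cg), 1.0)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / n
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    normalized = chi2 / (n * (min(rf, rg) - 1))
    return chi2, float(min(normalized, 1.0))


# ---------------------------------------------------------------------------
# MKMC greedy ranking
# ---------------------------------------------------------------------------

def mkmc_rank(table: FeatureTable, labels: np.ndarray, k: int, *,
              aggregator: str = "min", bins: int = DEFAULT_BINS) -> FeatureRanking:
    """Greedy maximum-relevance / minimum-redundancy ranking of ``k`` features.

    The first pick maximizes label relevance alone; each subsequent pick
    maximizes ``relevance(f) - redundancy(f, S)`` where the redundancy of a
    candidate against the selected set S aggregates the normalized
    chi-square against each member, with aggregator ``"min"`` (default) or
    ``"mean"``.  Ties break toward the lower feature index.  Scores are the
    greedy objective values at the moment of selection.
    """
    if not 1 <= k <= table.n_features:
        raise ValueError(f"k must be in [1, {table.n_features}], got {k}")
    if aggregator not in {"min", "mean"}:
        raise ValueError(f"unknown aggregator {aggregator!r}")

    relevance = label_relevance(table, labels)
    d = table.n_features
    codes = [None] * d  # lazy per-feature discretization cache

    def get_codes(j: int):
        if codes[j] is None:
            col = table.values[:, j]
            if np.all(col == col[0]):
                codes[j] = (None, 1)
            else:
                codes[j] = _equal_frequency_codes(col, bins)
        return codes[j]

    n = table.n_samples
    order: list[int] = []
    scores: list[float] = []
    remaining = np.ones(d, dtype=bool)
    # running redundancy aggregate per candidate against the selected set
    red_min = np.full(d, np.inf)
    red_sum = np.zeros(d)

    for step in range(k):
        if step == 0:
            objective = relevance.copy()
        else:
            red = red_min if aggregator == "min" else red_sum / step
            objective = relevance - red
        objective[~remaining] = -np.inf
        pick = int(np.argmax(objective))  # argmax takes the lowest index on ties
        order.append(pick)
        scores.append(float(objective[pick]))
        remaining[pick] = False

        if step == k - 1:
            break
        cp, rp = get_codes(pick)
        for j in np.flatnonzero(remaining):
            cj, rj = get_codes(j)
            if cp is None or cj is None:
                r = 0.0
            else:
                counts = np.zeros((rp, rj))
                np.add.at(counts, (cp, cj), 1.0)
                rowm = counts.sum(axis=1, keepdims=True)
                colm = counts.sum(axis=0, keepdims=True)
                expected = rowm @ colm / n
                chi2 = np.sum((counts - expected) ** 2 / expected)
                r = min(chi2 / (n * (min(rp, rj) - 1)), 1.0)
            red_min[j] = min(red_min[j], r)
            red_sum[j] += r

    return FeatureRanking(order, scores)


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

@dataclass
class ReliefFParams:
    """Sampling rounds ``m`` and neighbour count ``k`` for ReliefF.

    Defaults follow common practice: every instance is used once
    (``m = n_samples``) and ``k = 10`` neighbours, capped in
    :func:`relieff_weights` at the smallest class size minus one.
    """

    m: int | None = None  # None -> n_samples
    k: int = 10

    def __post_init__(self) -> None:
        if self.m is not None and self.m < 1:
            raise ValueError("m must be positive")
        if self.k < 1:
            raise ValueError("k must be positive")


def relieff_weights(table: FeatureTable, labels: np.ndarray,
                    params: ReliefFParams | None = None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Multi-class ReliefF feature weights.

    Features are min-max scaled before distances so every coordinate
    contributes comparably.  For each of ``m`` sampled instances, each
    feature's weight is decreased by the mean absolute difference to the
    ``k`` nearest hits and increased, per other class C, by
    ``P(C)/(1 - P(class(R)))`` times the mean difference to the ``k``
    nearest misses in C; all contributions are divided by ``m``.
    """
    params = params or ReliefFParams()
    rng = rng or np.random.default_rng()
    labels = check_labels(labels, table.n_samples)
    y = encode_labels(labels)
    n, d = table.values.shape

    classes, counts = np.unique(y, return_counts=True)
    k = min(params.k, int(counts.min()) - 1)
    if k < 1:
        raise ValueError("every class needs more than one member (k >= 1)")
    m = params.m if params.m is not None else n
    priors = counts / n

    # min-max scale; constant features scale to 0 and never contribute
    lo = table.values.min(axis=0)
    span = table.values.max(axis=0) - lo
    span[span == 0] = 1.0
    X = (table.values - lo) / span

    if m <= n:
        sampled = rng.permutation(n)[:m]
    else:
        sampled = rng.integers(0, n, size=m)

    by_class = {c: np.flatnonzero(y == c) for c in classes}
    weights = np.zeros(d)
    for i in sampled:
        diffs = np.abs(X - X[i])          # (n, d)
        dist = diffs.sum(axis=1)          # Manhattan distance
        ci = y[i]
        for c in classes:
            members = by_class[c]
            if c == ci:
                members = members[members != i]
            # k nearest within the class, deterministic tie-break by index
            nearest = members[np.lexsort((members, dist[members]))[:k]]
            contrib = diffs[nearest].mean(axis=0)
            if c == ci:
                weights -= contrib / m
            else:
                weights += priors[c] / (1.0 - priors[ci]) * contrib / m
    return weights


def relieff_rank(table: FeatureTable, labels: np.ndarray, keep: int,
                 params: ReliefFParams | None = None,
                 rng: np.random.Generator | None = None) -> FeatureRanking:
    """Top-``keep`` features by ReliefF weight, descending; ties by lower index."""
    if not 1 <= keep <= table.n_features:
        raise ValueError(f"keep must be in [1, {table.n_features}], got {keep}")
    w = relieff_weights(table, labels, params, rng)
    order = np.lexsort((np.arange(len(w)), -w))[:keep]
    return FeatureRanking([int(i) for i in order], [float(w[i]) for i in order])
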