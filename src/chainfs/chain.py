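"""The chain hybrid pipeline: preprocess -> MKMC -> ReliefF -> IGWO.

Three layers of dimensionality reduction run in sequence.  The bivariate
Kendall/chi-square filter ranks the raw features and keeps the top K
(candidate subset S1); ReliefF re-ranks S1 and keeps a configurable
fraction (candidate subset S2); the improved Grey Wolf Optimizer then
searches binary masks over S2, scoring each subset by cross-validated
classification accuracy blended with subset length.  The winning mask is
mapped back to original feature identifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import filters
from .data import FeatureTable, check_labels
from .evaluation import EvaluatorConfig, MetricsReport, make_evaluator, report_metrics
from .igwo import IGWOConfig, igwo_optimize

__all__ = [
    "ChainConfig",
    "SelectionResult",
    "preprocess",
    "candidate_count",
    "tandem_filter",
    "run_chain",
]

HIGH_DIM_THRESHOLD = 1000  # dimension above which the candidate cap kicks in
MAX_CANDIDATES = 100
OUTLIER_Z = 3.0


@dataclass
class ChainConfig:
    """Pipeline settings; defaults follow the reference protocol
    (population 30, 100 iterations, 10 repeated runs).

    ``stage2_fraction=None`` resolves per dataset: keep all of S1 when the
    raw dimension is at most 1000, keep 40% of S1 above that.
    """

    stage2_fraction: float | None = None
    pop_size: int = 30
    max_iter: int = 100
    runs: int = 10
    seed: int = 0
    aggregator: str = "min"        # MKMC redundancy aggregation over selected set
    bins: int = filters.DEFAULT_BINS
    relieff: filters.ReliefFParams = field(default_factory=filters.ReliefFParams)
    evaluator: EvaluatorConfig = field(default_factory=EvaluatorConfig)
    perturbation: bool = True
    random_a: bool = True
    skip_filters: bool = False     # ablation: IGWO over the raw table

    def __post_init__(self) -> None:
        if self.stage2_fraction is not None and not 0 < self.stage2_fraction <= 1:
            raise ValueError("stage2_fraction must be in (0, 1]")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")

    def resolve_fraction(self, dim: int) -> float:
        if self.stage2_fraction is not None:
            return self.stage2_fraction
        return 1.0 if dim <= HIGH_DIM_THRESHOLD else 0.4

    def igwo(self) -> IGWOConfig:
        return IGWOConfig(self.pop_size, self.max_iter,
                          perturbation=self.perturbation, random_a=self.random_a)


@dataclass
class SelectionResult:
    """Outcome of one pipeline run."""

    selected_ids: list[str]
    selected_indices: list[int]     # positions in the original table
    acc: float
    len: int
    drr: float
    fitness: float
    fitness_history: list[dict]
    stage_sizes: tuple[int, int, int, int]  # dim -> |S1| -> |S2| -> len
    seed: int


def preprocess(table: FeatureTable) -> FeatureTable:
    """Impute missing cells and tame outliers, column by column.

    Missing cells become the column mean of the observed values.  Observed
    cells more than 3 standard deviations from the column mean (both
    computed on observed values) are replaced by that same mean.  A column
    with no observed value at all is an error.
    """
    X = table.values.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        observed = ~np.isnan(col)
        if not observed.any():
            raise ValueError(f"column {table.feature_ids[j]!r} is entirely missing")
        mean = col[observed].mean()
        sd = col[observed].std()
        if sd > 0:
            z = np.abs(col - mean) / sd
            col[observed & (z > OUTLIER_Z)] = mean
        col[~observed] = mean
        X[:, j] = col
    return FeatureTable(X, list(table.feature_ids))


def candidate_count(dim: int) -> int:
    """Number of MKMC candidates K for a dataset of raw dimension ``dim``.

    Low-dimensional data (dim <= 1000) keeps everything; above that a
    max-min rule caps the candidate set:
    ``K = min(100, max(floor(e/2), floor(dim/3)))`` with e Euler's number,
    so floor(e/2) = 1 and in practice K = 100 for every dim > 1000.
    """
    if dim < 1:
        raise ValueError("dimension must be >= 1")
    if dim <= HIGH_DIM_THRESHOLD:
        return dim
    return min(MAX_CANDIDATES, max(math.floor(math.e / 2), dim // 3))


def tandem_filter(table: FeatureTable, labels: np.ndarray, config: ChainConfig,
                  rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Run the two filters in tandem; returns (S1, S2) as original indices.

    S1 = top ``candidate_count(dim)`` features of the MKMC ranking;
    S2 = ReliefF re-ranking of S1's columns, keeping
    ``ceil(stage2_fraction * |S1|)`` features.  Always S2 ⊆ S1.
    """
    labels = check_labels(labels, table.n_samples)
    dim = table.n_features
    k = candidate_count(dim)
    s1 = filters.mkmc_rank(table, labels, k, aggregator=config.aggregator,
                           bins=config.bins).order
    keep = max(1, math.ceil(config.resolve_fraction(dim) * len(s1)))
    sub = table.subset(s1)
    local = filters.relieff_rank(sub, labels, keep, config.relieff, rng).order
    s2 = [s1[i] for i in local]
    return s1, s2


def _run_once(table: FeatureTable, labels: np.ndarray, config: ChainConfig,
              seed: int) -> SelectionResult:
    rng = np.random.default_rng(seed)
    dim = table.n_features
    if config.skip_filters:
        s1 = list(range(dim))
        s2 = list(s1)
    else:
        s1, s2 = tandem_filter(table, labels, config, rng)
    search_table = table.subset(s2)

    evaluator = make_evaluator(search_table, labels, config.evaluator,
                               int(rng.integers(2**31)))
    result = igwo_optimize(len(s2), evaluator, config.igwo(), rng)

    local_idx = np.flatnonzero(result.mask)
    selected = [s2[i] for i in local_idx]
    return SelectionResult(
        selected_ids=[table.feature_ids[i] for i in selected],
        selected_indices=selected,
        acc=result.acc,
        len=len(selected),
        drr=len(selected) / dim,
        fitness=result.fitness,
        fitness_history=result.history,
        stage_sizes=(dim, len(s1), len(s2), len(selected)),
        seed=seed,
    )


def run_chain(raw_table: FeatureTable, labels: np.ndarray,
              config: ChainConfig | None = None,
              ) -> tuple[list[SelectionResult], MetricsReport]:
    """Run the full pipeline ``config.runs`` times and aggregate.

    The table is preprocessed once; each repetition re-runs filters and
    search with seed ``config.seed + run_index``.  Returns the per-run
    results and a report of mean accuracy plus the final run's subset
    length and dimension reduction rate.
    """
    config = config or ChainConfig()
    labels = check_labels(labels, raw_table.n_samples)
    table = preprocess(raw_table)
    results = [_run_once(table, labels, config, config.seed + i)
               for i in range(config.runs)]
    report = report_metrics([r.acc for r in results], results[-1].len,
                            table.n_features)
    return results, report


def result_to_dict(result: SelectionResult) -> dict:
    """JSON-friendly view of a run result."""
    return asdict(result)
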