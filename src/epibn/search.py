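"""Depth-first Branch-and-Bound search for the best-scoring parent set.

The search starts from the empty local disease structure and grows parent
sets one SNP at a time. Every child of an expanded state is scored; what is
pruned is the recursion *below* a child:

``practical`` (default)
    Greedy deepening: children are scored in order; each strictly improving
    child is recursed into, and the first non-improving child stops the
    sibling loop at that state. Fast, not guaranteed globally optimal, but
    every scored state remains a candidate for the returned optimum.

``bounded``
    Recurse into every child except those cut by the variance-increment
    bound: a branch is discarded only when the penalty increment
    Var_D(G^2(X, V2)) - Var_D(G^2(X, V1)) exceeds 2*N*H(X), the largest
    possible gain in G^2. Exhaustive (hence exact) up to ``max_parents``
    whenever the bound never fires.

Candidate children are expanded in descending single-SNP G^2 order
(tie-break: ascending index) or plain index order. Parent sets are unordered,
so states are canonicalized to sorted tuples and never revisited. Variance
estimates come from a shared :class:`~epibn.scoring.VarianceCache`, keyed by
sorted tuple with a seed derived from (global seed, tuple), which makes the
result independent of traversal order and identical between pruning checks
and scoring.

Parent sets are additionally confined to the score's statistical domain:
growth stops once the configuration count q = 3^k would exceed the sample
size N, where the saturated likelihood drives G^2 toward its ceiling
2*N*H(X) while the permutation variance stops tracking the 2*DF-scale
complexity growth, making score comparisons meaningless.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .dataset import GenotypeDataset
from .scoring import (
    LocalDiseaseStructure,
    ScoreBreakdown,
    ScoringConfig,
    SupportsVarianceLookup,
    VarianceCache,
    entropy_terms,
    g2_statistic,
    score,
    tabulate,
)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "branch_and_bound",
    "prune_check",
    "marginal_g2",
    "max_supported_parents",
]


def max_supported_parents(
    n_samples: int, arity_snp: int = 3, min_samples_per_config: int = 10
) -> int:
    """Largest parent count the sample size statistically supports.

    The EpiScore's premise — that the variance of the G^2 null distribution
    tracks model complexity — holds in the chi-square regime, which needs
    adequately filled contingency cells (a Cochran-style rule). Returns the
    largest k with arity^k * min_samples_per_config <= n_samples, at least 1.
    """
    k = 1
    while arity_snp ** (k + 1) * min_samples_per_config <= n_samples:
        k += 1
    return k

PRUNING_MODES = ("practical", "bounded")
CHILD_ORDERINGS = ("marginal_g2_desc", "index")


@dataclasses.dataclass
class SearchConfig:
    max_parents: int = 8
    pruning_mode: str = "practical"
    child_ordering: str = "marginal_g2_desc"
    scoring: ScoringConfig = dataclasses.field(default_factory=ScoringConfig)
    # Cochran-style validity rule: parent sets stop growing once the average
    # samples per genotype configuration would drop below this (1 disables).
    min_samples_per_config: int = 10

    def __post_init__(self) -> None:
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.min_samples_per_config < 1:
            raise ValueError("min_samples_per_config must be >= 1")
        if self.pruning_mode not in PRUNING_MODES:
            raise ValueError(f"pruning_mode must be one of {PRUNING_MODES}")
        if self.child_ordering not in CHILD_ORDERINGS:
            raise ValueError(f"child_ordering must be one of {CHILD_ORDERINGS}")


@dataclasses.dataclass
class SearchResult:
    best_parents: tuple[int, ...]
    best_score: ScoreBreakdown
    nodes_expanded: int
    nodes_pruned: int
    trace: list[tuple[tuple[int, ...], float]] | None = None

    def to_dict(self) -> dict:
        return {
            "best_parents": list(self.best_parents),
            "best_score": self.best_score.to_dict(),
            "nodes_expanded": self.nodes_expanded,
            "nodes_pruned": self.nodes_pruned,
        }


def marginal_g2(ds: GenotypeDataset, candidates: Sequence[int]) -> np.ndarray:
    """Single-SNP G^2 against the phenotype for each candidate column."""
    out = np.empty(len(candidates))
    for i, snp in enumerate(candidates):
        counts = tabulate(ds, LocalDiseaseStructure((int(snp),)))
        out[i], _ = g2_statistic(counts)
    return out


def prune_check(
    ds: GenotypeDataset,
    current: LocalDiseaseStructure,
    candidate_child: LocalDiseaseStructure,
    cfg: SearchConfig,
    *,
    variance_cache: SupportsVarianceLookup | None = None,
    current_score: float | None = None,
    child_score: float | None = None,
) -> bool:
    """True iff the branch below ``candidate_child`` may be discarded.

    In ``bounded`` mode this is the variance-increment bound (the penalty
    increase exceeds the largest possible G^2 gain, 2*N*H(X)); in
    ``practical`` mode it is the score-decrease stopping rule. Scores and
    variances are recomputed unless supplied by the caller.
    """
    cur = set(current.parents)
    child = set(candidate_child.parents)
    if not (cur < child and len(child) == len(cur) + 1):
        raise ValueError(
            "candidate_child must extend current by exactly one SNP"
        )
    cache = variance_cache or VarianceCache(ds, cfg.scoring)
    if cfg.pruning_mode == "bounded":
        counts = tabulate(ds, LocalDiseaseStructure(()))
        entropy_x, _ = entropy_terms(counts)
        var_cur = cache.get(current.parents) if current.parents else 0.0
        var_child = cache.get(candidate_child.parents)
        return bool(var_child - var_cur > 2.0 * counts.total * entropy_x)
    if current_score is None:
        current_score = score(ds, current, cfg.scoring, cache).score
    if child_score is None:
        child_score = score(ds, candidate_child, cfg.scoring, cache).score
    return bool(child_score <= current_score)


def branch_and_bound(
    ds: GenotypeDataset,
    cfg: SearchConfig,
    *,
    restrict: Sequence[int] | None = None,
    variance_cache: SupportsVarianceLookup | None = None,
    keep_trace: bool = False,
) -> SearchResult:
    """Search parent sets of the disease node for the best-scoring one.

    ``restrict`` limits candidate SNPs to the given column indices (used
    after screening). Deterministic given the scoring seed and config.
    """
    if ds.n_snps < 1:
        raise ValueError("dataset has no SNPs")
    scoring = cfg.scoring
    cache = variance_cache or VarianceCache(ds, scoring)
    candidates = (
        sorted(int(c) for c in restrict)
        if restrict is not None
        else list(range(ds.n_snps))
    )
    if cfg.child_ordering == "marginal_g2_desc":
        g2s = marginal_g2(ds, candidates)
        order = sorted(range(len(candidates)), key=lambda i: (-g2s[i], candidates[i]))
        candidates = [candidates[i] for i in order]

    counts0 = tabulate(ds, LocalDiseaseStructure(()))
    entropy_x, _ = entropy_terms(counts0)
    g2_cap = 2.0 * counts0.total * entropy_x  # max possible G^2 gain

    depth_cap = min(
        cfg.max_parents,
        max_supported_parents(
            ds.n_samples, min_samples_per_config=cfg.min_samples_per_config
        ),
    )
    empty_bd = score(ds, LocalDiseaseStructure(()), scoring, cache)
    best_key: tuple[int, ...] = ()
    best_bd = empty_bd
    visited: set[tuple[int, ...]] = {()}
    trace: list[tuple[tuple[int, ...], float]] | None = [] if keep_trace else None
    if keep_trace:
        trace.append(((), empty_bd.score))
    stats = {"expanded": 0, "pruned": 0}

    def expand(state: tuple[int, ...], state_bd: ScoreBreakdown) -> None:
        nonlocal best_key, best_bd
        stats["expanded"] += 1
        if len(state) >= depth_cap:
            return
        state_var = cache.get(state) if state else 0.0
        in_state = set(state)
        for snp in candidates:
            if snp in in_state:
                continue
            child_key = tuple(sorted(state + (snp,)))
            if child_key in visited:
                continue
            visited.add(child_key)
            child_bd = score(
                ds, LocalDiseaseStructure(child_key), scoring, cache
            )
            if trace is not None:
                trace.append((child_key, child_bd.score))
            if child_bd.score > best_bd.score:
                best_key, best_bd = child_key, child_bd
            if cfg.pruning_mode == "bounded":
                if cache.get(child_key) - state_var > g2_cap:
                    stats["pruned"] += 1
                else:
                    expand(child_key, child_bd)
            else:
                if child_bd.score > state_bd.score:
                    expand(child_key, child_bd)
                else:
                    # greedy deepening: the first non-improving child ends
                    # this state's sibling loop
                    stats["pruned"] += 1
                    break

    expand((), empty_bd)
    return SearchResult(
        best_parents=best_key,
        best_score=best_bd,
        nodes_expanded=stats["expanded"],
        nodes_pruned=stats["pruned"],
        trace=trace,
    )
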