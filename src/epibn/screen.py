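"""Metropolis-Hastings screening of candidate parent SNPs.

On marker panels too large for direct Branch-and-Bound, a Markov chain over
local disease structures shortlists SNPs by their edge posterior. Moves add
or remove a single edge (SNP), chosen uniformly among the legal moves; a
proposal is accepted with probability

    alpha = min{1, exp(EpiScore(proposed) - EpiScore(current))}

i.e. the likelihood ratio of the two structures under a uniform structure
prior, with the neighbourhood-cardinality ratio taken as one (the two
boundary states — the empty set and the parent cap — technically have
smaller neighbourhoods; the ratio is fixed at one regardless, a deliberate
simplification whose bias at two states out of the whole space is
negligible for screening). Because structures are scored jointly, SNPs whose
effect is only visible in combination are retained, unlike single-SNP
filters.

The edge posterior of SNP s is the fraction of post-burn-in states
containing s; the default candidate rule keeps every SNP with posterior
strictly greater than zero, i.e. any post-burn-in occurrence (a nonzero
threshold is available because the literal rule grows permissive with chain
length).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .dataset import GenotypeDataset
from .scoring import (
    LocalDiseaseStructure,
    ScoringConfig,
    SupportsVarianceLookup,
    VarianceCache,
    score,
)

__all__ = [
    "McmcConfig",
    "McmcResult",
    "propose_move",
    "acceptance_ratio",
    "mcmc_screen",
]


@dataclasses.dataclass
class McmcConfig:
    """Chain length, burn-in, state-size cap, scoring and threshold.

    Defaults scale the chain with the search space: 200 iterations per
    marker, 10% burn-in, at most 10 parents per sampled structure.
    """

    n_iterations: int
    burn_in: int
    rng_seed: int = 0
    max_parents_in_state: int = 10
    scoring: ScoringConfig = dataclasses.field(default_factory=ScoringConfig)
    posterior_threshold: float = 0.0
    # Cochran-style validity rule shared with the search (1 disables)
    min_samples_per_config: int = 10

    @classmethod
    def for_markers(cls, n_markers: int, **kwargs) -> "McmcConfig":
        n_iter = kwargs.pop("n_iterations", 200 * n_markers)
        burn = kwargs.pop("burn_in", n_iter // 10)
        return cls(n_iterations=n_iter, burn_in=burn, **kwargs)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.max_parents_in_state < 1:
            raise ValueError("max_parents_in_state must be >= 1")
        if not (0.0 <= self.posterior_threshold < 1.0):
            raise ValueError("posterior_threshold must be in [0, 1)")


@dataclasses.dataclass
class McmcResult:
    edge_posterior: np.ndarray  # per-SNP inclusion frequency, shape (M,)
    candidates: list[int]
    acceptance_rate: float
    chain_trace: list[tuple[int, float]] | None = None  # (|state|, score)
    state_trace: list[tuple[int, ...]] | None = None  # full per-iteration states

    def candidates_at(self, threshold: float) -> list[int]:
        return [int(i) for i in np.nonzero(self.edge_posterior > threshold)[0]]

    def to_dict(self) -> dict:
        return {
            "edge_posterior": self.edge_posterior.tolist(),
            "candidates": self.candidates,
            "acceptance_rate": self.acceptance_rate,
        }


def propose_move(
    state: tuple[int, ...],
    n_snps: int,
    rng: np.random.Generator,
    max_parents: int | None = None,
) -> tuple[int, ...]:
    """Propose a structure differing from ``state`` by one add or remove.

    The move is uniform over the legal one-edge neighbours: from the empty
    set only adds are possible, at the parent cap only removes.
    """
    members = set(state)
    moves: list[int] = []
    if max_parents is None or len(members) < max_parents:
        moves.extend(s for s in range(n_snps) if s not in members)
    if members:
        moves.extend(members)
    snp = moves[int(rng.integers(len(moves)))]
    if snp in members:
        members.remove(snp)
    else:
        members.add(snp)
    return tuple(sorted(members))


def acceptance_ratio(
    ds: GenotypeDataset,
    current: LocalDiseaseStructure,
    proposed: LocalDiseaseStructure,
    cfg: McmcConfig,
    variance_cache: SupportsVarianceLookup | None = None,
) -> float:
    """min{1, exp(score(proposed) - score(current))} for a one-move pair."""
    cur, prop = set(current.parents), set(proposed.parents)
    if len(cur.symmetric_difference(prop)) != 1:
        raise ValueError("structures must differ by exactly one move")
    cache = variance_cache or VarianceCache(ds, cfg.scoring)
    s_cur = score(ds, current, cfg.scoring, cache).score
    s_prop = score(ds, proposed, cfg.scoring, cache).score
    return min(1.0, math.exp(min(s_prop - s_cur, 0.0)))


def mcmc_screen(
    ds: GenotypeDataset,
    cfg: McmcConfig,
    *,
    variance_cache: SupportsVarianceLookup | None = None,
    keep_trace: bool = False,
) -> McmcResult:
    """Run the Metropolis-Hastings chain from the empty structure.

    Deterministic given ``cfg.rng_seed``. ``edge_posterior[s]`` is the
    fraction of post-burn-in iterations whose structure contains SNP s.
    """
    from .search import max_supported_parents

    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed]))
    cache = variance_cache or VarianceCache(ds, cfg.scoring)
    # confine states to the score's statistical domain (q = 3^k <= N)
    state_cap = min(
        cfg.max_parents_in_state,
        max_supported_parents(
            ds.n_samples, min_samples_per_config=cfg.min_samples_per_config
        ),
    )
    score_memo: dict[tuple[int, ...], float] = {}

    def state_score(key: tuple[int, ...]) -> float:
        if key not in score_memo:
            score_memo[key] = score(
                ds, LocalDiseaseStructure(key), cfg.scoring, cache
            ).score
        return score_memo[key]

    state: tuple[int, ...] = ()
    s_cur = state_score(state)
    inclusion = np.zeros(ds.n_snps, dtype=np.int64)
    kept = 0
    accepted = 0
    trace: list[tuple[int, float]] | None = [] if keep_trace else None
    states: list[tuple[int, ...]] | None = [] if keep_trace else None
    for t in range(cfg.n_iterations):
        proposed = propose_move(state, ds.n_snps, rng, state_cap)
        s_prop = state_score(proposed)
        if math.log(rng.random()) < s_prop - s_cur:
            state, s_cur = proposed, s_prop
            accepted += 1
        if t >= cfg.burn_in:
            kept += 1
            if state:
                inclusion[list(state)] += 1
        if trace is not None:
            trace.append((len(state), s_cur))
            states.append(state)
    posterior = inclusion / max(kept, 1)
    result = McmcResult(
        edge_posterior=posterior,
        candidates=[],
        acceptance_rate=accepted / cfg.n_iterations,
        chain_trace=trace,
        state_trace=states,
    )
    result.candidates = result.candidates_at(cfg.posterior_threshold)
    return result
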