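"""Information-theoretic scoring of a local disease structure (LDS).

The model is a two-layer Bayesian network: candidate parent SNPs point into a
single binary disease-status node X. For a parent set Pa(X) with q = 3^|Pa(X)|
genotype configurations and r = 2 disease states, the maximized log-likelihood
of the local structure is

    loglik = sum_jk N_jk * log(N_jk / N_j)          (natural log, nats)

with N_jk the number of samples in configuration j and disease state k. The
familiar identities tie everything together:

    loglik           = -N * H(X | Pa(X))
    loglik_empty     = -N * H(X)
    MI(X, Pa(X))     = H(X) - H(X | Pa(X)) = (loglik - loglik_empty) / N
    G^2              = 2 * N * MI
    DF               = (r - 1)(q - 1)

Three scores are available for a structure:

AIC        loglik - q(r-1)
BIC        loglik - (1/2) q(r-1) log N
EpiScore   (1/2) (G^2 - Var_D(G^2)) + loglik_empty - (r - 1)

where Var_D(G^2) is the variance of the G^2 null distribution estimated from
the data itself by phenotype permutation, replacing the chi-square asymptotic
value 2*DF that AIC implicitly uses. The trailing constant is the penalized
empty-structure score (the AIC of the empty LDS), shared by every structure on
a dataset, so with Var_D(G^2) = 2*DF the EpiScore reduces exactly to the AIC.

The permutation variance is computed without materializing permutations: under
random relabeling of the phenotype, the vector of case counts per parent
configuration follows a multivariate hypergeometric distribution with all
marginals fixed, so the per-replicate tables are drawn from that distribution
directly. This is the exact permutation null, sampled in O(B*q) per parent set.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping, Protocol

import numpy as np
from scipy.special import xlogy

from .dataset import GenotypeDataset

__all__ = [
    "LocalDiseaseStructure",
    "ContingencyCounts",
    "ScoringConfig",
    "ScoreBreakdown",
    "VarianceCache",
    "tabulate",
    "log_likelihood",
    "empty_log_likelihood",
    "entropy_terms",
    "mutual_information",
    "g2_statistic",
    "estimate_g2_variance",
    "score",
    "score_upper_bound",
]

SCORE_TYPES = ("aic", "bic", "episcore")


@dataclasses.dataclass(frozen=True)
class LocalDiseaseStructure:
    """The disease node plus edges from a set of candidate parent SNPs.

    ``parents`` is an ordered tuple of SNP column indices; the configuration
    count q is always the theoretical 3^|parents| (q = 1 for the empty set),
    because each SNP is a 3-state categorical variable even when a genotype
    state is unobserved.
    """

    parents: tuple[int, ...]
    arity_disease: int = 2
    arity_snp: int = 3

    def __post_init__(self) -> None:
        parents = tuple(int(p) for p in self.parents)
        object.__setattr__(self, "parents", parents)
        if len(set(parents)) != len(parents):
            raise ValueError(f"duplicate parent indices in {parents}")
        if any(p < 0 for p in parents):
            raise ValueError(f"negative parent index in {parents}")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def q(self) -> int:
        return self.arity_snp ** len(self.parents)

    def validate_against(self, ds: GenotypeDataset) -> None:
        for p in self.parents:
            if p >= ds.n_snps:
                raise IndexError(
                    f"parent index {p} out of range for {ds.n_snps} SNPs"
                )

    def sorted_key(self) -> tuple[int, ...]:
        return tuple(sorted(self.parents))


@dataclasses.dataclass
class ContingencyCounts:
    """An r x q table of disease-state-by-parent-configuration counts."""

    counts: np.ndarray  # shape (r, q); counts[k, j] = N_jk
    row_totals: np.ndarray  # shape (q,); N_j
    class_totals: np.ndarray  # shape (r,); N_k
    total: int  # N

    @classmethod
    def from_table(cls, counts: np.ndarray) -> "ContingencyCounts":
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be an r x q matrix")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        return cls(
            counts=counts,
            row_totals=counts.sum(axis=0),
            class_totals=counts.sum(axis=1),
            total=int(counts.sum()),
        )

    @property
    def r(self) -> int:
        return self.counts.shape[0]

    @property
    def q(self) -> int:
        return self.counts.shape[1]

    @property
    def q_observed(self) -> int:
        return int(np.count_nonzero(self.row_totals))


@dataclasses.dataclass
class ScoringConfig:
    """Which score to compute and how to estimate the variance penalty.

    The classical penalization function f(N) is realized through
    ``score_type``: f(N) = 1 gives AIC, f(N) = (1/2) log N gives BIC; the
    EpiScore replaces the AIC penalty 2*DF with a permutation estimate of
    Var_D(G^2) from ``n_permutations`` (B) phenotype relabelings.

    ``observed_configurations`` switches the configuration count used in DF
    and complexity terms from the theoretical 3^|parents| to the number of
    parent configurations actually observed (off by default).
    """

    score_type: str = "episcore"
    n_permutations: int = 1000
    rng_seed: int = 0
    observed_configurations: bool = False

    def __post_init__(self) -> None:
        if self.score_type not in SCORE_TYPES:
            raise ValueError(
                f"score_type {self.score_type!r} not in {SCORE_TYPES}"
            )
        if self.score_type == "episcore" and self.n_permutations < 2:
            raise ValueError("EpiScore needs n_permutations >= 2")
        if self.rng_seed < 0:
            raise ValueError("rng_seed must be nonnegative")


@dataclasses.dataclass
class ScoreBreakdown:
    """All intermediate quantities behind a single structure score (nats)."""

    loglik: float
    loglik_empty: float
    entropy_x: float
    cond_entropy: float
    mi: float
    g2: float
    df: int
    var_g2: float
    score: float
    score_type: str
    parents: tuple[int, ...] = ()
    config: ScoringConfig | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["parents"] = list(self.parents)
        if self.config is not None:
            d["config"] = dataclasses.asdict(self.config)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# Counting and information quantities
# ---------------------------------------------------------------------------

def _config_index(ds: GenotypeDataset, parents: tuple[int, ...]) -> np.ndarray:
    """Mixed-radix index of each sample's parent-genotype configuration."""
    if not parents:
        return np.zeros(ds.n_samples, dtype=np.int64)
    powers = 3 ** np.arange(len(parents), dtype=np.int64)
    return ds.genotypes[:, list(parents)].astype(np.int64) @ powers


def tabulate(
    ds: GenotypeDataset, lds: LocalDiseaseStructure
) -> ContingencyCounts:
    """Count samples per (disease state, parent configuration) cell.

    All q = 3^|parents| theoretical configurations appear; unobserved ones
    are zero columns.
    """
    lds.validate_against(ds)
    q = lds.q
    r = lds.arity_disease
    j = _config_index(ds, lds.parents)
    y = ds.phenotype.astype(np.int64)
    flat = np.bincount(j * r + y, minlength=q * r)
    counts = flat.reshape(q, r).T  # counts[k, j]
    return ContingencyCounts.from_table(counts)


def log_likelihood(counts: ContingencyCounts) -> float:
    """Maximized log-likelihood sum_jk N_jk log(N_jk / N_j), with 0 log 0 = 0."""
    c = counts.counts.astype(float)
    return float(xlogy(c, c).sum() - xlogy(counts.row_totals, counts.row_totals).sum())


def empty_log_likelihood(counts: ContingencyCounts) -> float:
    """Log-likelihood of the empty structure, sum_k N_k log(N_k / N)."""
    nk = counts.class_totals.astype(float)
    return float(xlogy(nk, nk).sum() - xlogy(counts.total, counts.total))


def entropy_terms(counts: ContingencyCounts) -> tuple[float, float]:
    """(H(X), H(X | Pa(X))) in nats; -N*H(X|Pa) is the log-likelihood."""
    n = counts.total
    if n == 0:
        return 0.0, 0.0
    entropy_x = -empty_log_likelihood(counts) / n
    cond_entropy = -log_likelihood(counts) / n
    return entropy_x, cond_entropy


def mutual_information(counts: ContingencyCounts) -> float:
    """Plug-in MI between disease status and the parent configuration."""
    entropy_x, cond_entropy = entropy_terms(counts)
    return max(entropy_x - cond_entropy, 0.0)


def g2_statistic(
    counts: ContingencyCounts, observed_configurations: bool = False
) -> tuple[float, int]:
    """Likelihood-ratio independence statistic G^2 = 2*N*MI and its DF.

    DF = (r-1)(q-1) with the theoretical configuration count q (or the
    observed count when ``observed_configurations``).
    """
    g2 = 2.0 * counts.total * mutual_information(counts)
    q = counts.q_observed if observed_configurations else counts.q
    df = (counts.r - 1) * (q - 1)
    return g2, df


# ---------------------------------------------------------------------------
# Permutation variance of G^2
# ---------------------------------------------------------------------------

def _g2_from_case_counts(
    case_counts: np.ndarray, row_totals: np.ndarray, class_totals: np.ndarray
) -> np.ndarray:
    """G^2 for a batch of tables sharing fixed marginals.

    ``case_counts`` has shape (B, q); row j of each replicate holds
    (row_totals[j] - cases, cases).
    """
    n = float(row_totals.sum())
    ctrl_counts = row_totals[None, :] - case_counts
    cells = xlogy(case_counts, case_counts).sum(axis=1)
    cells += xlogy(ctrl_counts, ctrl_counts).sum(axis=1)
    const = (
        -xlogy(row_totals, row_totals).sum()
        - xlogy(class_totals, class_totals).sum()
        + xlogy(n, n)
    )
    return 2.0 * (cells + const)


def estimate_g2_variance(
    ds: GenotypeDataset,
    lds: LocalDiseaseStructure,
    cfg: ScoringConfig,
) -> float:
    """Estimate Var_D(G^2(X, Pa(X))) under the permutation null.

    Randomly relabeling the phenotype breaks the X-Pa(X) association while
    preserving every marginal; conditional on the marginals the case-count
    vector per configuration is multivariate hypergeometric, which is sampled
    directly (B = ``cfg.n_permutations`` replicates). Returns the sample
    variance (ddof=1) of the replicate G^2 values. Deterministic given
    ``cfg.rng_seed`` and the (sorted) parent tuple.
    """
    if not lds.parents:
        raise ValueError(
            "variance penalty is undefined for the empty structure; "
            "the empty LDS is scored directly"
        )
    if cfg.n_permutations < 2:
        raise ValueError("need at least 2 permutation replicates")
    lds.validate_against(ds)
    # canonical parent order: G^2 is invariant to configuration relabeling,
    # and sorting makes the estimate independent of traversal order
    counts = tabulate(
        ds,
        LocalDiseaseStructure(lds.sorted_key(), lds.arity_disease, lds.arity_snp),
    )
    n_cases = int(counts.class_totals[1]) if counts.r > 1 else 0
    if n_cases == 0 or n_cases == counts.total:
        return 0.0  # constant phenotype: G^2 is identically zero
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.rng_seed, *lds.sorted_key()])
    )
    case_counts = rng.multivariate_hypergeometric(
        counts.row_totals, n_cases, size=cfg.n_permutations
    ).astype(float)
    g2s = _g2_from_case_counts(
        case_counts,
        counts.row_totals.astype(float),
        counts.class_totals.astype(float),
    )
    return float(np.var(g2s, ddof=1))


class SupportsVarianceLookup(Protocol):
    def get(self, parents: Iterable[int]) -> float: ...


class VarianceCache:
    """Deterministic per-parent-set cache of permutation variance estimates.

    Keys are sorted index tuples; each estimate is computed once with a seed
    derived from (rng_seed, sorted parent tuple), so the value is independent
    of traversal order and shared between search pruning and scoring.
    """

    def __init__(self, ds: GenotypeDataset, cfg: ScoringConfig):
        self.ds = ds
        self.cfg = cfg
        self._store: dict[tuple[int, ...], float] = {}

    def get(self, parents: Iterable[int]) -> float:
        key = tuple(sorted(int(p) for p in parents))
        if not key:
            return 0.0
        if key not in self._store:
            self._store[key] = estimate_g2_variance(
                self.ds, LocalDiseaseStructure(key), self.cfg
            )
        return self._store[key]

    def __len__(self) -> int:
        return len(self._store)

    def as_mapping(self) -> Mapping[tuple[int, ...], float]:
        return dict(self._store)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def score(
    ds: GenotypeDataset,
    lds: LocalDiseaseStructure,
    cfg: ScoringConfig,
    variance_cache: SupportsVarianceLookup | None = None,
) -> ScoreBreakdown:
    """Score a local disease structure under AIC, BIC or the EpiScore.

    For the empty structure the AIC/BIC complexity is r - 1 and the EpiScore
    is the penalized empty-structure value itself (no variance penalty).
    """
    lds.validate_against(ds)
    counts = tabulate(ds, lds)
    n = counts.total
    r = counts.r
    loglik = log_likelihood(counts)
    loglik_empty = empty_log_likelihood(counts)
    entropy_x, cond_entropy = entropy_terms(counts)
    mi = mutual_information(counts)
    g2, df = g2_statistic(counts, cfg.observed_configurations)
    q_eff = counts.q_observed if cfg.observed_configurations else counts.q

    empty_ref = loglik_empty - (r - 1)  # penalized empty-structure score
    var_g2 = 0.0
    if cfg.score_type == "aic":
        value = loglik - q_eff * (r - 1)
    elif cfg.score_type == "bic":
        value = loglik - 0.5 * q_eff * (r - 1) * np.log(n)
    else:  # episcore
        if lds.parents:
            if variance_cache is not None:
                var_g2 = float(variance_cache.get(lds.parents))
            else:
                var_g2 = estimate_g2_variance(ds, lds, cfg)
            value = 0.5 * (g2 - var_g2) + empty_ref
        else:
            value = empty_ref
    return ScoreBreakdown(
        loglik=loglik,
        loglik_empty=loglik_empty,
        entropy_x=entropy_x,
        cond_entropy=cond_entropy,
        mi=mi,
        g2=g2,
        df=df,
        var_g2=var_g2,
        score=float(value),
        score_type=cfg.score_type,
        parents=lds.parents,
        config=cfg,
    )


def score_upper_bound(ds: GenotypeDataset, cfg: ScoringConfig) -> float:
    """Upper bound on the EpiScore over every parent set of this dataset.

    G^2 is at most 2*N*H(X) and the variance penalty is nonnegative, so no
    structure can score above N*H(X) + loglik_empty.
    """
    counts = tabulate(ds, LocalDiseaseStructure(()))
    entropy_x, _ = entropy_terms(counts)
    return float(counts.total * entropy_x + empty_log_likelihood(counts))
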