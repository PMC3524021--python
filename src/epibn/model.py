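"""Model-object front end: build a scan from data, fit, inspect results.

`EpistasisScan` wraps a case-control genotype matrix; `fit()` runs the
configured pipeline (optional MCMC screening, then Branch-and-Bound over
parent sets of the disease node) and returns an `EpistasisScanResults`
carrying the selected SNPs, the full score breakdown and search/screening
diagnostics, with a text `summary()`.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from . import __version__ as _version
from .dataset import GenotypeDataset
from .scoring import (
    LocalDiseaseStructure,
    ScoreBreakdown,
    ScoringConfig,
    VarianceCache,
    g2_statistic,
    score_upper_bound,
    tabulate,
)
from .screen import McmcConfig, McmcResult, mcmc_screen
from .search import SearchConfig, SearchResult, branch_and_bound

__all__ = ["EpistasisScan", "EpistasisScanResults"]


class EpistasisScan:
    """Scan for the parent SNP set of a binary disease node.

    Parameters
    ----------
    genotypes : array-like (n_samples, n_snps)
        Minor-allele counts in {0, 1, 2}.
    phenotype : array-like (n_samples,)
        0 = control, 1 = case.
    snp_ids : sequence of str, optional
        Defaults to ``snp1..snpM``.

    Examples
    --------
    >>> scan = EpistasisScan.from_dataframe(df)      # doctest: +SKIP
    >>> res = scan.fit(seed=1)                       # doctest: +SKIP
    >>> print(res.summary())                         # doctest: +SKIP
    """

    def __init__(self, genotypes, phenotype, snp_ids=None, sample_ids=None):
        genotypes = np.asarray(genotypes)
        if snp_ids is None:
            snp_ids = [f"snp{j + 1}" for j in range(genotypes.shape[1])]
        self.data = GenotypeDataset(genotypes, np.asarray(phenotype), list(snp_ids), sample_ids)

    @classmethod
    def from_dataset(cls, ds: GenotypeDataset) -> "EpistasisScan":
        obj = cls.__new__(cls)
        obj.data = ds
        return obj

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, phenotype_col: str = "phenotype"
    ) -> "EpistasisScan":
        return cls.from_dataset(GenotypeDataset.from_dataframe(df, phenotype_col))

    @property
    def exog_names(self) -> list[str]:
        return list(self.data.snp_ids)

    def fit(
        self,
        score_type: str = "episcore",
        max_parents: int = 8,
        pruning_mode: str = "practical",
        n_permutations: int = 1000,
        seed: int = 0,
        screen: str | bool = "auto",
        screen_threshold: int = 1000,
        mcmc_iterations: int | None = None,
        burn_in: int | None = None,
        posterior_threshold: float = 0.0,
    ) -> "EpistasisScanResults":
        """Run screening (if enabled) and Branch-and-Bound; return results.

        ``screen`` may be ``True``, ``False`` or ``"auto"`` (screen only
        when the number of markers exceeds ``screen_threshold``).
        """
        scoring = ScoringConfig(
            score_type=score_type, n_permutations=n_permutations, rng_seed=seed
        )
        search_cfg = SearchConfig(
            max_parents=max_parents, pruning_mode=pruning_mode, scoring=scoring
        )
        cache = VarianceCache(self.data, scoring)
        do_screen = (
            self.data.n_snps > screen_threshold if screen == "auto" else bool(screen)
        )
        screen_result: McmcResult | None = None
        restrict = None
        if do_screen:
            mcfg = McmcConfig.for_markers(
                self.data.n_snps,
                rng_seed=seed,
                scoring=scoring,
                posterior_threshold=posterior_threshold,
                **(
                    {"n_iterations": mcmc_iterations}
                    if mcmc_iterations is not None
                    else {}
                ),
                **({"burn_in": burn_in} if burn_in is not None else {}),
            )
            screen_result = mcmc_screen(self.data, mcfg, variance_cache=cache)
            restrict = screen_result.candidates
        if restrict is not None and not restrict:
            search_result = None
            best = LocalDiseaseStructure(())
            from .scoring import score as _score

            breakdown = _score(self.data, best, scoring, cache)
            best_parents: tuple[int, ...] = ()
        else:
            search_result = branch_and_bound(
                self.data, search_cfg, restrict=restrict, variance_cache=cache
            )
            breakdown = search_result.best_score
            best_parents = search_result.best_parents
        return EpistasisScanResults(
            model=self,
            best_indices=best_parents,
            breakdown=breakdown,
            search_result=search_result,
            screen_result=screen_result,
            search_config=search_cfg,
            seed=seed,
        )


class EpistasisScanResults:
    """Fitted scan: selected SNPs, score breakdown, diagnostics."""

    def __init__(
        self,
        model: EpistasisScan,
        best_indices: tuple[int, ...],
        breakdown: ScoreBreakdown,
        search_result: SearchResult | None,
        screen_result: McmcResult | None,
        search_config: SearchConfig,
        seed: int,
    ):
        self.model = model
        self.best_indices = tuple(sorted(best_indices))
        self.breakdown = breakdown
        self.search_result = search_result
        self.screen_result = screen_result
        self.search_config = search_config
        self.seed = seed

    @property
    def best_snps(self) -> list[str]:
        return [self.model.data.snp_ids[i] for i in self.best_indices]

    @property
    def score(self) -> float:
        return self.breakdown.score

    def summary(self) -> str:
        ds = self.model.data
        bd = self.breakdown
        bound = score_upper_bound(ds, self.search_config.scoring)
        lines = [
            "Epistasis scan results",
            "=" * 58,
            f"No. samples:      {ds.n_samples}   (cases {ds.n_cases} / controls {ds.n_controls})",
            f"No. SNPs:         {ds.n_snps}",
            f"Score type:       {bd.score_type}",
            f"Search mode:      {self.search_config.pruning_mode}",
            f"Seed:             {self.seed}",
            "-" * 58,
            f"Selected SNPs:    {', '.join(self.best_snps) or '(none)'}",
            f"Score:            {bd.score:.4f}   (upper bound {bound:.4f})",
            f"G^2:              {bd.g2:.4f}   on DF = {bd.df}",
            f"Var_D(G^2):       {bd.var_g2:.4f}   (chi^2 value 2*DF = {2 * bd.df})",
            f"MI(X; Pa(X)):     {bd.mi:.6f} nats",
            f"H(X):             {bd.entropy_x:.6f} nats   H(X|Pa): {bd.cond_entropy:.6f}",
            "-" * 58,
        ]
        if self.best_indices:
            lines.append("Per-SNP marginal association:")
            lines.append(f"{'SNP':<14}{'G^2':>12}{'DF':>6}")
            for i in self.best_indices:
                counts = tabulate(ds, LocalDiseaseStructure((i,)))
                g2, df = g2_statistic(counts)
                lines.append(f"{ds.snp_ids[i]:<14}{g2:>12.4f}{df:>6}")
        if self.search_result is not None:
            lines.append(
                f"Search: {self.search_result.nodes_expanded} states expanded, "
                f"{self.search_result.nodes_pruned} branches pruned"
            )
        if self.screen_result is not None:
            lines.append(
                f"Screening: {len(self.screen_result.candidates)} candidates, "
                f"acceptance rate {self.screen_result.acceptance_rate:.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "version": _version,
            "seed": self.seed,
            "selected_indices": list(self.best_indices),
            "selected_snps": self.best_snps,
            "breakdown": self.breakdown.to_dict(),
            "search": self.search_result.to_dict() if self.search_result else None,
            "screen": self.screen_result.to_dict() if self.screen_result else None,
            "config": {
                "max_parents": self.search_config.max_parents,
                "pruning_mode": self.search_config.pruning_mode,
                "child_ordering": self.search_config.child_ordering,
                "scoring": dataclasses.asdict(self.search_config.scoring),
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)
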