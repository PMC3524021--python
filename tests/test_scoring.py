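import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from epibn import (
    ContingencyCounts,
    GenotypeDataset,
    LocalDiseaseStructure,
    ScoringConfig,
    VarianceCache,
    estimate_g2_variance,
    g2_statistic,
    score,
    score_upper_bound,
)
from epibn.scoring import (
    empty_log_likelihood,
    entropy_terms,
    log_likelihood,
    mutual_information,
    tabulate,
)
from .conftest import make_degenerate_dataset, make_random_dataset

CFG = ScoringConfig(n_permutations=100, rng_seed=0)


class FixedVariance:
    """Injectable stand-in for a variance cache returning preset values."""

    def __init__(self, value):
        self.value = value

    def get(self, parents):
        return self.value


class TestTabulate:
    def test_empty_parent_set_class_totals(self):
        ds = GenotypeDataset(
            np.zeros((5, 1), int), np.array([1, 1, 1, 0, 0]), ["a"]
        )
        counts = tabulate(ds, LocalDiseaseStructure(()))
        assert counts.q == 1
        assert counts.class_totals.tolist() == [2, 3]

    def test_monomorphic_parent_has_zero_configurations(self):
        ds = GenotypeDataset(
            np.zeros((6, 1), int), np.array([0, 1] * 3), ["a"]
        )
        counts = tabulate(ds, LocalDiseaseStructure((0,)))
        assert counts.q == 3
        assert counts.row_totals.tolist() == [6, 0, 0]

    def test_counts_match_brute_force_double_loop(self, rng):
        ds = make_random_dataset(rng, n_samples=200, n_snps=5)
        lds = LocalDiseaseStructure((3, 1))
        counts = tabulate(ds, lds)
        brute = np.zeros((2, 9), dtype=int)
        for i in range(ds.n_samples):
            j = ds.genotypes[i, 3] + 3 * ds.genotypes[i, 1]
            brute[ds.phenotype[i], j] += 1
        assert np.array_equal(counts.counts, brute)

    def test_out_of_range_parent(self, rng):
        ds = make_random_dataset(rng, n_snps=3)
        with pytest.raises(IndexError):
            tabulate(ds, LocalDiseaseStructure((5,)))


class TestInformationQuantities:
    def test_pure_rows_give_zero_loglik(self):
        counts = ContingencyCounts.from_table([[4, 0, 7], [0, 5, 0]])
        assert log_likelihood(counts) == pytest.approx(0.0)

    def test_balanced_split_closed_form(self):
        counts = ContingencyCounts.from_table([[50], [50]])
        assert empty_log_likelihood(counts) == pytest.approx(100 * math.log(0.5))
        entropy_x, _ = entropy_terms(counts)
        assert entropy_x == pytest.approx(math.log(2))

    def test_loglik_matches_direct_summation(self, rng):
        table = rng.integers(1, 30, size=(2, 3))
        counts = ContingencyCounts.from_table(table)
        expect = sum(
            table[k, j] * math.log(table[k, j] / table[:, j].sum())
            for k in range(2)
            for j in range(3)
        )
        assert log_likelihood(counts) == pytest.approx(expect, abs=1e-12)

    def test_entropy_identities_vs_loglik(self, rng):
        for _ in range(10):
            table = rng.integers(0, 25, size=(2, 4))
            table[0, 0] += 1
            table[1, 1] += 1
            counts = ContingencyCounts.from_table(table)
            entropy_x, cond = entropy_terms(counts)
            n = counts.total
            assert -n * cond == pytest.approx(log_likelihood(counts), abs=1e-9)
            assert -n * entropy_x == pytest.approx(
                empty_log_likelihood(counts), abs=1e-9
            )

    def test_mi_zero_when_independent(self):
        # rows proportional to class totals => X independent of parents
        counts = ContingencyCounts.from_table([[10, 20, 30], [20, 40, 60]])
        assert mutual_information(counts) == pytest.approx(0.0, abs=1e-12)
        entropy_x, cond = entropy_terms(counts)
        assert cond == pytest.approx(entropy_x, abs=1e-12)

    def test_mi_equals_entropy_when_deterministic(self):
        counts = ContingencyCounts.from_table([[30, 0, 0], [0, 25, 15]])
        entropy_x, _ = entropy_terms(counts)
        assert mutual_information(counts) == pytest.approx(entropy_x, abs=1e-12)

    def test_mi_matches_joint_distribution_oracle(self, rng):
        table = rng.integers(1, 40, size=(2, 6)).astype(float)
        counts = ContingencyCounts.from_table(table)
        p = table / table.sum()
        px = p.sum(axis=1, keepdims=True)
        pj = p.sum(axis=0, keepdims=True)
        expect = float(np.sum(p * np.log(p / (px * pj))))
        assert mutual_information(counts) == pytest.approx(expect, abs=1e-10)


class TestG2:
    @pytest.mark.parametrize("n_parents,df", [(1, 2), (2, 8), (3, 26)])
    def test_degrees_of_freedom(self, rng, n_parents, df):
        ds = make_random_dataset(rng, n_samples=100, n_snps=4)
        counts = tabulate(ds, LocalDiseaseStructure(tuple(range(n_parents))))
        assert g2_statistic(counts)[1] == df

    def test_zero_for_independence_structured_table(self):
        counts = ContingencyCounts.from_table([[5, 10, 15], [10, 20, 30]])
        assert g2_statistic(counts)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_log_likelihood_ratio(self, rng):
        """2N*MI equals the textbook G^2 = 2*sum O*log(O/E)."""
        for _ in range(20):
            table = rng.integers(1, 50, size=(2, rng.integers(2, 7)))
            counts = ContingencyCounts.from_table(table)
            g2, df = g2_statistic(counts)
            stat, _, dof, _ = chi2_contingency(
                table, correction=False, lambda_="log-likelihood"
            )
            assert g2 == pytest.approx(stat, abs=1e-8)
            assert df == dof


class TestVarianceEstimate:
    def test_constant_phenotype_gives_zero(self):
        ds = make_degenerate_dataset()
        lds = LocalDiseaseStructure((0,))
        assert estimate_g2_variance(ds, lds, CFG) == 0.0

    def test_deterministic_given_seed(self, rng):
        ds = make_random_dataset(rng, n_samples=150, n_snps=4)
        lds = LocalDiseaseStructure((1, 2))
        a = estimate_g2_variance(ds, lds, CFG)
        b = estimate_g2_variance(ds, lds, CFG)
        assert a == b
        c = estimate_g2_variance(ds, lds, ScoringConfig(n_permutations=100, rng_seed=9))
        assert a != c

    def test_order_invariant_via_sorted_key(self, rng):
        ds = make_random_dataset(rng, n_samples=150, n_snps=4)
        a = estimate_g2_variance(ds, LocalDiseaseStructure((2, 0)), CFG)
        b = estimate_g2_variance(ds, LocalDiseaseStructure((0, 2)), CFG)
        assert a == b

    def test_empty_parent_set_rejected(self, rng):
        ds = make_random_dataset(rng)
        with pytest.raises(ValueError, match="empty"):
            estimate_g2_variance(ds, LocalDiseaseStructure(()), CFG)

    def test_matches_explicit_permutation_null(self, rng):
        """Hypergeometric sampling reproduces brute-force label shuffling."""
        ds = make_random_dataset(rng, n_samples=120, n_snps=3)
        lds = LocalDiseaseStructure((0,))
        est = estimate_g2_variance(
            ds, lds, ScoringConfig(n_permutations=4000, rng_seed=3)
        )
        # brute force: physically permute the phenotype vector
        g2s = []
        y = ds.phenotype.copy()
        for _ in range(4000):
            rng.shuffle(y)
            perm = GenotypeDataset(ds.genotypes, y, ds.snp_ids)
            g2s.append(g2_statistic(tabulate(perm, lds))[0])
        brute = float(np.var(g2s, ddof=1))
        assert est == pytest.approx(brute, rel=0.15)


class TestScores:
    def test_empty_structure_aic_closed_form(self):
        ds = GenotypeDataset(
            np.zeros((100, 1), int),
            np.array([0, 1] * 50),
            ["a"],
        )
        bd = score(ds, LocalDiseaseStructure(()), ScoringConfig(score_type="aic"))
        assert bd.score == pytest.approx(100 * math.log(0.5) - 1)

    def test_episcore_with_chi2_variance_equals_aic(self, rng):
        """Forcing Var_D(G^2) = 2*DF recovers the AIC exactly."""
        ds = make_random_dataset(rng, n_samples=120, n_snps=4)
        for parents in [(0,), (1, 3), (0, 1, 2)]:
            lds = LocalDiseaseStructure(parents)
            counts = tabulate(ds, lds)
            _, df = g2_statistic(counts)
            epi = score(
                ds, lds, ScoringConfig(score_type="episcore"),
                variance_cache=FixedVariance(2 * df),
            )
            aic = score(ds, lds, ScoringConfig(score_type="aic"))
            assert epi.score == pytest.approx(aic.score, abs=1e-9)

    def test_aic_difference_identity_over_all_small_parent_sets(self, rng):
        """AIC(LDS) - AIC(LDS0) == N*MI - (r-1)(q-1) for every |Pa| <= 2."""
        ds = make_random_dataset(rng, n_samples=80, n_snps=5)
        cfg = ScoringConfig(score_type="aic")
        empty = score(ds, LocalDiseaseStructure(()), cfg).score
        for k in (1, 2):
            for parents in itertools.combinations(range(5), k):
                lds = LocalDiseaseStructure(parents)
                bd = score(ds, lds, cfg)
                counts = tabulate(ds, lds)
                expect = counts.total * mutual_information(counts) - (
                    (counts.r - 1) * (counts.q - 1)
                )
                assert bd.score - empty == pytest.approx(expect, abs=1e-9)

    def test_bic_penalty_stricter_than_aic(self, rng):
        """For N > e^2, BIC's per-parameter penalty exceeds AIC's."""
        ds = make_random_dataset(rng, n_samples=100, n_snps=4)
        lds = LocalDiseaseStructure((0, 1))
        aic = score(ds, lds, ScoringConfig(score_type="aic"))
        bic = score(ds, lds, ScoringConfig(score_type="bic"))
        assert bic.score < aic.score

    def test_upper_bound_dominates_exhaustive_episcore(self, rng):
        ds = make_random_dataset(rng, n_samples=90, n_snps=6)
        cfg = ScoringConfig(n_permutations=100, rng_seed=1)
        cache = VarianceCache(ds, cfg)
        bound = score_upper_bound(ds, cfg)
        best = -np.inf
        for k in (0, 1, 2, 3):
            for parents in itertools.combinations(range(6), k):
                bd = score(ds, LocalDiseaseStructure(parents), cfg, cache)
                best = max(best, bd.score)
        assert best <= bound
        # with loglik_empty = -N*H(X), the bound is identically zero
        assert bound == pytest.approx(0.0, abs=1e-9)

    def test_breakdown_serializes(self, rng):
        ds = make_random_dataset(rng)
        bd = score(ds, LocalDiseaseStructure((0,)), CFG)
        payload = bd.to_dict()
        assert payload["parents"] == [0]
        assert payload["config"]["n_permutations"] == 100
        bd.to_json()


class TestStructureInvariants:
    def test_duplicate_parents_rejected(self):
        with pytest.raises(ValueError):
            LocalDiseaseStructure((1, 1))

    def test_theoretical_configuration_count(self):
        assert LocalDiseaseStructure(()).q == 1
        assert LocalDiseaseStructure((4, 2, 7)).q == 27

    def test_variance_cache_computes_once_per_sorted_tuple(self, rng):
        ds = make_random_dataset(rng)
        cache = VarianceCache(ds, CFG)
        a = cache.get((2, 0))
        b = cache.get((0, 2))
        assert a == b and len(cache) == 1
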