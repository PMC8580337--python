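"""Quartile volcano, physiological-age correlation, leave-one-out value."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import physioage as pa
from physioage.ensemble import ModelSpec


def welch_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook Welch t-test p-value with Welch-Satterthwaite df."""
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)


def _cohort(values: np.ndarray) -> pa.CohortTable:
    n = values.shape[0]
    vals = pd.DataFrame(values, index=pd.Index([f"i{j}" for j in range(n)], name="id"),
                        columns=[f"t{j}" for j in range(values.shape[1])])
    meta = pd.DataFrame({"age": 30.0 + np.arange(n) % 50, "sex": 0,
                         "deceased": False, "lifespan": np.nan, "wave": 1},
                        index=vals.index)
    return pa.CohortTable(vals, meta)


class TestQuartileVolcano:
    def test_pvalues_match_bruteforce_welch(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(80, 6))
        cohort = _cohort(values)
        par = pd.Series(rng.uniform(0.9, 1.1, 80), index=cohort.values.index)
        out = pa.quartile_volcano(cohort, par).set_index("trait")
        order = np.argsort(par.to_numpy(), kind="stable")
        bottom, top = values[order[:20]], values[order[-20:]]
        for j, trait in enumerate(cohort.values.columns):
            expect = welch_bruteforce(top[:, j], bottom[:, j])
            assert out.loc[trait, "p"] == pytest.approx(expect, abs=1e-10)

    def test_null_trait_has_unit_fold_change_and_large_p(self):
        rng = np.random.default_rng(1)
        values = np.column_stack([np.full(40, 5.0), rng.normal(size=40)])
        values[:, 0] += rng.normal(0, 1e-9, 40)  # break exact ties only
        cohort = _cohort(values)
        par = pd.Series(rng.uniform(0.9, 1.1, 40), index=cohort.values.index)
        row = pa.quartile_volcano(cohort, par).set_index("trait").loc["t0"]
        assert row["fold_change"] == pytest.approx(1.0, abs=1e-6)
        assert row["p"] > 0.05

    def test_bonferroni_threshold_scales_as_alpha_over_t(self):
        rng = np.random.default_rng(2)
        for t in (10, 150, 200):
            cohort = _cohort(rng.normal(size=(40, t)))
            par = pd.Series(rng.uniform(0.9, 1.1, 40), index=cohort.values.index)
            out = pa.quartile_volcano(cohort, par, alpha=0.05)
            assert out["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / t)
        # 150 traits at the 5% single-test level: threshold 3.33e-4
        assert 0.05 / 150 == pytest.approx(3.33e-4, rel=2e-3)

    def test_par_tracking_trait_ranks_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            par_vals = np.exp(rng.normal(0, 0.08, n))
            values = np.column_stack(
                [par_vals + rng.normal(0, 0.01, n), rng.normal(5, 1, (n, 4))])
            cohort = _cohort(values)
            par = pd.Series(par_vals, index=cohort.values.index)
            out = pa.quartile_volcano(cohort, par)
            if out.iloc[0]["trait"] == "t0" and out.iloc[0]["fold_change"] > 1:
                hits += 1
        assert hits >= 9

    def test_degenerate_trait_ranks_last(self):
        rng = np.random.default_rng(3)
        values = np.column_stack([np.full(40, 2.0), rng.normal(size=40)])
        cohort = _cohort(values)
        par = pd.Series(rng.uniform(0.9, 1.1, 40), index=cohort.values.index)
        out = pa.quartile_volcano(cohort, par)
        assert out.iloc[-1]["trait"] == "t0"
        assert np.isnan(out.iloc[-1]["p"])


class TestAgeCorrelationRanking:
    def test_trait_equal_to_physiological_age_ranks_first(self):
        rng = np.random.default_rng(4)
        phys_vals = rng.uniform(20, 90, 100)
        values = np.column_stack([phys_vals, rng.normal(size=(100, 3))])
        cohort = _cohort(values)
        phys = pd.Series(phys_vals, index=cohort.values.index)
        out = pa.age_correlation_ranking(cohort, phys)
        assert out.iloc[0]["trait"] == "t0"
        assert abs(out.iloc[0]["r"]) == pytest.approx(1.0)

    def test_pure_noise_traits_have_small_r(self):
        rng = np.random.default_rng(5)
        cohort = _cohort(rng.normal(size=(1000, 4)))
        phys = pd.Series(rng.uniform(20, 90, 1000), index=cohort.values.index)
        out = pa.age_correlation_ranking(cohort, phys)
        assert out["r"].abs().max() < 0.1

    def test_negation_flips_sign_but_not_rank(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(60, 3))
        phys = pd.Series(rng.uniform(20, 90, 60))
        cohort_a = _cohort(base)
        phys.index = cohort_a.values.index
        out_a = pa.age_correlation_ranking(cohort_a, phys)
        flipped = base.copy()
        flipped[:, 1] *= -1
        out_b = pa.age_correlation_ranking(_cohort(flipped), phys)
        a1, b1 = out_a.set_index("trait"), out_b.set_index("trait")
        assert b1.loc["t1", "r"] == pytest.approx(-a1.loc["t1", "r"])
        assert b1.loc["t1", "rank"] == a1.loc["t1", "rank"]


class TestAddedValueRanking:
    def test_informative_trait_has_largest_delta_r2(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 250
            age = rng.uniform(20, 80, n)
            values = np.column_stack(
                [age / 10 + rng.normal(0, 0.5, n), rng.normal(size=(n, 5))])
            cohort = _cohort(values)
            cohort.meta["age"] = age
            out = pa.added_value_ranking(
                cohort, ModelSpec(family="linear", use_lda=False),
                splits_per_trait=25, seed=seed)
            if out.iloc[0]["trait"] == "t0":
                hits += 1
        assert hits >= 4

    def test_duplicated_trait_is_redundant(self):
        rng = np.random.default_rng(7)
        n = 300
        age = rng.uniform(20, 80, n)
        signal = age / 10 + rng.normal(0, 0.5, n)
        values = np.column_stack([signal, signal.copy(), rng.normal(size=(n, 2))])
        cohort = _cohort(values)
        cohort.meta["age"] = age
        out = pa.added_value_ranking(
            cohort, ModelSpec(family="linear", use_lda=False),
            splits_per_trait=25, seed=0).set_index("trait")
        assert abs(out.loc["t0", "delta_r2"]) < 0.02
        assert abs(out.loc["t1", "delta_r2"]) < 0.02


class TestRankConcordance:
    @staticmethod
    def _ranking(names, ranks):
        return pd.DataFrame({"trait": names, "rank": ranks})

    def test_identical_rankings(self):
        a = self._ranking(list("abcde"), [1, 2, 3, 4, 5])
        assert pa.rank_concordance(a, a) == pytest.approx(1.0)

    def test_reversed_rankings(self):
        a = self._ranking(list("abcde"), [1, 2, 3, 4, 5])
        b = self._ranking(list("abcde"), [5, 4, 3, 2, 1])
        assert pa.rank_concordance(a, b) == pytest.approx(-1.0)

    def test_adjacent_swap_hand_value(self):
        names = list("abcdefghij")
        a = self._ranking(names, list(range(1, 11)))
        swapped = list(range(1, 11))
        swapped[3], swapped[4] = swapped[4], swapped[3]
        b = self._ranking(names, swapped)
        # Spearman with sum d^2 = 2 at n = 10: 1 - 12/990
        assert pa.rank_concordance(a, b) == pytest.approx(1 - 12 / 990, abs=1e-12)

    def test_too_few_shared_traits(self):
        a = self._ranking(["x", "y"], [1, 2])
        with pytest.raises(ValueError, match="shared"):
            pa.rank_concordance(a, a)


def test_all_three_methods_find_the_planted_signal():
    """One trait tracks the latent rate; every ranking method should put it
    on top in most replicates."""
    top = {"volcano": 0, "corr": 0, "added": 0}
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n = 300
        age = rng.uniform(20, 80, n)
        rho = np.exp(rng.normal(0, 0.08, n))
        phys_vals = rho * age
        values = np.column_stack(
            [phys_vals + rng.normal(0, 2.0, n), rng.normal(size=(n, 4))])
        cohort = _cohort(values)
        cohort.meta["age"] = age
        par = pd.Series(phys_vals / age, index=cohort.values.index)
        phys = pd.Series(phys_vals, index=cohort.values.index)
        if pa.quartile_volcano(cohort, par).iloc[0]["trait"] == "t0":
            top["volcano"] += 1
        if pa.age_correlation_ranking(cohort, phys).iloc[0]["trait"] == "t0":
            top["corr"] += 1
        av = pa.added_value_ranking(cohort, ModelSpec(family="linear", use_lda=False),
                                    splits_per_trait=15, seed=seed)
        if av.iloc[0]["trait"] == "t0":
            top["added"] += 1
    assert min(top.values()) >= 8
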