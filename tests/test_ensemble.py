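"""The split engine, per-split fits, aggregation, scoring, and recalibration."""

import numpy as np
import pandas as pd
import pytest

import physioage as pa
from physioage.ensemble import AgePredictionSet, ModelSpec, fit_predict_once
from physioage.selection import make_age_bins


def _toy_cohort(n=200, seed=0, slope=2.0, intercept=3.0, noise=0.0):
    """Cohort whose single informative trait is an affine function of age."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 80, size=n)
    x1 = (age - intercept) / slope + rng.normal(0, noise, size=n)
    x2 = rng.normal(size=n)
    ids = [f"i{j}" for j in range(n)]
    vals = pd.DataFrame({"x1": x1, "x2": x2}, index=pd.Index(ids, name="id"))
    meta = pd.DataFrame({"age": age, "sex": 0, "deceased": False,
                         "lifespan": np.nan, "wave": 1}, index=vals.index)
    return pa.CohortTable(vals, meta)


class TestMakeSplits:
    def test_ten_percent_of_a_single_bin(self):
        bins = make_age_bins(np.linspace(20, 24, 10), width=5)
        plans = pa.make_splits(bins, m=1, seed=0)
        assert len(plans[0].test_idx) == 1

    def test_partition_contract_holds_for_every_plan(self):
        bins = make_age_bins(np.random.default_rng(1).uniform(20, 70, 97), width=5)
        for plan in pa.make_splits(bins, m=25, seed=4):
            union = np.sort(np.concatenate([plan.train_idx, plan.test_idx]))
            assert np.array_equal(union, np.arange(97))
            assert not set(plan.train_idx) & set(plan.test_idx)

    def test_everyone_eventually_appears_in_a_test_set(self):
        ages = np.random.default_rng(2).uniform(20, 60, 60)
        bins = make_age_bins(ages, width=5)
        seen = np.zeros(60, dtype=bool)
        for plan in pa.make_splits(bins, m=1000, seed=9):
            seen[plan.test_idx] = True
        counts = np.bincount(bins.assignment)
        eligible = counts[bins.assignment] >= 2
        assert seen[eligible].all()

    def test_stratification_keeps_test_fraction_per_bin(self):
        ages = np.concatenate([np.full(40, 22.0) + np.arange(40) * 0.01,
                               np.full(20, 47.0) + np.arange(20) * 0.01])
        bins = make_age_bins(ages, width=5)
        for plan in pa.make_splits(bins, m=10, seed=1):
            in_bin0 = np.isin(plan.test_idx, np.flatnonzero(bins.assignment == 0))
            assert in_bin0.sum() == 4 and (~in_bin0).sum() == 2

    def test_zero_splits_errors(self):
        bins = make_age_bins(np.linspace(20, 40, 10), width=5)
        with pytest.raises(ValueError):
            pa.make_splits(bins, m=0, seed=0)


class TestFitPredictOnce:
    def test_exact_linear_recovery_with_zero_noise(self):
        cohort = _toy_cohort(noise=0.0)
        values = cohort.values.to_numpy()
        ages = cohort.ages
        bins = make_age_bins(ages, width=5)
        plan = pa.make_splits(bins, m=1, seed=3)[0]
        spec = ModelSpec(family="linear", use_lda=False)
        preds = fit_predict_once(plan, values, bins, ages, spec)
        assert np.allclose(preds, ages[plan.test_idx], atol=1e-8)

    def test_trait_column_order_does_not_change_predictions(self):
        cohort = _toy_cohort(noise=0.5, seed=5)
        values = cohort.values.to_numpy()
        ages = cohort.ages
        bins = make_age_bins(ages, width=5)
        plan = pa.make_splits(bins, m=1, seed=6)[0]
        spec = ModelSpec(family="linear", use_lda=False)
        p1 = fit_predict_once(plan, values, bins, ages, spec)
        p2 = fit_predict_once(plan, values[:, ::-1], bins, ages, spec)
        assert np.allclose(p1, p2, atol=1e-10)

    def test_classifier_predictions_are_bin_centers(self, small_cohort):
        cohort, _, _ = small_cohort
        values = cohort.values.to_numpy()
        ages = cohort.ages
        bins = make_age_bins(ages, width=5)
        plan = pa.make_splits(bins, m=1, seed=7)[0]
        preds = fit_predict_once(plan, values, bins, ages, ModelSpec())
        assert set(np.round(preds, 9)) <= set(np.round(bins.centers, 9))


class TestEnsemble:
    def test_single_split_equals_single_prediction(self):
        cohort = _toy_cohort(noise=0.2, seed=8)
        preds = pa.ensemble_physio_age(cohort, ModelSpec(family="linear"),
                                       m=1, seed=2)
        assert (preds.n_appearances == 1).all()
        assert np.isnan(preds.sd).all()

    def test_mean_and_population_sd_convention(self):
        """Two appearances at 40 and 44 must aggregate to mean 42, SD 2."""
        cohort = _toy_cohort(n=60, seed=9, noise=0.3)
        plans_preds = {}
        values = cohort.values.to_numpy()
        ages = cohort.ages
        bins = make_age_bins(ages, width=5)
        spec = ModelSpec(family="linear", use_lda=False)
        m = 40
        per_indiv: dict[int, list[float]] = {}
        for plan in pa.make_splits(bins, m, seed=5):
            p = fit_predict_once(plan, values, bins, ages, spec)
            for idx, val in zip(plan.test_idx, p):
                per_indiv.setdefault(idx, []).append(val)
        ens = pa.ensemble_physio_age(cohort, spec, m=m, seed=5)
        id_to_pos = {pid: i for i, pid in enumerate(cohort.ids)}
        for pid, mean, sd in zip(ens.ids, ens.phys_age, ens.sd):
            vals = np.array(per_indiv[id_to_pos[pid]])
            assert mean == pytest.approx(vals.mean(), abs=1e-9)
            if len(vals) > 1:
                assert sd == pytest.approx(vals.std(), abs=1e-9)  # population SD

    def test_classifier_means_stay_within_bin_center_range(self, small_cohort):
        cohort, _, _ = small_cohort
        preds = pa.ensemble_physio_age(cohort, ModelSpec(), m=20, seed=1)
        bins = make_age_bins(cohort.ages, width=5)
        assert preds.phys_age.min() >= bins.centers.min()
        assert preds.phys_age.max() <= bins.centers.max()

    def test_incomplete_cohort_is_rejected(self):
        cohort = _toy_cohort(n=40)
        cohort.values.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pa.ensemble_physio_age(cohort, ModelSpec(family="linear"), m=2, seed=0)


class TestScorePredictions:
    @staticmethod
    def _pset(chron, phys):
        n = len(chron)
        return AgePredictionSet(
            ids=[f"i{j}" for j in range(n)], chron_age=np.asarray(chron, float),
            phys_age=np.asarray(phys, float), sd=np.full(n, np.nan),
            n_appearances=np.ones(n, int), m_iterations=1,
            spec=ModelSpec(family="linear"), k_used=1,
        )

    def test_perfect_predictions(self):
        m = pa.score_predictions(self._pset([30, 40, 50], [30, 40, 50]))
        assert m.r2 == pytest.approx(1.0) and m.mae == 0.0

    def test_mae_hand_example(self):
        m = pa.score_predictions(self._pset([1, 2, 3], [2, 2, 5]))
        assert m.mae == pytest.approx(1.0)

    def test_r2_ignores_affine_miscalibration(self):
        x = np.array([30.0, 40, 50, 60])
        m = pa.score_predictions(self._pset(x, 2 * x + 7))
        assert m.r2 == pytest.approx(1.0)
        assert m.mae > 0

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            pa.score_predictions(self._pset([30, 40, 50], [45, 45, 45]))


class TestRescaleTrim:
    @staticmethod
    def _pset(chron, phys):
        return TestScorePredictions._pset(chron, phys)

    def test_calibrated_predictions_are_a_fixed_point(self):
        x = np.linspace(20, 80, 50)
        preds = self._pset(x, x)
        out = pa.rescale_trim(preds, mode="rescale")
        assert np.allclose(out.phys_age, x, atol=1e-10)

    def test_rescaled_fit_line_is_identity(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(20, 90, 300)
        y = 0.6 * x + 12 + rng.normal(0, 2, 300)
        out = pa.rescale_trim(self._pset(x, y), mode="rescale")
        b, a = np.polyfit(out.chron_age, out.phys_age, 1)
        assert b == pytest.approx(1.0, abs=1e-8)
        assert a == pytest.approx(0.0, abs=1e-6)

    def test_anticorrelated_predictions_error(self):
        x = np.linspace(20, 80, 30)
        with pytest.raises(ValueError, match="slope"):
            pa.rescale_trim(self._pset(x, -x + 100), mode="rescale")

    def test_trim_drops_edge_bins(self):
        x = np.linspace(20, 79, 120)
        out = pa.rescale_trim(self._pset(x, x), mode="trim", trim_bins=1)
        assert out.chron_age.min() >= 25
        assert out.chron_age.max() < 75

    def test_rescale_weakens_par_age_correlation(self):
        """Regression-to-the-mean compresses predictions; inverting the
        calibration line should not worsen the PAR-age correlation."""
        improved = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.uniform(20, 90, 400)
            y = 0.7 * x + 18 + rng.normal(0, 3, 400)  # compressed predictions
            preds = self._pset(x, y)
            before = abs(np.corrcoef(x, preds.phys_age / x)[0, 1])
            out = pa.rescale_trim(preds, mode="rescale")
            after = abs(np.corrcoef(out.chron_age, out.phys_age / out.chron_age)[0, 1])
            if after <= before + 1e-12:
                improved += 1
        assert improved >= 9


def test_more_trait_noise_never_helps():
    """Mean prediction R^2 is nonincreasing along a noise-SD grid."""
    for seed in (3, 4):
        r2s = []
        for noise_sd in (0.5, 1.5, 4.0):
            cohort, _ = pa.generate_cohort(pa.SimulationConfig(
                n_individuals=500, seed=seed, noise_sd=noise_sd,
                n_continuous=15, n_ordinal=3, n_binary=2))
            preds = pa.ensemble_physio_age(
                cohort, ModelSpec(family="linear"), m=60, seed=seed)
            r2s.append(pa.score_predictions(preds).r2)
        assert r2s[0] >= r2s[1] >= r2s[2]
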