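"""Ensemble estimation of physiological age.

The estimator repeats, M times: split the cohort 90/10 within every
chronological age bin, rank traits by Fisher score on the training rows,
keep the top k, optionally project onto linear discriminants, fit an age
model, and predict age for the held-out 10%. An individual's physiological
age is the mean of their test-set predictions across all M splits; the
spread of those predictions is reported as a population SD.

The reference model family is a random-forest classifier over age-bin
labels (30 trees, Gini impurity, min split 2, min leaf 1) whose predicted
bin is mapped back to the bin's center age; continuous regressor families
(linear, lasso, elastic net, kNN, SVM) are provided for cross-model
agreement checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from .cohort import CohortTable
from .selection import AgeBins, lda_fit, make_age_bins, rank_traits

logger = logging.getLogger("physioage")

MODEL_FAMILIES = (
    "bin_classifier_forest", "elastic_net", "knn_regressor", "lasso", "linear", "svm",
)


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus hyperparameters for one ensemble run."""

    family: str = "bin_classifier_forest"
    hyperparameters: dict = field(default_factory=dict)
    use_lda: bool = True
    k: int | None = None   # top-k Fisher traits; None keeps all

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    def build(self, seed: int):
        hp = dict(self.hyperparameters)
        if self.family == "bin_classifier_forest":
            return RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 30),
                criterion=hp.pop("criterion", "gini"),
                min_samples_split=hp.pop("min_samples_split", 2),
                min_samples_leaf=hp.pop("min_samples_leaf", 1),
                random_state=seed,
                **hp,
            )
        if self.family == "elastic_net":
            return ElasticNet(random_state=seed, **hp)
        if self.family == "knn_regressor":
            return KNeighborsRegressor(**hp)
        if self.family == "lasso":
            return Lasso(random_state=seed, **hp)
        if self.family == "linear":
            return LinearRegression(**hp)
        return SVR(**hp)

    @property
    def is_classifier(self) -> bool:
        return self.family == "bin_classifier_forest"


@dataclass(frozen=True)
class SplitPlan:
    iteration: int
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class AgePredictionSet:
    """Per-individual physiological age aggregated over ensemble splits."""

    ids: list[str]
    chron_age: np.ndarray
    phys_age: np.ndarray      # mean predicted age over test appearances
    sd: np.ndarray            # population SD over appearances; NaN if 1 appearance
    n_appearances: np.ndarray
    m_iterations: int
    spec: ModelSpec
    k_used: int
    skipped_splits: int = 0
    provenance: str = "raw"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chron_age": self.chron_age, "phys_age": self.phys_age,
             "sd": self.sd, "n_appearances": self.n_appearances},
            index=pd.Index(self.ids, name="id"),
        )


def make_splits(bins: AgeBins, m: int, seed: int, test_frac: float = 0.1) -> list[SplitPlan]:
    """M independent splits, stratified so each age bin contributes ~10% to
    the test set (at least one test member whenever the bin has >= 2)."""
    if m < 1:
        raise ValueError("number of splits must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(m)]
    bin_members = [np.flatnonzero(bins.assignment == b) for b in range(bins.n_bins)]
    lone = [b for b, mem in enumerate(bin_members) if len(mem) < 2]
    if lone:
        logger.warning("bins %s have a single member: always in training", lone)
    plans = []
    for it, cs in enumerate(child_seeds):
        rng = np.random.default_rng(cs)
        test_parts = []
        for mem in bin_members:
            if len(mem) < 2:
                continue
            n_test = max(1, int(round(test_frac * len(mem))))
            n_test = min(n_test, len(mem) - 1)  # never empty the training side
            test_parts.append(rng.choice(mem, size=n_test, replace=False))
        test_idx = np.sort(np.concatenate(test_parts))
        mask = np.ones(len(bins.assignment), dtype=bool)
        mask[test_idx] = False
        plans.append(SplitPlan(it, cs, np.flatnonzero(mask), test_idx))
    return plans


def fit_predict_once(
    plan: SplitPlan,
    values: np.ndarray,
    bins: AgeBins,
    ages: np.ndarray,
    spec: ModelSpec,
) -> np.ndarray | None:
    """Fit on the training rows, return predicted ages for plan.test_idx.

    Fisher ranking and any LDA projection are computed on training rows
    only. Classifier families are trained on bin indices and their
    predictions mapped to bin-center ages. Returns None (the split is
    skipped) when the training side lost an entire class.
    """
    tr, te = plan.train_idx, plan.test_idx
    y_class = bins.assignment
    if spec.is_classifier and len(np.unique(y_class[tr])) < bins.n_bins:
        logger.info("split %d skipped: training set missing an age bin", plan.iteration)
        return None
    ranking = rank_traits(values[tr], AgeBins(bins.edges, bins.centers, y_class[tr]),
                          k=spec.k)
    cols = ranking.selected
    X_tr, X_te = values[np.ix_(tr, cols)], values[np.ix_(te, cols)]
    if spec.use_lda:
        proj = lda_fit(X_tr, y_class[tr])
        X_tr, X_te = proj.transform(X_tr), proj.transform(X_te)
    model = spec.build(plan.seed)
    if spec.is_classifier:
        model.fit(X_tr, y_class[tr])
        return bins.centers[model.predict(X_te)]
    model.fit(X_tr, ages[tr])
    return model.predict(X_te)


def ensemble_physio_age(
    cohort: CohortTable,
    spec: ModelSpec | None = None,
    m: int = 10_000,
    seed: int = 0,
    bin_width: float = 5.0,
    bins: AgeBins | None = None,
) -> AgePredictionSet:
    """Physiological age per individual: mean test-set prediction over M
    stratified 90/10 splits. Individuals never held out are dropped and
    logged."""
    if not cohort.is_complete:
        raise ValueError("cohort contains missing cells; run clean_missing first")
    spec = spec or ModelSpec()
    values = cohort.values.to_numpy(float)
    ages = cohort.ages
    if bins is None:
        bins = make_age_bins(ages, width=bin_width)
    n = len(ages)
    sums = np.zeros(n)
    sq_sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    skipped = 0
    for plan in make_splits(bins, m, seed):
        preds = fit_predict_once(plan, values, bins, ages, spec)
        if preds is None:
            skipped += 1
            continue
        np.add.at(sums, plan.test_idx, preds)
        np.add.at(sq_sums, plan.test_idx, preds**2)
        np.add.at(counts, plan.test_idx, 1)
    seen = counts > 0
    if not seen.all():
        logger.warning("%d individuals never appeared in a test set; excluded",
                       int((~seen).sum()))
    mean = sums[seen] / counts[seen]
    var = np.maximum(sq_sums[seen] / counts[seen] - mean**2, 0.0)
    sd = np.sqrt(var)
    sd[counts[seen] == 1] = np.nan
    ids = [pid for pid, s in zip(cohort.ids, seen) if s]
    k_used = spec.k if spec.k is not None else cohort.n_traits
    return AgePredictionSet(
        ids=ids, chron_age=ages[seen], phys_age=mean, sd=sd,
        n_appearances=counts[seen], m_iterations=m, spec=spec,
        k_used=k_used, skipped_splits=skipped,
    )


@dataclass(frozen=True)
class MetricsReport:
    r: float
    r2: float
    mae: float
    n: int
    par_age_r: float | None = None
    sd_age_r: float | None = None


def score_predictions(preds: AgePredictionSet) -> MetricsReport:
    """Accuracy of physiological vs chronological age: Pearson r, R² = r²,
    MAE in years; also the correlation of PAR and of prediction SD with age."""
    y, x = preds.phys_age, preds.chron_age
    if len(x) < 3:
        raise ValueError("need >= 3 individuals to score")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    mae = float(np.mean(np.abs(x - y)))
    par = y / x
    par_r = float(np.corrcoef(x, par)[0, 1])
    sd_ok = np.isfinite(preds.sd)
    sd_r = (float(np.corrcoef(x[sd_ok], preds.sd[sd_ok])[0, 1])
            if sd_ok.sum() >= 3 and np.std(preds.sd[sd_ok]) > 0 else None)
    return MetricsReport(r=r, r2=r * r, mae=mae, n=len(x), par_age_r=par_r, sd_age_r=sd_r)


def rescale_trim(
    preds: AgePredictionSet,
    mode: str = "rescale",
    trim_bins: int = 1,
    bin_width: float = 5.0,
) -> AgePredictionSet:
    """Correct the age-dependent imbalance of predicted ages.

    rescale: regress pred = a + b*age over the cohort and invert the line,
    output (pred - a)/b, so the recalibrated predictions track the identity
    line. trim: drop individuals in the trim_bins youngest and oldest age
    bins, where edge-of-range shrinkage is worst. both: trim then rescale.
    """
    if mode not in {"none", "rescale", "trim", "both"}:
        raise ValueError(f"unknown mode {mode!r}")
    ids = list(preds.ids)
    age, pred = preds.chron_age, preds.phys_age
    sd, napp = preds.sd, preds.n_appearances
    if mode in {"trim", "both"} and trim_bins > 0:
        bins = make_age_bins(age, width=bin_width)
        keep = (bins.assignment >= trim_bins) & (bins.assignment < bins.n_bins - trim_bins)
        if not keep.any():
            raise ValueError("trimming removed every individual")
        ids = [i for i, k in zip(ids, keep) if k]
        age, pred, sd, napp = age[keep], pred[keep], sd[keep], napp[keep]
    if mode in {"rescale", "both"}:
        b, a = np.polyfit(age, pred, 1)
        if b <= 0:
            raise ValueError(f"calibration slope {b:.4f} <= 0; cannot rescale")
        pred = (pred - a) / b
        sd = sd / b
    return AgePredictionSet(
        ids=ids, chron_age=age, phys_age=pred, sd=sd, n_appearances=napp,
        m_iterations=preds.m_iterations, spec=preds.spec, k_used=preds.k_used,
        skipped_splits=preds.skipped_splits, provenance=f"{preds.provenance}+{mode}",
    )


def evaluate_k_curve(
    cohort: CohortTable,
    spec: ModelSpec,
    candidate_ks: list[int],
    m_per_k: int = 200,
    seed: int = 0,
    bin_width: float = 5.0,
) -> tuple[int, list[tuple[int, float, float]]]:
    """Mean test R² as a function of the trait count k, and the argmax k.

    For each k the same ``m_per_k`` stratified splits are evaluated with the
    top-k Fisher traits (recomputed per training set); ties go to the
    smallest k. The full-model k = n_traits is always appended so the curve
    is anchored at the complete trait set.
    """
    from .selection import select_k

    values = cohort.values.to_numpy(float)
    ages = cohort.ages
    bins = make_age_bins(ages, width=bin_width)
    plans = make_splits(bins, m_per_k, seed)
    ks = sorted(set(list(candidate_ks) + [cohort.n_traits]))

    def evaluate(k: int) -> tuple[float, float]:
        r2s = []
        spec_k = ModelSpec(spec.family, dict(spec.hyperparameters), spec.use_lda, k)
        for plan in plans:
            preds = fit_predict_once(plan, values, bins, ages, spec_k)
            if preds is None:
                continue
            truth = ages[plan.test_idx]
            if np.std(preds) == 0 or np.std(truth) == 0:
                continue
            r = stats.pearsonr(truth, preds).statistic
            r2s.append(r * r)
        return (float(np.mean(r2s)), float(np.std(r2s))) if r2s else (0.0, 0.0)

    return select_k(evaluate, ks)
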