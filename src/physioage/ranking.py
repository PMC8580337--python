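"""Trait ranking: which traits drive the aging-rate signal.

Three orderings over the cohort's traits:

- quartile volcano: Welch two-tailed t-test of each trait between the top
  and bottom PAR quartiles, with a fold change of quartile means and a
  Bonferroni threshold alpha / n_traits;
- correlation with physiological age: per-trait Pearson r, ranked by |r|;
- added value: drop in ensemble test R² when one trait is removed from
  the model (Fisher selection re-run without it), averaged over repeated
  training/testing splits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .ensemble import ModelSpec, fit_predict_once, make_splits
from .selection import make_age_bins


def quartile_volcano(
    cohort: CohortTable, par: pd.Series, alpha: float = 0.05, welch: bool = True
) -> pd.DataFrame:
    """Welch-t volcano of trait differences between extreme PAR quartiles.

    Quartiles are the lowest and highest 25% of individuals by empirical
    PAR (boundary ties resolved by id order). Fold change is
    mean(top)/mean(bottom) when both means are positive, otherwise the
    flagged mean difference. Returns traits sorted by ascending p with a
    passes_bonferroni flag at alpha / n_traits.
    """
    shared = cohort.values.index.intersection(par.index)
    if len(shared) < 8:
        raise ValueError("need >= 8 individuals for quartile comparison")
    vals = cohort.values.loc[shared]
    pv = par.loc[shared]
    order = np.argsort(pv.to_numpy(), kind="stable")
    q = len(shared) // 4
    bottom = vals.iloc[order[:q]].to_numpy(float)
    top = vals.iloc[order[-q:]].to_numpy(float)

    rows = []
    for j, trait in enumerate(vals.columns):
        t_col, b_col = top[:, j], bottom[:, j]
        degenerate = np.std(t_col) == 0 and np.std(b_col) == 0
        if degenerate:
            p = np.nan
        else:
            p = float(stats.ttest_ind(t_col, b_col, equal_var=not welch).pvalue)
        mb, mt = b_col.mean(), t_col.mean()
        if mb > 0 and mt > 0:
            fc, fc_kind = mt / mb, "ratio"
        else:
            fc, fc_kind = mt - mb, "difference"
        rows.append((trait, p, fc, fc_kind))
    df = pd.DataFrame(rows, columns=["trait", "p", "fold_change", "fc_kind"])
    threshold = alpha / len(vals.columns)
    df["bonferroni_threshold"] = threshold
    df["passes_bonferroni"] = df["p"] < threshold
    df = df.sort_values("p", na_position="last", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def age_correlation_ranking(cohort: CohortTable, phys_age: pd.Series) -> pd.DataFrame:
    """Per-trait Pearson r with physiological age, ranked by |r| descending;
    constant traits get r = NaN and rank last."""
    shared = cohort.values.index.intersection(phys_age.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 individuals")
    vals = cohort.values.loc[shared].to_numpy(float)
    y = phys_age.loc[shared].to_numpy(float)
    rs = []
    for j in range(vals.shape[1]):
        col = vals[:, j]
        rs.append(np.nan if np.std(col) == 0
                  else float(stats.pearsonr(col, y).statistic))
    df = pd.DataFrame({"trait": cohort.values.columns, "r": rs})
    df["abs_r"] = df["r"].abs()
    df = df.sort_values("abs_r", ascending=False, na_position="last",
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="abs_r")


def added_value_ranking(
    cohort: CohortTable,
    spec: ModelSpec | None = None,
    splits_per_trait: int = 500,
    seed: int = 0,
    bin_width: float = 5.0,
) -> pd.DataFrame:
    """Leave-one-trait-out importance.

    Baseline mean test R² is computed over ``splits_per_trait`` stratified
    splits with the full trait set; each trait is then removed, Fisher
    selection re-run without it on the identical splits, and its added
    value reported as dR² = R²_baseline − R²_without. Negative values
    (removals that help) are kept and reported.
    """
    if not cohort.is_complete:
        raise ValueError("cohort contains missing cells; run clean_missing first")
    spec = spec or ModelSpec()
    values = cohort.values.to_numpy(float)
    ages = cohort.ages
    bins = make_age_bins(ages, width=bin_width)
    plans = make_splits(bins, splits_per_trait, seed)

    def mean_r2(cols: np.ndarray) -> float:
        sub = values[:, cols]
        k = spec.k if spec.k is None or spec.k <= len(cols) else len(cols)
        spec_sub = ModelSpec(spec.family, dict(spec.hyperparameters), spec.use_lda, k)
        r2s = []
        for plan in plans:
            preds = fit_predict_once(plan, sub, bins, ages, spec_sub)
            if preds is None:
                continue
            truth = ages[plan.test_idx]
            if np.std(preds) == 0 or np.std(truth) == 0:
                continue
            r = stats.pearsonr(truth, preds).statistic
            r2s.append(r * r)
        return float(np.mean(r2s)) if r2s else 0.0

    all_cols = np.arange(values.shape[1])
    baseline = mean_r2(all_cols)
    deltas = [baseline - mean_r2(np.delete(all_cols, j)) for j in all_cols]
    df = pd.DataFrame({
        "trait": cohort.values.columns,
        "delta_r2": deltas,
        "baseline_r2": baseline,
    })
    df = df.sort_values("delta_r2", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def rank_concordance(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Spearman rank correlation of two rankings over their shared traits."""
    ra = a.set_index("trait")["rank"]
    rb = b.set_index("trait")["rank"]
    shared = ra.index.intersection(rb.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared traits, got {len(shared)}")
    return float(stats.spearmanr(ra.loc[shared], rb.loc[shared]).statistic)
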