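"""Physiological aging rate (PAR) and generic aging-rate ratios.

PAR = physiological age / chronological age. PAR > 1 means an individual
is aging faster than expected for their chronological-age peers, PAR < 1
slower. The same ratio applied to an externally supplied clock age (e.g.
a DNA-methylation age) gives an epigenetic aging rate (EAR) or any other
modality-specific rate; ``agreement`` quantifies how well two such rate
vectors agree, optionally after removing age and sex as confounders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import AgePredictionSet

_EXPECTED_TOL = 1e-9


@dataclass(frozen=True)
class PARRecord:
    id: str
    par: float
    interpretation: str  # slower | expected | faster

    def __post_init__(self) -> None:
        if self.par <= 0:
            raise ValueError(f"PAR must be positive, got {self.par}")


def compute_par(phys_age: float, chron_age: float, id: str = "") -> PARRecord:
    """Exact ratio of physiological to chronological age with its label."""
    if chron_age <= 0:
        raise ValueError(f"chronological age must be positive, got {chron_age}")
    if phys_age <= 0:
        raise ValueError(f"physiological age must be positive, got {phys_age}")
    par = phys_age / chron_age
    if abs(par - 1.0) <= _EXPECTED_TOL:
        label = "expected"
    elif par < 1.0:
        label = "slower"
    else:
        label = "faster"
    return PARRecord(id=id, par=par, interpretation=label)


def rate_ratio(alt_age: float, chron_age: float) -> float:
    """Generic aging-rate ratio (EAR-style) for any user-supplied clock age."""
    return compute_par(alt_age, chron_age).par


def par_table(preds: AgePredictionSet) -> pd.DataFrame:
    """Per-individual PAR from an ensemble prediction set.

    Individuals whose mean predicted age is not positive (possible for
    regressor families extrapolating at the young edge before
    recalibration) are dropped and logged rather than given an undefined
    rate.
    """
    import logging

    rows = []
    dropped = 0
    for i, p, c in zip(preds.ids, preds.phys_age, preds.chron_age):
        if p <= 0:
            dropped += 1
            continue
        r = compute_par(p, c, i)
        rows.append((i, c, p, r.par, r.interpretation))
    if dropped:
        logging.getLogger("physioage").warning(
            "%d individuals dropped from PAR table: nonpositive predicted age",
            dropped)
    df = pd.DataFrame(rows, columns=["id", "chron_age", "phys_age", "par",
                                     "interpretation"]).set_index("id")
    return df


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), covariates])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


@dataclass(frozen=True)
class AgreementReport:
    r: float
    r2: float
    n: int
    partial_r: float | None = None  # after residualizing on age and sex


def agreement(
    rates_a: pd.Series,
    rates_b: pd.Series,
    age: pd.Series | None = None,
    sex: pd.Series | None = None,
) -> AgreementReport:
    """Pearson agreement of two per-individual rate vectors on their shared
    ids, plus the partial correlation after least-squares residualization of
    both on an intercept, age, and sex when those covariates are given."""
    shared = rates_a.index.intersection(rates_b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared ids, got {len(shared)}")
    a = rates_a.loc[shared].to_numpy(float)
    b = rates_b.loc[shared].to_numpy(float)
    r = float(stats.pearsonr(a, b).statistic)
    partial = None
    if age is not None:
        cov = [age.loc[shared].to_numpy(float)]
        if sex is not None:
            cov.append(sex.loc[shared].to_numpy(float))
        covariates = np.column_stack(cov)
        ra = _residualize(a, covariates)
        rb = _residualize(b, covariates)
        partial = float(stats.pearsonr(ra, rb).statistic)
    return AgreementReport(r=r, r2=r * r, n=len(shared), partial_r=partial)
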