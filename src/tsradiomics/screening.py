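"""Patient-level aggregation and univariate logistic screening.

Lesion feature vectors are averaged per patient (the mean over the selected
primary and metastatic lesions).  Each clinical variable and each feature is
then screened against the binary TS label with a univariate logistic model;
continuous predictors are standardized to zero mean / unit SD before the fit
so odds ratios are per-SD, while binary predictors stay on their natural 0/1
coding.  No multiplicity correction is applied by default; Benjamini-
Hochberg is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .features import FeatureVector, feature_names

__all__ = [
    "PatientFeatureVector",
    "ScreenRow",
    "aggregate_patient",
    "univariate_logistic",
    "screen_all",
    "DEFAULT_CLINICAL_VARIABLES",
]

#: clinical covariates screened alongside the 60 features
DEFAULT_CLINICAL_VARIABLES = ["age", "sex", "smoking", "egfr"]


@dataclass
class PatientFeatureVector:
    """Per-patient mean of the selected lesions' 60-feature vectors."""

    patient_id: str
    values: dict[str, float]
    missing: dict[str, str]
    n_lesions: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_lesions <= 5:
            raise ValueError(f"n_lesions must be in [1, 5], got {self.n_lesions}")


@dataclass
class ScreenRow:
    """One univariate screening result."""

    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    converged: bool = True
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.converged and self.p_value < 0.05


def aggregate_patient(
    patient_id: str, vectors: list[FeatureVector]
) -> PatientFeatureVector:
    """Element-wise mean of 1-5 lesion vectors; NaNs excluded pairwise.

    A feature missing in every lesion stays missing (with the first lesion's
    reason); a feature present in some lesions is averaged over those.
    Commutes with lesion ordering.
    """
    if not 1 <= len(vectors) <= 5:
        raise ValueError(f"expected 1-5 lesion vectors, got {len(vectors)}")
    names = feature_names()
    arr = np.array([[v.values[k] for k in names] for v in vectors], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = np.nanmean(arr, axis=0)
    values = dict(zip(names, means.tolist()))
    missing = {}
    for j, k in enumerate(names):
        if np.isnan(arr[:, j]).all():
            reasons = [v.missing.get(k, "undefined") for v in vectors]
            missing[k] = f"missing in all {len(vectors)} lesions: {reasons[0]}"
    return PatientFeatureVector(patient_id, values, missing, n_lesions=len(vectors))


def _is_binary(x: np.ndarray) -> bool:
    return np.unique(x).size == 2


def univariate_logistic(x, y, name: str = "x") -> ScreenRow:
    """Univariate logistic fit of a binary outcome on one predictor.

    Continuous predictors are standardized pre-fit; the reported odds ratio
    is then per SD.  Wald 95% CI and two-sided Wald p.  Complete separation
    is flagged as non-convergent (odds ratio unreported), not raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be the same length")
    if not set(np.unique(y)) <= {0.0, 1.0} or np.unique(y).size < 2:
        raise ValueError("y must be binary with both classes present")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    n = x.size
    if not _is_binary(x):
        sd = x.std()
        if sd == 0:
            return ScreenRow(name, np.nan, np.nan, np.nan, np.nan, n,
                             converged=False, note="constant predictor")
        x = (x - x.mean()) / sd
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(method="newton", maxiter=50, tol=1e-8, disp=False)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return ScreenRow(name, np.nan, np.nan, np.nan, np.nan, n,
                         converged=False, note="complete separation")
    if not res.mle_retvals.get("converged", False):
        return ScreenRow(name, np.nan, np.nan, np.nan, np.nan, n,
                         converged=False, note="did not converge")
    beta = res.params[1]
    se = res.bse[1]
    z = stats.norm.ppf(0.975)
    return ScreenRow(
        variable=name,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(res.pvalues[1]),
        n=n,
    )


def _encode(series: pd.Series) -> np.ndarray:
    """Numeric coding for clinical covariates (binary factors -> 0/1)."""
    if series.dtype.kind in "ifu":
        return series.to_numpy(dtype=float)
    codes = {
        "female": 0, "male": 1,
        "never": 0, "ever": 1,
        "neg": 0, "pos": 1,
    }
    mapped = series.astype(str).str.lower().map(codes)
    if mapped.isna().any():
        raise ValueError(f"cannot encode values {set(series[mapped.isna()])}")
    return mapped.to_numpy(dtype=float)


def screen_all(
    clinical: pd.DataFrame,
    patient_vectors: list[PatientFeatureVector] | None = None,
    clinical_variables: list[str] | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Screen every clinical variable and feature against the TS label.

    Rows with a missing predictor value are dropped pairwise ('unknown' EGFR
    is treated as missing).  Returns one row per variable with OR, 95% CI,
    p-value and a significance flag at p < 0.05 (optionally BH-adjusted).
    """
    if len(clinical) < 20:
        raise ValueError("need >= 20 patients for screening")
    y_all = clinical["ts_label"].to_numpy(dtype=float)
    rows: list[ScreenRow] = []

    for var in clinical_variables if clinical_variables is not None else DEFAULT_CLINICAL_VARIABLES:
        series = clinical[var]
        valid = series.notna()
        if series.dtype.kind not in "ifu":
            valid &= ~series.astype(str).str.lower().isin(["unknown", "nan"])
        try:
            rows.append(univariate_logistic(_encode(series[valid]), y_all[valid.to_numpy()], name=var))
        except ValueError as exc:
            rows.append(ScreenRow(var, np.nan, np.nan, np.nan, np.nan,
                                  int(valid.sum()), converged=False, note=str(exc)))

    if patient_vectors:
        ids = [pv.patient_id for pv in patient_vectors]
        y = clinical.loc[ids, "ts_label"].to_numpy(dtype=float)
        feat = np.array([[pv.values[k] for k in feature_names()] for pv in patient_vectors])
        for j, name in enumerate(feature_names()):
            col = feat[:, j]
            ok = np.isfinite(col)
            try:
                rows.append(univariate_logistic(col[ok], y[ok], name=name))
            except ValueError as exc:
                rows.append(ScreenRow(name, np.nan, np.nan, np.nan, np.nan,
                                      int(ok.sum()), converged=False, note=str(exc)))

    df = pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p_value": [r.p_value for r in rows],
            "n": [r.n for r in rows],
            "converged": [r.converged for r in rows],
            "note": [r.note for r in rows],
        }
    )
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        ok = df["p_value"].notna()
        adj = np.full(len(df), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
        df["p_adjusted"] = adj
        df["significant"] = df["p_adjusted"] < 0.05
    else:
        df["significant"] = df["converged"] & (df["p_value"] < 0.05)
    return df
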