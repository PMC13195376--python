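"""Tract-covariate linear models of prevalence estimates.

Fits, separately per estimate source (EHR-derived vs model-based), an
ordinary-least-squares regression of tract prevalence (percent, 0-100) on
tract covariates: percentage aged over 65, percentage Black, percentage
American Indian/Alaska Native, percentage Asian or Hawaiian/Pacific Islander,
social vulnerability index quartile (reference: quartile 1, the least
vulnerable), urbanicity (reference: urban), percentage below poverty and
percentage with a high-school degree or GED. Normal-theory 95% confidence
intervals and two-sided p-values are reported; inference assumes independence
across tracts (no spatial correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["assign_svi_quartiles", "ModelResult", "build_design", "fit_prevalence_model"]

MODEL_TERMS = [
    "pct_over_65",
    "pct_black",
    "pct_aian",
    "pct_asian_hpi",
    "svi_2",
    "svi_3",
    "svi_4",
    "urbanicity_exurban",
    "urbanicity_rural",
    "urbanicity_small_town",
    "pct_below_poverty",
    "pct_hs_or_ged",
]


def assign_svi_quartiles(values) -> np.ndarray:
    """Quartile labels 1-4 from continuous social vulnerability values.

    Boundaries are the within-dataset 25/50/75 percentiles (linear
    interpolation); a value tied with a boundary goes to the lower quartile.
    Quartile 1 is the lowest vulnerability. Degenerate (constant) input maps
    everything to quartile 1 with a logged warning.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 values to form quartiles")
    q1, q2, q3 = (np.percentile(arr, q) for q in (25, 50, 75))
    if q1 == q3:
        logger.warning("constant SVI values: all tracts assigned quartile 1")
    labels = np.full(arr.size, 4, dtype=int)
    labels[arr <= q3] = 3
    labels[arr <= q2] = 2
    labels[arr <= q1] = 1
    return labels


@dataclass
class ModelResult:
    """OLS fit of one (source, condition) prevalence outcome."""

    source: str
    condition: str
    params: pd.DataFrame  # term, estimate, ci_low, ci_high, p
    r_squared: float
    nobs: int

    def to_frame(self) -> pd.DataFrame:
        out = self.params.copy()
        out.insert(0, "condition", self.condition)
        out.insert(0, "source", self.source)
        out["r_squared"] = self.r_squared
        return out


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded design matrix (without intercept) from a covariate table.

    Expects ``svi_quartile`` (1-4) and ``urbanicity`` categories plus the
    percentage columns; references are SVI quartile 1 and urban.
    """
    X = pd.DataFrame(index=covariates.index)
    for col in ("pct_over_65", "pct_black", "pct_aian", "pct_asian_hpi"):
        X[col] = covariates[col].astype(float)
    for q in (2, 3, 4):
        X[f"svi_{q}"] = (covariates["svi_quartile"].astype(int) == q).astype(float)
    for u in ("exurban", "rural", "small_town"):
        X[f"urbanicity_{u}"] = (covariates["urbanicity"] == u).astype(float)
    X["pct_below_poverty"] = covariates["pct_below_poverty"].astype(float)
    X["pct_hs_or_ged"] = covariates["pct_hs_or_ged"].astype(float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # Pivoted QR: columns pivoted past the numerical rank are collinear.
        _, r, piv = scipy.linalg.qr(mat, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [X.columns[j] for j in piv[len(diag):]]
        raise ValueError(f"rank-deficient design; collinear terms: {sorted(bad)}")


def fit_prevalence_model(
    estimates: pd.DataFrame,
    covariates: pd.DataFrame,
    source: str | None = None,
    condition: str = "",
    value_col: str = "prevalence_pct",
) -> ModelResult:
    """OLS of tract prevalence on the covariate terms.

    ``estimates`` needs ``tract_id`` and the prevalence column; ``covariates``
    needs ``tract_id`` plus the model covariates (``svi_quartile`` may be
    supplied directly, otherwise it is derived from ``svi_continuous`` by
    within-dataset quartile cut). Tracts with missing values are dropped.
    """
    cov = covariates.copy()
    if "svi_quartile" not in cov.columns:
        cov["svi_quartile"] = assign_svi_quartiles(cov["svi_continuous"])
    df = estimates[["tract_id", value_col]].merge(cov, on="tract_id", how="inner")
    df = df.dropna(subset=[value_col])
    X = build_design(df)
    y = df[value_col].astype(float)
    if len(df) < X.shape[1] + 3:
        raise ValueError(
            f"too few complete tracts ({len(df)}) for {X.shape[1] + 1} parameters"
        )
    Xc = sm.add_constant(X, prepend=True)
    _check_rank(Xc)
    fit = sm.OLS(y.to_numpy(), Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    params = pd.DataFrame(
        {
            "term": Xc.columns,
            "estimate": fit.params.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    src = source if source is not None else (
        str(estimates["source"].iloc[0]) if "source" in estimates.columns else ""
    )
    return ModelResult(
        source=src,
        condition=condition,
        params=params,
        r_squared=float(fit.rsquared),
        nobs=int(fit.nobs),
    )
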