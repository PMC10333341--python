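"""Moderation models: does exposure duration moderate the group-EC link?

One ordinary least-squares fit per hub ROI:

    EC ~ intercept + months + psychotropic + opioid + MDD + group
         + months x group

Subjects missing the exposure variable are dropped list-wise. Interaction
p-values across hubs are adjusted by Benjamini-Hochberg; the within-case
simple slope is months + interaction with a delta-method standard error
from the coefficient covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

TERMS = ["intercept", "months", "psychotropic", "opioid", "mdd", "ptsd",
         "months_x_ptsd"]

MIN_SUBJECTS = 10
CONDITION_WARN = 1e8


class ModerationError(ValueError):
    pass


@dataclass
class ModerationFit:
    """Per-hub OLS fit of the moderation design."""

    roi: int | str
    coefficients: pd.Series         # indexed by TERMS
    se: pd.Series
    ci95: pd.DataFrame              # columns lower/upper
    p: pd.Series
    cov: pd.DataFrame               # coefficient covariance
    r2: float
    n_obs: int
    df_resid: float


def _design(pheno: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "months": pheno["months_on_site"].astype(float),
            "psychotropic": pheno["psychotropic"].astype(float),
            "opioid": pheno["opioid"].astype(float),
            "mdd": pheno["mdd"].astype(float),
            "ptsd": pheno["ptsd"].astype(float),
        },
        index=pheno.index,
    )
    X["months_x_ptsd"] = X["months"] * X["ptsd"]
    return X


def fit_moderation(
    ec: pd.DataFrame,
    phenotypes: pd.DataFrame,
    hub_rois,
) -> list[ModerationFit]:
    """Fit the moderation model at each hub ROI.

    ``ec`` is an EC table (``subject_id`` plus ``roi_*`` columns);
    ``hub_rois`` is a list of ROI indices or ``roi_*`` column names.
    """
    merged = ec.merge(phenotypes, on="subject_id", how="inner",
                      validate="one_to_one")
    n_total = len(merged)
    usable = merged.dropna(subset=["months_on_site"])
    n_dropped = n_total - len(usable)
    if n_dropped:
        logger.info("dropped %d subject(s) missing exposure months "
                    "(%d remain)", n_dropped, len(usable))
    if len(usable) < MIN_SUBJECTS:
        raise ModerationError(
            f"only {len(usable)} subjects with exposure months; "
            f"need at least {MIN_SUBJECTS}"
        )
    X = _design(usable)
    if np.ptp(X["months"].to_numpy()) == 0:
        raise ModerationError(
            "exposure months are constant; interaction is inestimable"
        )
    cond = np.linalg.cond(X.to_numpy())
    if cond > CONDITION_WARN:
        logger.warning("moderation design is ill-conditioned "
                       "(condition number %.3g)", cond)

    fits = []
    for roi in hub_rois:
        col = roi if isinstance(roi, str) else f"roi_{roi}"
        if col not in usable.columns:
            raise ModerationError(f"EC table has no column {col!r}")
        y = usable[col].astype(float)
        res = sm.OLS(y, X).fit()
        ci = res.conf_int(alpha=0.05)
        ci.columns = ["lower", "upper"]
        fits.append(
            ModerationFit(
                roi=roi,
                coefficients=res.params,
                se=res.bse,
                ci95=ci,
                p=res.pvalues,
                cov=res.cov_params(),
                r2=float(res.rsquared),
                n_obs=int(res.nobs),
                df_resid=float(res.df_resid),
            )
        )
    return fits


def adjust_pvalues_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving and idempotent; the largest input maps to itself.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ModerationError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ModerationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def simple_slope(fit: ModerationFit, group: str = "ptsd"
                 ) -> tuple[float, tuple[float, float], float]:
    """Within-group slope of EC on months: months + interaction for cases.

    Returns (estimate, (ci_lower, ci_upper), p) using the coefficient
    covariance from the fit; for the reference group the slope is just the
    months coefficient.
    """
    for term in ("months", "months_x_ptsd"):
        if term not in fit.coefficients.index:
            raise ModerationError(f"fit lacks the {term!r} term")
    if fit.cov is None or fit.cov.empty:
        raise ModerationError("fit lacks a coefficient covariance matrix")
    contrast = pd.Series(0.0, index=fit.coefficients.index)
    contrast["months"] = 1.0
    if group == "ptsd":
        contrast["months_x_ptsd"] = 1.0
    est = float(contrast @ fit.coefficients)
    var = float(contrast @ fit.cov @ contrast)
    se = np.sqrt(var)
    tcrit = stats.t.ppf(0.975, fit.df_resid)
    tval = est / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(tval), fit.df_resid)
    return est, (est - tcrit * se, est + tcrit * se), float(p)


def moderation_report(fits: list[ModerationFit],
                      adjust: bool = True) -> pd.DataFrame:
    """Long-format coefficient table, one block per hub.

    Interaction p-values are BH-adjusted across hubs when ``adjust`` is
    set; footer columns carry observations and R-squared.
    """
    rows = []
    for fit in fits:
        for term in fit.coefficients.index:
            rows.append(
                {
                    "roi": fit.roi,
                    "term": term,
                    "estimate": fit.coefficients[term],
                    "ci_lower": fit.ci95.loc[term, "lower"],
                    "ci_upper": fit.ci95.loc[term, "upper"],
                    "p": fit.p[term],
                    "n_obs": fit.n_obs,
                    "r2": fit.r2,
                }
            )
    table = pd.DataFrame(rows)
    if adjust and len(fits) > 0:
        mask = table["term"] == "months_x_ptsd"
        table.loc[mask, "p_adjusted"] = adjust_pvalues_bh(
            table.loc[mask, "p"].to_numpy()
        )
    return table
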