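"""Starch yield computation and spatial normalization of plot records.

Starch yield (SY) is tuber fresh weight times starch content. Within each
trial x treatment stratum, SY is corrected for the categorical design
factors block (B), row (R) and ridge (D) by an additive least-squares
model; the correction subtracts the fitted spatial component and restores
the stratum median, so values keep their absolute magnitude. Both linear
and log10 scales are supported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

log = logging.getLogger(__name__)

SPATIAL_FACTORS = ("block", "row", "ridge")
LOG_EPS = 1.0  # g, guard for the log10 scale


class NormalizationError(ValueError):
    pass


def starch_yield(fw_g, starch_content):
    """SY (g/plant) = tuber fresh weight x starch content."""
    fw = np.asarray(fw_g, dtype=float)
    content = np.asarray(starch_content, dtype=float)
    if np.any(fw < 0):
        raise NormalizationError("fresh weight must be non-negative")
    if np.any((content <= 0) | (content >= 1)):
        raise NormalizationError("starch content must be in (0, 1)")
    out = fw * content
    return out if out.ndim else float(out)


def _active_factors(df: pd.DataFrame) -> list[str]:
    return [f for f in SPATIAL_FACTORS
            if f in df.columns and df[f].nunique() >= 2]


def _normalize_stratum(values: np.ndarray, df: pd.DataFrame,
                       factors: list[str]) -> np.ndarray:
    """Subtract the fitted spatial component and restore the median
    exactly (the correction is a pure shift of the residuals)."""
    work = df[factors].copy()
    work["_y"] = values
    formula = "_y ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=work).fit()
    resid = values - fit.fittedvalues.to_numpy()
    return resid - np.median(resid) + np.median(values)


def normalize_spatial(records: pd.DataFrame, scale: str = "linear",
                      eps: float = LOG_EPS) -> pd.DataFrame:
    """Spatially normalized starch yield per trial x treatment stratum.

    Adds ``sy`` and ``sy_norm`` columns. Strata without any spatial
    factor at two or more levels pass through unchanged; a singular fit
    also falls back to pass-through with a warning. On the log scale the
    model is fitted to log10(SY + eps) and back-transformed.
    """
    if scale not in ("linear", "log"):
        raise NormalizationError("scale must be 'linear' or 'log'")
    df = records.copy()
    if "sy" not in df.columns:
        df["sy"] = starch_yield(df["fw_g"], df["starch_content"])
    df["sy_norm"] = df["sy"].astype(float)

    for (trial, treatment), idx in df.groupby(
            ["trial_id", "treatment"], sort=False).groups.items():
        sub = df.loc[idx]
        factors = _active_factors(sub)
        if not factors:
            continue
        y = sub["sy"].to_numpy(dtype=float)
        try:
            if scale == "log":
                z = np.log10(y + eps)
                z_norm = _normalize_stratum(z, sub, factors)
                y_norm = np.power(10.0, z_norm) - eps
                # restore the median on the linear scale too (the median
                # commutes with log only for odd record counts)
                y_norm = y_norm - np.median(y_norm) + np.median(y)
            else:
                y_norm = _normalize_stratum(y, sub, factors)
        except Exception as exc:  # singular/confounded design
            log.warning("normalize_spatial: pass-through for %s/%s (%s)",
                        trial, treatment, exc)
            continue
        df.loc[idx, "sy_norm"] = y_norm
    return df


def check_normalization(normalized: pd.DataFrame,
                        factors=SPATIAL_FACTORS,
                        alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA of ``sy_norm`` against each spatial factor, per
    trial x treatment stratum; flags any factor still significant."""
    rows = []
    for (trial, treatment), sub in normalized.groupby(
            ["trial_id", "treatment"], sort=False):
        for factor in factors:
            if factor not in sub.columns or sub[factor].nunique() < 2:
                continue
            groups = [grp["sy_norm"].to_numpy()
                      for _, grp in sub.groupby(factor)]
            if np.ptp(sub["sy_norm"].to_numpy()) == 0:
                f_stat, p = 0.0, 1.0
            else:
                f_stat, p = stats.f_oneway(*groups)
                f_stat, p = float(f_stat), float(p)
            rows.append({"trial_id": trial, "treatment": treatment,
                         "factor": factor, "F": f_stat, "p": p,
                         "significant": p < alpha})
    return pd.DataFrame(rows)


def rank_transform_bbch(bbch: pd.Series) -> pd.Series:
    """Within-trial rank transform of BBCH scores; rank 1 = smallest
    score, ties receive average ranks."""
    values = np.asarray(bbch, dtype=float)
    if values.size == 0:
        raise NormalizationError("rank_transform_bbch: empty input")
    ranks = stats.rankdata(values, method="average")
    return pd.Series(ranks, index=bbch.index if hasattr(bbch, "index") else None)
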