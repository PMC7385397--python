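"""Marker-based prediction of the drought tolerance index.

Metabolite intensities are normalized per sample to the mean intensity of
all annotated analytes and log10-transformed; transcript Ct values are
turned into 2^-dCt relative expression against the mean of the reference
genes. Missing cells are imputed by NIPALS PCA. An L1-penalized linear
model of genotype DRYM on marker levels is fitted with 10-fold
genotype-grouped cross-validation, the penalty chosen by the
"lambda_min + 1SE" rule for a sparse predictor set. Predictions are
averaged per genotype and ranked; metabolite and transcript rankings are
averaged into a combined score (lower = more tolerant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path

from .synthetic import MarkerMatrix

log = logging.getLogger(__name__)


class MarkerError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization

def normalize_metabolites(raw: MarkerMatrix) -> MarkerMatrix:
    """log10(intensity / per-sample mean intensity of present analytes).

    Missing cells stay missing; samples with no observed analyte are
    dropped with a log entry. The transform is invariant to per-sample
    scaling of the raw intensities.
    """
    values = raw.values.astype(float)
    if (values <= 0).any().any():
        raise MarkerError("metabolite intensities must be positive where present")
    sample_mean = values.mean(axis=1, skipna=True)
    empty = sample_mean.isna()
    if empty.any():
        log.info("normalize_metabolites: dropping %d all-missing samples",
                 int(empty.sum()))
        values = values.loc[~empty]
        sample_mean = sample_mean.loc[~empty]
    out = np.log10(values.div(sample_mean, axis=0))
    return MarkerMatrix(out, raw.meta.loc[out.index].copy(), "metabolite")


def transcript_expression(ct: MarkerMatrix,
                          reference_genes: Sequence[str]) -> MarkerMatrix:
    """2^-dCt expression after correction for the reference genes.

    dCt of a target gene is its Ct minus the per-sample mean Ct of the
    observed reference genes; values are shift-invariant per sample.
    Reference columns are removed from the output; samples with no
    observed reference gene are dropped with a log entry.
    """
    reference_genes = [g for g in reference_genes if g in ct.values.columns]
    if not reference_genes:
        raise MarkerError("no reference gene columns present")
    ref_mean = ct.values[reference_genes].mean(axis=1, skipna=True)
    no_ref = ref_mean.isna()
    if no_ref.any():
        log.info("transcript_expression: dropping %d samples without "
                 "reference observations", int(no_ref.sum()))
    targets = ct.values.drop(columns=reference_genes).loc[~no_ref]
    dct = targets.sub(ref_mean.loc[~no_ref], axis=0)
    return MarkerMatrix(np.power(2.0, -dct), ct.meta.loc[dct.index].copy(),
                        "transcript")


# ---------------------------------------------------------------------------
# NIPALS imputation

def impute_nipals(matrix: MarkerMatrix, n_components: int = 5,
                  tol: float = 1e-6, max_iter: int = 1000,
                  max_feature_missing: float = 0.5) -> MarkerMatrix:
    """Impute missing cells from a rank-``n_components`` NIPALS PCA model.

    NIPALS extracts components iteratively, skipping missing cells in
    every inner product, so the scores/loadings are estimated from the
    observed data alone. The rank-``n_components`` reconstruction is then
    refined by replacing the missing cells with their reconstruction and
    repeating the extraction until the imputed values stabilize, so exact
    low-rank structure is recovered exactly. Observed entries are
    returned untouched. A component that fails to converge within
    ``max_iter`` triggers a warning and the last iterate is used.
    """
    X = matrix.values.to_numpy(dtype=float)
    miss = np.isnan(X)
    if not miss.any():
        return matrix
    feat_missing = miss.mean(axis=0)
    if (feat_missing >= max_feature_missing).any():
        bad = matrix.values.columns[feat_missing >= max_feature_missing]
        raise MarkerError(
            f"features with >= {max_feature_missing:.0%} missing: {list(bad)}")
    n, p = X.shape
    n_components = min(n_components, n - 1, p)

    # pass 1: masked NIPALS on the observed cells only
    recon = _nipals_reconstruction(np.where(miss, np.nan, X), ~miss,
                                   n_components, tol, max_iter)
    out = X.copy()
    out[miss] = recon[miss]
    # refinement: re-extract on the completed matrix, re-impute, iterate
    all_obs = np.ones_like(miss)
    outer_tol = tol * 1e-3  # refinement converges linearly; stop well below
    for _ in range(100):
        recon = _nipals_reconstruction(out, all_obs, n_components, tol,
                                       max_iter)
        new = recon[miss]
        delta = np.max(np.abs(new - out[miss]))
        out[miss] = new
        if delta <= outer_tol * max(1.0, np.max(np.abs(out))):
            break
    return MarkerMatrix(
        pd.DataFrame(out, index=matrix.values.index,
                     columns=matrix.values.columns),
        matrix.meta.copy(), matrix.kind)


def _nipals_reconstruction(X: np.ndarray, obs: np.ndarray, n_components: int,
                           tol: float, max_iter: int) -> np.ndarray:
    """Rank-``n_components`` NIPALS model of X, skipping cells where
    ``obs`` is False; returns the reconstruction mean + sum(t p')."""
    n = X.shape[0]
    mu = np.nanmean(np.where(obs, X, np.nan), axis=0)
    R = np.where(obs, X - mu, 0.0)
    W = obs.astype(float)
    recon = np.tile(mu, (n, 1))
    for _ in range(n_components):
        col_var = (R ** 2).sum(axis=0)
        t = R[:, int(np.argmax(col_var))].copy()
        if not np.any(t):
            break
        p_vec = np.zeros(X.shape[1])
        for _it in range(max_iter):
            denom_p = W.T @ (t * t)
            p_vec = (R.T @ t) / np.where(denom_p > 0, denom_p, 1.0)
            norm = np.linalg.norm(p_vec)
            if norm == 0:
                break
            p_vec /= norm
            denom_t = W @ (p_vec * p_vec)
            t_new = (R @ p_vec) / np.where(denom_t > 0, denom_t, 1.0)
            delta = np.linalg.norm(t_new - t)
            t = t_new
            if delta <= tol * max(np.linalg.norm(t), 1.0):
                break
        else:
            warnings.warn("NIPALS component did not converge; using last "
                          "iterate", RuntimeWarning, stacklevel=2)
        recon += np.outer(t, p_vec)
        R = np.where(obs, R - np.outer(t, p_vec), 0.0)
    return recon


# ---------------------------------------------------------------------------
# LASSO with cross-validation and the 1SE rule

@dataclass
class LassoModel:
    """L1-penalized linear model of DRYM on marker levels."""

    intercept: float
    coef: pd.Series                 # per feature, original scale
    lambda_grid: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    seed: int | None = None
    kind: str = "marker"
    x_mean: pd.Series | None = None
    x_scale: pd.Series | None = None
    nonzero_path: np.ndarray | None = field(default=None, repr=False)

    @property
    def chosen_lambda(self) -> float:
        return self.lambda_1se

    @property
    def n_nonzero(self) -> int:
        return int((self.coef != 0).sum())

    def to_dict(self) -> dict:
        nz = self.coef[self.coef != 0]
        return {
            "kind": self.kind,
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in nz.items()},
            "lambda_min": float(self.lambda_min),
            "lambda_1se": float(self.lambda_1se),
            "n_nonzero": self.n_nonzero,
            "cv_curve": {
                "lambda": [float(v) for v in self.lambda_grid],
                "mean_mse": [float(v) for v in self.cv_mean],
                "se_mse": [float(v) for v in self.cv_se],
            },
            "seed": self.seed,
        }


#: dual-gap tolerance of the coordinate-descent solves (scaled by ||y||^2)
LASSO_TOL = 1e-10


def l1_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Coordinate-descent LASSO solutions along a descending lambda grid.

    Minimizes 1/(2n)||y - Xw||^2 + lambda ||w||_1 for each lambda
    (features assumed centered/standardized and y centered by the
    caller). Returns the (p, n_lambda) coefficient array. Coefficients
    with magnitude below 1e-12 are clipped to exactly zero: at the top
    of the grid w = 0 sits on the stationarity boundary and the solver
    can leave O(1e-16) residue.
    """
    _, coefs, _ = lasso_path(X, y, alphas=lambdas, tol=LASSO_TOL,
                             max_iter=100_000)
    coefs[np.abs(coefs) < 1e-12] = 0.0
    return coefs


def _grouped_folds(groups: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold index per sample with all samples of a group in one fold."""
    uniq = np.unique(groups)
    perm = rng.permutation(len(uniq))
    fold_of_group = {uniq[g]: i % n_folds for i, g in enumerate(perm)}
    return np.array([fold_of_group[g] for g in groups])


def _standardize(X: np.ndarray):
    xm = X.mean(axis=0)
    xs = X.std(axis=0)
    xs_safe = np.where(xs > 0, xs, 1.0)
    return (X - xm) / xs_safe, xm, xs


def fit_lasso_cv(matrix: MarkerMatrix, y: Mapping[str, float],
                 n_folds: int = 10, seed: int = 0, n_lambda: int = 100,
                 lambda_min_ratio: float = 1e-4) -> LassoModel:
    """Cross-validated LASSO of DRYM on marker levels, 1SE-rule penalty.

    ``y`` maps genotype ids to their DRYM; the genotype value is
    broadcast to every sample of that genotype. Folds are grouped by
    genotype so no genotype leaks across the train/validation split.
    Features are centered and scaled inside each fit; coefficients are
    returned on the original feature scale with an unpenalized
    intercept. The per-lambda objective is
    ``1/(2n) ||y - b0 - Xw||^2 + lambda ||w||_1``.
    """
    if matrix.values.isna().any().any():
        raise MarkerError("fit_lasso_cv requires a complete matrix; impute first")
    genotypes = matrix.meta["genotype_id"].to_numpy()
    have_y = np.array([g in y for g in genotypes])
    if not have_y.all():
        log.info("fit_lasso_cv: dropping %d samples without a DRYM value",
                 int((~have_y).sum()))
    X_df = matrix.values.loc[have_y]
    groups = genotypes[have_y]
    y_vec = np.array([y[g] for g in groups], dtype=float)
    n, p = X_df.shape
    if n < n_folds:
        raise MarkerError(f"need >= {n_folds} samples for {n_folds}-fold CV")
    X = X_df.to_numpy(dtype=float)
    features = X_df.columns

    if np.ptp(y_vec) == 0:
        warnings.warn("constant response; returning intercept-only model",
                      RuntimeWarning, stacklevel=2)
        return _intercept_only(float(y_vec.mean()), features, matrix.kind, seed)

    Xs, xm, xs = _standardize(X)
    lam_max = float(np.max(np.abs(Xs.T @ (y_vec - y_vec.mean())) / n))
    if lam_max == 0:
        warnings.warn("all features constant; returning intercept-only model",
                      RuntimeWarning, stacklevel=2)
        return _intercept_only(float(y_vec.mean()), features, matrix.kind, seed)
    lambdas = np.logspace(np.log10(lam_max),
                          np.log10(lam_max * lambda_min_ratio), n_lambda)

    rng = np.random.default_rng(seed)
    folds = _grouped_folds(groups, n_folds, rng)
    mse = np.full((n_folds, n_lambda), np.nan)
    for k in range(n_folds):
        tr, va = folds != k, folds == k
        Xtr, xm_k, xs_k = _standardize(X[tr])
        ytr = y_vec[tr]
        coefs = l1_path(Xtr, ytr - ytr.mean(), lambdas)
        xs_k_safe = np.where(xs_k > 0, xs_k, 1.0)
        Xva = (X[va] - xm_k) / xs_k_safe
        pred = ytr.mean() + Xva @ coefs
        mse[k] = ((pred - y_vec[va][:, None]) ** 2).mean(axis=0)
    cv_mean = mse.mean(axis=0)
    cv_se = mse.std(axis=0, ddof=1) / np.sqrt(n_folds)

    i_min = int(np.argmin(cv_mean))
    lam_min = float(lambdas[i_min])
    threshold = cv_mean[i_min] + cv_se[i_min]
    i_1se = int(np.flatnonzero(cv_mean <= threshold)[0])  # largest lambda
    lam_1se = float(lambdas[i_1se])

    coefs_full = l1_path(Xs, y_vec - y_vec.mean(), lambdas)
    w_std = coefs_full[:, i_1se]
    xs_safe = np.where(xs > 0, xs, 1.0)
    w = w_std / xs_safe
    w[xs == 0] = 0.0
    intercept = float(y_vec.mean() - xm @ w)
    return LassoModel(
        intercept=intercept,
        coef=pd.Series(w, index=features),
        lambda_grid=lambdas, cv_mean=cv_mean, cv_se=cv_se,
        lambda_min=lam_min, lambda_1se=lam_1se, seed=seed, kind=matrix.kind,
        x_mean=pd.Series(xm, index=features),
        x_scale=pd.Series(xs, index=features),
        nonzero_path=(np.abs(coefs_full) > 0).sum(axis=0),
    )


def _intercept_only(mean_y, features, kind, seed):
    return LassoModel(
        intercept=float(mean_y),
        coef=pd.Series(np.zeros(len(features)), index=features),
        lambda_grid=np.array([np.inf]), cv_mean=np.array([np.nan]),
        cv_se=np.array([np.nan]), lambda_min=np.inf, lambda_1se=np.inf,
        seed=seed, kind=kind)


# ---------------------------------------------------------------------------
# prediction and rank combination

def predict_drym(model: LassoModel, matrix: MarkerMatrix) -> pd.DataFrame:
    """Per-sample and per-genotype predicted DRYM with tolerance ranks.

    The genotype prediction is the mean over all its samples (both
    treatments, all trials); rank 1 is the most tolerant genotype.
    Unknown extra feature columns are ignored with a warning; features
    the model needs but the matrix lacks raise an error.
    """
    missing = [f for f in model.coef.index if f not in matrix.values.columns]
    if missing:
        raise MarkerError(f"matrix lacks model features: {missing[:5]}"
                          + ("..." if len(missing) > 5 else ""))
    extra = [f for f in matrix.values.columns if f not in model.coef.index]
    if extra:
        warnings.warn(f"ignoring {len(extra)} feature columns unseen by the "
                      "model", RuntimeWarning, stacklevel=2)
    X = matrix.values[model.coef.index]
    if X.isna().any().any():
        raise MarkerError("prediction requires a complete matrix; impute first")
    sample_pred = model.intercept + X.to_numpy(dtype=float) @ model.coef.to_numpy()
    per_sample = pd.DataFrame({
        "sample_id": matrix.values.index,
        "genotype_id": matrix.meta["genotype_id"].to_numpy(),
        "predicted_drym": sample_pred,
    })
    per_geno = (per_sample.groupby("genotype_id", as_index=False)
                ["predicted_drym"].mean())
    per_geno["rank"] = stats.rankdata(-per_geno["predicted_drym"],
                                      method="average")
    per_geno["model"] = model.kind
    return per_geno.sort_values("rank", ignore_index=True)


def combine_rankings(pred_metab: pd.DataFrame,
                     pred_transcript: pd.DataFrame) -> pd.DataFrame:
    """Average the two models' rank positions into a combined score
    (lower = more tolerant); genotype sets are intersected if needed."""
    a = pred_metab.set_index("genotype_id")
    b = pred_transcript.set_index("genotype_id")
    common = a.index.intersection(b.index)
    if common.empty:
        raise MarkerError("no genotypes shared between the two predictions")
    if len(common) < max(len(a), len(b)):
        log.info("combine_rankings: using %d shared genotypes "
                 "(of %d / %d)", len(common), len(a), len(b))
    out = pd.DataFrame({
        "genotype_id": common,
        "rank_metabolite": a.loc[common, "rank"].to_numpy(),
        "rank_transcript": b.loc[common, "rank"].to_numpy(),
        "mean_predicted_drym": 0.5 * (
            a.loc[common, "predicted_drym"].to_numpy()
            + b.loc[common, "predicted_drym"].to_numpy()),
    })
    out["combined_score"] = 0.5 * (out["rank_metabolite"]
                                   + out["rank_transcript"])
    return out.sort_values("combined_score", ignore_index=True)
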