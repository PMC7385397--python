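"""Statistical comparison of the selected subpopulations.

Overlap enrichment between selections (hypergeometric upper tail),
cross-test-system Pearson correlations of tolerance and yield, analysis
of covariance of DRYMp on population with cumulative VPD as covariate,
counting of lines superior to the parent cultivars, and truth-based
recovery metrics for synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

log = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class OverlapStats:
    """Hypergeometric overlap enrichment of two selections from a pool."""

    N: int          # pool size
    K: int          # size of set 1
    n: int          # size of set 2
    x: int          # observed overlap
    expected: float  # n*K/N
    fold: float      # x / expected
    p: float         # upper-tail P(X >= x)

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_enrichment(N: int, K: int, n: int, x: int) -> OverlapStats:
    """Fold enrichment and upper-tail hypergeometric probability of an
    observed overlap ``x`` between a set of ``K`` and a set of ``n``
    lines drawn from a pool of ``N``.

    The tail P(X >= x) includes x itself, so x = 0 gives p = 1; the
    survival function is evaluated in log space by scipy.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise EvaluationError("need K, n <= N and all counts non-negative")
    if not 0 <= x <= min(K, n):
        raise EvaluationError("overlap x must be in [0, min(K, n)]")
    expected = n * K / N if N else 0.0
    fold = x / expected if expected > 0 else 0.0
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    return OverlapStats(N=N, K=K, n=n, x=x, expected=expected,
                        fold=fold, p=min(p, 1.0))


def correlate_systems(values: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between per-system genotype means.

    ``values`` is a wide table (index genotype, one column per variable,
    e.g. ``drymp_pot``, ``sy_field``). Each pair uses its complete
    observations; returns (r, p, n) matrices. Constant variables yield
    missing correlations.
    """
    cols = list(values.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            if a == b:
                complete = values[a].dropna()
                n.loc[a, a] = len(complete)
                if len(complete) >= 3 and complete.nunique() >= 2:
                    r.loc[a, a], p.loc[a, a] = 1.0, 0.0
                continue
            pair = values[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < 3:
                continue
            if pair[a].nunique() < 2 or pair[b].nunique() < 2:
                log.info("correlate_systems: %s or %s constant; r undefined",
                         a, b)
                continue
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p, n


def ancova_drymp(records: pd.DataFrame, model_id: int = 1,
                 parent_label: str = "parent") -> pd.DataFrame:
    """ANCOVA of replicate DRYMp on population with cumulative VPD.

    Fits ``drymp ~ population + cum_vpd`` by least squares with
    sequential (Type I) sums of squares, population entered first.
    Model 1 keeps all population levels (parents included); model 2
    drops the parent records. With a single population level the
    population term is dropped and a covariate-only model is fitted.
    """
    df = records.copy()
    if model_id == 2:
        df = df[df["population"] != parent_label]
    elif model_id != 1:
        raise EvaluationError("model_id must be 1 or 2")
    if df.empty:
        raise EvaluationError("no records for the ANCOVA")
    if df["cum_vpd"].nunique() < 2:
        raise EvaluationError("covariate cum_vpd does not vary")
    n_pop = df["population"].nunique()
    if n_pop < 2:
        fit = smf.ols("drymp ~ cum_vpd", data=df).fit()
    else:
        fit = smf.ols("drymp ~ C(population) + cum_vpd", data=df).fit()
        rank_needed = n_pop + 1  # intercept + (n_pop-1) dummies + slope
        if np.linalg.matrix_rank(fit.model.exog) < rank_needed:
            raise EvaluationError(
                "rank-deficient design: population dummies and cum_vpd "
                "are aliased")
    table = anova_lm(fit, typ=1)
    table = table.rename(index={"C(population)": "population"})
    return table


def count_superior(line_values: pd.DataFrame, parent_replicates: pd.DataFrame,
                   mode: str = "percentile90") -> pd.DataFrame:
    """Count lines whose DRYMp exceeds a parent-based reference.

    ``line_values`` holds genotype-level DRYMp with columns genotype_id,
    population, system, drymp; ``parent_replicates`` holds parent
    replicate DRYMp with columns system, drymp. Reference modes:
    ``percentile90`` (90th percentile of parent replicate DRYMp) or
    ``ci95`` (parent mean + 1.96 * SE). Strictly 'above' counts.
    """
    if mode not in ("percentile90", "ci95"):
        raise EvaluationError("mode must be 'percentile90' or 'ci95'")
    rows = []
    for system, parents in parent_replicates.groupby("system"):
        vals = parents["drymp"].to_numpy(dtype=float)
        if mode == "percentile90":
            ref = float(np.percentile(vals, 90))
        else:
            if len(vals) < 3:
                log.warning("count_superior: < 3 parent replicates in %s; "
                            "CI mode unavailable", system)
                continue
            ref = float(vals.mean() + 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)))
        sub = line_values[line_values["system"] == system]
        for population, grp in sub.groupby("population"):
            rows.append({"system": system, "population": population,
                         "reference": ref, "mode": mode,
                         "n_superior": int((grp["drymp"] > ref).sum()),
                         "n_lines": len(grp)})
    return pd.DataFrame(rows)


def truth_metrics(memberships: Mapping[str, Iterable[str]],
                  truth_tolerance: pd.Series,
                  scores: Optional[Mapping[str, pd.Series]] = None,
                  top_fraction: float = 0.25) -> dict:
    """Recovery metrics against the generator's latent tolerance.

    For each subpopulation: the fraction of members in the top
    ``top_fraction`` tolerance quantile of the candidate pool (bottom
    quantile for MPs, which selects for sensitivity) and its fold over
    the random expectation. ``scores`` optionally maps subpopulation
    names to per-genotype selection scores for Spearman correlations
    with the true tolerance (sign-aligned so tolerance-directed scores
    correlate positively).
    """
    if truth_tolerance.empty:
        raise EvaluationError("truth tolerance is empty")
    tau = truth_tolerance.dropna()
    hi_cut = tau.quantile(1.0 - top_fraction)
    lo_cut = tau.quantile(top_fraction)
    out = {}
    for name, members in memberships.items():
        members = [g for g in members if g in tau.index]
        if not members:
            out[name] = {"precision": np.nan, "fold": np.nan, "n": 0}
            continue
        sel = tau.loc[members]
        if name.lower() == "mps":
            hit = (sel <= lo_cut).mean()
        else:
            hit = (sel >= hi_cut).mean()
        out[name] = {"precision": float(hit),
                     "fold": float(hit / top_fraction),
                     "n": len(members)}
    if scores:
        for name, score in scores.items():
            common = score.index.intersection(tau.index)
            if len(common) >= 3 and score.loc[common].nunique() > 1:
                rho = stats.spearmanr(score.loc[common], tau.loc[common])[0]
                out.setdefault(name, {})["spearman_vs_truth"] = float(rho)
    return out
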