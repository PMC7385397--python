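"""Eligibility filtering and subpopulation selection.

Two selection routes: phenotypic selection of the PPt subpopulation from
per-trial DRYM ranks (best-40 in at least two trials, outlier-robust),
and marker-based selection of the MPt (most tolerant) and MPs (most
sensitive) subpopulations from the combined predicted-DRYM ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indices import drym_table, genotype_relative_starch_yield, \
    replicate_relative_starch_yield

log = logging.getLogger(__name__)

MIN_TUBER_NUMBER = 5
OUTLIER_SD_MULTIPLIER = 3.0


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    """Subpopulation memberships and per-genotype selection bookkeeping."""

    ppt: list[str]
    mpt: list[str]
    mps: list[str]
    table: pd.DataFrame  # genotype_id, ppt/mpt/mps flags, scores, reasons
    shortlist: list[str] = field(default_factory=list)

    def __post_init__(self):
        if set(self.mpt) & set(self.mps):
            raise SelectionError("MPt and MPs overlap")


def filter_eligibility(plots: pd.DataFrame,
                       scoring_trials: Sequence[str],
                       delayed_emergence: Optional[Iterable[str]] = None,
                       min_tubers: int = MIN_TUBER_NUMBER) -> pd.DataFrame:
    """Eligible genotypes with exclusion reasons.

    A genotype is excluded when its mean control tuber number falls below
    ``min_tubers`` in any scoring trial (strict '<'), when it has no
    control records, or when it is flagged for delayed emergence.
    """
    delayed = set(delayed_emergence) if delayed_emergence is not None else set()
    rows = []
    control = plots[plots["treatment"] == "control"]
    control = control[control["trial_id"].isin(scoring_trials)]
    means = control.groupby(["genotype_id", "trial_id"])["tuber_number"].mean()
    for gid in plots["genotype_id"].unique():
        reason = "none"
        if gid in delayed:
            reason = "delayed emergence"
        elif gid not in means.index.get_level_values(0):
            reason = "no control records"
        elif (means.loc[gid] < min_tubers).any():
            reason = "low tuber production"
        rows.append({"genotype_id": gid, "eligible": reason == "none",
                     "exclusion_reason": reason})
    return pd.DataFrame(rows)


def flag_yield_outliers(norm: pd.DataFrame,
                        m: float = OUTLIER_SD_MULTIPLIER) -> pd.Series:
    """Flag records with sy_norm strictly outside mean +/- m*sd of their
    trial x treatment stratum (single pass, no recomputation).

    Strata with fewer than 3 records get no flags (warning logged).
    """
    flags = pd.Series(False, index=norm.index)
    for (trial, treatment), idx in norm.groupby(
            ["trial_id", "treatment"]).groups.items():
        vals = norm.loc[idx, "sy_norm"].to_numpy(dtype=float)
        if len(vals) < 3:
            log.warning("flag_yield_outliers: stratum %s/%s too small; "
                        "no flags", trial, treatment)
            continue
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            continue
        flags.loc[idx] = (vals < mu - m * sd) | (vals > mu + m * sd)
    return flags


def _trial_drym_ranks(norm: pd.DataFrame,
                      genotypes: set[str]) -> pd.DataFrame:
    """Per-trial DRYM and descending rank (1 = most tolerant) over the
    given genotypes; average ranks for ties."""
    sub = norm[norm["genotype_id"].isin(genotypes)]
    reps = replicate_relative_starch_yield(sub)
    if reps.empty:
        return pd.DataFrame(columns=["genotype_id", "trial_id", "drym", "rank"])
    table = drym_table(genotype_relative_starch_yield(reps))
    table["rank"] = np.nan
    for trial, idx in table.groupby("trial_id").groups.items():
        table.loc[idx, "rank"] = stats.rankdata(
            -table.loc[idx, "drym"].to_numpy(), method="average")
    return table[["genotype_id", "trial_id", "drym", "rank"]]


def phenotypic_select(norm: pd.DataFrame, eligible: Iterable[str],
                      shortlist_depth: int = 40, min_trials: int = 2,
                      k: int = 20,
                      outlier_flags: Optional[pd.Series] = None
                      ) -> tuple[list[str], pd.DataFrame]:
    """Phenotypic selection of the PPt subpopulation.

    Eligible genotypes are ranked by DRYM within each trial (the trials
    present in ``norm``; trials failing the stress-index criterion must
    be excluded upstream). Genotypes ranking within ``shortlist_depth``
    in at least ``min_trials`` trials are shortlisted. Genotypes whose
    qualification depends on records flagged as yield outliers are
    removed: ranks are recomputed with flagged records dropped and the
    shortlist rule re-applied. The final PPt is the top ``k`` of the
    surviving shortlist ordered by mean outlier-cleaned rank across its
    qualifying trials.
    """
    eligible = set(eligible)
    if outlier_flags is None:
        outlier_flags = flag_yield_outliers(norm)
    trials = norm["trial_id"].unique()
    if len(trials) < min_trials:
        raise SelectionError(
            f"phenotypic selection needs >= {min_trials} scoring trials")

    ranks0 = _trial_drym_ranks(norm, eligible)
    cleaned = _trial_drym_ranks(norm[~outlier_flags.to_numpy()], eligible)

    def qualifies(ranks: pd.DataFrame) -> pd.Series:
        ok = ranks[ranks["rank"] <= shortlist_depth]
        return ok.groupby("genotype_id").size() >= min_trials

    q0 = qualifies(ranks0)
    shortlist = sorted(q0[q0].index)
    qc = qualifies(cleaned)
    survivors = [g for g in shortlist if qc.get(g, False)]
    removed = sorted(set(shortlist) - set(survivors))
    if removed:
        log.info("phenotypic_select: removed %s (qualification depended on "
                 "outlier records)", removed)

    clean_q = cleaned[(cleaned["rank"] <= shortlist_depth)
                      & cleaned["genotype_id"].isin(survivors)]
    mean_rank = clean_q.groupby("genotype_id")["rank"].mean().sort_values()
    order = sorted(survivors, key=lambda g: (mean_rank.get(g, np.inf), g))
    if len(order) < k:
        log.warning("phenotypic_select: shortlist (%d) smaller than k=%d",
                    len(order), k)
    ppt = order[:k]

    detail = ranks0.pivot(index="genotype_id", columns="trial_id",
                          values="rank")
    detail.columns = [f"rank_{c}" for c in detail.columns]
    detail = detail.reset_index()
    detail["shortlisted"] = detail["genotype_id"].isin(shortlist)
    detail["outlier_removed"] = detail["genotype_id"].isin(removed)
    detail["ppt"] = detail["genotype_id"].isin(ppt)
    detail["mean_rank"] = detail["genotype_id"].map(mean_rank)
    return ppt, detail


def marker_select(combined: pd.DataFrame, k_tolerant: int = 24,
                  k_sensitive: int = 22,
                  exclude: Optional[Iterable[str]] = None
                  ) -> tuple[list[str], list[str]]:
    """Top/bottom of the combined predicted ranking.

    MPt takes the ``k_tolerant`` best (lowest combined score), MPs the
    ``k_sensitive`` worst. Ties are broken by mean predicted DRYM and
    then by genotype id, so the result is deterministic.
    """
    df = combined.copy()
    if exclude:
        df = df[~df["genotype_id"].isin(set(exclude))]
    if k_tolerant + k_sensitive > len(df):
        raise SelectionError(
            f"k_tolerant + k_sensitive = {k_tolerant + k_sensitive} exceeds "
            f"population size {len(df)}")
    order = df.sort_values(
        ["combined_score", "mean_predicted_drym", "genotype_id"],
        ascending=[True, False, True])["genotype_id"].tolist()
    mpt = order[:k_tolerant]
    mps = order[-k_sensitive:][::-1]  # most sensitive first; disjoint from MPt
    return mpt, mps


def venn_summary(ppt: Iterable[str], mpt: Iterable[str],
                 mps: Iterable[str]) -> dict:
    """Membership counts and pairwise overlaps of the three
    subpopulations (the selection Venn diagram)."""
    ppt, mpt, mps = set(ppt), set(mpt), set(mps)
    return {
        "ppt_total": len(ppt),
        "mpt_total": len(mpt),
        "mps_total": len(mps),
        "ppt_only": len(ppt - mpt - mps),
        "ppt_and_mpt": len(ppt & mpt),
        "ppt_and_mps": len(ppt & mps),
        "mpt_and_mps": len(mpt & mps),
        "all_selected": len(ppt | mpt | mps),
    }


def build_selection_result(ppt, mpt, mps, eligibility: pd.DataFrame,
                           combined: Optional[pd.DataFrame] = None,
                           ppt_detail: Optional[pd.DataFrame] = None
                           ) -> SelectionResult:
    """Assemble the per-genotype selection table."""
    table = eligibility.copy()
    table["ppt"] = table["genotype_id"].isin(set(ppt))
    table["mpt"] = table["genotype_id"].isin(set(mpt))
    table["mps"] = table["genotype_id"].isin(set(mps))
    if combined is not None:
        table = table.merge(
            combined[["genotype_id", "combined_score", "mean_predicted_drym"]],
            on="genotype_id", how="left")
    if ppt_detail is not None:
        keep = [c for c in ppt_detail.columns
                if c.startswith("rank_") or c in ("genotype_id", "shortlisted",
                                                  "outlier_removed", "mean_rank")]
        table = table.merge(ppt_detail[keep], on="genotype_id", how="left")
    return SelectionResult(list(ppt), list(mpt), list(mps), table)
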