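"""Drought tolerance indices DRYM and DRYMp from normalized starch yields.

relSY is a genotype's starch yield under stress relative to its own
control yield in the same trial. DRYM is the deviation of relSY from the
trial-wide median over genotypes; DRYMp instead subtracts the median
relSY of the three parent (check) cultivars, which keeps the reference
stable when the population composition changes during selection.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .microclimate import stress_index

log = logging.getLogger(__name__)

DEFAULT_SI_THRESHOLD = 0.1


class ToleranceError(ValueError):
    pass


def replicate_relative_starch_yield(norm: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate relSY: each stress replicate's sy_norm divided by the
    genotype's mean control sy_norm in the trial.

    Genotypes missing a treatment arm, or with non-positive control mean,
    are skipped with a log entry.
    """
    rows = []
    for (trial, gid), sub in norm.groupby(["trial_id", "genotype_id"],
                                          sort=False):
        control = sub.loc[sub["treatment"] == "control", "sy_norm"]
        stress = sub.loc[sub["treatment"] == "stress"]
        if control.empty or stress.empty:
            log.info("relSY: %s in %s lacks a treatment arm; skipped", gid, trial)
            continue
        cm = float(control.mean())
        if cm <= 0:
            log.info("relSY: %s in %s has non-positive control mean; excluded",
                     gid, trial)
            continue
        for _, rec in stress.iterrows():
            rows.append({"genotype_id": gid, "trial_id": trial,
                         "replicate": rec.get("replicate", np.nan),
                         "rel_sy": float(rec["sy_norm"]) / cm,
                         "n_control_reps": len(control),
                         "n_stress_reps": len(stress)})
    return pd.DataFrame(rows, columns=["genotype_id", "trial_id", "replicate",
                                       "rel_sy", "n_control_reps",
                                       "n_stress_reps"])


def genotype_relative_starch_yield(replicates: pd.DataFrame) -> pd.DataFrame:
    """Genotype-level relSY: mean over a genotype's replicate values."""
    return (replicates.groupby(["trial_id", "genotype_id"], as_index=False)
            .agg(rel_sy=("rel_sy", "mean"),
                 n_control_reps=("n_control_reps", "first"),
                 n_stress_reps=("n_stress_reps", "first")))


def relative_starch_yield(norm: pd.DataFrame,
                          level: str = "genotype") -> pd.DataFrame:
    """relSY at replicate or genotype level from normalized plot records."""
    reps = replicate_relative_starch_yield(norm)
    if level == "replicate":
        return reps
    if level == "genotype":
        return genotype_relative_starch_yield(reps)
    raise ToleranceError("level must be 'replicate' or 'genotype'")


def drym(trial_rel_sy: pd.Series) -> pd.Series:
    """DRYM per genotype: relSY minus the median over genotypes in the
    trial. Requires at least two genotypes."""
    if len(trial_rel_sy) < 2:
        raise ToleranceError("drym needs >= 2 genotypes per trial")
    return trial_rel_sy - float(np.median(trial_rel_sy.to_numpy()))


def drym_table(genotype_rel_sy: pd.DataFrame) -> pd.DataFrame:
    """DRYM for every trial in a genotype-level relSY table."""
    out = genotype_rel_sy.copy()
    out["drym"] = np.nan
    for trial, idx in out.groupby("trial_id").groups.items():
        sub = out.loc[idx]
        out.loc[idx, "drym"] = drym(
            sub.set_index("genotype_id")["rel_sy"]).to_numpy()
    return out


def drym_p(replicates: pd.DataFrame, parent_ids: Sequence[str]) -> pd.DataFrame:
    """DRYMp per replicate: relSY minus the median genotype-level relSY of
    the parent cultivars in the trial.

    The parent median is taken over the parents' genotype-level relSY
    (one value per cultivar), not over parent replicates. Every parent
    must be present in every trial; a missing parent raises an error
    naming it.
    """
    parent_ids = list(parent_ids)
    geno = genotype_relative_starch_yield(replicates)
    out = replicates.copy()
    out["drym_p"] = np.nan
    for trial, idx in out.groupby("trial_id").groups.items():
        trial_geno = geno[geno["trial_id"] == trial].set_index("genotype_id")
        missing = [p for p in parent_ids if p not in trial_geno.index]
        if missing:
            raise ToleranceError(
                f"parent cultivar(s) {missing} have no relSY in trial {trial}")
        parent_median = float(np.median(
            trial_geno.loc[parent_ids, "rel_sy"].to_numpy()))
        out.loc[idx, "drym_p"] = out.loc[idx, "rel_sy"] - parent_median
    return out


def normalize_to_parent_control(sy_norm: Iterable[float],
                                parent_control_sy: Iterable[float]) -> np.ndarray:
    """Starch yields divided by the median parent control yield of the
    trial (unitless scale for cross-trial comparison)."""
    parent = np.asarray(list(parent_control_sy), dtype=float)
    if parent.size == 0:
        raise ToleranceError("no parent control records")
    med = float(np.median(parent))
    if med == 0:
        raise ToleranceError("parent control median is zero")
    return np.asarray(list(sy_norm), dtype=float) / med


def trial_stress_indices(norm: pd.DataFrame) -> pd.Series:
    """Per-trial stress index from normalized yields (all genotypes)."""
    out = {}
    for trial, sub in norm.groupby("trial_id"):
        control = sub.loc[sub["treatment"] == "control", "sy_norm"]
        stress = sub.loc[sub["treatment"] == "stress", "sy_norm"]
        if control.empty or stress.empty:
            continue
        out[trial] = stress_index(control, stress)
    return pd.Series(out, name="stress_index")


def tolerance_table(norm: pd.DataFrame, parent_ids: Sequence[str],
                    si_threshold: float = DEFAULT_SI_THRESHOLD
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Genotype x trial tolerance records (relSY, DRYM, DRYMp).

    Trials whose stress index falls below ``si_threshold`` are excluded
    from tolerance computation (yield not materially affected by the
    treatment); the excluded trial ids are returned alongside.
    """
    si = trial_stress_indices(norm)
    excluded = [t for t, v in si.items() if v < si_threshold]
    if excluded:
        log.info("tolerance_table: excluding trials %s (SI < %.2f)",
                 excluded, si_threshold)
    kept = norm[~norm["trial_id"].isin(excluded)]
    reps = replicate_relative_starch_yield(kept)
    if reps.empty:
        return (pd.DataFrame(columns=["genotype_id", "trial_id", "rel_sy",
                                      "drym", "drym_p", "n_control_reps",
                                      "n_stress_reps"]), excluded)
    reps_p = drym_p(reps, parent_ids)
    geno = drym_table(genotype_relative_starch_yield(reps))
    geno_p = (reps_p.groupby(["trial_id", "genotype_id"], as_index=False)
              .agg(drym_p=("drym_p", "mean")))
    table = geno.merge(geno_p, on=["trial_id", "genotype_id"], how="left")
    cols = ["genotype_id", "trial_id", "rel_sy", "drym", "drym_p",
            "n_control_reps", "n_stress_reps"]
    return table[cols], excluded
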