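"""End-to-end pipeline: simulate -> climate -> normalize -> tolerance ->
predict -> select -> evaluate, with reproducible outputs and a manifest.

Each stage writes plain CSV/JSON artifacts into the output directory; the
run manifest records the configuration snapshot, seeds and a SHA-256
digest per output file so a rerun with the same seed can be verified
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, indices, markers, normalization, selection
from .config import SimConfig
from .microclimate import clean_series, cumulative_curves, daily_summaries
from .indices import DEFAULT_SI_THRESHOLD
from .synthetic import (build_sample_metadata, simulate_climate,
                        simulate_markers, simulate_population, simulate_trial)

log = logging.getLogger(__name__)

K_PPT_DEFAULT = 20
K_MPT_DEFAULT = 24
K_MPS_DEFAULT = 22
SHORTLIST_DEPTH_DEFAULT = 40
MIN_TRIALS_DEFAULT = 2
CV_FOLDS_DEFAULT = 10


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, index=False, float_format="%.10g", **kwargs)


def run_pipeline(config: SimConfig, out_dir, seed: int | None = None,
                 k_ppt: int = K_PPT_DEFAULT, k_mpt: int = K_MPT_DEFAULT,
                 k_mps: int = K_MPS_DEFAULT,
                 shortlist_depth: int = SHORTLIST_DEPTH_DEFAULT,
                 min_trials: int = MIN_TRIALS_DEFAULT,
                 si_threshold: float = DEFAULT_SI_THRESHOLD,
                 cv_folds: int = CV_FOLDS_DEFAULT,
                 scale: str = "log") -> dict:
    """Run every stage on synthetic data and write all artifacts.

    ``seed`` overrides ``config.seed``. Returns a result dictionary with
    the in-memory tables and the evaluation summary; all artifacts are
    also written to ``out_dir``.
    """
    config.validate()
    if seed is not None:
        config.seed = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) % (2 ** 31) for s in ss.generate_state(2 + 2 * len(config.trial_specs))]

    # --- simulate population ------------------------------------------------
    truth = simulate_population(config, seed=seeds[0])
    _write_csv(truth.genotypes, out / "truth.csv")
    _write_csv(pd.concat([truth.metab_features.assign(marker="metabolite"),
                          truth.transcript_features.assign(marker="transcript")]),
               out / "truth_features.csv")

    # --- climate ------------------------------------------------------------
    env_rows = []
    plots = []
    for i, spec in enumerate(config.trial_specs):
        series = simulate_climate(spec, seed=seeds[2 + 2 * i])
        _write_csv(series, out / f"climate_{spec.trial_id}.csv")
        curves = cumulative_curves(daily_summaries(clean_series(series)))
        env_rows.append({"trial_id": spec.trial_id, "system": spec.system,
                         "thermal_sum": float(curves["cum_thermal_sum"].iloc[-1]),
                         "cum_vpd": float(curves["cum_vpd"].iloc[-1])})
        plots.append(simulate_trial(truth, spec, seed=seeds[3 + 2 * i],
                                    noise_cv_yield=config.noise_cv_yield))
    plots = pd.concat(plots, ignore_index=True)
    _write_csv(plots, out / "plots.csv")

    # --- normalize ----------------------------------------------------------
    norm = normalization.normalize_spatial(plots, scale=scale)
    norm["outlier"] = selection.flag_yield_outliers(norm)
    _write_csv(norm, out / "normalized.csv")

    # --- tolerance ----------------------------------------------------------
    parents = config.parent_ids()
    tol, excluded_trials = indices.tolerance_table(
        norm, parents, si_threshold=si_threshold)
    _write_csv(tol, out / "tolerance.csv")
    si = indices.trial_stress_indices(norm)
    env = pd.DataFrame(env_rows)
    env["stress_index"] = env["trial_id"].map(si)
    env["scoring"] = ~env["trial_id"].isin(excluded_trials)
    _write_csv(env, out / "env_summary.csv")

    # --- markers and prediction --------------------------------------------
    meta = build_sample_metadata(truth, config)
    raw_metab, raw_ct = simulate_markers(truth, meta, config, seed=seeds[1])
    raw_metab.values.to_csv(out / "metabolites.csv", float_format="%.8g")
    raw_ct.values.to_csv(out / "transcripts.csv", float_format="%.8g")
    meta.to_csv(out / "sample_meta.csv")

    metab = markers.impute_nipals(markers.normalize_metabolites(raw_metab))
    ref_genes = truth.transcript_features.loc[
        truth.transcript_features["is_reference"], "feature_id"].tolist()
    transcript = markers.impute_nipals(
        markers.transcript_expression(raw_ct, ref_genes))

    y = (tol.groupby("genotype_id")["drym"].mean()).to_dict()
    model_metab = markers.fit_lasso_cv(metab, y, n_folds=cv_folds,
                                       seed=seeds[0] + 17)
    model_tr = markers.fit_lasso_cv(transcript, y, n_folds=cv_folds,
                                    seed=seeds[0] + 18)
    (out / "model_metabolite.json").write_text(
        json.dumps(model_metab.to_dict(), indent=1))
    (out / "model_transcript.json").write_text(
        json.dumps(model_tr.to_dict(), indent=1))
    pred_metab = markers.predict_drym(model_metab, metab)
    pred_tr = markers.predict_drym(model_tr, transcript)
    combined = markers.combine_rankings(pred_metab, pred_tr)
    _write_csv(combined, out / "predictions.csv")

    # --- selection ----------------------------------------------------------
    scoring_trials = [t for t in plots["trial_id"].unique()
                      if t not in excluded_trials]
    delayed = truth.genotypes.loc[truth.genotypes["emergence_delayed"],
                                  "genotype_id"]
    elig = selection.filter_eligibility(plots, scoring_trials,
                                        delayed_emergence=delayed)
    # parents are checks, not selection candidates
    elig.loc[elig["genotype_id"].isin(parents), "eligible"] = False
    elig.loc[elig["genotype_id"].isin(parents),
             "exclusion_reason"] = "parent cultivar"
    eligible = set(elig.loc[elig["eligible"], "genotype_id"])

    scoring_norm = norm[norm["trial_id"].isin(scoring_trials)]
    ppt, ppt_detail = selection.phenotypic_select(
        scoring_norm, eligible, shortlist_depth=shortlist_depth,
        min_trials=min_trials, k=k_ppt,
        outlier_flags=scoring_norm["outlier"])
    combined_elig = combined[combined["genotype_id"].isin(eligible)]
    mpt, mps = selection.marker_select(combined_elig, k_tolerant=k_mpt,
                                       k_sensitive=k_mps)
    result = selection.build_selection_result(ppt, mpt, mps, elig,
                                              combined, ppt_detail)
    _write_csv(result.table, out / "selection.csv")
    venn = selection.venn_summary(ppt, mpt, mps)
    (out / "venn.json").write_text(json.dumps(venn, indent=1))

    # --- evaluation ---------------------------------------------------------
    overlap = evaluation.overlap_enrichment(
        N=len(eligible), K=len(ppt), n=len(mpt),
        x=len(set(ppt) & set(mpt)))

    pop = pd.Series("G2_rest", index=truth.genotypes["genotype_id"])
    pop.loc[pop.index.isin(parents)] = "parent"
    pop.loc[pop.index.isin(mps)] = "MPs"
    pop.loc[pop.index.isin(mpt)] = "MPt"
    pop.loc[pop.index.isin(ppt)] = "PPt"

    system_of = plots.drop_duplicates("trial_id").set_index("trial_id")["system"]
    tol2 = tol.assign(system=tol["trial_id"].map(system_of),
                      population=tol["genotype_id"].map(pop).to_numpy())
    cum_vpd_of = env.set_index("trial_id")["cum_vpd"]
    anc_records = tol2.rename(columns={"drym_p": "drymp"})[
        ["genotype_id", "trial_id", "population", "drymp"]]
    anc_records["cum_vpd"] = anc_records["trial_id"].map(cum_vpd_of)
    ancova = {}
    for model_id in (1, 2):
        try:
            tab = evaluation.ancova_drymp(anc_records, model_id=model_id)
            ancova[f"model_{model_id}"] = {
                term: {"F": _nan_to_none(row["F"]),
                       "p": _nan_to_none(row["PR(>F)"]),
                       "df": float(row["df"])}
                for term, row in tab.iterrows()}
        except evaluation.EvaluationError as exc:
            ancova[f"model_{model_id}"] = {"error": str(exc)}

    sys_means = (tol2.groupby(["genotype_id", "system"])
                 .agg(drymp=("drym_p", "mean")).reset_index())
    control_sy = (norm[(norm["treatment"] == "control")
                       & norm["trial_id"].isin(scoring_trials)]
                  .groupby(["genotype_id", "system"])["sy_norm"]
                  .mean().rename("sy").reset_index())
    wide = sys_means.merge(control_sy, on=["genotype_id", "system"], how="outer")
    wide = wide.pivot(index="genotype_id", columns="system",
                      values=["drymp", "sy"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    r, p, n_mat = evaluation.correlate_systems(wide)

    parent_reps_tab = indices.drym_p(
        indices.replicate_relative_starch_yield(scoring_norm), parents)
    parent_reps_tab["system"] = parent_reps_tab["trial_id"].map(system_of)
    parent_reps = parent_reps_tab[
        parent_reps_tab["genotype_id"].isin(parents)][["system", "drym_p"]]
    parent_reps = parent_reps.rename(columns={"drym_p": "drymp"})
    line_vals = sys_means.assign(
        population=sys_means["genotype_id"].map(pop).to_numpy())
    line_vals = line_vals[line_vals["population"] != "parent"]
    superior = {
        mode: evaluation.count_superior(line_vals, parent_reps, mode=mode)
        .to_dict(orient="records")
        for mode in ("percentile90", "ci95")
    }

    tau_lines = truth.tolerance().loc[list(eligible)]
    tmetrics = evaluation.truth_metrics(
        {"ppt": ppt, "mpt": mpt, "mps": mps}, tau_lines,
        scores={"mpt": -combined_elig.set_index("genotype_id")["combined_score"]})

    eval_out = {
        "overlap": overlap.to_dict(),
        "venn": venn,
        "excluded_trials": excluded_trials,
        "stress_indices": {k: float(v) for k, v in si.items()},
        "ancova": ancova,
        "correlations": {"r": _frame_dict(r), "p": _frame_dict(p),
                         "n": _frame_dict(n_mat)},
        "count_superior": superior,
        "truth_metrics": tmetrics,
    }
    (out / "evaluation.json").write_text(json.dumps(eval_out, indent=1))

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "created": datetime.now(timezone.utc).isoformat(),
        "outputs": {f.name: _sha256(f)
                    for f in sorted(out.iterdir())
                    if f.suffix in (".csv", ".json")
                    and f.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {
        "truth": truth, "plots": plots, "normalized": norm, "tolerance": tol,
        "env_summary": env, "combined": combined, "selection": result,
        "evaluation": eval_out, "manifest": manifest,
        "models": {"metabolite": model_metab, "transcript": model_tr},
    }


def _nan_to_none(v):
    v = float(v)
    return None if np.isnan(v) else v


def _frame_dict(df: pd.DataFrame) -> dict:
    return {str(c): {str(i): _nan_to_none(v) for i, v in df[c].items()}
            for c in df.columns}
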