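"""Synthetic segregating population, trials, weather and marker data.

The generator produces data with the statistical structure the selection
analysis assumes: a latent drought tolerance per genotype (on the DRYM
scale) drawn about the mid-parent value of its cross, a yield potential
correlated with tolerance, plot-level starch yields whose stress/control
ratio equals clamp(1 - severity + tolerance, 0, 1) in expectation,
multiplicative spatial (block/row/ridge) effects, weather series that
reproduce target thermal sums and cumulative VPDs, and marker matrices
with a sparse linear tolerance signal and missing cells.

Every function takes explicit seeds; re-running with the same seed
reproduces every table bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig, TrialSpec
from .microclimate import vpd

SYSTEM_SCALE = {"pot": 0.25, "big-bag": 0.85, "field": 1.0}

#: Relative severity of the intermediate ("reduced" irrigation) treatment.
REDUCED_SEVERITY_FACTOR = 0.6


@dataclass
class SimTruth:
    """Ground truth exported by the generator for recovery checks."""

    genotypes: pd.DataFrame       # genotype_id, cross, is_parent, tolerance,
                                  # yield_potential, emergence_delayed
    metab_features: pd.DataFrame  # feature_id, beta, informative
    transcript_features: pd.DataFrame  # + is_reference

    def tolerance(self) -> pd.Series:
        return self.genotypes.set_index("genotype_id")["tolerance"]

    def line_ids(self) -> list[str]:
        g = self.genotypes
        return list(g.loc[~g["is_parent"], "genotype_id"])


@dataclass
class MarkerMatrix:
    """Samples x features values with metadata; NaN cells are missing."""

    values: pd.DataFrame  # index: sample_id, columns: feature ids
    meta: pd.DataFrame    # index: sample_id; genotype_id, trial_id, treatment
    kind: str             # "metabolite" | "transcript"

    def __post_init__(self):
        if not self.values.index.equals(self.meta.index):
            raise ValueError("MarkerMatrix: values and meta sample ids differ")
        for col in ("genotype_id", "trial_id", "treatment"):
            if self.meta[col].isna().any():
                raise ValueError(f"MarkerMatrix: incomplete metadata ({col})")

    @property
    def mask(self) -> pd.DataFrame:
        """True where the value is missing."""
        return self.values.isna()

    def missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean())


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_population(config: SimConfig, seed=None) -> SimTruth:
    """Draw the segregating population and the marker-effect truth.

    Offspring tolerance is Normal(mid-parent, tolerance_sd); yield
    potential is drawn jointly with tolerance at correlation
    ``rho_tol_yield``. Parents carry their configured tolerances exactly.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed)

    rows = []
    for p_id, tol in config.parent_tolerances.items():
        y0 = max(config.yield_potential_mean
                 + config.yield_potential_sd * rng.standard_normal(), 1.0)
        rows.append({"genotype_id": p_id, "cross": "parent", "is_parent": True,
                     "tolerance": float(tol), "yield_potential": float(y0),
                     "emergence_delayed": False})

    rho = config.rho_tol_yield
    for mother, father in config.crosses:
        cross = f"{mother}x{father}"
        prefix = mother[0] + father[0]
        mid = 0.5 * (config.parent_tolerances[mother]
                     + config.parent_tolerances[father])
        z1 = rng.standard_normal(config.n_lines_per_cross)
        z2 = rng.standard_normal(config.n_lines_per_cross)
        tau = mid + config.tolerance_sd * z1
        y0 = (config.yield_potential_mean
              + config.yield_potential_sd
              * (rho * z1 + np.sqrt(1.0 - rho ** 2) * z2))
        y0 = np.maximum(y0, 1.0)
        delayed = rng.random(config.n_lines_per_cross) < config.delayed_emergence_rate
        for i in range(config.n_lines_per_cross):
            rows.append({
                "genotype_id": f"{prefix}{i + 1:03d}", "cross": cross,
                "is_parent": False, "tolerance": float(tau[i]),
                "yield_potential": float(y0[i]),
                "emergence_delayed": bool(delayed[i]),
            })
    genotypes = pd.DataFrame(rows)

    metab = _draw_features(rng, "M", config.n_metab_features,
                           config.n_informative_metab, config.effect_size_sd)
    metab["is_reference"] = False
    transcript = _draw_features(rng, "T", config.n_transcript_features,
                                config.n_informative_transcript,
                                config.effect_size_sd)
    transcript["is_reference"] = False
    refs = pd.DataFrame({
        "feature_id": [f"REF{i + 1}" for i in range(config.n_reference_genes)],
        "beta": 0.0, "informative": False, "is_reference": True,
    })
    transcript = pd.concat([transcript, refs], ignore_index=True)
    return SimTruth(genotypes, metab, transcript)


def _draw_features(rng, prefix, n, n_informative, effect_size_sd):
    """Sparse effect vector: exactly n_informative nonzero coefficients.

    Magnitudes are uniform in [0.3, 1.5] x effect_size_sd with random
    signs, keeping every informative effect bounded away from zero.
    """
    beta = np.zeros(n)
    idx = rng.choice(n, size=n_informative, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_informative)
    beta[idx] = signs * effect_size_sd * rng.uniform(0.3, 1.5, size=n_informative)
    return pd.DataFrame({
        "feature_id": [f"{prefix}{i + 1:03d}" for i in range(n)],
        "beta": beta,
        "informative": beta != 0.0,
    })


def simulate_climate(spec: TrialSpec, seed) -> pd.DataFrame:
    """Hourly weather series reproducing the trial's environment targets.

    A sinusoidal diurnal temperature cycle (peak at 14:00) is scaled so
    the accumulated thermal sum matches ``target_thermal_sum``; relative
    humidity is set so the median midday VPD accumulates to
    ``target_cum_vpd``. Small Gaussian jitter keeps the series
    realistic; recomputed summaries stay within 5% (thermal sum) and 10%
    (cumulative VPD) of the targets.
    """
    spec.validate()
    rng = _rng(seed)
    n_days = spec.n_days or max(60, int(round(spec.target_thermal_sum / 18.0)))
    amp = 4.0
    t_mean = 6.0 + spec.target_thermal_sum / n_days
    if t_mean + amp > 30.0:
        raise ConfigError(
            "target_thermal_sum: infeasible without exceeding the 30 degC cap; "
            "increase n_days")

    hours = pd.date_range(spec.start_date, periods=n_days * 24, freq="h")
    hod = hours.hour.to_numpy()
    temp = (t_mean + amp * np.cos(2 * np.pi * (hod - 14) / 24.0)
            + rng.normal(0.0, 0.2, size=len(hours)))

    # RH chosen so the deterministic midday VPD equals the daily target.
    daily_target = spec.target_cum_vpd / n_days
    mid_hours = np.arange(10, 14)
    mid_temp = t_mean + amp * np.cos(2 * np.pi * (mid_hours - 14) / 24.0)
    mid_vpsat = 0.61365 * np.exp(17.502 * mid_temp / (240.97 + mid_temp))
    ratio = daily_target / float(np.median(mid_vpsat))
    if ratio >= 0.98:
        raise ConfigError(
            "target_cum_vpd: infeasible with the implied temperatures "
            "(would require RH < 2%)")
    rh = np.clip(100.0 * (1.0 - ratio) + rng.normal(0.0, 0.7, size=len(hours)),
                 2.0, 100.0)
    return pd.DataFrame({"timestamp": hours, "temp_C": temp, "rh_pct": rh})


def simulate_trial(truth: SimTruth, spec: TrialSpec, seed,
                   noise_cv_yield: float = 0.12) -> pd.DataFrame:
    """Plot-level phenotypes of one trial for every genotype in ``truth``.

    Control starch yield per replicate is yield potential x test-system
    scale x multiplicative block/row/ridge effects x lognormal noise;
    the stress expectation is the control expectation times
    clamp(1 - severity + tolerance, 0, 1). Fresh weight is derived from
    starch yield and a starch content drawn in (0.10, 0.25).
    """
    spec.validate()
    rng = _rng(seed)
    g = truth.genotypes
    scale = SYSTEM_SCALE[spec.system]

    eff = {}
    for factor, n_levels in (("block", spec.n_blocks), ("row", spec.n_rows),
                             ("ridge", spec.n_ridges)):
        eff[factor] = np.exp(rng.normal(0.0, spec.spatial_effect_sd, n_levels))

    sigma = np.sqrt(np.log1p(noise_cv_yield ** 2))
    # genotype-level nuisance effects, drawn per trial
    content_g = rng.uniform(0.13, 0.22, size=len(g))
    dev_g = rng.normal(0.0, 3.0, size=len(g))
    tuber_rate = np.maximum(
        12.0 * g["yield_potential"].to_numpy() / g["yield_potential"].mean(), 0.05)

    rows = []
    for treatment in spec.treatments():
        sev = {"control": 0.0, "reduced": REDUCED_SEVERITY_FACTOR
               * spec.stress_severity, "stress": spec.stress_severity}[treatment]
        for rep in range(spec.n_replicates):
            block = rep % spec.n_blocks
            order = rng.permutation(len(g))
            for pos, gi in enumerate(order):
                row = pos % spec.n_rows
                ridge = (pos // spec.n_rows) % spec.n_ridges
                tau = g["tolerance"].iat[gi]
                expect = (g["yield_potential"].iat[gi] * scale
                          * eff["block"][block] * eff["row"][row]
                          * eff["ridge"][ridge])
                if treatment != "control":
                    expect *= float(np.clip(1.0 - sev + tau, 0.0, 1.0))
                if sigma > 0:
                    sy = expect * np.exp(rng.normal(-sigma ** 2 / 2.0, sigma))
                else:
                    sy = expect
                content = float(np.clip(
                    content_g[gi] + rng.normal(0.0, 0.01), 0.105, 0.245))
                lam = tuber_rate[gi] * (1.0 - 0.3 * sev)
                rows.append({
                    "genotype_id": g["genotype_id"].iat[gi],
                    "trial_id": spec.trial_id,
                    "system": spec.system,
                    "treatment": treatment,
                    "replicate": rep + 1,
                    "block": f"B{block + 1}",
                    "row": f"R{row + 1}",
                    "ridge": f"D{ridge + 1}",
                    "fw_g": sy / content,
                    "starch_content": content,
                    "tuber_number": int(rng.poisson(lam)),
                    "bbch": int(np.clip(round(55 + dev_g[gi]
                                              + rng.normal(0.0, 2.0)), 31, 75)),
                    "shoot_height_cm": float(max(
                        10.0,
                        55.0 + 30.0 * (g["yield_potential"].iat[gi]
                                       / g["yield_potential"].mean() - 1.0)
                        + dev_g[gi] + rng.normal(0.0, 4.0))),
                })
    return pd.DataFrame(rows)


def build_sample_metadata(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """One pooled marker sample per genotype x marker trial x treatment."""
    known = {t.trial_id for t in config.trial_specs}
    rows = []
    for tid in config.marker_trial_ids:
        if tid not in known:
            raise ConfigError(f"marker_trial_ids: unknown trial {tid!r}")
        for treatment in ("control", "stress"):
            for gid in truth.genotypes["genotype_id"]:
                rows.append({
                    "sample_id": f"{tid}_{treatment}_{gid}",
                    "genotype_id": gid,
                    "trial_id": tid,
                    "treatment": treatment,
                })
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_markers(truth: SimTruth, samples: pd.DataFrame,
                     config: SimConfig, seed=None
                     ) -> tuple[MarkerMatrix, MarkerMatrix]:
    """Measurement-level marker matrices for the given samples.

    Metabolites are raw GC-MS-like intensities: the latent value
    alpha_j + beta_j*tau + gamma_j*1[stress] + trial effect + noise lives
    on the log10 scale and is multiplied by a per-sample loading, so the
    downstream per-sample normalization has real work to do. Transcripts
    are qRT-PCR Ct values for the 43 target genes plus the reference
    genes; the tolerance signal sits in the target genes' delta-Ct.
    Missing cells are masked completely at random at the configured
    rates.
    """
    config.validate()
    rng = _rng(config.seed + 1 if seed is None else seed)
    tau = truth.tolerance().reindex(samples["genotype_id"]).to_numpy()
    is_stress = (samples["treatment"] == "stress").to_numpy(dtype=float)
    trials = samples["trial_id"].to_numpy()
    trial_levels = pd.unique(trials)
    n = len(samples)

    def latent(features: pd.DataFrame) -> np.ndarray:
        p = len(features)
        alpha = rng.normal(0.0, 0.5, p)
        gamma = rng.normal(0.0, 0.3, p)
        trial_eff = {t: rng.normal(0.0, 0.1, p) for t in trial_levels}
        x = (alpha[None, :]
             + np.outer(tau, features["beta"].to_numpy())
             + np.outer(is_stress, gamma)
             + np.stack([trial_eff[t] for t in trials])
             + rng.normal(0.0, config.noise_sd_marker, (n, p)))
        return x

    # metabolites: raw intensities = loading * 10^latent
    x_met = latent(truth.metab_features)
    loading = np.exp(rng.normal(np.log(1e5), 0.5, n))
    raw_met = loading[:, None] * np.power(10.0, x_met)
    raw_met = _mask_mcar(raw_met, config.missing_rate_metab, rng)
    metab = MarkerMatrix(
        pd.DataFrame(raw_met, index=samples.index,
                     columns=truth.metab_features["feature_id"].tolist()),
        samples.copy(), "metabolite")

    # transcripts: Ct values; target Ct = reference level - latent signal
    targets = truth.transcript_features[~truth.transcript_features["is_reference"]]
    refs = truth.transcript_features[truth.transcript_features["is_reference"]]
    x_tr = latent(targets)
    ref_level = rng.normal(20.0, 1.0, n)
    base_ct = rng.uniform(1.0, 6.0, len(targets))
    ct_targets = ref_level[:, None] + base_ct[None, :] - x_tr
    ref_offsets = rng.uniform(-0.5, 0.5, len(refs))
    ct_refs = (ref_level[:, None] + ref_offsets[None, :]
               + rng.normal(0.0, 0.05, (n, len(refs))))
    ct = np.hstack([ct_targets, ct_refs])
    ct = _mask_mcar(ct, config.missing_rate_transcript, rng)
    transcript = MarkerMatrix(
        pd.DataFrame(ct, index=samples.index,
                     columns=targets["feature_id"].tolist()
                     + refs["feature_id"].tolist()),
        samples.copy(), "transcript")
    return metab, transcript


def _mask_mcar(x: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return x
    out = x.astype(float).copy()
    out[rng.random(x.shape) < rate] = np.nan
    return out
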