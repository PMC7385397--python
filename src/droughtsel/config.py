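"""Configuration objects for the simulation and selection pipeline.

The defaults encode the study conditions of the multi-environment potato
drought trials the pipeline analyses: a segregating population of ~200
tetraploid lines from two crosses between one tolerant (At) and two
sensitive (Es, Rs) parent cultivars, scored in pot, big-bag and field
trials under control and deficit irrigation, with leaf metabolite and
transcript markers sampled in two of the trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

SYSTEMS = ("pot", "big-bag", "field")
TREATMENTS = ("control", "reduced", "stress")

#: Default parent (check) cultivars with latent tolerances on the DRYM scale.
DEFAULT_PARENT_TOLERANCES = {"At": 0.05, "Es": -0.05, "Rs": -0.04}

#: The two crosses of the segregating population (mother x father).
DEFAULT_CROSSES = (("Es", "At"), ("At", "Rs"))


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class TrialSpec:
    """Design and environment targets of one trial.

    ``stress_severity`` is the expected relative starch-yield reduction of
    the stress treatment for a genotype of average tolerance;
    ``target_thermal_sum`` (degC days) and ``target_cum_vpd`` (kPa) are the
    end-of-trial environment summaries the synthetic weather generator
    reproduces.
    """

    trial_id: str
    system: str
    n_treatments: int = 2
    n_replicates: int = 3
    plants_per_replicate: int = 1
    stress_severity: float = 0.5
    target_thermal_sum: float = 1400.0
    target_cum_vpd: float = 150.0
    spatial_effect_sd: float = 0.05
    n_blocks: int = 2
    n_rows: int = 1
    n_ridges: int = 1
    start_date: str = "2014-04-15"
    n_days: int = 0  # 0 -> derived from target_thermal_sum

    def treatments(self) -> tuple[str, ...]:
        if self.n_treatments == 2:
            return ("control", "stress")
        return ("control", "reduced", "stress")

    def validate(self) -> None:
        if self.system not in SYSTEMS:
            raise ConfigError(f"system: {self.system!r} not one of {SYSTEMS}")
        if self.n_treatments not in (2, 3):
            raise ConfigError("n_treatments: must be 2 or 3")
        if not 1 <= self.n_replicates <= 5:
            raise ConfigError("n_replicates: must be in 1..5")
        if self.plants_per_replicate < 1:
            raise ConfigError("plants_per_replicate: must be positive")
        if not 0.0 <= self.stress_severity <= 1.0:
            raise ConfigError("stress_severity: must be in [0, 1]")
        if self.target_thermal_sum <= 0 or self.target_cum_vpd <= 0:
            raise ConfigError("target_thermal_sum/target_cum_vpd: must be positive")
        if self.spatial_effect_sd < 0:
            raise ConfigError("spatial_effect_sd: must be non-negative")
        for name in ("n_blocks", "n_rows", "n_ridges"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be positive")


def default_trial_specs() -> list[TrialSpec]:
    """Scoring-phase trials emulating the study's selection trials.

    One big-bag, one pot and one field trial with substantial stress, plus
    one field trial with negligible stress that the stress-index filter
    must exclude from tolerance scoring.
    """
    return [
        TrialSpec("B2", "big-bag", n_replicates=3, stress_severity=0.49,
                  target_thermal_sum=1306, target_cum_vpd=120.2,
                  n_blocks=2, n_rows=4, spatial_effect_sd=0.04),
        TrialSpec("P3", "pot", n_replicates=2, stress_severity=0.56,
                  target_thermal_sum=1459, target_cum_vpd=209.7,
                  n_blocks=2, spatial_effect_sd=0.03, start_date="2014-05-15"),
        TrialSpec("F2", "field", n_replicates=2, stress_severity=0.56,
                  target_thermal_sum=1165, target_cum_vpd=108.6,
                  n_blocks=2, n_rows=4, n_ridges=3, spatial_effect_sd=0.08,
                  start_date="2014-04-28"),
        TrialSpec("F1", "field", n_replicates=2, stress_severity=0.05,
                  target_thermal_sum=1605, target_cum_vpd=148.4,
                  n_blocks=2, n_rows=4, n_ridges=3, spatial_effect_sd=0.08,
                  start_date="2014-04-22"),
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic population, trials and marker data."""

    n_lines_per_cross: int = 100
    parent_tolerances: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARENT_TOLERANCES))
    crosses: Sequence[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_CROSSES))
    tolerance_sd: float = 0.05
    yield_potential_mean: float = 240.0  # g starch / plant, field scale
    yield_potential_sd: float = 60.0
    rho_tol_yield: float = -0.3
    trial_specs: list[TrialSpec] = field(default_factory=default_trial_specs)
    marker_trial_ids: Sequence[str] = ("B2", "P3")
    n_metab_features: int = 100
    n_informative_metab: int = 29
    n_transcript_features: int = 43  # target genes; 4 reference genes added
    n_reference_genes: int = 4
    n_informative_transcript: int = 23
    effect_size_sd: float = 2.0
    noise_sd_marker: float = 0.5
    missing_rate_metab: float = 0.055
    missing_rate_transcript: float = 0.022
    noise_cv_yield: float = 0.12
    delayed_emergence_rate: float = 0.02
    seed: int = 20140416

    def validate(self) -> None:
        if self.n_lines_per_cross < 1:
            raise ConfigError("n_lines_per_cross: must be positive")
        if not self.parent_tolerances:
            raise ConfigError("parent_tolerances: must name the parent cultivars")
        for mother, father in self.crosses:
            for p in (mother, father):
                if p not in self.parent_tolerances:
                    raise ConfigError(
                        f"crosses: parent {p!r} missing from parent_tolerances")
        for name in ("tolerance_sd", "yield_potential_sd", "effect_size_sd",
                     "noise_sd_marker", "noise_cv_yield"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be non-negative")
        if self.yield_potential_mean <= 0:
            raise ConfigError("yield_potential_mean: must be positive")
        if not -1.0 <= self.rho_tol_yield <= 1.0:
            raise ConfigError("rho_tol_yield: must be in [-1, 1]")
        for name in ("missing_rate_metab", "missing_rate_transcript",
                     "delayed_emergence_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1]")
        for n_name, k_name in (("n_metab_features", "n_informative_metab"),
                               ("n_transcript_features", "n_informative_transcript")):
            n, k = getattr(self, n_name), getattr(self, k_name)
            if n < 1 or k < 0:
                raise ConfigError(f"{n_name}/{k_name}: counts must be positive")
            if k > n:
                raise ConfigError(f"{k_name}: exceeds {n_name}")
        if not self.trial_specs:
            raise ConfigError("trial_specs: at least one trial required")
        trial_ids = [t.trial_id for t in self.trial_specs]
        if len(set(trial_ids)) != len(trial_ids):
            raise ConfigError("trial_specs: duplicate trial_id")
        for spec in self.trial_specs:
            spec.validate()
        for tid in self.marker_trial_ids:
            if tid not in trial_ids:
                raise ConfigError(f"marker_trial_ids: unknown trial {tid!r}")

    def parent_ids(self) -> list[str]:
        return list(self.parent_tolerances)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["parent_tolerances"] = dict(self.parent_tolerances)
        d["crosses"] = [list(c) for c in self.crosses]
        d["marker_trial_ids"] = list(self.marker_trial_ids)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "trial_specs" in d:
            d["trial_specs"] = [
                t if isinstance(t, TrialSpec) else TrialSpec(**t)
                for t in d["trial_specs"]
            ]
        if "crosses" in d:
            d["crosses"] = [tuple(c) for c in d["crosses"]]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(data)


def save_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
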