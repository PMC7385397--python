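import numpy as np
import pandas as pd
import pytest

from droughtsel.config import SimConfig, TrialSpec
from droughtsel.synthetic import MarkerMatrix, simulate_population


def small_config(**overrides) -> SimConfig:
    """Scaled-down study configuration for fast unit tests."""
    defaults = dict(
        n_lines_per_cross=15,
        n_metab_features=20,
        n_informative_metab=5,
        n_transcript_features=10,
        n_informative_transcript=4,
        trial_specs=[
            TrialSpec("B2", "big-bag", n_replicates=3, stress_severity=0.5,
                      target_thermal_sum=1306, target_cum_vpd=120.2,
                      n_blocks=2, n_rows=4, spatial_effect_sd=0.04),
            TrialSpec("P3", "pot", n_replicates=2, stress_severity=0.55,
                      target_thermal_sum=1459, target_cum_vpd=209.7,
                      n_blocks=2, spatial_effect_sd=0.03),
        ],
        marker_trial_ids=("B2", "P3"),
        seed=42,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def tiny_config():
    return small_config()


@pytest.fixture
def tiny_truth(tiny_config):
    return simulate_population(tiny_config)


def constant_climate(temp_c: float, rh_pct: float, n_days: int = 3,
                     start="2014-05-01", freq="h") -> pd.DataFrame:
    ts = pd.date_range(start, periods=n_days * 24, freq=freq)
    return pd.DataFrame({"timestamp": ts, "temp_C": temp_c, "rh_pct": rh_pct})


def marker_matrix_from_array(x: np.ndarray, kind: str = "metabolite",
                             genotypes=None) -> MarkerMatrix:
    n, p = x.shape
    idx = [f"s{i}" for i in range(n)]
    values = pd.DataFrame(x, index=idx, columns=[f"f{j}" for j in range(p)])
    meta = pd.DataFrame({
        "genotype_id": genotypes if genotypes is not None
        else [f"g{i}" for i in range(n)],
        "trial_id": "T1",
        "treatment": "control",
    }, index=idx)
    return MarkerMatrix(values, meta, kind)
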