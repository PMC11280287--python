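import numpy as np
import pytest

from ivpt import FranzCellConfig, ReceptorSeries, validate_config
from ivpt.simulate import reference_cell_config


@pytest.fixture
def cell_config() -> FranzCellConfig:
    """Reference Franz-cell configuration (5 mL / 300 µL / 0.64 sq·cm)."""
    return reference_cell_config()


@pytest.fixture
def unit_area_config() -> FranzCellConfig:
    """Cell with A = 1 sq·cm, where per-area and absolute conventions agree."""
    return validate_config(
        FranzCellConfig(
            receptor_volume=5.0,
            sample_volume=0.3,
            permeation_area=1.0,
            donor_concentration=1000.0,
            skin_thickness=0.031,
            clearance=118.0,
            donor_dose=100.0,
        )
    )


def series_from_profile(times, q, cfg, replicate_id="inv-1") -> ReceptorSeries:
    """Invert the sampling-replacement correction: build receptor
    concentrations whose corrected cumulative profile is exactly ``q``."""
    times = np.asarray(times, float)
    q = np.asarray(q, float)
    concs = np.zeros_like(q)
    for n in range(len(q)):
        withdrawn = cfg.sample_volume * concs[:n].sum()
        concs[n] = (cfg.permeation_area * q[n] - withdrawn) / cfg.receptor_volume
    if np.any(concs < 0):
        raise ValueError("profile not realizable with non-negative concentrations")
    return ReceptorSeries(replicate_id=replicate_id, times=times, concentrations=concs)
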