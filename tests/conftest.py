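import numpy as np
import pytest

from uscape import (
    DepthField,
    FeatureSpec,
    ScanSimConfig,
    compute_absorbance,
    render_depth_field,
    simulate_scan,
)

# Allura-Red-like defaults used throughout: blue extinction 0.00052 /mM/um.
EPS_B = 0.00052


@pytest.fixture
def noiseless_config():
    return ScanSimConfig(dpi=1200, i0=60000, noise_sd=0.0, seed=0)


@pytest.fixture
def cylinder_field():
    """One 500 um radius, 100 um deep cylindrical chamber at 1200 dpi."""
    feat = FeatureSpec("cylinder_chamber", center=(600, 600), radius=500,
                       depth=100)
    return render_depth_field([feat], (1200, 1200), 25400 / 1200)


@pytest.fixture
def basin_field():
    """Isotropic-etch basin well, mask radius 40 um, etch depth 10.9 um."""
    feat = FeatureSpec("basin_well", center=(60, 60), radius=40, depth=10.9)
    return render_depth_field([feat], (120, 120), 2.0)


def blank_field_like(fld: DepthField) -> DepthField:
    return DepthField(np.zeros_like(fld.depth), fld.pitch_um)


def absorbance_of(fld, config, channel="B", blank_seed_offset=1000):
    """Simulate sample + blank scans and return the absorbance map."""
    sample = simulate_scan(fld, config)
    blank_cfg = ScanSimConfig(
        dpi=config.dpi, i0=config.i0, noise_sd=config.noise_sd,
        eps_rgb=config.eps_rgb, concentration_mm=config.concentration_mm,
        seed=None if config.seed is None else config.seed + blank_seed_offset,
    )
    blank = simulate_scan(blank_field_like(fld), blank_cfg)
    return compute_absorbance(sample, blank, channel)
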