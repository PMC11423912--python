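"""Shared fixtures: presets and cached synthetic images."""

import numpy as np
import pytest

import cochleaquant as cq


def noise_free(preset):
    """Copy of a layout preset with all stochastic terms switched off."""
    p = cq.get_preset(preset) if isinstance(preset, str) else preset
    p.noise_sd_additive = 0.0
    p.texture_cv = 0.0
    p.channel_gain_cv = 0.0
    p.total_width_sd = 0.0
    p.is_fraction_sd = 0.0
    p.ls_fraction_sd = 0.0
    p.medial_fraction_sd = 0.0
    for band in p.medial_bands.values():
        band.extent_sd = 0.0
    return p


@pytest.fixture(scope="session")
def e14_noise_free_section():
    return cq.make_section(noise_free("e14_control"), 0)


@pytest.fixture(scope="session")
def e14_noisy_section():
    return cq.make_section(cq.get_preset("e14_control"), 0)


@pytest.fixture(scope="session")
def quiet_wholemount():
    """Small low-noise wholemount with a handful of planted doublets."""
    p = cq.get_preset("e18_nocre")
    p.length_mean = 1500.0
    p.length_sd = 0.0
    p.noise_sd = 0.01
    p.doublet_mean_by_region = {"base": 2.0, "mid": 3.0, "apex": 2.0}
    return cq.make_wholemount(p, 4)
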