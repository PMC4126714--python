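import dataclasses

import numpy as np
import pytest

from coloctop import ChannelImage, FieldOfView, SimParams, simulate_field


def make_params(**overrides) -> SimParams:
    """Desk-scale simulation defaults shared across the suite: small field,
    two cells, clean (no blur, no background, no noise) unless overridden."""
    base = dict(
        phenotype="dispersed_punctae",
        n_cells=2,
        image_shape=(160, 160),
        cell_radius=30,
        n_structures=12,
        true_overlap=0.6,
        green_loss=0.0,
        psf_sigma=0.0,
        background_level=0.0,
        photon_scale=0.0,
        read_noise_sd=0.0,
        bit_depth=16,
        seed=7,
    )
    base.update(overrides)
    return SimParams(**base)


def noisy_overrides(**extra):
    """The realistic imaging regime: PSF blur, shot + read noise, no
    background (Mander's sums are raw, so recovery assumes background-free
    images)."""
    d = dict(psf_sigma=1.2, background_level=0.0, photon_scale=4.0,
             read_noise_sd=2.0)
    d.update(extra)
    return d


@pytest.fixture
def clean_field():
    params = make_params()
    return simulate_field(params)


@pytest.fixture
def noisy_field():
    params = make_params(**noisy_overrides())
    return simulate_field(params)


def field_from_arrays(red, green, bit_depth=16, nuclei=None) -> FieldOfView:
    """Wrap raw integer arrays as a FieldOfView for direct metric tests."""
    red = np.asarray(red)
    green = np.asarray(green)
    nuc = ChannelImage(np.asarray(nuclei), bit_depth, "nuclei") if nuclei is not None else None
    return FieldOfView(
        red=ChannelImage(red, bit_depth, "red"),
        green=ChannelImage(green, bit_depth, "green"),
        nuclei=nuc,
    )
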