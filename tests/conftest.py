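"""Shared fixtures: small phantoms and random SUV volumes."""

from __future__ import annotations

import numpy as np
import pytest

from tmtvkit import (
    LesionSpec,
    PhantomSpec,
    SuvVolume,
    Voi,
    generate_phantom,
)

SPHERE_RADIUS_MM = 10.0
SPHERE_UPTAKE = 8.0
SPHERE_BACKGROUND = 0.5


def sphere_spec(psf_fwhm_mm: float = 0.0, noise_sd_suv: float = 0.0) -> PhantomSpec:
    """r=10 mm sphere, uptake 8 over background 0.5, on a 2 mm grid."""
    return PhantomSpec(
        grid_shape=(40, 40, 30),
        spacing_mm=(2.0, 2.0, 2.0),
        background_suv=SPHERE_BACKGROUND,
        lesions=(
            LesionSpec(
                center_mm=(39.0, 39.0, 29.0),
                radii_mm=(SPHERE_RADIUS_MM,) * 3,
                uptake_suv=SPHERE_UPTAKE,
            ),
        ),
        psf_fwhm_mm=psf_fwhm_mm,
        noise_sd_suv=noise_sd_suv,
        seed=7,
    )


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noiseless, unblurred sphere phantom with its ground-truth mask."""
    vol, masks, physio = generate_phantom(sphere_spec())
    return vol, masks[0], physio


@pytest.fixture(scope="session")
def blurred_sphere_phantom():
    vol, masks, physio = generate_phantom(sphere_spec(psf_fwhm_mm=6.0))
    return vol, masks[0], physio


def random_volume(rng: np.random.Generator, shape=(12, 12, 6)) -> SuvVolume:
    """A small random nonnegative SUV volume on a 2 mm grid."""
    values = rng.uniform(0.0, 10.0, size=shape)
    return SuvVolume(values=values, spacing_mm=(2.0, 2.0, 2.0))


def full_voi(vol: SuvVolume) -> Voi:
    return Voi(mask=np.ones(vol.shape, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
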