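"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from holorec import ExperimentConfig, OpticalConfig, run_recognition


def direct_fresnel_sum(field: np.ndarray, distance: float, wavelength: float,
                       dx: float, dy: float) -> np.ndarray:
    """Brute-force discrete Fresnel diffraction integral.

    Evaluates the spatial-domain Fresnel convolution kernel
    ``exp(j*2*pi*d/lam)/(j*lam*d) * exp(j*pi*((x-x')^2+(y-y')^2)/(lam*d))``
    pixel by pixel and sums over all source pixels.  Quadratic cost; only
    for small grids.  Independent of the FFT-based implementation.
    """
    ny, nx = field.shape
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    out = np.zeros((ny, nx), dtype=complex)
    pref = np.exp(1j * 2 * np.pi * distance / wavelength) / (
        1j * wavelength * distance
    ) * dx * dy
    ys, xs = np.nonzero(np.abs(field) > 0)
    for iy, ix in zip(ys, xs):
        chirp = np.exp(
            1j * np.pi
            * ((x[None, :] - x[ix]) ** 2 + (y[:, None] - y[iy]) ** 2)
            / (wavelength * distance)
        )
        out += field[iy, ix] * chirp
    return pref * out


@pytest.fixture(scope="session")
def critical_cfg() -> OpticalConfig:
    """64x64 grid at the critical pitch N*dx^2 = lambda*d, where the discrete
    Fresnel chirp kernel is exactly N-periodic and the transfer-function
    propagator coincides with the direct Fresnel sum."""
    import warnings

    n, lam, d = 64, 514.5e-9, 25e-6
    dx = float(np.sqrt(lam * d / n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # sub-wavelength critical pitch
        return OpticalConfig(
            wavelength=lam, pixel_pitch_x=dx, pixel_pitch_y=dx, nx=n, ny=n,
            reconstruction_distance=d, propagation_distance=d,
        )


@pytest.fixture(scope="session")
def desk_cfg() -> OpticalConfig:
    """256x256 desk-scale optics for simulate/reconstruct/segment tests."""
    return OpticalConfig(
        nx=256, ny=256, pixel_pitch_x=0.55e-6, pixel_pitch_y=0.55e-6,
        reconstruction_distance=25e-6, propagation_distance=25e-6,
    )


@pytest.fixture(scope="session")
def default_experiment_report() -> dict:
    """One full default two-class recognition experiment (512x512, n=200,
    m=100, alpha=0.01, sample sizes 50..200), shared across tests."""
    return run_recognition(ExperimentConfig(seed=1))


@pytest.fixture(scope="session")
def null_f_results():
    """10,000 equal-variance Gaussian pairs (n=200) through the F test."""
    from holorec import SamplingSegment, variance_ratio_test

    rng = np.random.default_rng(2024)
    out = []
    for _ in range(10_000):
        ref = SamplingSegment(rng.normal(0.0, 1.0, 200), "real")
        inp = SamplingSegment(rng.normal(0.0, 1.0, 200), "real")
        out.append(variance_ratio_test(ref, inp, alpha=0.01))
    return out
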