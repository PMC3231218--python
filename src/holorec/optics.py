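"""Optical configuration, complex fields and free-space Fresnel propagation.

Propagation is carried out in the frequency domain with the quadratic-phase
Fresnel transfer function (angular-spectrum style): the field's FFT is
multiplied by ``exp(-j*pi*lambda*d*(fx^2 + fy^2))`` (forward; the sign flips
for back-propagation) and inverse-transformed.  The transfer function has
unit modulus, so propagation is exactly unitary: total power is conserved
and ``propagate(+d)`` followed by ``propagate(-d)`` is the identity up to
floating-point rounding.

Coordinate conventions: pixel indexing is 0-based with the origin at the
array corner; physical coordinate ``x = index * pixel_pitch``.  Discrete
spatial frequencies are ``u / (N * pitch)`` for integer ``u`` in
``[-N/2, N/2)``.  Any magnification of a physical microscope objective is
absorbed into an *effective* pixel pitch at the object plane; the config
stores that effective pitch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["OpticalConfig", "ComplexField", "forward_propagate", "fresnel_transfer_function"]


@dataclass(frozen=True)
class OpticalConfig:
    """Recording geometry of an in-line (Gabor) holographic microscope.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in metres (default 514.5 nm, argon-ion line).
    pixel_pitch_x, pixel_pitch_y : float
        Effective pixel pitch at the object plane, metres.  The sensor pitch
        divided by the lateral magnification of the objective.
    nx, ny : int
        Grid size in x and y (sensor pixels).
    reconstruction_distance : float
        Default object-to-sensor distance used for reconstruction, metres.
    propagation_distance : float
        Recording distance used by the forward model, metres.
    """

    wavelength: float = 514.5e-9
    pixel_pitch_x: float = 9e-6
    pixel_pitch_y: float = 9e-6
    nx: int = 2048
    ny: int = 2048
    reconstruction_distance: float = 25e-6
    propagation_distance: float = 25e-6

    def __post_init__(self) -> None:
        for name in ("wavelength", "pixel_pitch_x", "pixel_pitch_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid size must be at least 8x8")
        if self.wavelength >= min(self.pixel_pitch_x, self.pixel_pitch_y):
            warnings.warn(
                "wavelength is not small compared to the pixel pitch; "
                "the paraxial Fresnel model may be inaccurate",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)``."""
        return (self.ny, self.nx)

    def with_grid(self, n: int) -> "OpticalConfig":
        """Return a copy with a square ``n x n`` grid."""
        return replace(self, nx=n, ny=n)


@dataclass
class ComplexField:
    """A 2-D complex optical field sampled at a stated axial plane.

    The real and imaginary parts of ``values`` are the two channels the
    statistical recognition tests operate on.
    """

    values: np.ndarray
    plane_z: float
    config: OpticalConfig = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.config.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match config {self.config.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def power(self) -> float:
        """Total power: sum of squared moduli."""
        return float(np.sum(np.abs(self.values) ** 2))


def fresnel_transfer_function(
    config: OpticalConfig, distance: float, *, sign: int = -1
) -> np.ndarray:
    """Frequency-domain Fresnel propagation kernel.

    ``sign=-1`` gives forward propagation over ``distance``;
    ``sign=+1`` gives the reconstruction (back-propagation) kernel, whose
    exponent is ``+j*pi*lambda*d0*(u^2/(dx*Nx)^2 + v^2/(dy*Ny)^2)``.
    A constant phase ``exp(j*2*pi*d/lambda)`` accounts for the on-axis
    optical path; it cancels in any round trip.
    """
    fx = np.fft.fftfreq(config.nx, config.pixel_pitch_x)
    fy = np.fft.fftfreq(config.ny, config.pixel_pitch_y)
    fsq = fx[None, :] ** 2 + fy[:, None] ** 2
    lam = config.wavelength
    return np.exp(-sign * 1j * 2 * np.pi * distance / lam) * np.exp(
        sign * 1j * np.pi * lam * distance * fsq
    )


def forward_propagate(
    field_in: ComplexField, distance: float, config: OpticalConfig | None = None
) -> ComplexField:
    """Propagate a complex field over ``distance`` metres (negative = back).

    Unitary in the discrete 2-norm; ``distance=0`` returns the input values
    unchanged.
    """
    cfg = config if config is not None else field_in.config
    if field_in.values.shape != cfg.shape:
        raise ValueError(
            f"field shape {field_in.values.shape} does not match config {cfg.shape}"
        )
    if distance == 0:
        return ComplexField(field_in.values.copy(), field_in.plane_z, cfg)
    h = fresnel_transfer_function(cfg, distance, sign=-1)
    out = np.fft.ifft2(np.fft.fft2(field_in.values) * h)
    return ComplexField(out, field_in.plane_z + distance, cfg)
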