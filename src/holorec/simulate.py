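"""Synthetic phase-object specimens and in-line (Gabor) hologram recording.

Real microorganisms such as filamentous cyanobacteria (*Oscillatoria*) and
patterned diatom frustules are semitransparent: they modulate mainly the
phase of coherent light.  This module emulates them as thin phase screens —
a compact support (curved ribbon or pore-patterned ellipse) carrying a
spatially correlated random phase texture whose mean encodes optical
thickness and whose standard deviation (the *phase dispersion*) is the
class-discriminating property the recognition tests exploit.

Recording follows the in-line geometry: the unscattered (ballistic)
illumination acts as the reference wave R = A_r exp(j*phi_r); the scattered
component of the object transmission, ``t - 1`` with ``t = exp(j*phase)``,
is Fresnel-propagated to the sensor plane, and the recorded intensity is
``|R + O_h|^2`` (optionally with additive Gaussian sensor noise, clipped at
zero).  The specimen is collapsed to a single effective phase screen at the
recording plane: the specimens emulated are only a few micrometres thick,
and a single plane is reconstructed per hologram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy import ndimage

from .optics import ComplexField, OpticalConfig, forward_propagate

__all__ = [
    "PhaseObject",
    "Hologram",
    "generate_phase_object",
    "record_hologram",
    "SPECIMEN_CLASSES",
]


@dataclass
class PhaseObject:
    """A thin phase screen: phase map (radians) on a compact support."""

    phase_map: np.ndarray
    support_mask: np.ndarray
    axial_extent: float
    class_label: str

    def __post_init__(self) -> None:
        self.phase_map = np.asarray(self.phase_map, dtype=np.float64)
        self.support_mask = np.asarray(self.support_mask, dtype=bool)
        if self.phase_map.shape != self.support_mask.shape:
            raise ValueError("phase_map and support_mask shapes differ")
        if not self.support_mask.any():
            raise ValueError("support_mask is empty")
        if self.axial_extent < 0:
            raise ValueError("axial_extent must be nonnegative")
        if np.any(self.phase_map[~self.support_mask] != 0):
            raise ValueError("phase_map must be zero outside the support")

    def transmission(self) -> np.ndarray:
        """Complex transmission t = exp(j*phase)."""
        return np.exp(1j * self.phase_map)


@dataclass
class Hologram:
    """Recorded in-line hologram intensity plus recording metadata."""

    intensity: np.ndarray
    config: OpticalConfig
    reference_amplitude: float
    reference_phase: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.shape != self.config.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != config {self.config.shape}"
            )
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be nonnegative")


# ---------------------------------------------------------------------------
# Support-shape builders (registry keyed by class label)
# ---------------------------------------------------------------------------


def _filament_support(config: OpticalConfig, params: dict[str, Any]) -> np.ndarray:
    """Curved ribbon: pixels within half the width of a gently bent
    centerline.  Emulates a filamentous cyanobacterium."""
    from scipy.spatial import cKDTree

    length = params.get("length", 100e-6)
    width = params.get("width", 4e-6)
    bend = params.get("bend", 10e-6)
    theta = np.deg2rad(params.get("orientation_deg", 30.0))
    dx, dy = config.pixel_pitch_x, config.pixel_pitch_y

    # centerline sampled at <= 0.05 px so nearest-sample distance is a
    # faithful distance-to-curve (keeps the pixel count close to the
    # analytic ribbon area length*width)
    n_pts = max(int(np.ceil(length / (0.05 * min(dx, dy)))), 64)
    t = np.linspace(-0.5, 0.5, n_pts)
    along = t * length
    across = bend * np.sin(np.pi * (t + 0.5))
    cx, cy = config.nx * dx / 2, config.ny * dy / 2
    x = cx + along * np.cos(theta) - across * np.sin(theta)
    y = cy + along * np.sin(theta) + across * np.cos(theta)

    xs = (np.arange(config.nx) + 0.5) * dx
    ys = (np.arange(config.ny) + 0.5) * dy
    half = width / 2
    col = (xs >= x.min() - half - dx) & (xs <= x.max() + half + dx)
    row = (ys >= y.min() - half - dy) & (ys <= y.max() + half + dy)
    mask = np.zeros(config.shape, dtype=bool)
    if not col.any() or not row.any():
        return mask
    X, Y = np.meshgrid(xs[col], ys[row])
    tree = cKDTree(np.column_stack([x, y]))
    dist, _ = tree.query(np.column_stack([X.ravel(), Y.ravel()]), workers=-1)
    sub = dist.reshape(X.shape) <= half
    mask[np.ix_(row, col)] = sub
    return mask


def _ellipse_support(config: OpticalConfig, params: dict[str, Any]) -> np.ndarray:
    """Elliptical support punctured by a regular lattice of circular pores,
    emulating a patterned diatom frustule."""
    semi_major = params.get("semi_major", 15e-6)
    semi_minor = params.get("semi_minor", 7.5e-6)
    theta = np.deg2rad(params.get("orientation_deg", 0.0))
    pore_radius = params.get("pore_radius", 1.5e-6)
    pore_spacing = params.get("pore_spacing", 6e-6)
    dx, dy = config.pixel_pitch_x, config.pixel_pitch_y

    cx, cy = config.nx * dx / 2, config.ny * dy / 2
    xs = (np.arange(config.nx) + 0.5) * dx - cx
    ys = (np.arange(config.ny) + 0.5) * dy - cy
    X, Y = np.meshgrid(xs, ys)
    u = X * np.cos(theta) + Y * np.sin(theta)
    v = -X * np.sin(theta) + Y * np.cos(theta)
    mask = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
    if pore_radius > 0 and pore_spacing > 0:
        pu = (np.mod(u + pore_spacing / 2, pore_spacing) - pore_spacing / 2)
        pv = (np.mod(v + pore_spacing / 2, pore_spacing) - pore_spacing / 2)
        pores = pu**2 + pv**2 <= pore_radius**2
        mask &= ~pores
    return mask


SPECIMEN_CLASSES: dict[str, Callable[[OpticalConfig, dict[str, Any]], np.ndarray]] = {
    "filament": _filament_support,
    "ellipse": _ellipse_support,
}


def generate_phase_object(
    class_label: str,
    grid: OpticalConfig,
    shape_params: dict[str, Any] | None = None,
    phase_dispersion: float = 0.5,
    seed: int = 0,
    *,
    mean_phase: float = 1.2,
    texture_sigma_px: float = 2.0,
    axial_extent: float = 3e-6,
) -> PhaseObject:
    """Generate a synthetic specimen as a thin phase screen.

    The phase inside the support is a spatially correlated Gaussian random
    field (white noise smoothed with a Gaussian kernel of ``texture_sigma_px``
    pixels) rescaled so that its standard deviation over the support equals
    ``phase_dispersion`` exactly, around ``mean_phase``.  ``phase_dispersion=0``
    yields a constant phase on the support.  Deterministic for a fixed seed.

    Parameters
    ----------
    class_label : str
        One of the registered specimen classes (``filament``, ``ellipse``).
    grid : OpticalConfig
        Defines grid size and effective pixel pitch at the object plane.
    shape_params : dict, optional
        Geometry of the support, in metres (see the class builders).
    phase_dispersion : float
        Spatial standard deviation of the phase over the support, radians.
    seed : int
        Seed for the phase texture.
    mean_phase : float
        Mean optical phase delay over the support, radians.
    """
    if phase_dispersion < 0:
        raise ValueError("phase_dispersion must be nonnegative")
    try:
        builder = SPECIMEN_CLASSES[class_label]
    except KeyError:
        raise ValueError(
            f"unknown class_label {class_label!r}; registered classes: "
            f"{sorted(SPECIMEN_CLASSES)}"
        ) from None
    support = builder(grid, dict(shape_params or {}))
    if not support.any():
        raise ValueError(
            f"specimen support is empty on a {grid.ny}x{grid.nx} grid; "
            "check shape_params against the pixel pitch"
        )

    phase = np.zeros(grid.shape)
    if phase_dispersion > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(grid.shape)
        if texture_sigma_px > 0:
            noise = ndimage.gaussian_filter(noise, texture_sigma_px)
        vals = noise[support]
        sd = vals.std()
        if sd == 0:  # pragma: no cover - single-pixel support corner case
            vals = np.zeros_like(vals)
        else:
            vals = (vals - vals.mean()) / sd * phase_dispersion
        phase[support] = mean_phase + vals
    else:
        phase[support] = mean_phase
    return PhaseObject(phase, support, axial_extent, class_label)


def record_hologram(
    obj: PhaseObject,
    config: OpticalConfig,
    reference_amplitude: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    *,
    reference_phase: float = 0.0,
) -> Hologram:
    """Record the in-line hologram ``I = |A_r e^{j phi_r} + O_h|^2``.

    ``O_h`` is the scattered component ``t - 1`` Fresnel-propagated over the
    recording distance ``config.propagation_distance``.  Additive Gaussian
    noise of standard deviation ``noise_sigma`` is applied to the intensity
    and the result clipped at zero.  With ``noise_sigma=0`` the recording is
    deterministic.  The weak-object ratio ``max|O_h| / A_r`` is reported in
    ``meta`` so the in-line approximation (|A_h| << A_r) can be audited.
    """
    if reference_amplitude <= 0:
        raise ValueError("reference_amplitude must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if obj.phase_map.shape != config.shape:
        raise ValueError("phase object shape does not match config grid")

    scattered = ComplexField(obj.transmission() - 1.0, 0.0, config)
    o_h = forward_propagate(scattered, config.propagation_distance)
    ref = reference_amplitude * np.exp(1j * reference_phase)
    intensity = np.abs(ref + o_h.values) ** 2
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, size=intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    meta = {
        "class_label": obj.class_label,
        "noise_sigma": noise_sigma,
        "weak_object_ratio": float(np.max(np.abs(o_h.values)) / reference_amplitude),
        "propagation_distance": config.propagation_distance,
    }
    return Hologram(intensity, config, reference_amplitude, reference_phase, meta)
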