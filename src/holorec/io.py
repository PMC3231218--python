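"""File interchange: holograms as 16-bit TIFF, fields as float32 TIFF pairs.

A hologram is stored as a 16-bit grayscale TIFF with the intensity linearly
scaled to the full range; the scale factor and the optics metadata travel in
a YAML sidecar next to the image.  A reconstructed complex field is stored
as two 32-bit float TIFFs (real and imaginary planes) plus a sidecar.
Masks are 8-bit PNGs with values 0/255.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .optics import ComplexField, OpticalConfig
from .simulate import Hologram

__all__ = [
    "write_hologram",
    "read_hologram",
    "write_field",
    "read_field",
    "write_mask",
    "read_mask",
]

_U16_MAX = 65535


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yml")


def write_hologram(hologram: Hologram, path: str | Path) -> Path:
    """Write a hologram as 16-bit TIFF + YAML sidecar; returns sidecar path."""
    path = Path(path)
    peak = float(hologram.intensity.max())
    scale = _U16_MAX / peak if peak > 0 else 1.0
    raw = np.round(hologram.intensity * scale).astype(np.uint16)
    tifffile.imwrite(path, raw)
    cfg = hologram.config
    meta = {
        "wavelength_m": cfg.wavelength,
        "pixel_pitch_m": [cfg.pixel_pitch_x, cfg.pixel_pitch_y],
        "distance_m": cfg.propagation_distance,
        "reconstruction_distance_m": cfg.reconstruction_distance,
        "reference_amplitude": hologram.reference_amplitude,
        "reference_phase": hologram.reference_phase,
        "scale": scale,
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return sidecar


def read_hologram(path: str | Path, sidecar: str | Path | None = None) -> Hologram:
    """Read a hologram TIFF plus its YAML sidecar back into a Hologram."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    meta = yaml.safe_load(sidecar.read_text())
    raw = tifffile.imread(path).astype(np.float64)
    intensity = raw / meta["scale"]
    ppx, ppy = meta["pixel_pitch_m"]
    ny, nx = raw.shape
    cfg = OpticalConfig(
        wavelength=meta["wavelength_m"],
        pixel_pitch_x=ppx,
        pixel_pitch_y=ppy,
        nx=nx,
        ny=ny,
        reconstruction_distance=meta.get("reconstruction_distance_m", meta["distance_m"]),
        propagation_distance=meta["distance_m"],
    )
    return Hologram(
        intensity,
        cfg,
        reference_amplitude=meta["reference_amplitude"],
        reference_phase=meta.get("reference_phase", 0.0),
    )


def write_field(field: ComplexField, stem: str | Path) -> tuple[Path, Path]:
    """Write a complex field as <stem>_re.tif / <stem>_im.tif + sidecar."""
    stem = Path(stem)
    re_path = stem.with_name(stem.name + "_re.tif")
    im_path = stem.with_name(stem.name + "_im.tif")
    tifffile.imwrite(re_path, field.values.real.astype(np.float32))
    tifffile.imwrite(im_path, field.values.imag.astype(np.float32))
    cfg = field.config
    meta = {
        "wavelength_m": cfg.wavelength,
        "pixel_pitch_m": [cfg.pixel_pitch_x, cfg.pixel_pitch_y],
        "plane_z_m": field.plane_z,
    }
    _sidecar_path(re_path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return re_path, im_path


def read_field(re_path: str | Path, im_path: str | Path) -> ComplexField:
    """Read a complex field from paired real/imaginary float TIFFs."""
    re_path, im_path = Path(re_path), Path(im_path)
    re = tifffile.imread(re_path).astype(np.float64)
    im = tifffile.imread(im_path).astype(np.float64)
    meta = yaml.safe_load(_sidecar_path(re_path).read_text())
    ppx, ppy = meta["pixel_pitch_m"]
    ny, nx = re.shape
    cfg = OpticalConfig(
        wavelength=meta["wavelength_m"],
        pixel_pitch_x=ppx,
        pixel_pitch_y=ppy,
        nx=nx,
        ny=ny,
    )
    return ComplexField(re + 1j * im, meta.get("plane_z_m", 0.0), cfg)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    img = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(img, mode="L").save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask back to boolean."""
    return np.asarray(Image.open(Path(path)).convert("L")) > 127
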