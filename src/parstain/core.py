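"""Shared containers and file I/O for the virtual-staining pipeline.

Coordinate convention (used everywhere in the package): pixel ``(row, col)``
= ``(0, 0)`` is the top-left pixel; a stage position in micrometres maps to
the pixel *center*, i.e. pixel ``(r, c)`` is centered at
``origin + (c + 0.5, r + 0.5) * pitch``; the image extent is half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "ContrastStack",
    "StainedImage",
    "CHANNEL_NAMES",
    "read_contrast_stack",
    "read_stained_image",
]

#: Fixed channel order of every 3-channel TA-PARS raster in this package.
CHANNEL_NAMES = ("non_radiative", "radiative", "scattering")


@dataclass
class ContrastStack:
    """Co-registered 3-channel raster (non-radiative, radiative, scattering).

    Parameters
    ----------
    channels : ndarray, shape (3, H, W)
        Channel values in [0, 1].
    pixel_pitch_nm : float
        Physical pixel pitch in nanometres (must be positive).
    origin_um : tuple of float
        Physical (x, y) position of the top-left image corner, micrometres.
    valid_mask : ndarray of bool, shape (H, W), optional
        True where pixel values were measured; False where they were filled
        by interpolation (see ``acquisition.reconstruct_grid``).
    """

    channels: np.ndarray
    pixel_pitch_nm: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError(
                f"channels must have shape (3, H, W), got {self.channels.shape}"
            )
        if not self.pixel_pitch_nm > 0:
            raise ValueError("pixel_pitch_nm must be positive")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.shape:
                raise ValueError("valid_mask shape must match channel shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def save(self, path: str | Path) -> None:
        """Write as multi-page 16-bit TIFF plus a YAML metadata sidecar."""
        path = Path(path)
        data = np.clip(self.channels, 0.0, 1.0)
        tifffile.imwrite(path, (data * 65535.0 + 0.5).astype(np.uint16))
        meta = {
            "pixel_pitch_nm": float(self.pixel_pitch_nm),
            "origin_um": [float(v) for v in self.origin_um],
            "channel_order": list(CHANNEL_NAMES),
        }
        if self.valid_mask is not None:
            meta["valid_fraction"] = float(self.valid_mask.mean())
            np.savetxt(
                path.with_suffix(".mask.csv"),
                self.valid_mask.astype(np.uint8),
                fmt="%d",
                delimiter=",",
            )
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


@dataclass
class StainedImage:
    """RGB raster of a (real or virtual) H&E-stained section.

    ``rgb`` has shape (H, W, 3) with values in [0, 1];
    ``pixel_pitch_nm`` is the physical pixel pitch. ``oob_mask`` marks
    pixels that fell outside the source image during warping.
    """

    rgb: np.ndarray
    pixel_pitch_nm: float
    oob_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.float64)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"rgb must have shape (H, W, 3), got {self.rgb.shape}")
        if not self.pixel_pitch_nm > 0:
            raise ValueError("pixel_pitch_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def save(self, path: str | Path) -> None:
        """Write as 8-bit RGB TIFF (or PNG by extension) + YAML sidecar."""
        path = Path(path)
        data = (np.clip(self.rgb, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
        if path.suffix.lower() == ".png":
            import imageio.v3 as iio

            iio.imwrite(path, data)
        else:
            tifffile.imwrite(path, data)
        path.with_suffix(".yaml").write_text(
            yaml.safe_dump({"pixel_pitch_nm": float(self.pixel_pitch_nm)})
        )


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing pixel-pitch metadata sidecar {sidecar.name} for {path.name}"
        )
    return yaml.safe_load(sidecar.read_text())


def read_contrast_stack(path: str | Path) -> ContrastStack:
    path = Path(path)
    meta = _read_sidecar(path)
    raw = tifffile.imread(path).astype(np.float64)
    if raw.ndim != 3:
        raise ValueError(f"{path} is not a 3-page contrast TIFF")
    if raw.shape[0] != 3 and raw.shape[2] == 3:  # tolerate HWC layout
        raw = np.moveaxis(raw, 2, 0)
    stack = ContrastStack(
        raw / 65535.0,
        pixel_pitch_nm=float(meta["pixel_pitch_nm"]),
        origin_um=tuple(meta.get("origin_um", (0.0, 0.0))),
    )
    mask_path = path.with_suffix(".mask.csv")
    if mask_path.exists():
        stack.valid_mask = np.loadtxt(mask_path, delimiter=",", dtype=np.uint8).astype(bool)
    return stack


def read_stained_image(path: str | Path) -> StainedImage:
    path = Path(path)
    meta = _read_sidecar(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        raw = iio.imread(path)
    else:
        raw = tifffile.imread(path)
    return StainedImage(raw.astype(np.float64) / 255.0, float(meta["pixel_pitch_nm"]))


def asdict_shallow(obj) -> dict:
    """dataclass -> dict without recursing into ndarray fields."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
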