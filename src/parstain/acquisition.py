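"""Cartesian image formation from per-pulse scan records.

A point-scanned PARS microscope emits one excitation pulse per position and
records, per pulse, the scattering, radiative and non-radiative responses.
Each response is compressed to a single scalar feature which becomes a pixel
value; pixels are then fitted onto a Cartesian grid from the stage position
signals. This module reproduces that image-formation step: feature
extraction from raw traces, nearest-center binning onto the grid with
in-pixel averaging, and nearest-neighbor fill of unsampled pixels (tracked
in a validity mask).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import ndimage

from .core import ContrastStack

__all__ = [
    "PulseRecord",
    "PulseStream",
    "pulse_feature",
    "reconstruct_grid",
    "physical_extent",
    "read_pulse_stream",
    "write_pulse_stream",
    "EmptyReconstructionError",
]


class EmptyReconstructionError(ValueError):
    """No scan record fell inside the requested reconstruction extent."""


@dataclass(frozen=True)
class PulseRecord:
    """One excitation event: stage position plus per-channel features."""

    x_um: float
    y_um: float
    features: tuple[float, float, float]  # (non-radiative, radiative, scattering)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_um) and np.isfinite(self.y_um)):
            raise ValueError("pulse position must be finite")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("pulse features must be finite")


class PulseStream(Sequence):
    """Vectorized sequence of :class:`PulseRecord`.

    Stores positions as ``(N,)`` arrays and features as ``(N, 3)`` so that
    megapixel streams stay cheap; indexing returns ``PulseRecord`` objects.
    """

    def __init__(self, x_um: np.ndarray, y_um: np.ndarray, features: np.ndarray):
        self.x_um = np.asarray(x_um, dtype=np.float64)
        self.y_um = np.asarray(y_um, dtype=np.float64)
        self.features = np.asarray(features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[1] != 3:
            raise ValueError("features must have shape (N, 3)")
        if not (len(self.x_um) == len(self.y_um) == len(self.features)):
            raise ValueError("position and feature arrays must share length")

    def __len__(self) -> int:
        return len(self.x_um)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return PulseStream(self.x_um[i], self.y_um[i], self.features[i])
        return PulseRecord(float(self.x_um[i]), float(self.y_um[i]), tuple(self.features[i]))

    def __iter__(self) -> Iterator[PulseRecord]:
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def from_records(cls, records: Iterable[PulseRecord]) -> "PulseStream":
        records = list(records)
        return cls(
            np.array([r.x_um for r in records]),
            np.array([r.y_um for r in records]),
            np.array([r.features for r in records]),
        )


def _as_stream(records) -> PulseStream:
    if isinstance(records, PulseStream):
        return records
    return PulseStream.from_records(records)


def pulse_feature(trace: np.ndarray) -> float:
    """Compress a sampled per-pulse signal to a single pixel value.

    The reducer is peak amplitude above baseline, ``max(trace) -
    median(trace)``: invariant to constant offsets and nonnegative, matching
    the amplitude-projection convention of point-scanned photoacoustic
    imaging. Alternative reducers (``"integral"``, ``"max"``) are available
    through :func:`pulse_feature_named`.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size == 0:
        raise ValueError("pulse trace is empty")
    return float(np.max(trace) - np.median(trace))


def pulse_feature_named(trace: np.ndarray, reducer: str = "peak_above_baseline") -> float:
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size == 0:
        raise ValueError("pulse trace is empty")
    if reducer == "peak_above_baseline":
        return pulse_feature(trace)
    if reducer == "integral":
        return float(np.sum(trace - np.median(trace)))
    if reducer == "max":
        return float(np.max(trace))
    raise ValueError(f"unknown reducer {reducer!r}")


def reconstruct_grid(
    records,
    pitch_nm: float,
    extent: tuple[int, int],
    origin_um: tuple[float, float] = (0.0, 0.0),
    method: str = "bin",
) -> ContrastStack:
    """Fit per-pulse pixel values onto a Cartesian grid.

    With ``method="bin"`` (default) each record is assigned to the pixel
    whose center is nearest its stage position (equivalently: binned into
    the half-open pixel it falls in); multiple records per pixel are
    averaged; pixels no record reached are filled from their nearest
    sampled neighbor and flagged False in the returned stack's
    ``valid_mask``. Binning is exactly invertible on jitter-free streams.
    ``method="interpolate"`` instead linearly interpolates the scattered
    records at the pixel centers (nearest-neighbor outside their convex
    hull, flagged in the mask).

    Parameters
    ----------
    records : PulseStream or iterable of PulseRecord
    pitch_nm : float
        Grid pitch in nanometres.
    extent : (height_px, width_px)
        Output raster size.
    origin_um : (x, y)
        Physical position of the top-left image corner.

    Raises
    ------
    EmptyReconstructionError
        If every record lies outside the extent.
    """
    stream = _as_stream(records)
    if pitch_nm <= 0:
        raise ValueError("pitch_nm must be positive")
    if method not in ("bin", "interpolate"):
        raise ValueError(f"unknown reconstruction method {method!r}")
    h, w = int(extent[0]), int(extent[1])
    if h <= 0 or w <= 0:
        raise ValueError("extent must be positive")
    pitch_um = pitch_nm * 1e-3

    col = np.floor((stream.x_um - origin_um[0]) / pitch_um).astype(np.int64)
    row = np.floor((stream.y_um - origin_um[1]) / pitch_um).astype(np.int64)
    inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    if not inside.any():
        raise EmptyReconstructionError("all scan records fall outside the extent")

    if method == "interpolate":
        return _interpolate_grid(stream, inside, pitch_um, (h, w), origin_um, pitch_nm)

    flat = row[inside] * w + col[inside]
    counts = np.bincount(flat, minlength=h * w).astype(np.float64)
    channels = np.empty((3, h, w), dtype=np.float64)
    valid = counts.reshape(h, w) > 0
    for c in range(3):
        sums = np.bincount(flat, weights=stream.features[inside, c], minlength=h * w)
        mean = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
        channels[c] = mean.reshape(h, w)

    if not valid.all():
        # nearest-sampled-neighbor fill for unvisited pixels
        _, (ir, ic) = ndimage.distance_transform_edt(~valid, return_indices=True)
        channels = channels[:, ir, ic]

    return ContrastStack(channels, pixel_pitch_nm=pitch_nm, origin_um=tuple(origin_um), valid_mask=valid)


def _interpolate_grid(stream, inside, pitch_um, shape, origin_um, pitch_nm) -> ContrastStack:
    from scipy.interpolate import griddata

    h, w = shape
    px = (stream.x_um[inside] - origin_um[0]) / pitch_um - 0.5  # pixel coords
    py = (stream.y_um[inside] - origin_um[1]) / pitch_um - 0.5
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    pts = np.column_stack([py, px])
    channels = np.empty((3, h, w))
    valid = np.ones((h, w), dtype=bool)
    for c in range(3):
        vals = stream.features[inside, c]
        if len(pts) >= 4:
            lin = griddata(pts, vals, (gy, gx), method="linear")
        else:
            lin = np.full((h, w), np.nan)
        hull_miss = np.isnan(lin)
        if hull_miss.any():
            near = griddata(pts, vals, (gy, gx), method="nearest")
            lin[hull_miss] = near[hull_miss]
        channels[c] = lin
        valid &= ~hull_miss
    return ContrastStack(
        np.clip(channels, 0.0, 1.0), pixel_pitch_nm=pitch_nm,
        origin_um=tuple(origin_um), valid_mask=valid,
    )


def physical_extent(width_px: int, height_px: int, pitch_nm: float) -> tuple[float, float, float]:
    """Physical size of a raster: (width_mm, height_mm, area_mm2).

    E.g. a 4000 x 6500 px image at 250 nm pitch covers 1.0 x 1.625 mm,
    area 1.625 mm^2.
    """
    if width_px <= 0 or height_px <= 0 or pitch_nm <= 0:
        raise ValueError("all arguments must be positive")
    width_mm = width_px * pitch_nm * 1e-6
    height_mm = height_px * pitch_nm * 1e-6
    return width_mm, height_mm, width_mm * height_mm


# --- pulse stream CSV I/O ---------------------------------------------------

_STREAM_HEADER = ["x_um", "y_um", "ch1", "ch2", "ch3"]


def write_pulse_stream(stream, path: str | Path) -> None:
    """Write records as headered CSV (x_um, y_um, ch1, ch2, ch3)."""
    stream = _as_stream(stream)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_STREAM_HEADER)
        for i in range(len(stream)):
            writer.writerow(
                [repr(float(stream.x_um[i])), repr(float(stream.y_um[i]))]
                + [repr(float(v)) for v in stream.features[i]]
            )


def read_pulse_stream(path: str | Path) -> PulseStream:
    data = np.genfromtxt(path, delimiter=",", names=True)
    data = np.atleast_1d(data)
    feats = np.stack([data["ch1"], data["ch2"], data["ch3"]], axis=1)
    return PulseStream(data["x_um"], data["y_um"], feats)
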