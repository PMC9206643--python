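"""Intensity normalization of the contrast channels for colorization.

Each channel is min-max normalized, contrast stretched by saturating the
top 1% and bottom 1% of all pixel values, then color-reversed (x -> 1 - x)
so that strong absorbers (nuclei in the non-radiative channel) appear dark,
matching the colormap and histogram orientation of grayscale H&E. Channel
order is fixed: (non-radiative, radiative, scattering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import CHANNEL_NAMES, ContrastStack

__all__ = ["NormalizedStack", "stretch_percentile", "color_reverse", "prepare_input"]


@dataclass
class NormalizedStack:
    """Colorizer-ready 3-channel stack in [0, 1] with an applied-ops log."""

    channels: np.ndarray  # (3, H, W)
    provenance: list[str] = field(default_factory=list)
    pixel_pitch_nm: float | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError("channels must have shape (3, H, W)")
        if self.channels.min() < 0 or self.channels.max() > 1:
            raise ValueError("normalized channels must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def save(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, (self.channels * 65535.0 + 0.5).astype(np.uint16))
        path.with_suffix(".yaml").write_text(
            yaml.safe_dump(
                {
                    "provenance": list(self.provenance),
                    "channel_order": list(CHANNEL_NAMES),
                    "pixel_pitch_nm": self.pixel_pitch_nm,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "NormalizedStack":
        import tifffile

        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        return cls(
            tifffile.imread(path).astype(np.float64) / 65535.0,
            provenance=list(meta.get("provenance", [])),
            pixel_pitch_nm=meta.get("pixel_pitch_nm"),
        )


def stretch_percentile(channel: np.ndarray, low_pct: float = 1.0, high_pct: float = 1.0) -> np.ndarray:
    """Contrast stretch saturating ``low_pct``% of the lowest and
    ``high_pct``% of the highest pixel values.

    Percentiles are computed over the whole channel with the linear
    interpolation convention; output is ``clip((x - p_lo)/(p_hi - p_lo),
    0, 1)``. A constant channel (``p_hi == p_lo``) maps to all zeros.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise ValueError("channel is empty")
    if low_pct < 0 or high_pct < 0 or low_pct + high_pct >= 100:
        raise ValueError("require 0 <= low_pct + high_pct < 100")
    p_lo = np.percentile(channel, low_pct)
    p_hi = np.percentile(channel, 100.0 - high_pct)
    if p_hi == p_lo:
        return np.zeros_like(channel)
    return np.clip((channel - p_lo) / (p_hi - p_lo), 0.0, 1.0)


def color_reverse(channel: np.ndarray) -> np.ndarray:
    """Reverse intensities, x -> 1 - x (involution on [0, 1])."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.min() < 0 or channel.max() > 1:
        raise ValueError("channel must lie in [0, 1] before reversal")
    return 1.0 - channel


PROVENANCE_TAG = "minmax|stretch(1,1)|reverse"


def prepare_input(
    stack: ContrastStack | NormalizedStack,
    low_pct: float = 1.0,
    high_pct: float = 1.0,
    per_channel: bool = True,
    histogram_match_to: np.ndarray | None = None,
) -> NormalizedStack:
    """Build the colorizer input from a raw contrast stack.

    Per channel: min-max normalize -> percentile stretch -> color reverse,
    preserving the (non-radiative, radiative, scattering) order. Applying
    the preparation to an already-prepared stack is not idempotent and
    emits a provenance warning. With ``per_channel=False`` the min-max and
    percentile bounds are computed jointly across the three channels.
    ``histogram_match_to`` optionally matches each prepared channel's
    histogram to a reference grayscale raster in [0, 1] (off by default;
    the plain reversal already mirrors the histogram orientation).
    """
    if isinstance(stack, NormalizedStack):
        if any("prepare_input" in p for p in stack.provenance):
            warnings.warn(
                "prepare_input applied to an already-prepared stack; "
                "the operation is not idempotent"
            )
        channels = stack.channels
        prior = list(stack.provenance)
        pitch = stack.pixel_pitch_nm
    else:
        channels = stack.channels
        prior = []
        pitch = stack.pixel_pitch_nm
    if channels.shape[0] != 3:
        raise ValueError("expected 3 channels (non-radiative, radiative, scattering)")

    out = np.empty_like(channels, dtype=np.float64)
    if per_channel:
        for c in range(3):
            ch = channels[c]
            lo, hi = ch.min(), ch.max()
            norm = (ch - lo) / (hi - lo) if hi > lo else np.zeros_like(ch)
            out[c] = color_reverse(stretch_percentile(norm, low_pct, high_pct))
    else:
        lo, hi = channels.min(), channels.max()
        norm = (channels - lo) / (hi - lo) if hi > lo else np.zeros_like(channels)
        stretched = stretch_percentile(norm, low_pct, high_pct)
        out = color_reverse(stretched)

    mode = "per_channel" if per_channel else "global"
    tag = f"prepare_input[{PROVENANCE_TAG};{mode};low={low_pct};high={high_pct}]"
    if histogram_match_to is not None:
        from skimage.exposure import match_histograms

        reference = np.asarray(histogram_match_to, dtype=np.float64)
        for c in range(3):
            out[c] = np.clip(match_histograms(out[c], reference), 0.0, 1.0)
        tag += "|histmatch"
    return NormalizedStack(out, provenance=prior + [tag], pixel_pitch_nm=pitch)
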