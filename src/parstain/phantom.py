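"""Synthetic tissue phantom with full ground truth.

Emulates the statistical structure of total-absorption PARS data on thin
tissue sections: a nuclear concentration map (random ellipses — nuclei),
an extranuclear map (smooth cytoplasm texture, fibrous connective-tissue
curves, bright vessel blobs), a three-channel contrast stack in which
non-radiative absorption is dominated by the nuclear compartment and
radiative absorption by the extranuclear compartment (with small
cross-talk), a paired H&E render through a Beer-Lambert stain-mixing
forward model, a misregistered copy of that render produced by a known
smooth warp, and a per-pulse scan stream. Everything is a pure function of
(spec, seed), so identical specs reproduce bit-identical samples.

Not modelled (out of scope): biophysically accurate photoacoustic signal
generation, optical point-spread functions, 3-D structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .acquisition import PulseStream, write_pulse_stream
from .core import ContrastStack, StainedImage
from .registration import LandmarkSet, SpatialTransform, fit_transform, warp_raster

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "sample_phantom",
    "render_he",
    "apply_misregistration",
    "emit_scan_stream",
    "DEFAULT_STAIN_VECTORS",
]

# Widely used hematoxylin / eosin absorbance directions (unit norm),
# standard in stain-unmixing work; configurable per call.
DEFAULT_STAIN_VECTORS = np.array(
    [
        [0.65, 0.70, 0.29],  # hematoxylin: deep blue-purple, binds nuclei
        [0.07, 0.99, 0.11],  # eosin: pink, binds cytoplasm / ECM
    ]
)
DEFAULT_STAIN_VECTORS /= np.linalg.norm(DEFAULT_STAIN_VECTORS, axis=1, keepdims=True)

# Channel forward-model coefficients: each contrast favours one compartment
# strongly; cross-talk defaults to 10% of the dominant term.
A_NN, A_NE = 0.9, 0.09  # non-radiative
B_EE, B_EN = 0.9, 0.09  # radiative

# Stain "dose" applied to the concentration maps before Beer-Lambert mixing.
HEMATOXYLIN_DOSE = 1.8
EOSIN_DOSE = 1.0


class InvalidSpecError(ValueError):
    """Phantom specification violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic specimen.

    ``nuclei_density`` is the expected nucleus count per 100x100 px region;
    ``nucleus_axes_px`` gives (mean, sd) of the ellipse semi-axes;
    ``noise_sd`` holds per-channel additive noise standard deviations in
    [0, 1] for (non-radiative, radiative, scattering).
    """

    height_px: int = 512
    width_px: int = 512
    pixel_pitch_nm: float = 250.0
    nuclei_density: float = 5.0
    nucleus_axes_px: tuple[float, float] = (6.0, 1.5)
    fiber_count: int = 12
    fiber_thickness_px: float = 2.0
    vessel_count: int = 3
    noise_sd: tuple[float, float, float] = (0.02, 0.02, 0.02)
    warp_amplitude_px: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise InvalidSpecError("image extents must be positive")
        if self.pixel_pitch_nm <= 0:
            raise InvalidSpecError("pixel_pitch_nm must be positive")
        if self.nuclei_density < 0 or self.fiber_count < 0 or self.vessel_count < 0:
            raise InvalidSpecError("densities and counts must be nonnegative")
        if self.fiber_thickness_px <= 0:
            raise InvalidSpecError("fiber_thickness_px must be positive")
        if any(not (0 <= s <= 1) for s in self.noise_sd):
            raise InvalidSpecError("noise_sd components must lie in [0, 1]")
        if self.warp_amplitude_px < 0:
            raise InvalidSpecError("warp_amplitude_px must be nonnegative")

    def save(self, path: str | Path) -> None:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        doc["nucleus_axes_px"] = list(self.nucleus_axes_px)
        doc["noise_sd"] = list(self.noise_sd)
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def load(cls, path: str | Path) -> "PhantomSpec":
        doc = yaml.safe_load(Path(path).read_text())
        doc["nucleus_axes_px"] = tuple(doc["nucleus_axes_px"])
        doc["noise_sd"] = tuple(doc["noise_sd"])
        return cls(**doc)


@dataclass
class PhantomSample:
    """One fully ground-truthed specimen (see module docstring)."""

    spec: PhantomSpec
    contrast: ContrastStack
    he_true: StainedImage
    he_moving: StainedImage
    true_warp: SpatialTransform
    landmarks_true: LandmarkSet
    c_nuclear: np.ndarray
    c_extranuclear: np.ndarray
    pulse_stream: PulseStream
    n_nuclei: int

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.spec.save(directory / "spec.yaml")
        self.contrast.save(directory / "contrast.tiff")
        self.he_true.save(directory / "he_true.tiff")
        self.he_moving.save(directory / "he_moving.tiff")
        self.true_warp.save(directory / "true_warp.yaml")
        self.landmarks_true.save(directory / "landmarks_true.csv")
        write_pulse_stream(self.pulse_stream, directory / "pulse_stream.csv")


def _draw_nuclei(rng: np.random.Generator, spec: PhantomSpec) -> tuple[np.ndarray, int]:
    h, w = spec.height_px, spec.width_px
    c_n = np.zeros((h, w))
    mean_ax, sd_ax = spec.nucleus_axes_px
    count = int(rng.poisson(spec.nuclei_density * h * w / 1e4))
    for _ in range(count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = max(1.0, rng.normal(mean_ax, sd_ax))
        b = max(1.0, rng.normal(mean_ax, sd_ax))
        theta = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        intensity = rng.uniform(0.7, 1.0)
        c_n[rr, cc] = np.maximum(c_n[rr, cc], intensity)
    return c_n, count


def _draw_fibers(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Fibers as smoothed random curves (a bounded direction random walk)."""
    h, w = spec.height_px, spec.width_px
    canvas = np.zeros((h, w))
    n_steps = max(h, w)
    for _ in range(spec.fiber_count):
        y, x = rng.uniform(0, h), rng.uniform(0, w)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            angle += rng.normal(0, 0.15)
            y += math.sin(angle)
            x += math.cos(angle)
            if not (0 <= y < h and 0 <= x < w):
                break
            canvas[int(y), int(x)] = 1.0
    if canvas.any():
        canvas = ndimage.gaussian_filter(canvas, spec.fiber_thickness_px / 2.0)
        canvas /= canvas.max()
    return canvas


def _draw_vessels(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    canvas = np.zeros((h, w))
    scale = min(h, w)
    for _ in range(spec.vessel_count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(0.03, 0.08) * scale
        b = rng.uniform(0.03, 0.08) * scale
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=rng.uniform(0, np.pi))
        canvas[rr, cc] = np.maximum(canvas[rr, cc], rng.uniform(0.8, 1.0))
    return ndimage.gaussian_filter(canvas, 2.0)


def sample_phantom(spec: PhantomSpec) -> PhantomSample:
    """Draw one specimen from the phantom model.

    Nucleus count is Poisson with mean ``nuclei_density * area / 1e4``.
    Channel forward model (before clipping to [0, 1]):

    - non-radiative = ``A_NN * c_n + A_NE * c_e`` + noise (nuclear-dominated)
    - radiative     = ``B_EE * c_e + B_EN * c_n`` + noise (extranuclear)
    - scattering    = smoothed ``(c_n + c_e)`` with multiplicative speckle

    Vessels are bright blobs folded into the extranuclear map, so they
    appear strongly in the radiative and scattering channels and weakly
    (via cross-talk) in the non-radiative channel, while ``c_n`` remains
    positive exactly where nuclei were drawn.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    c_n, n_nuclei = _draw_nuclei(rng, spec)

    cytoplasm = ndimage.gaussian_filter(rng.standard_normal((h, w)), 4.0)
    lo, hi = cytoplasm.min(), cytoplasm.max()
    cytoplasm = (cytoplasm - lo) / (hi - lo) if hi > lo else np.zeros((h, w))
    c_e = 0.35 * cytoplasm
    c_e += 0.6 * _draw_fibers(rng, spec)
    c_e += 0.9 * _draw_vessels(rng, spec)
    c_e = np.clip(c_e, 0.0, None)

    sd = spec.noise_sd
    nonrad = A_NN * c_n + A_NE * c_e + sd[0] * rng.standard_normal((h, w))
    rad = B_EE * c_e + B_EN * c_n + sd[1] * rng.standard_normal((h, w))
    scat = ndimage.gaussian_filter(c_n + c_e, 2.0)
    scat = 0.8 * scat * (1.0 + sd[2] * rng.standard_normal((h, w)))  # speckle
    channels = np.clip(np.stack([nonrad, rad, scat]), 0.0, 1.0)
    contrast = ContrastStack(channels, pixel_pitch_nm=spec.pixel_pitch_nm)

    he_true = render_he(c_n, c_e)
    he_true.pixel_pitch_nm = spec.pixel_pitch_nm
    he_moving, true_warp, landmarks = apply_misregistration(
        he_true, spec.warp_amplitude_px, seed=spec.seed + 1
    )
    stream = emit_scan_stream(contrast, jitter_px=0.0, seed=spec.seed + 2)

    return PhantomSample(
        spec=spec,
        contrast=contrast,
        he_true=he_true,
        he_moving=he_moving,
        true_warp=true_warp,
        landmarks_true=landmarks,
        c_nuclear=c_n,
        c_extranuclear=c_e,
        pulse_stream=stream,
        n_nuclei=n_nuclei,
    )


def render_he(
    c_n: np.ndarray,
    c_e: np.ndarray,
    stain_vectors: np.ndarray = DEFAULT_STAIN_VECTORS,
    doses: tuple[float, float] = (HEMATOXYLIN_DOSE, EOSIN_DOSE),
) -> StainedImage:
    """Beer-Lambert H&E forward render.

    Per-pixel optical density ``OD = dose_h * c_n * S_h + dose_e * c_e *
    S_e`` and ``RGB = exp(-OD)``, so zero concentration gives pure white
    and increasing either concentration monotonically darkens every
    channel. ``stain_vectors`` is a (2, 3) nonnegative array of
    (hematoxylin, eosin) absorbance directions.
    """
    c_n = np.asarray(c_n, dtype=np.float64)
    c_e = np.asarray(c_e, dtype=np.float64)
    if c_n.shape != c_e.shape:
        raise ValueError("concentration maps must share a shape")
    if c_n.min() < 0 or c_e.min() < 0:
        raise ValueError("concentrations must be nonnegative")
    stains = np.asarray(stain_vectors, dtype=np.float64)
    if stains.shape != (2, 3) or stains.min() < 0:
        raise ValueError("stain_vectors must be a nonnegative (2, 3) array")
    od = (
        doses[0] * c_n[:, :, None] * stains[0][None, None, :]
        + doses[1] * c_e[:, :, None] * stains[1][None, None, :]
    )
    return StainedImage(np.exp(-od), pixel_pitch_nm=1.0)


def apply_misregistration(
    image: StainedImage,
    warp_amplitude_px: float,
    seed: int,
    grid_step: int = 64,
) -> tuple[StainedImage, SpatialTransform, LandmarkSet]:
    """Create a misregistered copy of an H&E image with known ground truth.

    A control-point grid in the moving frame receives random displacements
    of magnitude at most ``warp_amplitude_px``; a thin-plate spline through
    the displaced grid defines the moving->reference map used to resample
    the image (out-of-bounds fills white). Returns the warped image, the
    true reference->moving transform, and the true landmark pairs.
    """
    if warp_amplitude_px < 0:
        raise ValueError("warp_amplitude_px must be nonnegative")
    h, w = image.shape
    if warp_amplitude_px == 0:
        identity = SpatialTransform("identity")
        pts = _grid_points(h, w, grid_step, margin=8)
        return (
            StainedImage(image.rgb.copy(), image.pixel_pitch_nm),
            identity,
            LandmarkSet(pts, pts.copy()),
        )

    rng = np.random.default_rng(seed)
    margin = int(np.ceil(warp_amplitude_px)) + 8
    mov_pts = _grid_points(h, w, grid_step, margin)
    angle = rng.uniform(0, 2 * np.pi, len(mov_pts))
    mag = warp_amplitude_px * np.sqrt(rng.uniform(0, 1, len(mov_pts)))
    disp = np.column_stack([mag * np.cos(angle), mag * np.sin(angle)])
    ref_pts = mov_pts + disp  # Tinv(mov grid point) = matching ref point

    inverse = fit_transform(LandmarkSet(mov_pts, ref_pts), "thin-plate-spline")
    warped = np.empty_like(image.rgb)
    oob = None
    for c in range(3):
        warped[:, :, c], oob = warp_raster(image.rgb[:, :, c], inverse, (h, w), fill=1.0)
    moving = StainedImage(warped, image.pixel_pitch_nm, oob_mask=oob)

    landmarks = LandmarkSet(ref_pts, mov_pts)
    true_warp = fit_transform(landmarks, "thin-plate-spline")
    return moving, true_warp, landmarks


def _grid_points(h: int, w: int, step: int, margin: int) -> np.ndarray:
    ys = np.linspace(margin, h - 1 - margin, max(2, round((h - 2 * margin) / step) + 1))
    xs = np.linspace(margin, w - 1 - margin, max(2, round((w - 2 * margin) / step) + 1))
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def emit_scan_stream(
    contrast: ContrastStack, jitter_px: float = 0.0, seed: int = 0
) -> PulseStream:
    """Serialize a contrast stack into per-pulse records, one per pixel in
    raster (row-major) order, positions at pixel centers plus optional
    uniform jitter of at most ``jitter_px`` per axis."""
    if jitter_px < 0:
        raise ValueError("jitter_px must be nonnegative")
    h, w = contrast.shape
    pitch_um = contrast.pixel_pitch_nm * 1e-3
    cols = np.tile(np.arange(w), h).astype(np.float64)
    rows = np.repeat(np.arange(h), w).astype(np.float64)
    x = contrast.origin_um[0] + (cols + 0.5) * pitch_um
    y = contrast.origin_um[1] + (rows + 0.5) * pitch_um
    if jitter_px > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.uniform(-jitter_px, jitter_px, h * w) * pitch_um
        y = y + rng.uniform(-jitter_px, jitter_px, h * w) * pitch_um
    feats = contrast.channels.reshape(3, -1).T.copy()
    return PulseStream(x, y, feats)
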