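"""Landmark-based co-registration of H&E images onto the TA-PARS frame.

The multi-contrast stack is the reference frame (all its channels are
intrinsically registered, so only the non-radiative channel is used for
matching); the brightfield H&E image is the moving image. Registration is
control-point based: coarse pitch matching, normalized-cross-correlation
refinement of landmark pairs, a fitted non-rigid transform (thin-plate
spline by default, exact at its landmarks and bending-energy minimal
elsewhere), and inverse-mapping bilinear resampling of the H&E image onto
the reference grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage.transform import rescale

from .core import ContrastStack, StainedImage

__all__ = [
    "LandmarkSet",
    "SpatialTransform",
    "match_fov",
    "refine_landmarks",
    "fit_transform",
    "warp_image",
    "auto_landmarks",
    "register_pair",
    "DegenerateLandmarksError",
]


class DegenerateLandmarksError(ValueError):
    """Landmark configuration too degenerate to fit the requested family."""


@dataclass
class LandmarkSet:
    """Paired control points: reference-frame and moving-frame (x, y).

    ``ref`` and ``mov`` are (N, 2) arrays in pixel coordinates of their
    respective frames.
    """

    ref: np.ndarray
    mov: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.atleast_2d(np.asarray(self.ref, dtype=np.float64))
        self.mov = np.atleast_2d(np.asarray(self.mov, dtype=np.float64))
        if self.ref.shape != self.mov.shape or self.ref.shape[1] != 2:
            raise ValueError("ref and mov must both have shape (N, 2)")

    def __len__(self) -> int:
        return len(self.ref)

    @property
    def pairs(self) -> list[tuple[tuple[float, float], tuple[float, float]]]:
        return [
            ((float(r[0]), float(r[1])), (float(m[0]), float(m[1])))
            for r, m in zip(self.ref, self.mov)
        ]

    def save(self, path: str | Path) -> None:
        header = "x_ref,y_ref,x_mov,y_mov"
        np.savetxt(
            path,
            np.hstack([self.ref, self.mov]),
            delimiter=",",
            header=header,
            comments="",
        )

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkSet":
        data = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
        return cls(data[:, :2], data[:, 2:4])


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r = 0.5 r^2 log r^2, with U(0) = 0
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = 0.5 * r2[nz] * np.log(r2[nz])
    return out


@dataclass
class SpatialTransform:
    """Mapping from reference-frame to moving-frame pixel coordinates.

    Families: ``identity``; ``affine`` (6 parameters per axis pair, least
    squares); ``thin-plate-spline`` (exact interpolation at its defining
    landmarks, minimal bending energy elsewhere).
    """

    family: str
    parameters: dict = field(default_factory=dict)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if self.family == "identity":
            return pts.copy()
        if self.family == "affine":
            a = np.asarray(self.parameters["matrix"], dtype=np.float64)  # (3, 2)
            return np.hstack([pts, np.ones((len(pts), 1))]) @ a
        if self.family == "thin-plate-spline":
            src = np.asarray(self.parameters["source_points"], dtype=np.float64)
            w = np.asarray(self.parameters["weights"], dtype=np.float64)  # (N+3, 2)
            d2 = ((pts[:, None, :] - src[None, :, :]) ** 2).sum(-1)
            basis = np.hstack([_tps_kernel(d2), np.ones((len(pts), 1)), pts])
            return basis @ w
        raise ValueError(f"unknown transform family {self.family!r}")

    def save(self, path: str | Path) -> None:
        params = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.parameters.items()
        }
        Path(path).write_text(yaml.safe_dump({"family": self.family, "parameters": params}))

    @classmethod
    def load(cls, path: str | Path) -> "SpatialTransform":
        doc = yaml.safe_load(Path(path).read_text())
        params = {k: np.asarray(v) for k, v in doc["parameters"].items()}
        return cls(doc["family"], params)


def match_fov(reference: ContrastStack, moving: StainedImage) -> StainedImage:
    """Resample the moving image so its pixel pitch matches the reference.

    Bilinear; a moving image at 500 nm pitch against a 250 nm reference
    doubles in pixel dimensions. Pitch metadata must be present on both.
    """
    if getattr(reference, "pixel_pitch_nm", None) is None or getattr(
        moving, "pixel_pitch_nm", None
    ) is None:
        raise ValueError("pixel pitch metadata required on both images")
    ratio = moving.pixel_pitch_nm / reference.pixel_pitch_nm
    if np.isclose(ratio, 1.0):
        return StainedImage(moving.rgb.copy(), reference.pixel_pitch_nm)
    out = rescale(moving.rgb, ratio, order=1, channel_axis=2, anti_aliasing=ratio < 1)
    return StainedImage(np.clip(out, 0.0, 1.0), reference.pixel_pitch_nm)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def _parabolic_delta(s_minus: float, s0: float, s_plus: float) -> float:
    """Subpixel peak offset from three NCC samples (0 when not concave)."""
    if not (np.isfinite(s_minus) and np.isfinite(s_plus)):
        return 0.0
    denom = s_minus - 2.0 * s0 + s_plus
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (s_minus - s_plus) / denom, -0.5, 0.5))


def refine_landmarks(
    reference_channel: np.ndarray,
    moving: np.ndarray,
    landmarks: LandmarkSet,
    window_px: int = 21,
    search_px: int = 5,
    subpixel: bool = False,
    return_scores: bool = False,
):
    """Fine-tune moving landmarks by local normalized cross-correlation.

    For each pair, a ``window_px`` square around the reference point is
    compared against the moving image at every integer offset within
    ``+-search_px`` of the current moving point; the point is shifted to the
    best-NCC offset, ties broken toward zero shift. Points whose windows are
    flat (zero variance) or would leave the image are returned unchanged
    with a warning. With ``subpixel=True`` the integer peak is refined by a
    separable parabolic fit through the neighboring NCC values. With
    ``return_scores=True`` also returns the per-point peak NCC (NaN for
    unmatched points).
    """
    ref = np.asarray(reference_channel, dtype=np.float64)
    mov = np.asarray(moving, dtype=np.float64)
    if mov.ndim == 3:
        mov = mov.mean(axis=2)
    half = window_px // 2
    new_mov = landmarks.mov.copy()
    scores = np.full(len(landmarks), np.nan)

    # offsets sorted by distance from zero so argmax keeps ties at zero shift
    offs = [
        (dy, dx)
        for dy in range(-search_px, search_px + 1)
        for dx in range(-search_px, search_px + 1)
    ]
    offs.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2, abs(o[0]), abs(o[1])))

    for i, ((xr, yr), (xm, ym)) in enumerate(zip(landmarks.ref, landmarks.mov)):
        r0, c0 = int(round(yr)), int(round(xr))
        if not (half <= r0 < ref.shape[0] - half and half <= c0 < ref.shape[1] - half):
            warnings.warn(f"landmark {i}: reference window out of bounds; unchanged")
            continue
        patch = ref[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1]
        if patch.std() == 0:
            warnings.warn(f"landmark {i}: flat reference window; unchanged")
            continue
        rm0, cm0 = int(round(ym)), int(round(xm))

        def score_at(dy: int, dx: int) -> float:
            r, c = rm0 + dy, cm0 + dx
            if not (half <= r < mov.shape[0] - half and half <= c < mov.shape[1] - half):
                return -np.inf
            return _ncc(patch, mov[r - half : r + half + 1, c - half : c + half + 1])

        best, best_off = -np.inf, (0, 0)
        for dy, dx in offs:
            score = score_at(dy, dx)
            if np.isfinite(score) and score > best:
                best, best_off = score, (dy, dx)
        if not np.isfinite(best):
            warnings.warn(f"landmark {i}: flat search region; unchanged")
            continue
        off_y, off_x = float(best_off[0]), float(best_off[1])
        if subpixel:
            off_y += _parabolic_delta(
                score_at(best_off[0] - 1, best_off[1]), best,
                score_at(best_off[0] + 1, best_off[1]),
            )
            off_x += _parabolic_delta(
                score_at(best_off[0], best_off[1] - 1), best,
                score_at(best_off[0], best_off[1] + 1),
            )
        new_mov[i] = (cm0 + off_x, rm0 + off_y)
        scores[i] = best
    result = LandmarkSet(landmarks.ref.copy(), new_mov)
    if return_scores:
        return result, scores
    return result


def fit_transform(landmarks: LandmarkSet, family: str = "thin-plate-spline") -> SpatialTransform:
    """Fit a spatial transform (reference -> moving) to landmark pairs.

    Thin-plate spline (default) interpolates its landmarks exactly; affine
    is a least-squares fit. Degenerate configurations (duplicate points;
    collinear points for families that need a full 2-D basis) raise
    :class:`DegenerateLandmarksError` naming the offending points.
    """
    src, dst = landmarks.ref, landmarks.mov
    n = len(src)

    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    dup = np.argwhere(np.triu(d2 < 1e-12, k=1))
    if len(dup):
        raise DegenerateLandmarksError(
            f"duplicated reference points at index pairs {dup.tolist()}"
        )

    if family == "affine":
        if n < 3:
            raise DegenerateLandmarksError("affine requires at least 3 landmark pairs")
        basis = np.hstack([src, np.ones((n, 1))])
        if np.linalg.matrix_rank(basis) < 3:
            raise DegenerateLandmarksError(f"collinear reference points: {src.tolist()}")
        matrix, *_ = np.linalg.lstsq(basis, dst, rcond=None)
        return SpatialTransform("affine", {"matrix": matrix})

    if family == "thin-plate-spline":
        if n < 4:
            raise DegenerateLandmarksError(
                "thin-plate spline requires at least 4 landmark pairs"
            )
        poly = np.hstack([np.ones((n, 1)), src])
        if np.linalg.matrix_rank(poly) < 3:
            raise DegenerateLandmarksError(f"collinear reference points: {src.tolist()}")
        # [[K, P], [P^T, 0]] [w; a] = [dst; 0]
        system = np.zeros((n + 3, n + 3))
        system[:n, :n] = _tps_kernel(d2)
        system[:n, n:] = poly
        system[n:, :n] = poly.T
        rhs = np.zeros((n + 3, 2))
        rhs[:n] = dst
        try:
            weights = np.linalg.solve(system, rhs)
        except np.linalg.LinAlgError as exc:
            raise DegenerateLandmarksError(f"singular TPS system: {exc}") from exc
        return SpatialTransform(
            "thin-plate-spline", {"source_points": src.copy(), "weights": weights}
        )

    if family == "identity":
        return SpatialTransform("identity")
    raise ValueError(f"unknown transform family {family!r}")


def warp_image(
    moving: StainedImage | np.ndarray,
    transform: SpatialTransform,
    output_shape: tuple[int, int],
    fill: float = 1.0,
) -> StainedImage:
    """Resample the moving image onto the reference grid (inverse mapping).

    For each reference pixel center, the moving image is sampled bilinearly
    at ``transform(x, y)``. Out-of-bounds pixels are filled with ``fill``
    (white by default — the brightfield H&E background) and flagged in the
    returned image's ``oob_mask``.
    """
    if isinstance(moving, StainedImage):
        data, pitch = moving.rgb, moving.pixel_pitch_nm
    else:
        data = np.asarray(moving, dtype=np.float64)
        pitch = 1.0
    if data.ndim == 2:
        out, oob = warp_raster(data, transform, output_shape, fill)
        img = StainedImage(np.repeat(out[:, :, None], 3, axis=2), pitch, oob_mask=oob)
        return img

    h, w = int(output_shape[0]), int(output_shape[1])
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    mapped = transform(pts)
    mx = mapped[:, 0].reshape(h, w)
    my = mapped[:, 1].reshape(h, w)
    oob = _out_of_bounds(mx, my, data.shape)
    mx = np.clip(mx, 0, data.shape[1] - 1)
    my = np.clip(my, 0, data.shape[0] - 1)

    out = np.empty((h, w, data.shape[2]))
    for c in range(data.shape[2]):
        out[:, :, c] = ndimage.map_coordinates(
            data[:, :, c], [my, mx], order=1, mode="constant", cval=fill
        )
    out[oob] = fill
    return StainedImage(out, pitch, oob_mask=oob)


_BOUNDS_EPS = 1e-6  # numerical slack so fitted identity maps stay in-bounds


def _out_of_bounds(mx: np.ndarray, my: np.ndarray, shape: tuple) -> np.ndarray:
    return (
        (mx < -_BOUNDS_EPS)
        | (mx > shape[1] - 1 + _BOUNDS_EPS)
        | (my < -_BOUNDS_EPS)
        | (my > shape[0] - 1 + _BOUNDS_EPS)
    )


def warp_raster(
    raster: np.ndarray,
    transform: SpatialTransform,
    output_shape: tuple[int, int],
    fill: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-channel variant of :func:`warp_image`; returns (warped, oob)."""
    data = np.asarray(raster, dtype=np.float64)
    h, w = int(output_shape[0]), int(output_shape[1])
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    mapped = transform(pts)
    mx = mapped[:, 0].reshape(h, w)
    my = mapped[:, 1].reshape(h, w)
    oob = _out_of_bounds(mx, my, data.shape)
    mx = np.clip(mx, 0, data.shape[1] - 1)
    my = np.clip(my, 0, data.shape[0] - 1)
    out = ndimage.map_coordinates(data, [my, mx], order=1, mode="constant", cval=fill)
    out[oob] = fill
    return out, oob


def auto_landmarks(
    reference_channel: np.ndarray,
    grid_step: int = 64,
    margin: int = 16,
    min_local_sd: float = 0.01,
    window_px: int = 21,
    min_points: int = 8,
) -> LandmarkSet:
    """Automatic control-point candidates on a regular grid.

    Interactive picking is replaced by a grid of candidates filtered by
    local standard deviation (flat windows carry no matchable texture);
    moving points are initialized at the reference positions. If fewer than
    ``min_points`` candidates pass the threshold (small or low-texture
    fields), the ``min_points`` highest-variance candidates are kept
    instead. A file-based manual override is available through
    :meth:`LandmarkSet.load`.
    """
    ref = np.asarray(reference_channel, dtype=np.float64)
    half = window_px // 2
    pts, sds = [], []
    rows = np.arange(margin, ref.shape[0] - margin, grid_step)
    cols = np.arange(margin, ref.shape[1] - margin, grid_step)
    for r in rows:
        for c in cols:
            if not (half <= r < ref.shape[0] - half and half <= c < ref.shape[1] - half):
                continue
            pts.append((c, r))
            sds.append(ref[r - half : r + half + 1, c - half : c + half + 1].std())
    pts = np.asarray(pts, dtype=np.float64)
    sds = np.asarray(sds)
    keep = sds >= min_local_sd
    if keep.sum() < min(min_points, len(pts)):
        keep = np.zeros(len(pts), dtype=bool)
        keep[np.argsort(sds)[::-1][:min_points]] = True
    pts = pts[keep]
    return LandmarkSet(pts, pts.copy())


def _matching_rasters(reference: ContrastStack, moving: StainedImage) -> tuple[np.ndarray, np.ndarray]:
    """Rasters used for landmark matching: the (normalized) non-radiative
    channel against the optical density of the H&E red channel.

    Hematoxylin absorbs strongly in red while eosin barely does, and
    ``-log(red)`` linearizes the Beer-Lambert response, so both rasters are
    approximately linear in the nuclear concentration — the regime where
    normalized cross-correlation is unbiased."""
    nonrad = reference.channels[0]
    match_ref = (nonrad - nonrad.min()) / max(np.ptp(nonrad), 1e-12)
    mov_od = -np.log(np.clip(moving.rgb[:, :, 0], 1e-3, 1.0))
    return match_ref, mov_od


def register_pair(
    reference: ContrastStack,
    moving: StainedImage,
    landmarks: LandmarkSet | None = None,
    search_px: int = 10,
    window_px: int = 25,
    grid_step: int = 32,
    min_local_sd: float = 0.05,
    min_ncc: float = 0.5,
    passes: int = 3,
    phase_half_px: int = 16,
) -> tuple[StainedImage, SpatialTransform, LandmarkSet]:
    """Full registration: pitch match, two-stage landmark refinement,
    thin-plate-spline fit, warp.

    Matching uses the non-radiative channel only (channel 0) against the
    optical density of the H&E red channel (see :func:`_matching_rasters`).
    Stage one finds coarse integer offsets by windowed normalized
    cross-correlation (variance-filtered grid candidates; matches with peak
    NCC below ``min_ncc`` are dropped). The remaining ``passes - 1`` stages
    warp the moving image with the current fit and measure the residual
    displacement at each landmark by upsampled phase cross-correlation on
    Hann-windowed patches, which resolves subpixel shifts accurately once
    the residual warp is locally near-uniform.
    """
    moving = match_fov(reference, moving)
    match_ref, mov_od = _matching_rasters(reference, moving)
    if landmarks is None:
        landmarks = auto_landmarks(
            match_ref, grid_step=grid_step, window_px=window_px, min_local_sd=min_local_sd
        )
    refined, scores = refine_landmarks(
        match_ref, mov_od, landmarks, window_px=window_px, search_px=search_px,
        subpixel=True, return_scores=True,
    )
    keep = scores >= min_ncc
    if keep.sum() >= 4:
        filtered = LandmarkSet(refined.ref[keep], refined.mov[keep])
        try:
            transform = fit_transform(filtered, "thin-plate-spline")
            refined = filtered
        except DegenerateLandmarksError:
            # confident matches alone are degenerate (e.g. collinear on a
            # small field); fall back to the full refined set
            transform = fit_transform(refined, "thin-plate-spline")
    else:
        transform = fit_transform(refined, "thin-plate-spline")

    from skimage.registration import phase_cross_correlation

    h, w = reference.shape
    half = phase_half_px
    hann = np.outer(np.hanning(2 * half), np.hanning(2 * half))
    for _ in range(max(0, passes - 1)):
        registered = warp_image(moving, transform, (h, w))
        reg_od = -np.log(np.clip(registered.rgb[:, :, 0], 1e-3, 1.0))
        new_mov = np.empty_like(refined.mov)
        for i, (x, y) in enumerate(refined.ref):
            r0, c0 = int(round(y)) - half, int(round(x)) - half
            if r0 < 0 or c0 < 0 or r0 + 2 * half > h or c0 + 2 * half > w:
                new_mov[i] = transform(np.array([[x, y]]))[0]
                continue
            pr = match_ref[r0 : r0 + 2 * half, c0 : c0 + 2 * half]
            pm = reg_od[r0 : r0 + 2 * half, c0 : c0 + 2 * half]
            pr = (pr - pr.mean()) * hann
            pm = (pm - pm.mean()) * hann
            (dy, dx), _, _ = phase_cross_correlation(
                pr, pm, upsample_factor=20, normalization=None
            )
            # registered content sits at ref - (dx, dy); map back to moving
            new_mov[i] = transform(np.array([[x - dx, y - dy]]))[0]
        refined = LandmarkSet(refined.ref, new_mov)
        transform = fit_transform(refined, "thin-plate-spline")

    registered = warp_image(moving, transform, reference.shape)
    return registered, transform, refined
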