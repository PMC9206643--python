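"""Reference experiments run on the synthetic phantom.

Two phantom-scale experiments summarize what the pipeline achieves without
any microscope data:

``overfit_bracketing``
    The upper-bound protocol: a colorizer trained and evaluated on the
    same tiles brackets attainable quality from above; a second model
    trained with an evaluation subset held out measures generalization on
    exactly those tiles. Comparing both on the same tiles isolates the
    effect of having seen them from tile-content difficulty.

``registration_recovery``
    A phantom with a known smooth warp is registered back; landmark
    residuals are measured against the exact inverse warp the phantom
    applied, and image recovery as interior mean absolute error.
"""

from __future__ import annotations

import numpy as np

from .colorizer import TrainConfig, train, make_training_pairs
from .evaluation import LAB_RANGES, rgb_to_lab, ssim
from .phantom import PhantomSpec, sample_phantom
from .preprocess import prepare_input
from .registration import LandmarkSet, fit_transform, register_pair
from .tiling import plan_tiles

__all__ = ["lab_ssim_tiles", "overfit_bracketing", "registration_recovery"]


def lab_ssim_tiles(pred_tiles: np.ndarray, true_tiles: np.ndarray) -> float:
    """Mean Lab-space SSIM over channel-first RGB tile pairs."""
    vals = []
    for p, t in zip(pred_tiles, true_tiles):
        lp = rgb_to_lab(np.clip(p, 0, 1).transpose(1, 2, 0).astype(np.float64))
        lt = rgb_to_lab(np.clip(t, 0, 1).transpose(1, 2, 0).astype(np.float64))
        vals.append(
            np.mean([ssim(lp[:, :, k], lt[:, :, k], 7, LAB_RANGES[k]) for k in range(3)])
        )
    return float(np.mean(vals))


def _predict(bundle, tiles: np.ndarray, batch: int = 16) -> np.ndarray:
    gen = bundle.build_generator()
    return np.concatenate(
        [gen.forward(tiles[i : i + batch]) for i in range(0, len(tiles), batch)]
    )


def overfit_bracketing(
    seed: int,
    size_px: int = 512,
    tile_px: int = 64,
    n_eval_tiles: int = 16,
    max_epochs: int = 100,
) -> dict:
    """Upper-bound vs generalization Lab SSIM on one phantom.

    Returns overfit SSIM (model trained on every tile, scored on the
    evaluation subset), held-out SSIM (model that never saw the evaluation
    subset, scored on it), and the overfit model's SSIM on all its
    training tiles.
    """
    sample = sample_phantom(PhantomSpec(height_px=size_px, width_px=size_px, seed=seed))
    norm = prepare_input(sample.contrast)
    grid = plan_tiles(norm.shape, tile_px, 0.0)
    x, y = make_training_pairs(norm, sample.he_true, grid)

    order = np.random.default_rng(seed).permutation(len(x))
    eval_idx, rest_idx = order[:n_eval_tiles], order[n_eval_tiles:]

    config = dict(
        max_epochs=max_epochs, patience_epochs=max_epochs, batch_size=4,
        seed=seed, depth=3, base_width=8, disc_base_width=8, lr=1e-3,
    )
    upper = train((x, y), None, TrainConfig(**config))
    general = train((x[rest_idx], y[rest_idx]), None, TrainConfig(**config))

    return {
        "overfit_ssim": lab_ssim_tiles(_predict(upper, x[eval_idx]), y[eval_idx]),
        "heldout_ssim": lab_ssim_tiles(_predict(general, x[eval_idx]), y[eval_idx]),
        "train_tiles_ssim": lab_ssim_tiles(_predict(upper, x), y),
        "n_tiles": int(len(x)),
        "n_train_tiles_general": int(len(rest_idx)),
    }


def registration_recovery(
    seed: int,
    size_px: int = 256,
    warp_amplitude_px: float = 5.0,
    search_px: int = 8,
    grid_step: int = 32,
) -> dict:
    """Recover a known phantom warp; residuals against the exact inverse."""
    sample = sample_phantom(
        PhantomSpec(height_px=size_px, width_px=size_px,
                    warp_amplitude_px=warp_amplitude_px, seed=seed)
    )
    registered, _, landmarks = register_pair(
        sample.contrast, sample.he_moving, search_px=search_px, grid_step=grid_step
    )
    # the exact inverse: the TPS the phantom resampled with, reconstructed
    # from the true landmark pairs (same linear system, swapped roles)
    true_inverse = fit_transform(
        LandmarkSet(sample.landmarks_true.mov, sample.landmarks_true.ref)
    )
    residuals = np.linalg.norm(true_inverse(landmarks.mov) - landmarks.ref, axis=1)
    margin = int(np.ceil(warp_amplitude_px)) + 8
    interior = np.s_[margin:-margin, margin:-margin]
    mae = float(np.abs(registered.rgb[interior] - sample.he_true.rgb[interior]).mean())
    return {
        "mean_residual_px": float(residuals.mean()),
        "max_residual_px": float(residuals.max()),
        "interior_mae_frac": mae,
        "n_landmarks": int(len(landmarks)),
    }
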