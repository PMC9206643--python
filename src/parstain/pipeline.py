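"""End-to-end orchestration: phantom -> registration -> training -> metrics.

A run is a directory of per-stage artifacts (images as TIFF, landmarks and
pulse streams as CSV, configs as YAML, metrics as JSON) plus a structured
log with per-stage timing. Stages communicate only through these files, so
a run is resumable per stage: existing stage outputs are reused unless
``force`` is set, and deleting an intermediate and resuming reproduces the
downstream outputs in deterministic mode.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import acquisition, colorizer, evaluation, phantom, preprocess, registration, tiling
from .core import ContrastStack, StainedImage, read_contrast_stack, read_stained_image

__all__ = ["RunConfig", "run_pipeline", "make_fixture", "FIXTURES"]

logger = logging.getLogger("parstain")

STAGES = (
    "phantom",
    "acquisition",
    "registration",
    "preprocess",
    "tiling",
    "train",
    "colorize",
    "evaluate",
)


@dataclass
class RunConfig:
    """One reproducible pipeline run (single YAML document).

    The global ``seed`` is propagated to every stochastic stage with fixed
    offsets so stages stay independently reproducible.
    """

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    use_acquisition: bool = True
    phantom_spec: dict = field(default_factory=dict)
    tile_px: int = 64
    overlap_frac: float = 0.5
    train: dict = field(default_factory=dict)
    val_fraction: float = 0.2
    n_patches: int = 200
    patch_px: int = 64
    registration_search_px: int = 10
    registration_grid_step: int = 32

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)

    def save(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(doc))


def _stage_done(run_dir: Path, stage: str) -> bool:
    return (run_dir / stage / ".done").exists()


def _mark_done(run_dir: Path, stage: str) -> None:
    (run_dir / stage / ".done").write_text("ok")


def run_pipeline(config: RunConfig, run_dir: str | Path, force: bool = False) -> Path:
    """Execute the selected stages, writing artifacts under ``run_dir``.

    Returns the run directory; the final metrics land in
    ``run_dir/evaluate/metrics.json``. A failing stage halts the run with
    a stage-tagged error; prior stage outputs are retained.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.save(run_dir / "run_config.yaml")
    timings: dict[str, float] = {}

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _run_stage(stage, config, run_dir, state, force)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", stage, timings[stage])

    (run_dir / "timings.json").write_text(json.dumps(timings, indent=2))
    return run_dir


def _run_stage(stage: str, config: RunConfig, run_dir: Path, state: dict, force: bool) -> None:
    out = run_dir / stage
    out.mkdir(exist_ok=True)

    if stage == "phantom":
        if _stage_done(run_dir, stage) and not force:
            state["sample"] = None  # will reload lazily below
        else:
            spec = phantom.PhantomSpec(**{**config.phantom_spec, "seed": config.seed})
            sample = phantom.sample_phantom(spec)
            sample.save(out)
            _mark_done(run_dir, stage)
            state["sample"] = sample
        if state.get("sample") is None:
            spec = phantom.PhantomSpec.load(out / "spec.yaml")
            state["sample"] = phantom.sample_phantom(spec)  # deterministic rebuild
        sample = state["sample"]
        state["contrast"] = sample.contrast
        state["he_moving"] = sample.he_moving
        state["he_true"] = sample.he_true
        return

    if stage == "acquisition":
        if not config.use_acquisition:
            return
        src = state["contrast"]
        if _stage_done(run_dir, stage) and not force:
            state["contrast"] = read_contrast_stack(out / "reconstructed.tiff")
            return
        stream = phantom.emit_scan_stream(src, jitter_px=0.0, seed=config.seed + 2)
        acquisition.write_pulse_stream(stream, out / "pulse_stream.csv")
        recon = acquisition.reconstruct_grid(
            stream, src.pixel_pitch_nm, src.shape, src.origin_um
        )
        recon.save(out / "reconstructed.tiff")
        _mark_done(run_dir, stage)
        state["contrast"] = read_contrast_stack(out / "reconstructed.tiff")
        return

    if stage == "registration":
        if _stage_done(run_dir, stage) and not force:
            state["he_registered"] = read_stained_image(out / "he_registered.tiff")
            return
        registered, transform, landmarks = registration.register_pair(
            state["contrast"],
            state["he_moving"],
            search_px=config.registration_search_px,
            grid_step=config.registration_grid_step,
        )
        registered.save(out / "he_registered.tiff")
        transform.save(out / "transform.yaml")
        landmarks.save(out / "landmarks.csv")
        _mark_done(run_dir, stage)
        # downstream stages consume the file artifact (8-bit), not the
        # in-memory float image, so resumed runs are bit-identical
        state["he_registered"] = read_stained_image(out / "he_registered.tiff")
        return

    if stage == "preprocess":
        if _stage_done(run_dir, stage) and not force:
            state["normalized"] = preprocess.NormalizedStack.load(out / "normalized.tiff")
            return
        norm = preprocess.prepare_input(state["contrast"])
        norm.save(out / "normalized.tiff")
        _mark_done(run_dir, stage)
        state["normalized"] = preprocess.NormalizedStack.load(out / "normalized.tiff")
        return

    if stage == "tiling":
        grid = tiling.plan_tiles(
            state["normalized"].shape, config.tile_px, config.overlap_frac
        )
        grid.save(out / "grid.yaml")
        _mark_done(run_dir, stage)
        state["grid"] = grid
        return

    if stage == "train":
        if _stage_done(run_dir, stage) and not force:
            state["bundle"] = colorizer.ModelBundle.load(out / "bundle")
            return
        target = state.get("he_registered", state.get("he_true"))
        x, y = colorizer.make_training_pairs(state["normalized"], target, state["grid"])
        rng = np.random.default_rng(config.seed + 10)
        order = rng.permutation(len(x))
        n_val = max(1, int(round(config.val_fraction * len(x)))) if len(x) > 1 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        tcfg = colorizer.TrainConfig(**{**config.train, "seed": config.seed + 10})
        bundle = colorizer.train(
            (x[train_idx], y[train_idx]),
            (x[val_idx], y[val_idx]) if n_val else None,
            tcfg,
            provenance=state["normalized"].provenance,
        )
        bundle.save(out / "bundle")
        _mark_done(run_dir, stage)
        state["bundle"] = bundle
        return

    if stage == "colorize":
        if _stage_done(run_dir, stage) and not force:
            state["virtual_he"] = read_stained_image(out / "virtual_he.tiff")
            return
        virtual = colorizer.colorize(state["bundle"], state["normalized"], state["grid"])
        virtual.save(out / "virtual_he.tiff")
        _mark_done(run_dir, stage)
        state["virtual_he"] = read_stained_image(out / "virtual_he.tiff")
        return

    if stage == "evaluate":
        target = state.get("he_registered", state.get("he_true"))
        report = evaluation.evaluate_pair(
            state["virtual_he"],
            target,
            n_patches=config.n_patches,
            patch_px=config.patch_px,
            seed=config.seed + 20,
        )
        report.to_json(out / "metrics.json")
        (out / "metrics.txt").write_text(str(report) + "\n")
        _mark_done(run_dir, stage)
        state["report"] = report
        return

    raise ValueError(f"unknown stage {stage!r}")


# --- canonical small test inputs -------------------------------------------


def _fixture_ramp200(directory: Path) -> list[Path]:
    ramp = np.linspace(0.0, 1.0, 200).reshape(1, -1)
    path = directory / "ramp200.csv"
    np.savetxt(path, ramp, delimiter=",")
    return [path]

def _fixture_checkerboard(directory: Path) -> list[Path]:
    board = np.indices((16, 16)).sum(axis=0) % 2
    path = directory / "checkerboard16.csv"
    np.savetxt(path, board, fmt="%d", delimiter=",")
    return [path]

def _fixture_phantom_s1(directory: Path) -> list[Path]:
    spec = phantom.PhantomSpec(height_px=512, width_px=512, seed=1)
    sample = phantom.sample_phantom(spec)
    target = directory / "phantom-s1"
    sample.save(target)
    return sorted(target.iterdir())


FIXTURES = {
    "ramp200": _fixture_ramp200,
    "checkerboard": _fixture_checkerboard,
    "phantom-s1": _fixture_phantom_s1,
}


def make_fixture(name: str, directory: str | Path = ".") -> list[Path]:
    """Write a named canonical test input; repeatable byte-identically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder(directory)
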