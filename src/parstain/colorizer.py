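"""Conditional-GAN colorizer: normalized contrast tiles -> H&E RGB tiles.

A pix2pix-style pair of networks is trained adversarially on co-registered
patch pairs: a U-Net generator (encoder-decoder with mirrored skip
connections, sigmoid-bounded RGB output) learns the statistical mapping
from the 3-channel contrast representation to the H&E color domain, while
a patch-level discriminator scores overlapping receptive fields of the
(input, RGB) channel concatenation as real or fake. The generator objective
combines the adversarial term with an L1 fidelity term (weight
``lambda_l1``, default 100); the discriminator minimizes classification
error. Training runs to ``max_epochs`` (500 at full scale) with early
stopping when the validation generator loss stops improving, and keeps the
best-validation parameters. Whole-image inference tiles the input,
colorizes each tile, and blends with raised-cosine stitching.
"""

from __future__ import annotations

import copy
import csv
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .core import StainedImage
from .preprocess import NormalizedStack
from .tiling import TileGrid, extract_tiles, stitch_tiles

__all__ = [
    "GeneratorNet",
    "DiscriminatorNet",
    "TrainConfig",
    "ModelBundle",
    "discriminator_loss",
    "generator_loss",
    "train",
    "colorize",
    "make_training_pairs",
]


class GeneratorNet:
    """U-Net generator: 3-channel stack in, bounded 3-channel RGB out.

    ``depth`` downsampling stages (stride-2 convs), nearest-upsample +
    conv decoding with skip concatenation at every resolution, sigmoid
    output so predictions stay in [0, 1] for arbitrary finite input.
    """

    def __init__(self, depth: int = 3, base_width: int = 16, in_ch: int = 3,
                 out_ch: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.depth, self.base_width = depth, base_width
        w = base_width
        self.inc = nn.Conv2d(in_ch, w, 3, rng=rng)
        self.inc_act = nn.LeakyReLU()
        self.downs, self.down_acts = [], []
        for i in range(depth):
            self.downs.append(nn.Conv2d(w * 2**i, w * 2 ** (i + 1), 3, stride=2, rng=rng))
            self.down_acts.append(nn.LeakyReLU())
        self.bott = nn.Conv2d(w * 2**depth, w * 2**depth, 3, rng=rng)
        self.bott_act = nn.LeakyReLU()
        self.ups, self.up_acts, self.merges, self.merge_acts = [], [], [], []
        for i in reversed(range(depth)):
            self.ups.append(nn.Conv2d(w * 2 ** (i + 1), w * 2**i, 3, rng=rng))
            self.up_acts.append(nn.LeakyReLU())
            self.merges.append(nn.Conv2d(2 * w * 2**i, w * 2**i, 3, rng=rng))
            self.merge_acts.append(nn.LeakyReLU())
        self.upsample = [nn.UpsampleNearest2() for _ in range(depth)]
        self.outc = nn.Conv2d(w, out_ch, 3, rng=rng)
        self.out_act = nn.Sigmoid()

    def param_layers(self) -> list[nn.Layer]:
        return [self.inc, *self.downs, self.bott, *self.ups, *self.merges, self.outc]

    def zero_grad(self) -> None:
        for layer in self.param_layers():
            layer.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        a = self.inc_act.forward(self.inc.forward(x))
        skips.append(a)
        for conv, act in zip(self.downs, self.down_acts):
            a = act.forward(conv.forward(a))
            skips.append(a)
        a = self.bott_act.forward(self.bott.forward(a))
        for j, i in enumerate(reversed(range(self.depth))):
            a = self.upsample[j].forward(a)
            a = self.up_acts[j].forward(self.ups[j].forward(a))
            a = np.concatenate([a, skips[i]], axis=1)
            a = self.merge_acts[j].forward(self.merges[j].forward(a))
        return self.out_act.forward(self.outc.forward(a))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w = self.base_width
        da = self.outc.backward(self.out_act.backward(dy))
        dskips: list[np.ndarray | None] = [None] * (self.depth + 1)
        # decoder stage j (forward order) consumed skips[depth - 1 - j];
        # walk the stages in reverse: layer index jr, skip resolution j.
        for j in range(self.depth):
            jr = self.depth - 1 - j
            da = self.merges[jr].backward(self.merge_acts[jr].backward(da))
            ch = w * 2**j  # channels of the up path at this resolution
            d_up, d_skip = da[:, :ch], da[:, ch:]
            dskips[j] = d_skip
            d_up = self.ups[jr].backward(self.up_acts[jr].backward(d_up))
            da = self.upsample[jr].backward(d_up)
        da = self.bott.backward(self.bott_act.backward(da))
        for i in reversed(range(self.depth)):
            if dskips[i + 1] is not None:
                da = da + dskips[i + 1]
            da = self.downs[i].backward(self.down_acts[i].backward(da))
        if dskips[0] is not None:
            da = da + dskips[0]
        return self.inc.backward(self.inc_act.backward(da))


class DiscriminatorNet:
    """Patch-level classifier on the (stack, RGB) channel concatenation.

    Three strided/valid-ish convolutions produce a 2-D logit map spatially
    smaller than the input; each score depends only on a bounded receptive
    field, so real/fake decisions are local texture judgements.
    """

    def __init__(self, base_width: int = 16, in_ch: int = 6,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.base_width = base_width
        self.net = nn.Sequential(
            nn.Conv2d(in_ch, base_width, 4, stride=2, pad=1, rng=rng),
            nn.LeakyReLU(),
            nn.Conv2d(base_width, base_width * 2, 4, stride=2, pad=1, rng=rng),
            nn.LeakyReLU(),
            nn.Conv2d(base_width * 2, 1, 4, stride=1, pad=1, rng=rng),
        )

    def param_layers(self) -> list[nn.Layer]:
        return self.net.param_layers()

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)


# --- public loss surface (on post-sigmoid probability maps) -----------------

_EPS = 1e-12


def _bce_prob(p: np.ndarray, target: float) -> float:
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    return float(np.mean(-(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))))


def discriminator_loss(score_real: np.ndarray, score_fake: np.ndarray) -> float:
    """Mean BCE with targets 1 (real scores) and 0 (fake scores), summed.

    Perfect discrimination (real scores 1, fake scores 0) drives the loss
    to 0; a maximally confused discriminator scoring everything 0.5 sits at
    2 ln 2.
    """
    score_real, score_fake = np.asarray(score_real), np.asarray(score_fake)
    if score_real.shape != score_fake.shape:
        raise ValueError("score maps must share a shape")
    return _bce_prob(score_real, 1.0) + _bce_prob(score_fake, 0.0)


def generator_loss(score_fake: np.ndarray, fake_rgb: np.ndarray, real_rgb: np.ndarray,
                   lambda_l1: float = 100.0) -> float:
    """Adversarial term (BCE of fake scores against target 1, i.e. fooling
    the discriminator) plus ``lambda_l1 * mean |fake - real|``."""
    fake_rgb, real_rgb = np.asarray(fake_rgb), np.asarray(real_rgb)
    if fake_rgb.shape != real_rgb.shape:
        raise ValueError("images must share a shape")
    return _bce_prob(score_fake, 1.0) + lambda_l1 * float(np.mean(np.abs(fake_rgb - real_rgb)))


# --- training ---------------------------------------------------------------


@dataclass
class TrainConfig:
    max_epochs: int = 500
    patience_epochs: int = 20
    min_delta: float = 1e-4
    lambda_l1: float = 100.0
    lr: float = 2e-4
    beta1: float = 0.5
    batch_size: int = 8
    seed: int = 0
    val_fraction: float = 0.1
    depth: int = 3
    base_width: int = 16
    disc_base_width: int = 16
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be nonnegative")


@dataclass
class ModelBundle:
    """Trained generator + discriminator with config and history.

    ``history`` holds per-epoch mean discriminator loss, generator loss and
    validation generator loss; ``provenance`` records the preprocessing
    applied to the training inputs so inference can verify it sees
    identically prepared data.
    """

    gen_params: list[dict]
    disc_params: list[dict]
    config: TrainConfig
    history: dict = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    best_epoch: int = 0

    def build_generator(self) -> GeneratorNet:
        gen = GeneratorNet(self.config.depth, self.config.base_width)
        for layer, params in zip(gen.param_layers(), self.gen_params):
            for k, v in params.items():
                layer.params[k] = v.copy()
                layer.grads[k] = np.zeros_like(v)
        return gen

    def build_discriminator(self) -> DiscriminatorNet:
        disc = DiscriminatorNet(self.config.disc_base_width)
        for layer, params in zip(disc.param_layers(), self.disc_params):
            for k, v in params.items():
                layer.params[k] = v.copy()
                layer.grads[k] = np.zeros_like(v)
        return disc

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, p in enumerate(self.gen_params):
            for k, v in p.items():
                arrays[f"gen.{i}.{k}"] = v
        for i, p in enumerate(self.disc_params):
            for k, v in p.items():
                arrays[f"disc.{i}.{k}"] = v
        np.savez(directory / "params.npz", **arrays)
        meta = {"config": asdict(self.config), "provenance": list(self.provenance),
                "best_epoch": int(self.best_epoch)}
        (directory / "config.yaml").write_text(yaml.safe_dump(meta))
        with open(directory / "history.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            keys = list(self.history)
            writer.writerow(["epoch"] + keys)
            for e in range(len(self.history.get("g_loss", []))):
                writer.writerow([e] + [repr(self.history[k][e]) for k in keys])

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        meta = yaml.safe_load((directory / "config.yaml").read_text())
        config = TrainConfig(**meta["config"])
        with np.load(directory / "params.npz") as data:
            gen_params: dict[int, dict] = {}
            disc_params: dict[int, dict] = {}
            for key in data.files:
                which, i, k = key.split(".")
                target = gen_params if which == "gen" else disc_params
                target.setdefault(int(i), {})[k] = data[key]
        history: dict[str, list] = {}
        hist_path = directory / "history.csv"
        if hist_path.exists():
            with open(hist_path) as fh:
                rows = list(csv.reader(fh))
            if len(rows) > 1:
                for j, key in enumerate(rows[0][1:]):
                    history[key] = [float(r[j + 1]) for r in rows[1:]]
        return cls(
            gen_params=[gen_params[i] for i in sorted(gen_params)],
            disc_params=[disc_params[i] for i in sorted(disc_params)],
            config=config,
            history=history,
            provenance=list(meta.get("provenance", [])),
            best_epoch=int(meta.get("best_epoch", 0)),
        )


def _snapshot(net) -> list[dict]:
    return [
        {k: v.copy() for k, v in layer.params.items()} for layer in net.param_layers()
    ]


def _gen_val_loss(gen: GeneratorNet, disc: DiscriminatorNet, xv: np.ndarray,
                  yv: np.ndarray, lambda_l1: float) -> float:
    fake = gen.forward(xv)
    z = disc.forward(np.concatenate([xv, fake], axis=1))
    adv, _ = nn.bce_with_logits(z, 1.0)
    l1, _ = nn.l1_loss(fake, yv)
    return adv + lambda_l1 * l1


def train(
    train_pairs: tuple[np.ndarray, np.ndarray],
    val_pairs: tuple[np.ndarray, np.ndarray] | None,
    config: TrainConfig,
    provenance: list[str] | None = None,
) -> ModelBundle:
    """Adversarial training of the colorizer on paired tiles.

    ``train_pairs``/``val_pairs`` are ``(x, y)`` arrays of shape
    ``(N, 3, t, t)``: x the prepared contrast tiles, y the H&E targets.
    Per batch the discriminator is updated on a real and a generated pair,
    then the generator on the adversarial + L1 objective. Stops early when
    the validation generator loss (training loss if no validation split)
    has not improved by ``min_delta`` for ``patience_epochs`` epochs, and
    returns the best-validation parameters. Fully seeded: identical data,
    config and seed reproduce identical histories.
    """
    x, y = (np.asarray(a, dtype=np.float64) for a in train_pairs)
    if len(x) == 0:
        raise ValueError("training set is empty")
    if x.shape != y.shape or x.shape[2] != x.shape[3]:
        raise ValueError("tiles must be square and pairs equal-shaped")
    if val_pairs is not None:
        xv, yv = (np.asarray(a, dtype=np.float64) for a in val_pairs)
    else:
        xv = yv = None

    rng = np.random.default_rng(config.seed)
    gen = GeneratorNet(config.depth, config.base_width, rng=rng)
    disc = DiscriminatorNet(config.disc_base_width, rng=rng)
    opt_g = nn.Adam(gen.param_layers(), lr=config.lr, beta1=config.beta1)
    opt_d = nn.Adam(disc.param_layers(), lr=config.lr, beta1=config.beta1)

    history = {"d_loss": [], "g_loss": [], "val_g_loss": []}
    best_val = np.inf
    best_params = _snapshot(gen)
    best_disc = _snapshot(disc)
    best_epoch = 0
    stall = 0

    n = len(x)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]

            fake = gen.forward(xb)

            # discriminator update: real pair then generated pair
            disc.zero_grad()
            z_real = disc.forward(np.concatenate([xb, yb], axis=1))
            loss_r, dz_r = nn.bce_with_logits(z_real, 1.0)
            disc.backward(dz_r)
            z_fake = disc.forward(np.concatenate([xb, fake], axis=1))
            loss_f, dz_f = nn.bce_with_logits(z_fake, 0.0)
            disc.backward(dz_f)
            opt_d.step()

            # generator update through the refreshed discriminator
            gen.zero_grad()
            disc.zero_grad()
            z_fake2 = disc.forward(np.concatenate([xb, fake], axis=1))
            adv_loss, dz = nn.bce_with_logits(z_fake2, 1.0)
            d_input = disc.backward(dz)
            d_fake_adv = d_input[:, 3:]
            l1, d_l1 = nn.l1_loss(fake, yb)
            gen.backward(d_fake_adv + config.lambda_l1 * d_l1)
            opt_g.step()

            d_losses.append(loss_r + loss_f)
            g_losses.append(adv_loss + config.lambda_l1 * l1)
            if not np.isfinite(g_losses[-1]) or not np.isfinite(d_losses[-1]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (d={d_losses[-1]}, "
                    f"g={g_losses[-1]}); aborting"
                )

        mean_g = float(np.mean(g_losses))
        history["d_loss"].append(float(np.mean(d_losses)))
        history["g_loss"].append(mean_g)
        if xv is not None and len(xv):
            val_loss = _gen_val_loss(gen, disc, xv, yv, config.lambda_l1)
        else:
            val_loss = mean_g
        history["val_g_loss"].append(val_loss)

        if val_loss < best_val - config.min_delta:
            best_val = val_loss
            best_params = _snapshot(gen)
            best_disc = _snapshot(disc)
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall > config.patience_epochs:
                break

    return ModelBundle(
        gen_params=best_params,
        disc_params=best_disc,
        config=config,
        history=history,
        provenance=list(provenance or []),
        best_epoch=best_epoch,
    )


def make_training_pairs(
    stack: NormalizedStack, he: StainedImage | np.ndarray, grid: TileGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Cut co-registered (input, target) tile arrays from a prepared stack
    and its H&E ground truth; outputs shaped (N, 3, t, t)."""
    he_rgb = he.rgb if isinstance(he, StainedImage) else np.asarray(he)
    x_tiles = extract_tiles(np.moveaxis(stack.channels, 0, 2), grid)
    y_tiles = extract_tiles(he_rgb, grid)
    return (
        np.ascontiguousarray(x_tiles.transpose(0, 3, 1, 2)),
        np.ascontiguousarray(y_tiles.transpose(0, 3, 1, 2)),
    )


def colorize(
    bundle: ModelBundle,
    stack: NormalizedStack,
    grid: TileGrid,
    batch_size: int = 8,
) -> StainedImage:
    """Virtually stain a whole prepared stack.

    Tiles the stack on ``grid``, runs the generator per tile batch, and
    blends predictions with raised-cosine stitching; output RGB lies in
    [0, 1] with the spatial shape of the input. Warns if the stack's
    preprocessing provenance differs from the bundle's training provenance.
    """
    if stack.channels.shape[0] != 3:
        raise ValueError("colorizer input must have 3 channels")
    if bundle.provenance and list(stack.provenance) != list(bundle.provenance):
        warnings.warn(
            "input provenance does not match the bundle's training provenance; "
            f"got {stack.provenance}, trained on {bundle.provenance}"
        )
    gen = bundle.build_generator()
    x_tiles = extract_tiles(np.moveaxis(stack.channels, 0, 2), grid).transpose(0, 3, 1, 2)
    outs = []
    for start in range(0, len(x_tiles), batch_size):
        outs.append(gen.forward(x_tiles[start : start + batch_size]))
    pred = np.concatenate(outs).transpose(0, 2, 3, 1)
    rgb = np.clip(stitch_tiles(pred, grid), 0.0, 1.0)
    return StainedImage(rgb, stack.pixel_pitch_nm or 1.0)
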