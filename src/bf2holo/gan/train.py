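"""Adversarial training loop, checkpoints and full-image inference.

Per iteration, ``batch_size`` bright-field/hologram pairs are cropped at
random positions from randomly selected training pairs; the discriminator
takes one optimizer step (stochastic gradient descent with momentum and
weight decay), then the generator takes one (adaptive-moment/Adam), exactly
alternating.  The generator loss is the RMS image error against the ground
truth plus the adversarial term; the discriminator is trained to score
generated crops toward 0 and recorded crops toward 1.  All randomness (crop
positions, pair selection, weight initialization) flows from one seed, so a
fixed seed reproduces the loss history bit for bit.

The reference protocol follows the recording instrument's scale: 256-pixel
crops, batch 4, generator learning rate 4e-6, discriminator 2e-2 with
momentum 0.9 and weight decay 5e-5, up to 500,000 iterations.  A desk-scale
profile (64-pixel crops, a few thousand iterations, a larger generator
learning rate to compensate for the far shorter schedule) is provided for
CPU-bound smoke runs and is what the test-suite exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ..images import BFImage, Hologram
from ..metrics import mse_rms
from .model import (
    Discriminator,
    DiscriminatorSpec,
    GeneratorSpec,
    MultiscaleGenerator,
    build_multiscale_inputs,
)

__all__ = ["TrainConfig", "Checkpoint", "train", "translate", "load_pairs_from_manifest"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol for the translation GAN."""

    crop_size: int = 256
    batch_size: int = 4
    gen_learning_rate: float = 4e-6
    disc_learning_rate: float = 2e-2
    disc_momentum: float = 0.9
    disc_weight_decay: float = 5e-5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    max_iterations: int = 500_000
    eval_every: int = 1000
    #: multiplicative generator learning-rate decay over the run (1 = none);
    #: the desk-scale profile anneals 10x so late iterations consolidate the
    #: particle structure instead of re-randomizing it
    gen_lr_decay: float = 1.0
    rng_seed: int = 0
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)

    def __post_init__(self) -> None:
        if min(self.gen_learning_rate, self.disc_learning_rate) <= 0:
            raise ValueError("learning rates must be positive")
        if self.crop_size % 16 != 0:
            raise ValueError("crop_size must be divisible by 16 (the coarsest scale factor)")

    @classmethod
    def smoke(cls, max_iterations: int = 5000, rng_seed: int = 0) -> "TrainConfig":
        """Desk-scale CPU profile: small crops, short schedule, rescaled rates.

        The generator rate is raised (far fewer steps than the reference
        schedule) and the discriminator rate lowered so the adversary does
        not saturate before the generator approaches the data manifold.
        """
        return cls(
            crop_size=64,
            gen_learning_rate=5e-4,
            disc_learning_rate=1e-6,
            gen_lr_decay=0.1,
            max_iterations=max_iterations,
            eval_every=max(max_iterations // 10, 1),
            rng_seed=rng_seed,
        )


@dataclass
class Checkpoint:
    """Serialized training state: weights, architecture, config, iteration."""

    gen_weights: list[np.ndarray]
    disc_weights: list[np.ndarray]
    config: TrainConfig
    iteration: int

    def save(self, path: str | Path) -> None:
        arrays = {f"gen_{i}": w for i, w in enumerate(self.gen_weights)}
        arrays.update({f"disc_{i}": w for i, w in enumerate(self.disc_weights)})
        cfg = asdict(self.config)
        cfg["generator"] = asdict(self.config.generator)
        np.savez_compressed(
            path,
            _config=np.frombuffer(repr(cfg).encode(), dtype=np.uint8),
            _iteration=np.array(self.iteration),
            _n_gen=np.array(len(self.gen_weights)),
            _n_disc=np.array(len(self.disc_weights)),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        from ast import literal_eval

        data = np.load(path)
        cfg = literal_eval(bytes(data["_config"]).decode())
        cfg["generator"] = GeneratorSpec(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in cfg["generator"].items()
        })
        config = TrainConfig(**cfg)
        gen = [data[f"gen_{i}"] for i in range(int(data["_n_gen"]))]
        disc = [data[f"disc_{i}"] for i in range(int(data["_n_disc"]))]
        return cls(gen, disc, config, int(data["_iteration"]))


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


class _SGD:
    """SGD with momentum, weight decay and global gradient-norm clipping.

    The clip keeps the unnormalized discriminator from entering the
    exploding-activation regime at the reference learning rate."""

    def __init__(self, params, lr, momentum, weight_decay, clip_norm=1.0):
        self.params = params
        self.lr, self.mu, self.wd = lr, momentum, weight_decay
        self.clip = clip_norm
        self.vel = [np.zeros_like(p) for p, _ in params]

    def step(self):
        total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for _, g in self.params))
        scale = min(1.0, self.clip / (total + 1e-12))
        for (p, g), v in zip(self.params, self.vel):
            v *= self.mu
            v += scale * g + self.wd * p
            p -= (self.lr * v).astype(p.dtype)


def _as_array(img) -> np.ndarray:
    return img.values if hasattr(img, "values") else np.asarray(img, dtype=np.float64)


def _batch_multiscale(crops: np.ndarray) -> list[np.ndarray]:
    """Multiscale NCHW input pyramid for a batch of 2D crops."""
    scales = [[], [], [], []]
    for crop in crops:
        for k, s in enumerate(build_multiscale_inputs(crop)):
            scales[k].append(s)
    return [np.stack(s)[:, None].astype(np.float32) for s in scales]


def _set_weights(net, weights: list[np.ndarray]) -> None:
    params = net.params
    if len(params) != len(weights):
        raise ValueError("checkpoint does not match the network architecture")
    for (p, _), w in zip(params, weights):
        p[...] = w.astype(p.dtype)


def _get_weights(net) -> list[np.ndarray]:
    return [p.copy() for p, _ in net.params]


def _test_l2(gen: MultiscaleGenerator, test_pairs) -> float:
    errs = []
    for bf, holo in test_pairs:
        out = _generator_full_image(gen, _as_array(bf))
        errs.append(mse_rms(out, _as_array(holo)))
    return float(np.mean(errs))


#: inference apron (pixels): the input is edge-padded by this much on every
#: side and the output cropped back, so the convolutional border artifacts
#: (which the coarsest scale spreads ~3 upsampled kernels, i.e. tens of
#: pixels, into the frame) fall outside the returned image
INFERENCE_APRON = 32


def _generator_full_image(gen: MultiscaleGenerator, bf: np.ndarray) -> np.ndarray:
    """Forward one full image through the generator (pad to /16, crop back)."""
    h, w = bf.shape
    a = INFERENCE_APRON
    padded = np.pad(bf, a, mode="edge")
    inputs = [s[None, None].astype(np.float32) for s in build_multiscale_inputs(padded)]
    out = gen.forward(inputs)[0, 0]
    return np.clip(out[a : a + h, a : a + w].astype(np.float64), 0.0, 1.0)


def train(
    pairs,
    cfg: TrainConfig,
    test_pairs=None,
    resume_from: Checkpoint | None = None,
    checkpoint_path: str | Path | None = None,
) -> tuple[Checkpoint, pd.DataFrame]:
    """Train the translation GAN on paired BF/hologram images.

    ``pairs`` (and optional ``test_pairs``) are sequences of
    ``(bf, hologram)`` tuples; entries may be arrays or BFImage/Hologram
    containers.  Pairs whose two images disagree in shape are skipped with a
    warning.  Returns the final checkpoint and a history table with columns
    iteration, loss_g, loss_d, l2_test.
    """
    import warnings as _w

    clean_pairs = []
    for bf, holo in pairs:
        a, b = _as_array(bf), _as_array(holo)
        if a.shape != b.shape:
            _w.warn(f"skipping pair with mismatched shapes {a.shape} vs {b.shape}")
            continue
        clean_pairs.append((a.astype(np.float32), b.astype(np.float32)))
    if not clean_pairs:
        raise ValueError("no usable training pairs")

    rng = np.random.default_rng(cfg.rng_seed)
    gen = MultiscaleGenerator(cfg.generator, rng=np.random.default_rng(int(rng.integers(2**31))))
    disc = Discriminator(
        DiscriminatorSpec(input_size=cfg.crop_size),
        rng=np.random.default_rng(int(rng.integers(2**31))),
    )
    start_iter = 0
    if resume_from is not None:
        _set_weights(gen, resume_from.gen_weights)
        _set_weights(disc, resume_from.disc_weights)
        start_iter = resume_from.iteration

    opt_g = _Adam(gen.params, cfg.gen_learning_rate, cfg.adam_beta1, cfg.adam_beta2)
    opt_d = _SGD(disc.params, cfg.disc_learning_rate, cfg.disc_momentum, cfg.disc_weight_decay)

    c = cfg.crop_size
    history = []
    n_pix = c * c
    for it in range(start_iter, cfg.max_iterations):
        if cfg.gen_lr_decay != 1.0:
            opt_g.lr = cfg.gen_learning_rate * cfg.gen_lr_decay ** (it / max(cfg.max_iterations, 1))
        idx = rng.integers(0, len(clean_pairs), size=cfg.batch_size)
        bf_crops = np.empty((cfg.batch_size, c, c), dtype=np.float32)
        holo_crops = np.empty_like(bf_crops)
        for b, i in enumerate(idx):
            bf_img, holo_img = clean_pairs[i]
            r = int(rng.integers(0, bf_img.shape[0] - c + 1))
            q = int(rng.integers(0, bf_img.shape[1] - c + 1))
            bf_crops[b] = bf_img[r : r + c, q : q + c]
            holo_crops[b] = holo_img[r : r + c, q : q + c]

        inputs = _batch_multiscale(bf_crops)
        generated = gen.forward(inputs)  # B,1,c,c
        truth = holo_crops[:, None]

        # --- discriminator step (generated crops detached) ---
        disc.zero_grads()
        stacked = np.concatenate([generated, truth], axis=0)
        logits = disc.forward_logit(stacked)
        scores = 1.0 / (1.0 + np.exp(-np.clip(logits, -30.0, 30.0)))
        s_gen, s_truth = scores[: cfg.batch_size], scores[cfg.batch_size :]
        loss_d = float(
            np.mean(-np.log1p(-np.clip(s_gen, None, 1 - 1e-7)))
            + np.mean(-np.log(np.clip(s_truth, 1e-7, None)))
        )
        grad_logit = np.concatenate([s_gen, s_truth - 1.0]) / cfg.batch_size
        disc.backward_from_logit(grad_logit)
        opt_d.step()

        # --- generator step (through the updated discriminator) ---
        gen.zero_grads()
        disc.zero_grads()
        logits_g = disc.forward_logit(generated)
        scores_g = 1.0 / (1.0 + np.exp(-np.clip(logits_g, -30.0, 30.0)))
        resid = (generated - truth).astype(np.float64)
        rms = np.sqrt(np.mean(resid.reshape(cfg.batch_size, -1) ** 2, axis=1))
        loss_g = float(np.mean(rms) + np.mean(-np.log(np.clip(scores_g, 1e-7, None))))
        grad_rms = resid / (n_pix * np.maximum(rms, 1e-12))[:, None, None, None] / cfg.batch_size
        grad_adv = disc.backward_from_logit((scores_g - 1.0) / cfg.batch_size)
        gen.backward((grad_rms + grad_adv).astype(np.float32))
        opt_g.step()

        if (it + 1) % cfg.eval_every == 0 or it + 1 == cfg.max_iterations:
            l2 = _test_l2(gen, test_pairs) if test_pairs else np.nan
            history.append(dict(iteration=it + 1, loss_g=loss_g, loss_d=loss_d, l2_test=l2))

    ckpt = Checkpoint(_get_weights(gen), _get_weights(disc), cfg, cfg.max_iterations)
    if checkpoint_path is not None:
        ckpt.save(checkpoint_path)
    return ckpt, pd.DataFrame(history, columns=["iteration", "loss_g", "loss_d", "l2_test"])


def translate(bf, checkpoint: Checkpoint):
    """Translate a bright-field image into a hologram with a trained generator.

    Accepts a BFImage or a bare 2D array; returns a Hologram (provenance
    "generated") when optics metadata is available, else the bare array.
    Dimensions not divisible by 16 are padded and cropped back.
    """
    gen = MultiscaleGenerator(checkpoint.config.generator)
    _set_weights(gen, checkpoint.gen_weights)
    values = _generator_full_image(gen, _as_array(bf))
    if isinstance(bf, BFImage):
        return Hologram(values, bf.optics, provenance="generated", particles=list(bf.particles))
    return values


def load_pairs_from_manifest(manifest_path: str | Path):
    """Load the (bf, hologram) image pairs referenced by a dataset manifest."""
    from ..imgio import read_image

    manifest = pd.read_csv(manifest_path)
    pairs = []
    for _, group in manifest.groupby("pair_id"):
        row = group.iloc[0]
        bf, _ = read_image(row.bf_path)
        holo, _ = read_image(row.holo_path)
        pairs.append((bf, holo))
    return pairs, manifest
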