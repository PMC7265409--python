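"""Validated pipeline configuration and the staged simulate-to-evaluate runner.

A :class:`PipelineConfig` gathers the optical configuration, file paths and
per-stage parameter blocks; it round-trips losslessly through YAML and
rejects unknown keys.  :func:`run_pipeline` executes the requested stages in
order (simulate, train, translate, reconstruct, locate, scatter, evaluate),
writes each stage's outputs and a machine-readable JSON run report with
versions, the seed, per-stage parameters, wall times and output hashes.
Deterministic stages are hash-stable across reruns with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .images import Hologram
from .imgio import read_image, write_image
from .optics import OpticalConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "train", "translate", "reconstruct", "locate", "scatter", "evaluate")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsBlock(_Strict):
    wavelength: float = 0.532
    pixel_pitch: float = 0.53
    image_shape: tuple[int, int] = (256, 256)

    def to_config(self) -> OpticalConfig:
        return OpticalConfig(self.wavelength, self.pixel_pitch, tuple(self.image_shape))


class SimulateBlock(_Strict):
    n_pairs: int = 8
    particle_density: tuple[int, int] = (1, 3)
    depth_range: tuple[float, float] = (0.0, 200.0)
    radius: float = 7.46
    kind: str = "sphere"
    noise_sigma_hologram: float = 0.06
    noise_sigma_bf: float = 0.02


class TrainBlock(_Strict):
    """Desk-scale training defaults (see the methods note on learning rates)."""

    crop_size: int = 64
    max_iterations: int = 2000
    gen_learning_rate: float = 5e-4
    disc_learning_rate: float = 1e-6
    eval_every: int = 500
    test_fraction: float = 0.1


class ReconstructBlock(_Strict):
    z_min: float = 0.0
    z_max: float = 300.0
    dz: float = 1.0
    propagation_sign: int = -1
    subtract_mean: bool = False


class LocateBlock(_Strict):
    min_distance: int = 15
    threshold: float = 0.45
    window_half_size: int = 28
    smooth_sigma: float | None = None
    subtract_mean: bool = True


class ScatterBlock(_Strict):
    prominence: float = 0.35
    orientation: str = "horizontal"


class PipelineConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected on load."""

    stages: list[str] = Field(default_factory=lambda: ["simulate"])
    out_dir: str = "pipeline_out"
    seed: int = 0
    optics: OpticsBlock = Field(default_factory=OpticsBlock)
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    reconstruct: ReconstructBlock = Field(default_factory=ReconstructBlock)
    locate: LocateBlock = Field(default_factory=LocateBlock)
    scatter: ScatterBlock = Field(default_factory=ScatterBlock)
    input_images: list[str] = Field(default_factory=list)
    checkpoint: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write a JSON run report.

    Returns the report dictionary; any stage failure raises with the stage
    name attached.
    """
    for stage in config.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid stages: {_STAGES}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    optics = config.optics.to_config()
    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}

    for stage in config.stages:
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](config, optics, out_dir, state)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        elapsed = time.time() - t0
        hashes = {name: _sha256(Path(p)) for name, p in outputs.items() if Path(p).is_file()}
        params = getattr(config, stage, None)
        report["stages"][stage] = {
            "wall_time_s": round(elapsed, 3),
            "parameters": json.loads(params.model_dump_json()) if params is not None else {},
            "outputs": {k: str(v) for k, v in outputs.items()},
            "sha256": hashes,
        }
        logger.info("stage %s finished in %.2fs (%d outputs)", stage, elapsed, len(outputs))

    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2))
    return report


def _stage_simulate(config: PipelineConfig, optics, out_dir: Path, state: dict) -> dict:
    from .simulate import make_dataset

    blk = config.simulate
    manifest = make_dataset(
        blk.n_pairs,
        out_dir / "dataset",
        seed=config.seed,
        particle_density=tuple(blk.particle_density),
        depth_range=tuple(blk.depth_range),
        optics=optics,
        radius=blk.radius,
        kind=blk.kind,
        noise_sigma_hologram=blk.noise_sigma_hologram,
        noise_sigma_bf=blk.noise_sigma_bf,
    )
    state["manifest"] = manifest
    outputs = {"manifest": out_dir / "dataset" / "manifest.csv"}
    for i, row in manifest.drop_duplicates("pair_id").iterrows():
        outputs[f"bf_{row.pair_id}"] = row.bf_path
        outputs[f"holo_{row.pair_id}"] = row.holo_path
    return outputs


def _stage_train(config: PipelineConfig, optics, out_dir: Path, state: dict) -> dict:
    from .gan import TrainConfig, load_pairs_from_manifest, train

    blk = config.train
    pairs, _ = load_pairs_from_manifest(out_dir / "dataset" / "manifest.csv")
    n_test = max(1, int(len(pairs) * blk.test_fraction))
    cfg = TrainConfig(
        crop_size=blk.crop_size,
        gen_learning_rate=blk.gen_learning_rate,
        disc_learning_rate=blk.disc_learning_rate,
        max_iterations=blk.max_iterations,
        eval_every=blk.eval_every,
        rng_seed=config.seed,
    )
    ckpt_path = out_dir / "checkpoint.npz"
    ckpt, history = train(pairs[n_test:], cfg, test_pairs=pairs[:n_test], checkpoint_path=ckpt_path)
    history_path = out_dir / "training_history.csv"
    history.to_csv(history_path, index=False)
    state["checkpoint"] = ckpt
    return {"checkpoint": ckpt_path, "history": history_path}


def _load_checkpoint(config: PipelineConfig, out_dir: Path, state: dict):
    from .gan import Checkpoint

    if "checkpoint" in state:
        return state["checkpoint"]
    path = config.checkpoint or out_dir / "checkpoint.npz"
    return Checkpoint.load(path)


def _input_holograms(config: PipelineConfig, optics, out_dir: Path, state: dict):
    """Holograms for reconstruction: explicit inputs, else translated, else simulated."""
    if "generated" in state:
        return state["generated"]
    holos = []
    if config.input_images:
        for p in config.input_images:
            values, _ = read_image(p)
            holos.append((Path(p).stem, Hologram(values, optics, provenance="ground_truth")))
    elif "manifest" in state:
        for _, row in state["manifest"].drop_duplicates("pair_id").iterrows():
            values, _ = read_image(row.holo_path)
            holos.append((f"pair{row.pair_id:05d}", Hologram(values, optics, provenance="simulated")))
    else:
        raise ValueError("no input holograms: provide input_images or run simulate/translate first")
    return holos


def _stage_translate(config: PipelineConfig, optics, out_dir: Path, state: dict) -> dict:
    from .gan import translate

    ckpt = _load_checkpoint(config, out_dir, state)
    outputs = {}
    generated = []
    if config.input_images:
        sources = [(Path(p).stem, read_image(p)[0]) for p in config.input_images]
    elif "manifest" in state:
        sources = [
            (f"pair{row.pair_id:05d}", read_image(row.bf_path)[0])
            for _, row in state["manifest"].drop_duplicates("pair_id").iterrows()
        ]
    else:
        raise ValueError("no bright-field inputs for translation")
    gen_dir = out_dir / "generated"
    gen_dir.mkdir(exist_ok=True)
    for name, bf in sources:
        values = translate(bf, ckpt)
        values = values if isinstance(values, np.ndarray) else values.values
        path = gen_dir / f"{name}_generated.tif"
        write_image(values, path)
        outputs[name] = path
        generated.append((name, Hologram(values, optics, provenance="generated")))
    state["generated"] = generated
    return outputs


def _stage_reconstruct(config: PipelineConfig, optics, out_dir: Path, state: dict) -> dict:
    from .reconstruct import reconstruct_volume

    blk = config.reconstruct
    stacks = []
    outputs = {}
    rec_dir = out_dir / "reconstruction"
    rec_dir.mkdir(exist_ok=True)
    for name, holo in _input_holograms(config, optics, out_dir, state):
        stack = reconstruct_volume(
            holo, blk.z_min, blk.z_max, blk.dz,
            propagation_sign=blk.propagation_sign, subtract_mean=blk.subtract_mean,
        )
        import tifffile

        stack_path = rec_dir / f"{name}_stack.tif"
        tifffile.imwrite(stack_path, (np.clip(stack.amplitudes, 0, 2) * 32767).astype(np.uint16))
        sidecar = rec_dir / f"{name}_zvalues.json"
        sidecar.write_text(json.dumps({"z_um": stack.z_values.tolist()}))
        outputs[f"{name}_stack"] = stack_path
        outputs[f"{name}_z"] = sidecar
        stacks.append((name, holo, stack))
    state["stacks"] = stacks
    return outputs


def _locate_stack(config: PipelineConfig, holo, blk):
    from .locate import PeakParams, locate_all
    from .reconstruct import reconstruct_volume

    rec = config.reconstruct
    stack = reconstruct_volume(
        holo, rec.z_min, rec.z_max, rec.dz,
        propagation_sign=rec.propagation_sign, subtract_mean=blk.subtract_mean,
    )
    params = PeakParams(
        min_distance=blk.min_distance, threshold=blk.threshold,
        window_half_size=blk.window_half_size, smooth_sigma=blk.smooth_sigma,
    )
    return stack, locate_all(stack, params)


def _stage_locate(config: PipelineConfig, optics, out_dir: Path, state: dict) -> dict:
    blk = config.locate
    rows = []
    detections = []
    for name, holo in _input_holograms(config, optics, out_dir, state):
        stack, found = _locate_stack(config, holo, blk)
        detections.append((name, holo, stack, found))
        for i, det in enumerate(found):
            rows.append(
                dict(image=name, particle_id=i, x_um=det.x, y_um=det.y, z_um=det.z,
                     peak_intensity=det.peak_intensity)
            )
    path = out_dir / "detections.csv"
    pd.DataFrame(rows, columns=["image", "particle_id", "x_um", "y_um", "z_um", "peak_intensity"]).to_csv(path, index=False)
    state["detections"] = detections
    return {"detections": path}


def _stage_scatter(config: PipelineConfig, optics, out_dir: Path, state: dict) -> dict:
    from .scatter import extract_scatter_map, find_foci

    if "detections" not in state:
        _stage_locate(config, optics, out_dir, state)
    blk = config.scatter
    rows = []
    outputs = {}
    sc_dir = out_dir / "scatter"
    sc_dir.mkdir(exist_ok=True)
    import tifffile

    for name, holo, stack, found in state["detections"]:
        for i, det in enumerate(found):
            smap = extract_scatter_map(stack, det, orientation=blk.orientation)
            smap.foci = find_foci(
                smap, prominence=blk.prominence,
                propagation_sign=config.reconstruct.propagation_sign,
            )
            map_path = sc_dir / f"{name}_p{i}_xz.tif"
            tifffile.imwrite(map_path, smap.intensity.astype(np.float32))
            outputs[f"{name}_p{i}"] = map_path
            for focus in smap.foci:
                rows.append(
                    dict(image=name, particle_id=i, focus_type=focus.kind,
                         focal_length_um=focus.focal_length, z_um=focus.z,
                         peak_intensity=focus.peak_intensity)
                )
    path = sc_dir / "foci.csv"
    pd.DataFrame(rows, columns=["image", "particle_id", "focus_type", "focal_length_um", "z_um", "peak_intensity"]).to_csv(path, index=False)
    outputs["foci"] = path
    return outputs


def _stage_evaluate(config: PipelineConfig, optics, out_dir: Path, state: dict) -> dict:
    """Score generated holograms against simulated ground truth (SNR, SSIM, L2)."""
    from .metrics import fringe_signal_mask, mse_rms, snr, ssim_global

    if "manifest" not in state or "generated" not in state:
        raise ValueError("evaluate requires the simulate and translate stages")
    manifest = state["manifest"]
    generated = dict(state["generated"])
    rows = []
    for pair_id, group in manifest.groupby("pair_id"):
        name = f"pair{pair_id:05d}"
        if name not in generated:
            continue
        truth, _ = read_image(group.iloc[0].holo_path)
        gen = generated[name].values
        pitch = optics.pixel_pitch
        centers = [(r.y_um / pitch - 0.5, r.x_um / pitch - 0.5) for r in group.itertuples()]
        radii = [
            (r.radius_um + 2.0 * np.sqrt(optics.wavelength * r.z_um)) / pitch
            for r in group.itertuples()
        ]
        mask = fringe_signal_mask(truth.shape, centers, radii)
        rows.append(
            dict(
                pair_id=pair_id,
                snr_generated=snr(gen, mask),
                snr_truth=snr(truth, mask),
                ssim=ssim_global(gen, truth),
                l2=mse_rms(gen, truth),
            )
        )
    path = out_dir / "evaluation.csv"
    pd.DataFrame(rows, columns=["pair_id", "snr_generated", "snr_truth", "ssim", "l2"]).to_csv(path, index=False)
    return {"evaluation": path}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "train": _stage_train,
    "translate": _stage_translate,
    "reconstruct": _stage_reconstruct,
    "locate": _stage_locate,
    "scatter": _stage_scatter,
    "evaluate": _stage_evaluate,
}
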