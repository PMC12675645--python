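"""Image/volume readers and writers, run configuration and the pipeline.

Images travel as PNG (8-bit, values assumed in [0, 1] and quantized) or
TIFF (integer types stored as-is, floats as lossless float32), with an
optional JSON sidecar carrying pixel spacing and acquisition metadata.
Volumes can be written as NIfTI (nibabel) or multi-page TIFF.

``run_pipeline`` chains the four workflow parts — training-data
preparation, model training, DES synthesis evaluation, tumor tracking —
under a single master seed that fans out to per-stage seeds through
``derive_seed`` (SeedSequence over the master seed and a stage label hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .des import GridConfig, TrainingPair, generate_dataset
from .harness import (
    default_synthesis_cases,
    desk_model_config,
    desk_phantom_config,
    run_synthesis_eval,
    run_tracking_comparison,
)
from .model import ModelConfig, TrainedSynthesizer, build_model, train
from .phantom import MaterialVolume, PhantomConfig
from .projection import DetectorConfig, RadiographImage

__all__ = [
    "read_image",
    "write_image",
    "read_volume",
    "write_volume",
    "RunConfig",
    "load_run_config",
    "derive_seed",
    "run_pipeline",
]

logger = logging.getLogger("fluorosynth")


def derive_seed(master_seed: int, label: str) -> int:
    """Per-stage seed below 2^31, stable in the master seed and stage label."""
    h = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# images


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(path, image: RadiographImage | np.ndarray) -> Path:
    """Write an image with a JSON metadata sidecar.

    PNG: uint8 stored as-is, floats quantized from [0, 1] to 8 bits.
    TIFF: uint8/uint16 stored as-is, floats stored as float32 (lossless).
    """
    path = Path(path)
    if isinstance(image, RadiographImage):
        pixels, spacing, meta = image.pixels, image.pixel_spacing, image.meta
    else:
        pixels, spacing, meta = np.asarray(image), (1.0, 1.0), {}
    suffix = path.suffix.lower()
    if suffix == ".png":
        if pixels.dtype != np.uint8:
            pixels = np.round(np.clip(pixels, 0.0, 1.0) * 255.0).astype(np.uint8)
        iio.imwrite(path, pixels)
    elif suffix in (".tif", ".tiff"):
        if pixels.dtype not in (np.uint8, np.uint16):
            pixels = pixels.astype(np.float32)
        tifffile.imwrite(path, pixels)
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    clean = {
        k: v
        for k, v in meta.items()
        if isinstance(v, (str, int, float, bool, type(None)))
    }
    _sidecar(path).write_text(
        json.dumps({"pixel_spacing": list(spacing), "meta": clean})
    )
    return path


def read_image(path) -> RadiographImage:
    """Read a PNG/TIFF image (and its sidecar, if present) back.

    8-bit PNGs are returned as floats in [0, 1]; TIFFs at their stored type.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".png":
        pixels = iio.imread(path).astype(np.float64) / 255.0
    elif suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    spacing, meta = (1.0, 1.0), {}
    sc = _sidecar(path)
    if sc.exists():
        d = json.loads(sc.read_text())
        spacing = tuple(d.get("pixel_spacing", spacing))
        meta = d.get("meta", {})
    return RadiographImage(pixels=pixels, pixel_spacing=spacing, meta=meta)


# ---------------------------------------------------------------------------
# volumes


def write_volume(path, volume: MaterialVolume | np.ndarray, spacing=None) -> Path:
    path = Path(path)
    if isinstance(volume, MaterialVolume):
        data, spacing = volume.labels, volume.spacing
    else:
        data, spacing = np.asarray(volume), spacing or (1.0, 1.0, 1.0)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.Nifti1Image(np.asarray(data), np.diag(list(spacing) + [1.0]))
        nib.save(img, path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(data))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return path


def read_volume(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        return np.asarray(nib.load(path).dataobj)
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Master configuration of the four-part pipeline."""

    master_seed: int = 0
    out_dir: str = "fluorosynth_run"
    phantom: dict = field(default_factory=dict)  # PhantomConfig overrides
    dataset: dict = field(default_factory=lambda: {"n_pairs": 500})
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    synthesis_cases: dict = field(default_factory=lambda: {"frames": 30})
    tracking: dict = field(default_factory=lambda: {"n_cases": 10, "frames": 150})
    detector_shape: tuple[int, int] = (64, 64)
    verbosity: int = 1

    _SCHEMA = {
        "master_seed": int,
        "out_dir": str,
        "phantom": dict,
        "dataset": dict,
        "model": dict,
        "synthesis_cases": dict,
        "tracking": dict,
        "detector_shape": (list, tuple),
        "verbosity": int,
    }

    def __post_init__(self):
        for k, t in self._SCHEMA.items():
            if not isinstance(getattr(self, k), t):
                raise ValueError(f"config field {k!r} must be of type {t}")
        self.detector_shape = tuple(self.detector_shape)


def load_run_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    unknown = set(data) - set(RunConfig._SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# dataset loading and the pipeline


def load_dataset(ds_dir) -> list[TrainingPair]:
    """Read a generated (SE, DES) dataset and its manifest back."""
    ds_dir = Path(ds_dir)
    manifest = pd.read_csv(ds_dir / "manifest.csv")
    pairs = []
    for _, row in manifest.iterrows():
        i = int(row["index"])
        se = tifffile.imread(ds_dir / "pairs" / f"{i:06d}_se.tif")
        des = tifffile.imread(ds_dir / "pairs" / f"{i:06d}_des.tif")
        prov = {"phase": int(row["phase"]), "manifest_row": row.to_dict()}
        pairs.append(
            TrainingPair(
                se=RadiographImage(se, (1.0, 1.0), {"kind": "SE"}),
                des=RadiographImage(des, (1.0, 1.0), {"kind": "DES"}),
                provenance=prov,
            )
        )
    return pairs


_STAGES = ("part1", "part2", "part3", "part4")


def run_pipeline(config: RunConfig, resume: str | None = None) -> Path:
    """Execute parts 1–4: dataset, training, synthesis eval, tracking.

    With ``resume='partN'`` the stages before N are skipped when their
    outputs already exist (and are left untouched).  Every stage logs its
    wall time; any failure halts with a stage-named diagnostic.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start_at = _STAGES.index(resume) if resume else 0
    phantom_cfg = desk_phantom_config(**config.phantom)
    detector = DetectorConfig(output_shape=config.detector_shape)
    ds_dir = out / "dataset"
    model_path = out / "model.bin"

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name} failed: {e}") from e
        logger.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)

    if start_at <= 0 or not (ds_dir / "manifest.csv").exists():
        _stage(
            "part1",
            lambda: generate_dataset(
                phantom_cfg,
                GridConfig(),
                ds_dir,
                n_pairs=config.dataset.get("n_pairs", 500),
                master_seed=derive_seed(config.master_seed, "dataset"),
                detector=detector,
            ),
        )

    if start_at <= 1 or not model_path.exists():

        def _part2():
            pairs = load_dataset(ds_dir)
            mc = desk_model_config(
                input_shape=config.detector_shape,
                seed=derive_seed(config.master_seed, "model"),
                **config.model,
            )
            ts = train(build_model(mc), pairs, mc)
            ts.save(model_path)
            pd.DataFrame(ts.history).to_csv(out / "training_log.csv", index=False)

        _stage("part2", _part2)

    def _part3():
        ts = TrainedSynthesizer.load(model_path)
        cases = default_synthesis_cases(
            frames=config.synthesis_cases.get("frames", 30),
            cycles=config.synthesis_cases.get("cycles", 5),
        )
        df = run_synthesis_eval(ts, cases, phantom_cfg, detector)
        df.to_csv(out / "table2.csv", index=False)
        (out / "table2.json").write_text(df.to_json(orient="records", indent=2))

    _stage("part3", _part3)

    def _part4():
        from .harness import make_tracking_cases

        tr = config.tracking
        seed = derive_seed(config.master_seed, "tracking")
        cases = make_tracking_cases(
            tr.get("n_cases", 10),
            seed,
            phantom_cfg,
            frames=tr.get("frames", 150),
            cycles=tr.get("cycles", 5),
        )
        df = run_tracking_comparison(
            cases,
            phantom_cfg,
            DetectorConfig(output_shape=tuple(tr.get("detector_shape", (128, 128)))),
            n_resamples=tr.get("n_resamples", 1000),
            seed=seed,
        )
        df.to_csv(out / "table3.csv", index=False)
        (out / "table3.json").write_text(df.to_json(orient="records", indent=2))

    _stage("part4", _part4)
    return out
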