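"""End-to-end orchestration: phantoms/volumes -> VAE -> classes -> reports.

A run is described by a :class:`RunConfig` (YAML on disk, validated with
pydantic).  Exactly one input mode is active: ``phantom`` (synthetic lesion
stacks generated in-package) or ``volumes`` (co-registered NIfTI trios plus
an ROI mask per lesion).  The pipeline writes every artifact — per-slice
PNGs, the model checkpoint, the loss trace CSV, the latent scatter, the
per-lesion reports, the cohort CSV — plus a manifest with a config echo,
the seed, software versions and content hashes, so a run is reproducible
from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import __version__
from .classify import (
    ClassBoundaries,
    LesionReport,
    calibrate_boundaries,
    classify_points,
    cohort_table,
    score_lesion,
)
from .phantom import LabelledStack, PhantomSpec, generate_phantom, write_stack
from .preprocess import (
    load_contrast_volume,
    load_roi_mask,
    normalize_cohort,
    preprocess_lesion,
    standardize_slice,
)
from .plotting import class_map_strip, latent_scatter, loss_curves
from .vae import TissueVAE, VaeConfig, VAEResults

logger = logging.getLogger("plaquevae")

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


class PhantomLesionConfig(BaseModel):
    lesion_id: str
    class_sequence: list[int]
    noise_sd: float = 0.0
    wall_thickness_px: int = 5

    @field_validator("class_sequence")
    @classmethod
    def _classes_valid(cls, v: list[int]) -> list[int]:
        bad = [i for i, c in enumerate(v) if c not in (1, 2, 3, 4)]
        if bad:
            raise ValueError(f"invalid tissue class at slice indices {bad}")
        if not v:
            raise ValueError("class_sequence must be non-empty")
        return v


class VolumeLesionConfig(BaseModel):
    lesion_id: str
    t1w: str
    t2w: str
    ute: str
    mask: str


class VaeSection(BaseModel):
    preset: Literal["full", "desk"] = "desk"
    encoder_depths: Optional[list[int]] = None
    epochs: Optional[int] = None
    batch_size: Optional[int] = None
    learning_rate: Optional[float] = None
    kl_weight: Optional[float] = None
    latent_dim: int = 2

    def build(self, seed: int) -> VaeConfig:
        overrides = {
            k: v
            for k, v in {
                "encoder_depths": tuple(self.encoder_depths)
                if self.encoder_depths
                else None,
                "epochs": self.epochs,
                "batch_size": self.batch_size,
                "learning_rate": self.learning_rate,
                "kl_weight": self.kl_weight,
            }.items()
            if v is not None
        }
        if self.preset == "desk":
            return VaeConfig.desk_scale(
                seed=seed, latent_dim=self.latent_dim, **overrides
            )
        return VaeConfig(seed=seed, latent_dim=self.latent_dim, **overrides)


class BoundariesSection(BaseModel):
    calibrate: bool = True
    calibration_fraction: float = Field(0.5, gt=0.0, le=1.0)
    x_threshold: float = 0.8
    y_threshold: float = 0.8

    def fixed(self) -> ClassBoundaries:
        return ClassBoundaries(self.x_threshold, self.y_threshold)


class RunConfig(BaseModel):
    """Validated run description; exactly one input mode must be set."""

    out_dir: str
    seed: int = 0
    log_level: str = "INFO"
    phantom: Optional[list[PhantomLesionConfig]] = None
    volumes: Optional[list[VolumeLesionConfig]] = None
    vae: VaeSection = VaeSection()
    boundaries: BoundariesSection = BoundariesSection()

    @model_validator(mode="after")
    def _one_mode(self) -> "RunConfig":
        if (self.phantom is None) == (self.volumes is None):
            raise ValueError(
                "exactly one input mode must be configured: 'phantom' or 'volumes'"
            )
        return self


def load_run_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str) -> None:
    logger.info("=== %s ===", name)


def _gather_phantom_stacks(config: RunConfig) -> list[LabelledStack]:
    stacks = []
    for i, lesion in enumerate(config.phantom):
        spec = PhantomSpec(
            class_sequence=tuple(lesion.class_sequence),
            noise_sd=lesion.noise_sd,
            wall_thickness_px=lesion.wall_thickness_px,
            seed=config.seed * 10007 + i,
        )
        raw = generate_phantom(spec, lesion_id=lesion.lesion_id)
        # same tail of the preprocessing chain as patient data: crop,
        # resize, strip the wall signal
        stacks.append(
            LabelledStack(
                slices=[standardize_slice(sl) for sl in raw.slices],
                labels=list(raw.labels),
                lesion_id=raw.lesion_id,
                meta=raw.meta,
            )
        )
    return stacks


def _gather_volume_stacks(config: RunConfig) -> list[LabelledStack]:
    # cohort-wide normalization, then per-lesion fuse/reslice/crop/filter
    volumes = []
    per_lesion = {}
    for lesion in config.volumes:
        t1 = load_contrast_volume(lesion.t1w, "T1w", lesion.lesion_id)
        t2 = load_contrast_volume(lesion.t2w, "T2w", lesion.lesion_id)
        ute = load_contrast_volume(lesion.ute, "UTE", lesion.lesion_id)
        mask = load_roi_mask(lesion.mask, lesion.lesion_id)
        volumes += [t1, t2, ute]
        per_lesion[lesion.lesion_id] = mask
    normalized = normalize_cohort(volumes)
    by_key = {(v.lesion_id, v.contrast): v for v in normalized}
    stacks = []
    for lesion in config.volumes:
        slices = preprocess_lesion(
            by_key[(lesion.lesion_id, "T1w")],
            by_key[(lesion.lesion_id, "T2w")],
            by_key[(lesion.lesion_id, "UTE")],
            per_lesion[lesion.lesion_id],
        )
        # no ground truth for real volumes; labels filled post-classification
        stacks.append(
            LabelledStack(
                slices=slices,
                labels=[1] * len(slices),
                lesion_id=lesion.lesion_id,
                meta={"ground_truth": False},
            )
        )
    return stacks


def _calibration_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Stratified boolean mask selecting the labelled calibration subset."""
    sel = np.zeros(len(labels), dtype=bool)
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        take = max(1, int(round(fraction * len(idx))))
        sel[rng.choice(idx, size=take, replace=False)] = True
    return sel


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return the run manifest (also written).

    Stages: generate/preprocess -> train -> encode -> classify -> score ->
    report.  Any stage failure aborts with the stage name in the exception.
    """
    logging.basicConfig(
        level=config.log_level.upper(),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "versions": {
            "plaquevae": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
        "outputs": {},
        "stages": [],
    }

    def record(path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    stage = "input"
    try:
        _stage("input")
        phantom_mode = config.phantom is not None
        stacks = (
            _gather_phantom_stacks(config)
            if phantom_mode
            else _gather_volume_stacks(config)
        )
        slices_dir = out / "slices"
        for st in stacks:
            sidecar = write_stack(st, slices_dir)
            record(sidecar)
        manifest["stages"].append("input")

        stage = "train"
        _stage("train")
        all_images = np.concatenate([st.as_array() for st in stacks])
        vae_config = config.vae.build(seed=config.seed)
        model = TissueVAE(all_images, vae_config)
        results = model.fit(
            callback=lambda e, r, k: logger.debug(
                "epoch %d recon %.5f kl %.4f", e, r, k
            )
        )
        ckpt = results.save(out / "vae_checkpoint.npz")
        record(ckpt)
        record(out / "vae_checkpoint.json")
        loss_csv = out / "loss_trace.csv"
        results.loss_trace.to_csv(loss_csv)
        record(loss_csv)
        manifest["stages"].append("train")

        stage = "encode"
        _stage("encode")
        points = results.encode(all_images)
        manifest["stages"].append("encode")

        stage = "classify"
        _stage("classify")
        labels = np.concatenate([np.asarray(st.labels) for st in stacks])
        have_truth = phantom_mode
        if config.boundaries.calibrate and have_truth:
            rng = np.random.default_rng(config.seed)
            cal = _calibration_split(
                labels, config.boundaries.calibration_fraction, rng
            )
            bounds, cal_agreement = calibrate_boundaries(points[cal], labels[cal])
            manifest["calibration"] = {
                "n_calibration": int(cal.sum()),
                "agreement_on_calibration": cal_agreement,
            }
            predicted = classify_points(points, bounds)
            held_out = ~cal
            if held_out.any():
                manifest["calibration"]["agreement_on_held_out"] = float(
                    np.mean(predicted[held_out] == labels[held_out])
                )
        else:
            bounds = config.boundaries.fixed()
            predicted = classify_points(points, bounds)
        (out / "boundaries.json").write_text(json.dumps(bounds.to_dict(), indent=2))
        record(out / "boundaries.json")
        scatter = latent_scatter(points, predicted, bounds, out / "latent_scatter.png")
        record(scatter)
        manifest["stages"].append("classify")

        stage = "score"
        _stage("score")
        reports: list[LesionReport] = []
        offset = 0
        for st in stacks:
            n = len(st)
            rep = score_lesion(predicted[offset : offset + n], st.lesion_id)
            offset += n
            reports.append(rep)
            rp = rep.save_json(out / f"report_{st.lesion_id}.json")
            record(rp)
            record(class_map_strip(rep, out / f"classmap_{st.lesion_id}.png"))
        cohort = cohort_table(reports)
        cohort_csv = out / "cohort.csv"
        cohort.to_csv(cohort_csv, index=False)
        record(cohort_csv)
        record(loss_curves(results.loss_trace, out / "loss_curves.png"))
        manifest["stages"].append("score")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", manifest_path)
    return manifest
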