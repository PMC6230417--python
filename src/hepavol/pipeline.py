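"""End-to-end orchestration: liver -> tumors -> metrics (-> cohort stats).

:class:`RunConfig` carries every tunable of every stage, each defaulting to
the package's documented default, and round-trips through YAML.  A run
directory accumulates stage outputs (NIfTI masks, the classifier JSON, the
per-patient ``record.json`` and a ``run_log.json`` listing every parameter
actually used); re-running with the same config resumes from whatever stage
outputs already exist.

Inputs are either a pair of CT volumes on disk plus seed-slice annotations,
or a ``phantom`` block, in which case the synthetic generator renders the
pair (and its ground truth) first and seeds the liver stage from the truth
mask — the package's self-contained demonstration path.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, cohort, liver, metrics, phantom, texture
from .errors import StageError, ValidationError
from .io import (
    BinaryMask,
    read_cohort,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

__all__ = ["RunConfig", "run_pipeline", "train_on_phantom"]


@dataclass
class RunConfig:
    """Every stage parameter, defaulting to the documented design choices."""

    out_dir: str = "run"
    seed: int = 0
    # inputs: either file paths ...
    pre_volume: str | None = None
    post_volume: str | None = None
    pre_seed_slice: int | None = None
    post_seed_slice: int | None = None
    pre_seed_mask: str | None = None
    post_seed_mask: str | None = None
    # ... or a phantom block (kwargs of PhantomConfig, seed filled from `seed`)
    phantom: dict | None = None
    # liver stage
    liver_k: float = 2.5
    liver_closing_vox: int = 2
    # texture stage
    window: int = 11
    levels: int = 32
    hu_window: tuple[float, float] = (-100.0, 300.0)
    # classifier stage
    hidden_sizes: tuple[int, int] = (16, 8)
    learning_rate: float = 0.5
    momentum: float = 0.9
    epochs: int = 500
    threshold: float = 0.5
    model_path: str | None = None
    train_samples_per_class: int = 3000
    # morphology stage
    tumor_closing_vox: int = 1
    tumor_opening_vox: int = 1
    edits: str | None = None
    # cohort stage
    cohort_table: str | None = None

    def __post_init__(self):
        # canonicalize so a config compares equal after a YAML round trip
        if self.phantom is not None:
            self.phantom = {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.phantom.items()
            }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("hu_window", "hidden_sizes"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["hu_window"] = list(self.hu_window)
        d["hidden_sizes"] = list(self.hidden_sizes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
        return Path(path)


def train_on_phantom(
    config: RunConfig, train_seed: int | None = None
) -> classify.ClassifierModel:
    """Train the voxel classifier on a phantom disjoint from the analysis pair.

    Ground-truth tumor and liver-parenchyma voxels of a freshly generated
    phantom provide the labels; ``train_samples_per_class`` voxels per class
    are subsampled for the full-batch fit.
    """
    pcfg_kwargs = dict(config.phantom or {})
    pcfg_kwargs["seed"] = train_seed if train_seed is not None else config.seed + 1000
    pcfg = phantom.PhantomConfig(**pcfg_kwargs)
    pre, post, truth = phantom.make_phantom(pcfg)

    rng = np.random.default_rng(config.seed)
    n_half = max(config.train_samples_per_class // 2, 1)

    def _sample(mask: np.ndarray) -> np.ndarray:
        coords = np.argwhere(mask)
        n = min(n_half, len(coords))
        return coords[rng.choice(len(coords), size=n, replace=False)]

    # both time points contribute examples so the classifier sees the
    # post-treatment lesion appearance (shifted HU, rescaled size) too
    feats_all, labels_all = [], []
    for vol, tumor_mask in ((pre, truth.tumor_mask_pre), (post, truth.tumor_mask_post)):
        tumor = tumor_mask.data
        parenchyma = truth.liver_mask.data & ~tumor
        coords = np.vstack([_sample(tumor), _sample(parenchyma)])
        labels = np.concatenate(
            [np.ones(min(n_half, int(tumor.sum()))),
             np.zeros(min(n_half, int(parenchyma.sum())))]
        )
        roi = BinaryMask(_coords_to_mask(coords, vol.shape), vol.spacing)
        roi_coords, feats = texture.feature_map(
            vol, roi, window=config.window, levels=config.levels, hu_window=config.hu_window
        )
        index = {tuple(c): i for i, c in enumerate(roi_coords)}
        feats_all.append(feats[[index[tuple(c)] for c in coords]])
        labels_all.append(labels)
    feats = np.vstack(feats_all)
    labels = np.concatenate(labels_all)
    return classify.train_classifier(
        feats,
        labels,
        hidden_sizes=config.hidden_sizes,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        epochs=config.epochs,
        seed=config.seed,
    )


def _coords_to_mask(coords: np.ndarray, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[coords[:, 0], coords[:, 1], coords[:, 2]] = True
    return m


def _segment_tumors(config: RunConfig, vol, liver_mask, model) -> BinaryMask:
    coords, feats = texture.feature_map(
        vol, liver_mask, window=config.window, levels=config.levels, hu_window=config.hu_window
    )
    raw = classify.classify_voxels(
        model, coords, feats, vol.shape, vol.spacing, threshold=config.threshold
    )
    mask = classify.postprocess(raw, config.tumor_closing_vox, config.tumor_opening_vox)
    if config.edits:
        mask = classify.apply_refinement(mask, classify.read_edits(config.edits))
    return mask


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, resuming from existing stage outputs.

    Returns the run directory; ``record.json`` inside it holds the four
    delta statistics and the RECIST category of the pre/post pair.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(config), "stages": {}}

    # ---- inputs -----------------------------------------------------------
    truth = None
    if config.phantom is not None:
        pre_path, post_path = out / "pre.nii.gz", out / "post.nii.gz"
        pcfg = phantom.PhantomConfig(**{**config.phantom, "seed": config.phantom.get("seed", config.seed)})
        pre, post, truth = phantom.make_phantom(pcfg)
        if not pre_path.exists():
            write_volume(pre, pre_path)
            write_volume(post, post_path)
            write_mask(truth.liver_mask, out / "truth_liver.nii.gz")
            write_mask(truth.tumor_mask_pre, out / "truth_tumors_pre.nii.gz")
            write_mask(truth.tumor_mask_post, out / "truth_tumors_post.nii.gz")
        log["stages"]["make-phantom"] = {"seed": pcfg.seed, "shape": list(pcfg.shape)}
    else:
        if not (config.pre_volume and config.post_volume):
            raise StageError("inputs", "need pre_volume/post_volume paths or a phantom block")
        for p in (config.pre_volume, config.post_volume):
            if not Path(p).exists():
                raise StageError("inputs", f"missing volume {p}")
        pre = read_volume(config.pre_volume)
        post = read_volume(config.post_volume)

    # ---- liver ------------------------------------------------------------
    liver_masks = {}
    for tag, vol in (("pre", pre), ("post", post)):
        mask_path = out / f"liver_{tag}.nii.gz"
        if mask_path.exists():
            liver_masks[tag] = read_mask(mask_path)
            continue
        if truth is not None:
            seed_z = int(np.argmax(truth.liver_mask.data.sum(axis=(1, 2))))
            seed_mask = truth.liver_mask.data[seed_z]
        else:
            seed_z = config.pre_seed_slice if tag == "pre" else config.post_seed_slice
            seed_path = config.pre_seed_mask if tag == "pre" else config.post_seed_mask
            if seed_z is None or seed_path is None:
                raise StageError("segment-liver", f"no seed slice/mask for {tag} volume")
            seed_mask = read_mask(seed_path).data[seed_z]
        try:
            mask, model, rng = liver.segment_liver(
                vol, seed_z, seed_mask, k=config.liver_k,
                closing_radius_vox=config.liver_closing_vox, return_details=True,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("segment-liver", str(exc)) from exc
        write_mask(mask, mask_path)
        liver_masks[tag] = mask
        log["stages"][f"segment-liver-{tag}"] = {
            "seed_slice": seed_z,
            "k": config.liver_k,
            "weights": model.weights.tolist(),
            "means": model.means.tolist(),
            "variances": model.variances.tolist(),
            "range": [rng.lo, rng.hi],
        }

    # ---- classifier -------------------------------------------------------
    model_path = Path(config.model_path) if config.model_path else out / "model.json"
    if config.model_path and not model_path.exists():
        raise StageError("segment-tumors", f"missing model file {model_path}")
    if model_path.exists():
        model = classify.ClassifierModel.load(model_path)
    else:
        if config.phantom is None:
            raise StageError("train-tumor-clf", "no model_path and no phantom to train on")
        model = train_on_phantom(config)
        model.save(model_path)
    log["stages"]["train-tumor-clf"] = {
        "model": str(model_path),
        "layer_sizes": list(model.layer_sizes),
        "final_loss": model.final_loss,
    }

    # ---- tumors -----------------------------------------------------------
    tumor_masks = {}
    for tag, vol in (("pre", pre), ("post", post)):
        mask_path = out / f"tumors_{tag}.nii.gz"
        if mask_path.exists():
            tumor_masks[tag] = read_mask(mask_path)
            continue
        try:
            tumor_masks[tag] = _segment_tumors(config, vol, liver_masks[tag], model)
        except Exception as exc:  # noqa: BLE001
            raise StageError("segment-tumors", str(exc)) from exc
        write_mask(tumor_masks[tag], mask_path)
    log["stages"]["segment-tumors"] = {
        "threshold": config.threshold,
        "closing": config.tumor_closing_vox,
        "opening": config.tumor_opening_vox,
    }

    # ---- measure ----------------------------------------------------------
    record = metrics.response_record(
        metrics.label_lesions(tumor_masks["pre"], pre),
        metrics.label_lesions(tumor_masks["post"], post),
    )
    (out / "record.json").write_text(json.dumps(record.to_dict(), sort_keys=True, indent=1))
    log["stages"]["measure"] = {"record": "record.json"}

    # ---- cohort -----------------------------------------------------------
    if config.cohort_table:
        table = read_cohort(config.cohort_table)
        report = cohort.correlation_report(table)
        payload = {
            "correlations": {
                k: dataclasses.asdict(v) for k, v in report["correlations"].items()
            },
            "groups": {k: dataclasses.asdict(v) for k, v in report["groups"].items()},
            "n_complete": report["n_complete"],
        }
        (out / "cohort_report.json").write_text(json.dumps(payload, sort_keys=True, indent=1))
        cohort.plot_scatter(report, out / "plots")
        log["stages"]["cohort-stats"] = {"table": config.cohort_table}

    (out / "run_log.json").write_text(json.dumps(log, sort_keys=True, indent=1))
    return out
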