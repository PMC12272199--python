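"""Readers and writers: NIfTI map stacks, TSV matrices, JSON sidecars.

Voxel order is always the C-order linear index over mask-true voxels, so
NIfTI and TSV representations of the same study are interchangeable.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .decoders import ActivationMapStack
from .synthetic import (
    MapStudy,
    MapStudyConfig,
    MapStudyTruth,
    SedationStudy,
    SedationStudyConfig,
    SubjectTimeseries,
    gen_region_set,
)

__all__ = [
    "load_map_stack",
    "load_map_stack_tsv",
    "save_map_stack_tsv",
    "save_map_study",
    "load_map_study",
    "save_sedation_study",
    "load_sedation_study",
    "stack_to_volumes",
]


def _mask_indices(mask_data: np.ndarray) -> np.ndarray:
    idx = np.flatnonzero(np.asarray(mask_data) > 0)
    if idx.size == 0:
        raise ValueError("mask contains no voxels")
    return idx


def load_map_stack(
    paths: list[str | Path], mask: str | Path
) -> ActivationMapStack:
    """Load per-subject NIfTI volumes masked by a NIfTI mask.

    Voxel order is the C-order linear index over mask-true voxels.
    """
    mask_img = nib.load(str(mask))
    mask_idx = _mask_indices(np.asarray(mask_img.dataobj))
    affine = mask_img.affine
    rows, ids = [], []
    for path in paths:
        img = nib.load(str(path))
        if not np.allclose(img.affine, affine, atol=1e-6):
            raise ValueError(f"affine mismatch between {path} and the mask")
        vals = np.asarray(img.dataobj, dtype=float).ravel()[mask_idx]
        bad = np.flatnonzero(np.isnan(vals))
        if bad.size:
            raise ValueError(f"NaNs inside mask in {path} at voxels {bad[:10].tolist()}...")
        rows.append(vals)
        ids.append(Path(path).stem)
    return ActivationMapStack(
        np.asarray(rows), ids, mask=mask_idx,
        grid_shape=tuple(mask_img.shape), affine=affine,
    )


def load_map_stack_tsv(path: str | Path) -> ActivationMapStack:
    """Subjects x voxels TSV with a voxel-id header row and subject index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    return ActivationMapStack(df.to_numpy(dtype=float), [str(i) for i in df.index])


def save_map_stack_tsv(stack: ActivationMapStack, path: str | Path) -> None:
    df = pd.DataFrame(
        stack.values,
        index=stack.subject_ids,
        columns=[f"vox{j}" for j in range(stack.n_voxels)],
    )
    df.to_csv(path, sep="\t")


def stack_to_volumes(stack: ActivationMapStack, outdir: str | Path, prefix: str) -> list[Path]:
    """Write one NIfTI volume per subject (plus the mask volume)."""
    if stack.grid_shape is None:
        raise ValueError("stack has no grid geometry; write TSV instead")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = stack.affine if stack.affine is not None else np.eye(4)
    mask_idx = stack.mask if stack.mask is not None else np.arange(stack.n_voxels)
    mask_vol = np.zeros(int(np.prod(stack.grid_shape)), dtype=np.int16)
    mask_vol[mask_idx] = 1
    mask_path = outdir / f"{prefix}_mask.nii.gz"
    nib.save(nib.Nifti1Image(mask_vol.reshape(stack.grid_shape), affine), mask_path)
    paths = [mask_path]
    for sid, row in zip(stack.subject_ids, stack.values):
        vol = np.zeros(int(np.prod(stack.grid_shape)))
        vol[mask_idx] = row
        path = outdir / f"{prefix}_{sid}.nii.gz"
        nib.save(nib.Nifti1Image(vol.reshape(stack.grid_shape), affine), path)
        paths.append(path)
    return paths


def save_map_study(study: MapStudy, outdir: str | Path) -> Path:
    """TSV matrices (or NIfTI volumes when the config has a grid) plus a
    JSON sidecar holding config and generating truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = study.config.grid_shape if study.config is not None else None
    if grid is not None:
        stack_to_volumes(study.maps_interest, outdir, "interest")
        stack_to_volumes(study.maps_nointerest, outdir, "nointerest")
    else:
        save_map_stack_tsv(study.maps_interest, outdir / "interest.tsv")
        save_map_stack_tsv(study.maps_nointerest, outdir / "nointerest.tsv")
    sidecar = {
        "config": asdict(study.config) if study.config is not None else None,
        "truth": {
            "delta": study.truth.delta.tolist(),
            "loadings": study.truth.loadings.tolist(),
            "factor_scores": study.truth.factor_scores.tolist(),
        },
        "motion": study.motion.tolist() if study.motion is not None else None,
    }
    (outdir / "study.json").write_text(json.dumps(sidecar))
    return outdir


def load_map_study(indir: str | Path) -> MapStudy:
    indir = Path(indir)
    sidecar = json.loads((indir / "study.json").read_text())
    cfg = sidecar["config"]
    config = None
    if cfg is not None:
        if cfg.get("grid_shape") is not None:
            cfg["grid_shape"] = tuple(cfg["grid_shape"])
        config = MapStudyConfig(**cfg)
    if config is not None and config.grid_shape is not None:
        mask = indir / "interest_mask.nii.gz"
        ids = [f"sub-{i:03d}" for i in range(config.n_subjects)]
        interest = load_map_stack([indir / f"interest_{s}.nii.gz" for s in ids], mask)
        nointerest = load_map_stack(
            [indir / f"nointerest_{s}.nii.gz" for s in ids], indir / "nointerest_mask.nii.gz"
        )
        interest.subject_ids = ids
        nointerest.subject_ids = ids
    else:
        interest = load_map_stack_tsv(indir / "interest.tsv")
        nointerest = load_map_stack_tsv(indir / "nointerest.tsv")
    truth = MapStudyTruth(
        delta=np.asarray(sidecar["truth"]["delta"]),
        loadings=np.asarray(sidecar["truth"]["loadings"]),
        factor_scores=np.asarray(sidecar["truth"]["factor_scores"]),
    )
    motion = None if sidecar["motion"] is None else np.asarray(sidecar["motion"])
    return MapStudy(
        maps_interest=interest, maps_nointerest=nointerest,
        truth=truth, motion=motion, config=config,
    )


def save_sedation_study(study: SedationStudy, outdir: str | Path) -> Path:
    """One TSV per subject/state/run plus a JSON sidecar (config, stimulus,
    region labels)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (sid, state, run_type), ts in study.runs.items():
        pd.DataFrame(ts.data).to_csv(
            outdir / f"{sid}_{state}_{run_type}.tsv", sep="\t", index=False
        )
    cfg = asdict(study.config)
    cfg["states"] = [list(sg) for sg in study.config.states]
    sidecar = {
        "config": cfg,
        "stimulus": study.stimulus.tolist(),
        "regions": {k: v.tolist() for k, v in study.regions.regions.items()},
    }
    (outdir / "study.json").write_text(json.dumps(sidecar))
    return outdir


def load_sedation_study(indir: str | Path) -> SedationStudy:
    indir = Path(indir)
    sidecar = json.loads((indir / "study.json").read_text())
    cfg = sidecar["config"]
    cfg["states"] = tuple((s, float(g)) for s, g in cfg["states"])
    config = SedationStudyConfig(**cfg)
    regions = gen_region_set(dict(config.region_sizes), config.n_voxels)
    runs = {}
    for i in range(config.n_subjects):
        sid = f"sub-{i:03d}"
        for state, _ in config.states:
            for run_type in ("task", "rest"):
                data = pd.read_csv(
                    indir / f"{sid}_{state}_{run_type}.tsv", sep="\t"
                ).to_numpy(dtype=float)
                runs[(sid, state, run_type)] = SubjectTimeseries(
                    data=data, subject_id=sid, state=state, run_type=run_type
                )
    return SedationStudy(
        runs=runs, stimulus=np.asarray(sidecar["stimulus"]),
        regions=regions, config=config,
    )
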