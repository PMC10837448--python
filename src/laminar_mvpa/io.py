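"""Reading and writing the pipeline's on-disk formats.

Simulated subjects are written as 4-D NIfTI runs (voxels laid out along
the first axis of an N x 1 x 1 x T volume — a flat lattice, since
synthetic voxels carry no spatial neighbourhood), BIDS-style events TSVs
(onset, duration, trial_type) per run, and one ``subject.json`` sidecar
holding the TR, the seed, the generator config and the full ground truth.
Beta matrices are stored as an HDF5 (values) / TSV (labels) pair; pRF
model sets and ROIs as JSON; rivalry trials and tidy accuracy tables as
TSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .glm import BetaMatrix
from .retinotopy import (
    Disc,
    HalfPlane,
    PRFModel,
    Region,
    RegionIntersection,
    RegionUnion,
    ROI,
)
from .synth import (
    GroundTruthVoxel,
    SubjectConfig,
    SubjectData,
    VisualFieldGrid,
    make_retinotopy_stimulus,
    ConditionEffect,
)

__all__ = [
    "write_subject",
    "read_subject",
    "write_betas",
    "read_betas",
    "write_prf_models",
    "read_prf_models",
    "write_roi",
    "read_roi",
    "region_from_dict",
]


def _nifti(ts: np.ndarray, tr_s: float) -> nib.Nifti1Image:
    """Pack a voxels x time matrix as an N x 1 x 1 x T NIfTI volume."""
    img = nib.Nifti1Image(
        np.asarray(ts, dtype=np.float32)[:, None, None, :], np.eye(4)
    )
    img.header.set_zooms((1.0, 1.0, 1.0, tr_s))
    return img


def _unpack(img: nib.Nifti1Image) -> np.ndarray:
    data = np.asarray(img.dataobj, dtype=float)
    return data.reshape(data.shape[0], data.shape[-1])


def _config_to_dict(config: SubjectConfig) -> dict:
    d = dataclasses.asdict(config)
    d["grid"] = dataclasses.asdict(config.grid)
    d["effects"] = {
        k: {"effect_size": v.effect_size, "depth_band": v.depth_band}
        for k, v in config.effects.items()
    }
    if config.prf_candidates is not None:
        d["prf_candidates"] = np.asarray(config.prf_candidates).tolist()
    return d


def _config_from_dict(d: dict) -> SubjectConfig:
    d = dict(d)
    d["grid"] = VisualFieldGrid(**d["grid"])
    d["effects"] = {
        k: ConditionEffect(
            v["effect_size"],
            tuple(v["depth_band"]) if v["depth_band"] is not None else None,
        )
        for k, v in d["effects"].items()
    }
    if d.get("prf_candidates") is not None:
        d["prf_candidates"] = np.asarray(d["prf_candidates"], dtype=float)
    d["sigma_range"] = tuple(d["sigma_range"])
    return SubjectConfig(**d)


def write_subject(subject: SubjectData, outdir: str | Path) -> Path:
    """Write one simulated subject to a directory; returns the path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tr = subject.config.tr_s
    for i, ts in enumerate(subject.task_runs):
        nib.save(_nifti(ts, tr), out / f"task_run-{i:02d}_bold.nii.gz")
        events = subject.design[subject.design["run"] == i]
        pd.DataFrame(
            {
                "onset": events["onset_s"],
                "duration": events["duration_s"],
                "trial_type": events["condition"] + "_" + events["colour"],
                "condition": events["condition"],
                "colour": events["colour"],
            }
        ).to_csv(out / f"task_run-{i:02d}_events.tsv", sep="\t", index=False)
    for kind, ts in subject.retinotopy_runs.items():
        nib.save(_nifti(ts, tr), out / f"retinotopy_{kind}_bold.nii.gz")
    sidecar = {
        "tr_s": tr,
        "seed": subject.seed,
        "config": _config_to_dict(subject.config),
        "truth": [
            {
                **{
                    f: getattr(v, f)
                    for f in (
                        "prf_x",
                        "prf_y",
                        "prf_sigma",
                        "depth",
                        "baseline_intensity",
                        "amplitude_gain",
                        "column",
                    )
                },
                "pattern_weights": {
                    f"{c}/{col}": w for (c, col), w in v.pattern_weights.items()
                },
            }
            for v in subject.truth
        ],
    }
    (out / "subject.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_subject(indir: str | Path) -> SubjectData:
    """Reload a simulated subject directory written by :func:`write_subject`."""
    indir = Path(indir)
    sidecar = json.loads((indir / "subject.json").read_text())
    config = _config_from_dict(sidecar["config"])
    task_runs, frames = [], []
    for i in range(config.n_runs):
        task_runs.append(_unpack(nib.load(indir / f"task_run-{i:02d}_bold.nii.gz")))
        ev = pd.read_csv(indir / f"task_run-{i:02d}_events.tsv", sep="\t")
        frames.append(
            pd.DataFrame(
                {
                    "run": i,
                    "condition": ev["condition"],
                    "colour": ev["colour"],
                    "onset_s": ev["onset"],
                    "duration_s": ev["duration"],
                }
            )
        )
    retinotopy_runs = {
        kind: _unpack(nib.load(indir / f"retinotopy_{kind}_bold.nii.gz"))
        for kind in ("wedge", "ring")
    }
    truth = [
        GroundTruthVoxel(
            prf_x=v["prf_x"],
            prf_y=v["prf_y"],
            prf_sigma=v["prf_sigma"],
            depth=v["depth"],
            baseline_intensity=v["baseline_intensity"],
            amplitude_gain=v["amplitude_gain"],
            pattern_weights={
                tuple(k.split("/")): w for k, w in v["pattern_weights"].items()
            },
            column=v["column"],
        )
        for v in sidecar["truth"]
    ]
    apertures = {
        kind: make_retinotopy_stimulus(kind, config.grid, config.tr_s)
        for kind in ("wedge", "ring")
    }
    return SubjectData(
        task_runs=task_runs,
        retinotopy_runs=retinotopy_runs,
        design=pd.concat(frames, ignore_index=True),
        truth=truth,
        seed=sidecar["seed"],
        config=config,
        apertures=apertures,
    )


def write_betas(betas: BetaMatrix, h5_path: str | Path) -> None:
    """Store a BetaMatrix as HDF5 (values) plus a TSV label table."""
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("values", data=betas.values)
    betas.labels.to_csv(h5_path.with_suffix(".tsv"), sep="\t", index=False)


def read_betas(h5_path: str | Path) -> BetaMatrix:
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "r") as f:
        values = f["values"][()]
    labels = pd.read_csv(h5_path.with_suffix(".tsv"), sep="\t")
    return BetaMatrix(values, labels)


def write_prf_models(models: list[PRFModel], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([dataclasses.asdict(m) for m in models], indent=1)
    )


def read_prf_models(path: str | Path) -> list[PRFModel]:
    return [PRFModel(**d) for d in json.loads(Path(path).read_text())]


def region_from_dict(d: dict) -> Region:
    kind = d["type"]
    if kind == "disc":
        return Disc(d["cx"], d["cy"], d["radius"])
    if kind == "halfplane":
        return HalfPlane(d["nx"], d["ny"], d["offset"])
    if kind == "intersection":
        return RegionIntersection(tuple(region_from_dict(p) for p in d["parts"]))
    if kind == "union":
        return RegionUnion(tuple(region_from_dict(p) for p in d["parts"]))
    raise ValueError(f"unknown region type {kind!r}")


def write_roi(roi: ROI, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "name": roi.name,
                "region": roi.region.describe(),
                "r2_threshold": roi.r2_threshold,
                "voxel_indices": roi.voxel_indices.tolist(),
                "direct": sorted(roi.direct),
                "completed": sorted(roi.completed),
            },
            indent=1,
        )
    )


def read_roi(path: str | Path) -> ROI:
    d = json.loads(Path(path).read_text())
    return ROI(
        name=d["name"],
        region=region_from_dict(d["region"]),
        voxel_indices=np.asarray(d["voxel_indices"], dtype=int),
        r2_threshold=d["r2_threshold"],
        direct=set(d["direct"]),
        completed=set(d["completed"]),
    )
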