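"""Artifact persistence: HDF5 phantoms and probability maps, 16-bit TIFF
projections with JSON sidecars, palette PNG risk maps, CSV/JSON manifests
and reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationMap
from .ground_truth import RiskMap
from .phantom import CohortConfig, CohortManifest, PerlinConfig, VoxelPhantom
from .segmentation import ProbabilityMap


def save_phantom(phantom: VoxelPhantom, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=phantom.labels.astype(np.uint8),
                         compression="gzip")
        f.create_dataset("lesion_weight",
                         data=phantom.lesion_weight.astype(np.float32),
                         compression="gzip")
        for k in ("voxel_pitch_mm", "cbt_mm", "cnd_mm", "seed", "vbd"):
            f.attrs[k] = getattr(phantom, k)


def load_phantom(path) -> VoxelPhantom:
    with h5py.File(path, "r") as f:
        return VoxelPhantom(
            labels=f["labels"][...],
            lesion_weight=f["lesion_weight"][...],
            voxel_pitch_mm=float(f.attrs["voxel_pitch_mm"]),
            cbt_mm=float(f.attrs["cbt_mm"]),
            cnd_mm=float(f.attrs["cnd_mm"]),
            seed=int(f.attrs["seed"]),
            vbd=float(f.attrs["vbd"]),
        )


def save_manifest(manifest: CohortManifest, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.records.to_csv(out / "manifest.csv", index=False)
    cfg = dataclasses.asdict(manifest.config)
    sidecar = {"config": cfg, "master_seed": manifest.master_seed}
    (out / "manifest.json").write_text(json.dumps(sidecar, indent=2))


def load_manifest(out_dir) -> CohortManifest:
    out = Path(out_dir)
    records = pd.read_csv(out / "manifest.csv")
    meta = json.loads((out / "manifest.json").read_text())
    cfg = dict(meta["config"])
    for key in ("cbt_grid_mm", "cnd_grid_mm", "vbd_grid", "split_ratio",
                "lesion_ids"):
        cfg[key] = tuple(cfg[key])
    cfg["perlin"] = PerlinConfig(**cfg["perlin"])
    records["split"] = records["split"].fillna("")
    return CohortManifest(records=records, config=CohortConfig(**cfg),
                          master_seed=int(meta["master_seed"]))


def save_projection_tiff(pixels: np.ndarray, path, sidecar: dict) -> None:
    """16-bit TIFF of photon counts (clipped) plus a JSON sidecar."""
    arr = np.clip(np.round(pixels), 0, 2 ** 16 - 1).astype(np.uint16)
    tifffile.imwrite(path, arr)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def save_risk_map_png(risk_map: RiskMap, path) -> None:
    """Single-channel PNG; pixel value = risk class code (0..3)."""
    iio.imwrite(path, risk_map.labels.astype(np.uint8))


def save_training_pairs(pairs, path) -> None:
    """Bundle (image, target) pairs of one split into HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("images",
                         data=np.stack([p.image for p in pairs])
                         .astype(np.float32), compression="gzip")
        f.create_dataset("targets",
                         data=np.stack([p.target for p in pairs])
                         .astype(np.uint8), compression="gzip")
        f.create_dataset("phantom_ids", data=np.asarray(
            [-1 if p.phantom_id is None else p.phantom_id for p in pairs]))


def load_training_pairs(path):
    from .ground_truth import TrainingPair
    with h5py.File(path, "r") as f:
        images = f["images"][...]
        targets = f["targets"][...]
        pids = f["phantom_ids"][...]
    return [TrainingPair(image=i, target=t,
                         phantom_id=None if p < 0 else int(p))
            for i, t, p in zip(images, targets, pids)]


def save_probability_maps(maps: list[ProbabilityMap], path,
                          phantom_ids=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "probs", data=np.stack([m.probs for m in maps]).astype(np.float32),
            compression="gzip")
        f.attrs["calibrated"] = bool(maps[0].calibrated)
        if phantom_ids is not None:
            f.create_dataset("phantom_ids", data=np.asarray(phantom_ids))


def load_probability_maps(path) -> list[ProbabilityMap]:
    with h5py.File(path, "r") as f:
        probs = f["probs"][...]
        cal = bool(f.attrs["calibrated"])
        pids = f["phantom_ids"][...] if "phantom_ids" in f else [None] * len(probs)
    return [ProbabilityMap(probs=p.astype(np.float64), phantom_id=pid,
                           calibrated=cal)
            for p, pid in zip(probs, pids)]


def save_calibration_map(cal: CalibrationMap, path) -> None:
    payload = {"k": cal.k, "W": cal.W.tolist(), "b": cal.b.tolist(),
               "fit_info": cal.fit_info}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration_map(path) -> CalibrationMap:
    d = json.loads(Path(path).read_text())
    return CalibrationMap(W=np.asarray(d["W"], dtype=float),
                          b=np.asarray(d["b"], dtype=float),
                          fit_info=d.get("fit_info", {}))


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, cls=_ReportEncoder,
                                     sort_keys=True))
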