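"""Compressed-breast voxel phantoms with Perlin-noise parenchyma and lesions.

The phantom is a 3D label volume on an isotropic voxel grid. Axes follow the
convention ``(x, y, z) = (left-right, posteroanterior, craniocaudal)`` with
arrays indexed ``labels[ix, iy, iz]``; physical coordinates are in mm from the
chest-wall / detector-side corner of the grid (x is centred on the chest-wall
midline, y = 0 at the chest wall, z spans the compressed thickness).

Label codes are ordered by radiological "risk" so that a maximum projection
along z returns the most suspicious tissue on each ray:

    0 background (air), 1 skin, 2 adipose, 3 dense, 4 lesion
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidParameterError, PlacementError
from .perlin import fractal_noise

BACKGROUND, SKIN, ADIPOSE, DENSE, LESION = 0, 1, 2, 3, 4

#: nominal lesion model catalogue: model id -> (shape, dims in mm, w)
LESION_MODELS = {
    "I": ("ellipsoidal", (7.0, 7.0, 7.0), 0.20),
    "II": ("spiculated", (9.0, 8.0, 3.0), 0.35),
    "III": ("spiculated", (10.0, 14.0, 4.0), 0.35),
    "IV": ("spiculated", (15.0, 15.0, 4.0), 0.35),
}


@dataclass
class VoxelPhantom:
    """3D label volume plus per-voxel lesion density weight."""

    labels: np.ndarray          # uint8, shape (nx, ny, nz)
    lesion_weight: np.ndarray   # float32, same shape; w where label == LESION
    voxel_pitch_mm: float
    cbt_mm: float
    cnd_mm: float
    seed: int
    vbd: float = float("nan")   # realized dense fraction among interior voxels

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def origin_mm(self) -> np.ndarray:
        """Grid corner (x0, y0, z0) in mm; x centred, y = 0 at chest wall."""
        nx = self.labels.shape[0]
        return np.array([-0.5 * nx * self.voxel_pitch_mm, 0.0, 0.0])

    def voxel_centers_mm(self, mask: np.ndarray) -> np.ndarray:
        """(n, 3) physical centres of the voxels selected by ``mask``."""
        idx = np.argwhere(mask)
        return self.origin_mm + (idx + 0.5) * self.voxel_pitch_mm

    def interior_mask(self) -> np.ndarray:
        return self.labels >= ADIPOSE

    def copy(self) -> "VoxelPhantom":
        return replace(self, labels=self.labels.copy(),
                       lesion_weight=self.lesion_weight.copy())


@dataclass(frozen=True)
class PerlinConfig:
    """Fractal-noise parameters for parenchyma synthesis.

    ``density_threshold_quantile`` q maps noise to tissue: interior voxels with
    noise above the q-quantile become dense, so the dense fraction is 1 - q.
    """

    octaves: int = 6
    base_frequency_mm: float = 1.0 / 40.0
    persistence: float = 0.5
    lacunarity: float = 2.0
    density_threshold_quantile: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.octaves < 1:
            raise InvalidParameterError("octaves must be >= 1")
        if not (0.0 < self.persistence <= 1.0):
            raise InvalidParameterError("persistence must be in (0, 1]")
        if self.lacunarity <= 1.0:
            raise InvalidParameterError("lacunarity must be > 1")
        if not (0.0 < self.density_threshold_quantile < 1.0):
            raise InvalidParameterError("density_threshold_quantile in (0,1)")


@dataclass(frozen=True)
class LesionModel:
    """A binary lesion mask with nominal dimensions and dense-tissue weight w."""

    model_id: str
    shape: str                 # "ellipsoidal" | "spiculated"
    dims_mm: tuple[float, float, float]
    w: float
    mask: np.ndarray           # bool, shape ~ dims_mm / pitch
    voxel_pitch_mm: float
    seed: int

    @property
    def bounding_sphere_radius_mm(self) -> float:
        return 0.5 * float(np.linalg.norm(self.dims_mm))


def generate_outline(
    cbt_mm: float,
    cnd_mm: float,
    width_mm: float,
    skin_mm: float = 1.5,
    voxel_pitch_mm: float = 0.5,
    seed: int = 0,
) -> VoxelPhantom:
    """Parametric compressed-breast outline: background, skin, adipose interior.

    The interior is a super-ellipse in the axial (x, y) plane — flat chest-wall
    face at y = 0, curved nipple-ward boundary reaching ``cnd_mm`` — extruded
    between flat compression surfaces with a rounded rim near top and bottom.
    A skin shell of ``skin_mm`` wraps every surface except the chest-wall face.
    The total z extent equals ``cbt_mm``; the outline itself is deterministic
    (the seed is carried for downstream stages).
    """
    if min(cbt_mm, cnd_mm, width_mm, skin_mm, voxel_pitch_mm) <= 0:
        raise InvalidParameterError("all outline dimensions must be positive")
    if not (30.0 <= cbt_mm <= 70.0) or not (50.0 <= cnd_mm <= 110.0):
        warnings.warn(
            f"CBT={cbt_mm} mm / CND={cnd_mm} mm outside the modelled "
            "30-70 / 50-110 mm compression ranges", stacklevel=2)

    p = voxel_pitch_mm
    nz = int(np.ceil(cbt_mm / p))
    ny = int(np.ceil((cnd_mm + skin_mm) / p)) + 1
    nx = int(np.ceil(width_mm / p)) + 2

    x = (np.arange(nx) + 0.5) * p - 0.5 * nx * p
    y = (np.arange(ny) + 0.5) * p
    z = (np.arange(nz) + 0.5) * p

    # interior semi-axes, inset by the skin thickness on curved surfaces
    ax = 0.5 * width_mm - skin_mm
    by = float(cnd_mm)
    z_lo, z_hi = skin_mm, cbt_mm - skin_mm
    zc, hz = 0.5 * (z_lo + z_hi), 0.5 * (z_hi - z_lo)

    # rim rounding: the axial outline shrinks near the compression surfaces
    t = np.clip((z - zc) / max(hz, p), -1.0, 1.0)
    round_depth = min(0.5 * cbt_mm, 0.25 * cnd_mm)
    s = 1.0 - (round_depth / by) * (1.0 - np.sqrt(1.0 - t ** 2))
    s[(z < z_lo) | (z > z_hi)] = 0.0

    n_exp = 2.5  # super-ellipse exponent: fuller than an ellipse at the sides
    r2d = (np.abs(x[:, None]) / ax) ** n_exp + (y[None, :] / by) ** n_exp
    interior = r2d[:, :, None] <= s[None, None, :] ** n_exp

    # dilate by skin_mm to form the shell; pad with interior at the chest wall
    # so no skin grows on the y = 0 face, and with air beyond the z faces
    padded = np.pad(interior, ((0, 0), (2, 0), (2, 2)), mode="edge")
    padded[:, :, :2] = False
    padded[:, :, -2:] = False
    dist = ndimage.distance_transform_edt(~padded, sampling=p)
    # shell at least one voxel thick so it stays closed at coarse pitch
    breast = dist[:, 2:, 2:-2] <= max(skin_mm, p)

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[breast] = SKIN
    labels[interior] = ADIPOSE
    return VoxelPhantom(
        labels=labels,
        lesion_weight=np.zeros_like(labels, dtype=np.float32),
        voxel_pitch_mm=p, cbt_mm=float(cbt_mm), cnd_mm=float(cnd_mm),
        seed=int(seed),
    )


def synthesize_parenchyma(
    phantom: VoxelPhantom,
    perlin_cfg: PerlinConfig,
    target_vbd: float | None = None,
) -> VoxelPhantom:
    """Relabel interior voxels adipose/dense by thresholding fractal noise.

    ``target_vbd`` (dense fraction among interior voxels) overrides the
    quantile in ``perlin_cfg``; the threshold is the empirical quantile of the
    noise over the interior, so the realized vbd matches the target up to ties.
    """
    if target_vbd is None:
        target_vbd = 1.0 - perlin_cfg.density_threshold_quantile
    if not (0.0 < target_vbd < 1.0):
        raise InvalidParameterError("target_vbd must be in (0, 1)")
    interior = phantom.interior_mask()
    if not interior.any():
        raise InvalidParameterError("phantom has no interior voxels")

    pts = phantom.voxel_centers_mm(interior)
    noise = fractal_noise(
        pts, octaves=perlin_cfg.octaves,
        base_frequency_mm=perlin_cfg.base_frequency_mm,
        persistence=perlin_cfg.persistence, lacunarity=perlin_cfg.lacunarity,
        seed=perlin_cfg.seed,
    )
    thr = np.quantile(noise, 1.0 - target_vbd)
    out = phantom.copy()
    lab = np.where(noise > thr, DENSE, ADIPOSE).astype(np.uint8)
    out.labels[interior] = lab
    out.vbd = float(np.mean(lab == DENSE))
    return out


def _spiculated_mask(dims_mm, pitch, rng) -> np.ndarray:
    """Ellipsoidal core with radial conical spicules filling the dims box."""
    half = np.asarray(dims_mm, dtype=float) / 2.0
    n = np.maximum(np.round(np.asarray(dims_mm) / pitch).astype(int), 1)
    coords = [
        (np.arange(n[a]) + 0.5) * pitch - half[a] for a in range(3)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)

    core_half = 0.7 * half
    mask = np.sum((pts / core_half) ** 2, axis=-1) <= 1.0

    core_r = float(np.mean(core_half))
    # six axis-aligned spicules guarantee the mask spans the nominal box,
    # plus 8-16 randomly oriented ones for irregularity
    dirs = list(np.vstack([np.eye(3), -np.eye(3)]))
    n_rand = int(rng.integers(8, 17))
    v = rng.normal(size=(n_rand, 3))
    dirs += list(v / np.linalg.norm(v, axis=1, keepdims=True))

    r = np.linalg.norm(pts, axis=-1)
    base_radius = max(0.15 * core_r, pitch)
    for i, d in enumerate(dirs):
        # radius of the dims-box ellipsoid along this direction
        r_box = 1.0 / np.sqrt(np.sum((d / half) ** 2))
        if i < 6:
            tip = r_box
        else:
            r_core = 1.0 / np.sqrt(np.sum((d / core_half) ** 2))
            tip = min(r_core + rng.uniform(0.2, 0.5) * core_r, r_box)
        along = pts @ d
        perp = np.sqrt(np.maximum(r ** 2 - along ** 2, 0.0))
        # taper to a floor of ~one voxel so spicule tips survive voxelisation
        width = np.maximum(base_radius * (1.0 - along / tip), 0.75 * pitch)
        cone = (along >= 0) & (along <= tip) & (perp <= width)
        mask |= cone
    # clip to the dims-box ellipsoid so the bounding box never exceeds dims
    mask &= np.sum((pts / half) ** 2, axis=-1) <= 1.0 + 1e-9
    return mask


def make_lesion(model_id: str, voxel_pitch_mm: float = 0.5,
                seed: int = 0) -> LesionModel:
    """Build one of the four lesion models on a voxel grid of given pitch."""
    if model_id not in LESION_MODELS:
        raise InvalidParameterError(
            f"unknown lesion model {model_id!r}; expected one of I-IV")
    shape, dims, w = LESION_MODELS[model_id]
    rng = np.random.default_rng(seed)
    if shape == "ellipsoidal":
        half = np.asarray(dims) / 2.0
        n = np.maximum(np.round(np.asarray(dims) / voxel_pitch_mm).astype(int), 1)
        coords = [(np.arange(n[a]) + 0.5) * voxel_pitch_mm - half[a]
                  for a in range(3)]
        X, Y, Z = np.meshgrid(*coords, indexing="ij")
        mask = (X / half[0]) ** 2 + (Y / half[1]) ** 2 + (Z / half[2]) ** 2 <= 1.0
    else:
        mask = _spiculated_mask(dims, voxel_pitch_mm, rng)
    return LesionModel(model_id=model_id, shape=shape, dims_mm=dims, w=w,
                       mask=mask, voxel_pitch_mm=voxel_pitch_mm, seed=int(seed))


def insert_lesion(phantom: VoxelPhantom, lesion: LesionModel,
                  center_voxel: tuple[int, int, int]) -> VoxelPhantom:
    """Voxel-additive lesion insertion at ``center_voxel`` (in place).

    Covered voxels take the lesion label and carry weight w (the proportion of
    dense tissue added per voxel, which controls X-ray attenuation downstream).
    The placement must lie fully inside parenchyma and clear of prior lesions;
    on any violation the phantom is left untouched.
    """
    if abs(lesion.voxel_pitch_mm - phantom.voxel_pitch_mm) > 1e-9:
        raise PlacementError("lesion and phantom voxel pitch differ")
    m = lesion.mask
    offset = [center_voxel[a] - m.shape[a] // 2 for a in range(3)]
    lo = np.array(offset)
    hi = lo + np.array(m.shape)
    if (lo < 0).any() or (hi > np.array(phantom.shape)).any():
        raise PlacementError("lesion extends outside the phantom grid")
    region = phantom.labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    covered = region[m]
    if (covered < ADIPOSE).any():
        raise PlacementError("lesion would overlap skin or background")
    if (covered == LESION).any():
        raise PlacementError("lesion would overlap an existing lesion")
    region[m] = LESION
    wreg = phantom.lesion_weight[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    wreg[m] = lesion.w
    return phantom


@dataclass(frozen=True)
class CohortConfig:
    """Study-population parameters for a seeded phantom cohort."""

    size: int = 16
    cbt_grid_mm: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 70.0)
    cnd_grid_mm: tuple[float, ...] = (50.0, 65.0, 80.0, 95.0, 110.0)
    vbd_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    split_ratio: tuple[int, int, int, int] = (7, 1, 1, 2)  # train:val:cal:test
    lesion_ids: tuple[str, ...] = ("I", "II", "III", "IV")
    lesions_per_phantom: int = 2
    voxel_pitch_mm: float = 0.5
    skin_mm: float = 1.5
    width_over_cnd: float = 1.5   # compressed-breast width relative to CND
    perlin: PerlinConfig = field(default_factory=PerlinConfig)
    max_placement_tries: int = 100


@dataclass
class CohortManifest:
    """Per-phantom parameter table with stratified split assignment."""

    records: pd.DataFrame
    config: CohortConfig
    master_seed: int

    def split_ids(self, split: str) -> list:
        return list(self.records.loc[self.records["split"] == split,
                                     "phantom_id"])


SPLITS = ("train", "validation", "calibration", "test")


def _split_sizes(n: int, ratio: tuple[int, ...]) -> list[int]:
    """Largest-remainder apportionment of n records to the ratio."""
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    sizes = [int(q) for q in quotas]
    rem = n - sum(sizes)
    order = np.argsort([-(q - int(q)) for q in quotas], kind="stable")
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def _assign_splits(strata: list, rng: np.random.Generator,
                   ratio: tuple[int, ...]) -> list[str]:
    """Controlled rounding of the stratum x split proportionality table.

    Every stratum/split cell receives floor or ceil of its exact proportional
    share (so no stratum deviates from proportionality by more than one
    record) while the global split sizes match the ratio exactly. The
    remainders are reconciled with a feasibility max-flow; members are dealt
    to splits in seeded random order within each stratum.
    """
    import networkx as nx

    n = len(strata)
    sizes = _split_sizes(n, ratio)
    keys = sorted(set(str(s) for s in strata))
    members = {k: [] for k in keys}
    for i, s in enumerate(strata):
        members[str(s)].append(i)
    total = sum(ratio)
    f = {(k, s): len(members[k]) * ratio[s] / total
         for k in keys for s in range(4)}
    c = {ks: int(np.floor(v)) for ks, v in f.items()}
    row_def = {k: len(members[k]) - sum(c[(k, s)] for s in range(4))
               for k in keys}
    col_def = {s: sizes[s] - sum(c[(k, s)] for k in keys) for s in range(4)}

    if sum(row_def.values()) > 0:
        g = nx.DiGraph()
        for k in keys:
            if row_def[k]:
                g.add_edge("src", ("row", k), capacity=row_def[k])
            for s in range(4):
                if f[(k, s)] > c[(k, s)]:
                    g.add_edge(("row", k), ("col", s), capacity=1)
        for s in range(4):
            if col_def[s]:
                g.add_edge(("col", s), "snk", capacity=col_def[s])
        _, flow = nx.maximum_flow(g, "src", "snk")
        for k in keys:
            for s, units in flow.get(("row", k), {}).items():
                if isinstance(s, tuple) and units:
                    c[(k, s[1])] += units

    out = [""] * n
    for k in keys:
        idx = list(members[k])
        rng.shuffle(idx)
        pos = 0
        for s in range(4):
            for i in idx[pos:pos + c[(k, s)]]:
                out[i] = SPLITS[s]
            pos += c[(k, s)]
    return out


def _tercile(values: np.ndarray) -> np.ndarray:
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    return np.digitize(values, [q1, q2])


def build_phantom_from_record(rec: dict, cfg: CohortConfig) -> VoxelPhantom:
    """Regenerate a cohort phantom bit-identically from its manifest row."""
    ph = generate_outline(
        rec["cbt_mm"], rec["cnd_mm"], rec["width_mm"], cfg.skin_mm,
        cfg.voxel_pitch_mm, seed=int(rec["perlin_seed"]))
    pcfg = replace(cfg.perlin, seed=int(rec["perlin_seed"]))
    ph = synthesize_parenchyma(ph, pcfg, target_vbd=rec["target_vbd"])
    for k in range(cfg.lesions_per_phantom):
        lm = make_lesion(rec[f"lesion{k + 1}_model"], cfg.voxel_pitch_mm,
                         seed=int(rec[f"lesion{k + 1}_seed"]))
        center = tuple(int(rec[f"lesion{k + 1}_{a}"]) for a in ("cx", "cy", "cz"))
        insert_lesion(ph, lm, center)
    return ph


def build_cohort(
    cfg: CohortConfig, master_seed: int, out_dir=None,
) -> tuple[CohortManifest, list[VoxelPhantom]]:
    """Generate a seeded cohort with two lesions per phantom and a stratified
    train/validation/calibration/test split.

    Placement draws random posteroanterior and left-right positions with the
    craniocaudal centre fixed at mid-thickness; candidate positions are
    rejected until the lesion fits inside parenchyma without touching the
    other lesion (minimum centre separation = sum of bounding-sphere radii).
    A phantom whose placements cannot be satisfied is recorded as failed and
    excluded from the split.
    """
    if out_dir is not None:
        from pathlib import Path
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(master_seed)
    rows, phantoms = [], []
    for pid in range(cfg.size):
        cbt = float(rng.choice(cfg.cbt_grid_mm))
        cnd = float(rng.choice(cfg.cnd_grid_mm))
        vbd = float(rng.choice(cfg.vbd_grid))
        width = cfg.width_over_cnd * cnd
        pseed = int(rng.integers(0, 2 ** 31 - 1))
        ph = generate_outline(cbt, cnd, width, cfg.skin_mm,
                              cfg.voxel_pitch_mm, seed=pseed)
        ph = synthesize_parenchyma(ph, replace(cfg.perlin, seed=pseed),
                                   target_vbd=vbd)
        rec = {
            "phantom_id": pid, "cbt_mm": cbt, "cnd_mm": cnd,
            "width_mm": width, "target_vbd": vbd, "vbd": ph.vbd,
            "perlin_seed": pseed, "failed": False,
        }
        zc = ph.shape[2] // 2
        placed = []
        ok = True
        for k in range(cfg.lesions_per_phantom):
            mid = str(rng.choice(cfg.lesion_ids))
            lseed = int(rng.integers(0, 2 ** 31 - 1))
            lm = make_lesion(mid, cfg.voxel_pitch_mm, seed=lseed)
            success = False
            for _ in range(cfg.max_placement_tries):
                cx = int(rng.integers(0, ph.shape[0]))
                cy = int(rng.integers(0, ph.shape[1]))
                sep_ok = all(
                    np.hypot(cx - px, cy - py) * cfg.voxel_pitch_mm
                    >= lm.bounding_sphere_radius_mm + prad
                    for px, py, prad in placed)
                if not sep_ok:
                    continue
                try:
                    insert_lesion(ph, lm, (cx, cy, zc))
                except PlacementError:
                    continue
                placed.append((cx, cy, lm.bounding_sphere_radius_mm))
                rec.update({
                    f"lesion{k + 1}_model": mid,
                    f"lesion{k + 1}_shape": lm.shape,
                    f"lesion{k + 1}_w": lm.w,
                    f"lesion{k + 1}_seed": lseed,
                    f"lesion{k + 1}_cx": cx, f"lesion{k + 1}_cy": cy,
                    f"lesion{k + 1}_cz": zc,
                })
                success = True
                break
            if not success:
                ok = False
                break
        if not ok:
            rec["failed"] = True
            rows.append(rec)
            continue
        rows.append(rec)
        phantoms.append(ph)
        if out_dir is not None:
            from .io import save_phantom
            save_phantom(ph, f"{out_dir}/phantom_{pid:04d}.h5")

    df = pd.DataFrame(rows)
    good = df[~df["failed"]].copy()
    shape_combo = good.apply(
        lambda r: "".join(sorted(r[f"lesion{k + 1}_shape"][0]
                                 for k in range(cfg.lesions_per_phantom))),
        axis=1)
    strata = list(zip(_tercile(good["vbd"].to_numpy()),
                      shape_combo,
                      _tercile(good["cbt_mm"].to_numpy())))
    split_rng = np.random.default_rng(master_seed + 1)
    good["split"] = _assign_splits(strata, split_rng, cfg.split_ratio)
    df = df.merge(good[["phantom_id", "split"]], on="phantom_id", how="left")
    df["split"] = df["split"].fillna("")
    manifest = CohortManifest(records=df, config=cfg,
                              master_seed=int(master_seed))
    if out_dir is not None:
        from .io import save_manifest
        save_manifest(manifest, out_dir)
    return manifest, phantoms
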