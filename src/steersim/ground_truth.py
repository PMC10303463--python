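"""Ground-truth risk maps and training pairs.

A risk map labels each pixel with the most suspicious tissue any vertical ray
meets: a maximum projection of the ordered phantom label codes along the
craniocaudal axis, folded to four risk classes

    0 background/skin, 1 predominantly adipose, 2 predominantly dense, 3 lesion

and rescaled to the detector grid of the central projection using the
magnification of the phantom mid-plane. Maps are indexed ``labels[row, col]``
with rows posteroanterior (chest wall at row 0) and columns left-right,
matching :mod:`steersim.projection` images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, resize_local_mean

from .errors import AlignmentError
from .phantom import VoxelPhantom
from .projection import AcquisitionGeometry, ProjectionImage

N_RISK_CLASSES = 4

#: phantom label code (0..4) -> risk class (0..3)
_FOLD = np.array([0, 0, 1, 2, 3], dtype=np.uint8)


@dataclass
class RiskMap:
    labels: np.ndarray            # uint8 (rows, cols), classes 0..3
    alignment: dict               # grid descriptor (see compute_mip)


@dataclass
class TrainingPair:
    image: np.ndarray             # float32 (rows, cols)
    target: np.ndarray            # uint8 (rows, cols), classes 0..3
    phantom_id: int | None = None
    split: str | None = None


def compute_mip(phantom: VoxelPhantom) -> RiskMap:
    """Orthographic maximum-label projection along the compression axis.

    Because the label codes are ordered by risk, the per-column maximum is the
    highest-risk tissue on each ray; skin and background then fold together
    into class 0.
    """
    mip = phantom.labels.max(axis=2)          # (nx, ny)
    labels = _FOLD[mip].T.copy()              # (rows=y, cols=x)
    x0, y0, _ = phantom.origin_mm
    return RiskMap(
        labels=labels,
        alignment={
            "grid": "phantom",
            "pitch_mm": phantom.voxel_pitch_mm,
            "origin_xy_mm": (float(x0), float(y0)),
            "cbt_mm": phantom.cbt_mm,
        },
    )


def rescale_to_projection(risk_map: RiskMap,
                          geometry: AcquisitionGeometry) -> RiskMap:
    """Resample a phantom-grid risk map onto the detector pixel grid.

    Each detector pixel centre is back-projected through the cone geometry to
    the phantom mid-plane (air gap + CBT/2 above the detector) and sampled by
    nearest neighbour, so no new label values can appear. Pixels falling
    outside the phantom grid are background (class 0).
    """
    if risk_map.alignment.get("grid") != "phantom":
        raise AlignmentError("risk map is not on the phantom grid")
    pitch = risk_map.alignment["pitch_mm"]
    x0, y0 = risk_map.alignment["origin_xy_mm"]
    cbt = risk_map.alignment["cbt_mm"]
    mag = geometry.magnification(geometry.air_gap_mm + 0.5 * cbt)

    nv, nu = geometry.n_pixels
    iv, iu = np.meshgrid(np.arange(nv), np.arange(nu), indexing="ij")
    pix = geometry.pixel_center_mm(iv, iu)
    xq = pix[..., 0] / mag
    yq = pix[..., 1] / mag
    col = np.floor((xq - x0) / pitch).astype(int)
    row = np.floor((yq - y0) / pitch).astype(int)
    rows, cols = risk_map.labels.shape
    inside = (row >= 0) & (row < rows) & (col >= 0) & (col < cols)
    out = np.zeros((nv, nu), dtype=np.uint8)
    out[inside] = risk_map.labels[row[inside], col[inside]]
    return RiskMap(labels=out, alignment={
        "grid": "projection", "magnification": float(mag),
        "n_pixels": (nv, nu),
    })


@dataclass(frozen=True)
class CropConfig:
    """Crop-and-downsample settings shared by every image in a cohort.

    ``keep_rows`` retains detector rows [0, keep_rows) — the chest-wall side —
    discarding the mostly-air nipple side; it is computed once per cohort from
    the largest magnified AP extent (or a default 20% reduction). Both members
    of a pair are then resampled to ``target_shape``: the image by local-mean
    averaging, the labels by nearest neighbour.
    """

    keep_rows: int
    target_shape: tuple[int, int] = (600, 360)   # (rows, cols)


def crop_for_cohort(geometry: AcquisitionGeometry,
                    max_ap_extent_mm: float | None,
                    cbt_for_mag_mm: float = 50.0,
                    target_shape: tuple[int, int] = (600, 360),
                    fraction: float = 0.8) -> CropConfig:
    """Crop window for a cohort: the larger of the magnified maximum AP extent
    and ``fraction`` of the detector height, in detector rows."""
    nv, _ = geometry.n_pixels
    keep = int(round(fraction * nv))
    if max_ap_extent_mm is not None:
        mag = geometry.magnification(geometry.air_gap_mm + 0.5 * cbt_for_mag_mm)
        keep = max(
            min(int(np.ceil(max_ap_extent_mm * mag
                            / geometry.detector_element_mm[1])), nv),
            1)
    return CropConfig(keep_rows=keep, target_shape=target_shape)


def make_training_pair(projection: ProjectionImage, risk_map: RiskMap,
                       crop_cfg: CropConfig) -> TrainingPair:
    """Apply the cohort crop window and downsample to the training grid."""
    img = projection.pixels
    if risk_map.labels.shape != img.shape:
        raise AlignmentError(
            f"projection {img.shape} and risk map {risk_map.labels.shape} "
            "are on different grids")
    keep = crop_cfg.keep_rows
    img_c = img[:keep, :].astype(np.float64)
    lab_c = risk_map.labels[:keep, :]
    shape = crop_cfg.target_shape
    image = resize_local_mean(img_c, shape).astype(np.float32)
    target = resize(lab_c, shape, order=0, preserve_range=True,
                    anti_aliasing=False).astype(np.uint8)
    return TrainingPair(image=image, target=target)
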