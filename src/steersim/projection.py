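"""Single low-dose projection simulation by Siddon ray tracing.

The acquisition emulates the central projection of a next-generation
tomosynthesis (NGT) geometry: a point source on the normal through the
midpoint of the chest-wall detector edge, an ideal photon-counting detector
in the z = 0 plane, and the phantom resting ``air_gap_mm`` above the
detector. Attenuation is monoenergetic (effective energy, default 20 keV)
with Beer-Lambert transmission; quantum noise is Poisson.

Detector images are indexed ``pixels[iv, iu]`` with rows running
posteroanteriorly (v, chest wall at v = 0) and columns left-right (u).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ConfigurationError, InvalidParameterError
from .phantom import LESION, VoxelPhantom

# NGT central-projection constants
NGT_SOURCE_IMAGE_DISTANCE_MM = 738.01
NGT_DETECTOR_SIZE_MM = (239.36, 304.64)      # width (u) x height (v)
NGT_DETECTOR_ELEMENT_MM = (0.085, 0.085)


@dataclass(frozen=True)
class AcquisitionGeometry:
    source_position_mm: tuple[float, float, float]
    source_image_distance_mm: float = NGT_SOURCE_IMAGE_DISTANCE_MM
    detector_size_mm: tuple[float, float] = NGT_DETECTOR_SIZE_MM
    detector_element_mm: tuple[float, float] = NGT_DETECTOR_ELEMENT_MM
    detector_offset_mm: tuple[float, float] = (0.0, 0.0)
    air_gap_mm: float = 25.0

    @property
    def n_pixels(self) -> tuple[int, int]:
        """(n_v, n_u): detector grid dims = round(size / element size)."""
        return (
            int(round(self.detector_size_mm[1] / self.detector_element_mm[1])),
            int(round(self.detector_size_mm[0] / self.detector_element_mm[0])),
        )

    def pixel_center_mm(self, iv, iu) -> np.ndarray:
        """Physical (x, y, z) of detector pixel centres; z = 0 plane."""
        du, dv = self.detector_element_mm
        w = self.detector_size_mm[0]
        x = -0.5 * w + (np.asarray(iu) + 0.5) * du + self.detector_offset_mm[0]
        y = (np.asarray(iv) + 0.5) * dv + self.detector_offset_mm[1]
        return np.stack(np.broadcast_arrays(x, y, np.zeros_like(x + 0.0)),
                        axis=-1)

    def magnification(self, height_mm: float) -> float:
        """Magnification of a plane ``height_mm`` above the detector."""
        sid = self.source_image_distance_mm
        return sid / (sid - height_mm)


def ngt_central(element_scale: float = 1.0,
                air_gap_mm: float = 25.0) -> AcquisitionGeometry:
    """The NGT central-projection geometry.

    ``element_scale`` > 1 coarsens the detector grid (same physical detector,
    larger elements) for CPU-scale studies; 1.0 is the native 85 um pitch.
    """
    return AcquisitionGeometry(
        source_position_mm=(0.0, 0.0, NGT_SOURCE_IMAGE_DISTANCE_MM),
        detector_element_mm=(NGT_DETECTOR_ELEMENT_MM[0] * element_scale,
                             NGT_DETECTOR_ELEMENT_MM[1] * element_scale),
        air_gap_mm=air_gap_mm,
    )


@dataclass(frozen=True)
class ExposureSettings:
    photons_per_pixel_air: float
    effective_energy_keV: float = 20.0

    def __post_init__(self):
        if self.photons_per_pixel_air <= 0:
            raise InvalidParameterError("photons_per_pixel_air must be > 0")


@dataclass(frozen=True)
class MaterialTable:
    """Linear attenuation coefficients (mm^-1) at the effective energy.

    Defaults are representative soft-tissue values at 20 keV; they satisfy
    mu_air < mu_adipose < mu_skin <= mu_dense. The lesion is not a separate
    material: a lesion voxel attenuates as a (1 - w)/w mixture of its
    underlying tissue (adipose unless recorded otherwise) and dense tissue.
    """

    mu_air: float = 8.0e-5
    mu_skin: float = 0.080
    mu_adipose: float = 0.054
    mu_dense: float = 0.084

    def __post_init__(self):
        ok = (0 <= self.mu_air < self.mu_adipose < self.mu_skin
              <= self.mu_dense)
        if not ok:
            raise ConfigurationError(
                "require 0 <= mu_air < mu_adipose < mu_skin <= mu_dense")

    def by_label(self) -> np.ndarray:
        return np.array([self.mu_air, self.mu_skin, self.mu_adipose,
                         self.mu_dense, np.nan])


@dataclass
class ProjectionImage:
    pixels: np.ndarray          # (n_v, n_u), mean signal or photon counts
    geometry: AcquisitionGeometry
    exposure: ExposureSettings
    phantom_id: int | None = None
    noise_seed: int | None = None


def mu_volume(phantom: VoxelPhantom,
              table: MaterialTable | None = None) -> np.ndarray:
    """Per-voxel linear attenuation, mixing lesion voxels with dense tissue."""
    table = table or MaterialTable()
    mu = table.by_label()[np.minimum(phantom.labels, LESION - 1)]
    les = phantom.labels == LESION
    if les.any():
        w = phantom.lesion_weight[les].astype(np.float64)
        mu[les] = (1.0 - w) * table.mu_adipose + w * table.mu_dense
    return np.ascontiguousarray(mu, dtype=np.float64)


def _volume_frame(phantom: VoxelPhantom, geometry: AcquisitionGeometry):
    origin = phantom.origin_mm + np.array([0.0, 0.0, geometry.air_gap_mm])
    return origin, float(phantom.voxel_pitch_mm)


def siddon_raypath(geometry: AcquisitionGeometry, pixel_index,
                   phantom: VoxelPhantom):
    """Exact voxel traversal for one detector pixel's ray.

    Returns a list of ``((ix, iy, iz), length_mm)`` for every voxel the
    source-to-pixel segment crosses, via the classic merged plane-crossing
    construction: parametric intersections with all grid planes are sorted
    and consecutive pairs identify one voxel each.
    """
    iv, iu = pixel_index
    nv, nu = geometry.n_pixels
    if not (0 <= iv < nv and 0 <= iu < nu):
        raise InvalidParameterError("pixel index outside the detector grid")
    p0 = np.asarray(geometry.source_position_mm, dtype=float)
    p1 = geometry.pixel_center_mm(iv, iu).astype(float)
    origin, pitch = _volume_frame(phantom, geometry)
    dims = np.array(phantom.shape)
    d = p1 - p0

    tmin, tmax = 0.0, 1.0
    for a in range(3):
        lo, hi = origin[a], origin[a] + dims[a] * pitch
        if d[a] == 0.0:
            if not (lo <= p0[a] <= hi):
                return []
        else:
            t0, t1 = (lo - p0[a]) / d[a], (hi - p0[a]) / d[a]
            tmin = max(tmin, min(t0, t1))
            tmax = min(tmax, max(t0, t1))
    if tmax <= tmin:
        return []

    ts = [np.array([tmin, tmax])]
    for a in range(3):
        if d[a] != 0.0:
            planes = origin[a] + pitch * np.arange(dims[a] + 1)
            t = (planes - p0[a]) / d[a]
            ts.append(t[(t > tmin) & (t < tmax)])
    t = np.unique(np.concatenate(ts))
    mid = p0 + 0.5 * (t[:-1] + t[1:])[:, None] * d
    idx = np.floor((mid - origin) / pitch).astype(int)
    seg = np.diff(t) * np.linalg.norm(d)
    keep = (idx >= 0).all(axis=1) & (idx < dims).all(axis=1) & (seg > 0)
    return [(tuple(i), float(s)) for i, s in zip(idx[keep], seg[keep])]


@njit(cache=True)
def _line_integrals(p0, pix, mu, origin, pitch, out):  # pragma: no cover
    nx, ny, nz = mu.shape
    for r in range(pix.shape[0]):
        dx = pix[r, 0] - p0[0]
        dy = pix[r, 1] - p0[1]
        dz = pix[r, 2] - p0[2]
        length = (dx * dx + dy * dy + dz * dz) ** 0.5
        tmin, tmax = 0.0, 1.0
        ok = True
        for a in range(3):
            d = dx if a == 0 else (dy if a == 1 else dz)
            s = p0[a]
            lo = origin[a]
            hi = origin[a] + pitch * (nx if a == 0 else (ny if a == 1 else nz))
            if d == 0.0:
                if s < lo or s > hi:
                    ok = False
                    break
            else:
                t0 = (lo - s) / d
                t1 = (hi - s) / d
                if t0 > t1:
                    t0, t1 = t1, t0
                if t0 > tmin:
                    tmin = t0
                if t1 < tmax:
                    tmax = t1
        if not ok or tmax <= tmin:
            out[r] = 0.0
            continue
        # entry voxel (nudged inside to dodge face-exact starts)
        teps = tmin + 1e-12
        ix = int((p0[0] + teps * dx - origin[0]) / pitch)
        iy = int((p0[1] + teps * dy - origin[1]) / pitch)
        iz = int((p0[2] + teps * dz - origin[2]) / pitch)
        if ix < 0:
            ix = 0
        if iy < 0:
            iy = 0
        if iz < 0:
            iz = 0
        if ix > nx - 1:
            ix = nx - 1
        if iy > ny - 1:
            iy = ny - 1
        if iz > nz - 1:
            iz = nz - 1
        big = 1e30
        stepx = 1 if dx > 0 else -1
        stepy = 1 if dy > 0 else -1
        stepz = 1 if dz > 0 else -1
        dtx = pitch / abs(dx) if dx != 0.0 else big
        dty = pitch / abs(dy) if dy != 0.0 else big
        dtz = pitch / abs(dz) if dz != 0.0 else big
        if dx != 0.0:
            nxt = origin[0] + (ix + (1 if dx > 0 else 0)) * pitch
            tx = (nxt - p0[0]) / dx
        else:
            tx = big
        if dy != 0.0:
            nxt = origin[1] + (iy + (1 if dy > 0 else 0)) * pitch
            ty = (nxt - p0[1]) / dy
        else:
            ty = big
        if dz != 0.0:
            nxt = origin[2] + (iz + (1 if dz > 0 else 0)) * pitch
            tz = (nxt - p0[2]) / dz
        else:
            tz = big
        acc = 0.0
        t = tmin
        while t < tmax - 1e-14:
            if tx <= ty and tx <= tz:
                tnext = tx
            elif ty <= tz:
                tnext = ty
            else:
                tnext = tz
            if tnext > tmax:
                tnext = tmax
            if tnext > t:
                acc += mu[ix, iy, iz] * (tnext - t) * length
                t = tnext
            if t >= tmax - 1e-14:
                break
            if tx <= ty and tx <= tz:
                ix += stepx
                tx += dtx
            elif ty <= tz:
                iy += stepy
                ty += dty
            else:
                iz += stepz
                tz += dtz
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny \
                    or iz < 0 or iz >= nz:
                break
        out[r] = acc


def line_integral_image(phantom: VoxelPhantom, geometry: AcquisitionGeometry,
                        table: MaterialTable | None = None) -> np.ndarray:
    """Path integral of mu along every detector pixel's ray (mm^-1 * mm)."""
    mu = mu_volume(phantom, table)
    origin, pitch = _volume_frame(phantom, geometry)
    nv, nu = geometry.n_pixels
    iv, iu = np.meshgrid(np.arange(nv), np.arange(nu), indexing="ij")
    pix = geometry.pixel_center_mm(iv.ravel(), iu.ravel())
    out = np.empty(pix.shape[0], dtype=np.float64)
    _line_integrals(np.asarray(geometry.source_position_mm, dtype=np.float64),
                    np.ascontiguousarray(pix, dtype=np.float64),
                    mu, origin.astype(np.float64), pitch, out)
    return out.reshape(nv, nu)


def project(phantom: VoxelPhantom, geometry: AcquisitionGeometry,
            exposure: ExposureSettings,
            material_table: MaterialTable | None = None,
            noise_seed: int | None = None) -> ProjectionImage:
    """Simulate one projection: Beer-Lambert mean signal, optional Poisson noise.

    Mean pixel signal = ``photons_per_pixel_air * exp(-integral mu dl)``; an
    air-only ray therefore reads the unattenuated photon count. With a noise
    seed, pixels are independent Poisson draws around the mean.
    """
    integ = line_integral_image(phantom, geometry, material_table)
    mean = exposure.photons_per_pixel_air * np.exp(-integ)
    if noise_seed is None:
        pixels = mean
    else:
        pixels = np.random.default_rng(noise_seed).poisson(mean).astype(
            np.float64)
    return ProjectionImage(pixels=pixels, geometry=geometry,
                           exposure=exposure, phantom_id=None,
                           noise_seed=noise_seed)


def aec_exposure(cbt_mm: float, vbd: float,
                 target_count: float = 200.0,
                 table: MaterialTable | None = None,
                 effective_energy_keV: float = 20.0) -> ExposureSettings:
    """Automatic-exposure-control surrogate.

    Scales the incident fluence so the mean transmitted count behind a
    homogeneous breast of the given thickness and glandularity equals
    ``target_count``: photons_air = target * exp(mu_eff(vbd) * cbt), with
    mu_eff the vbd-weighted adipose/dense mixture. Monotone in both inputs.
    """
    if cbt_mm <= 0:
        raise InvalidParameterError("cbt_mm must be > 0")
    table = table or MaterialTable()
    mu_eff = (1.0 - vbd) * table.mu_adipose + vbd * table.mu_dense
    return ExposureSettings(
        photons_per_pixel_air=float(target_count * np.exp(mu_eff * cbt_mm)),
        effective_energy_keV=effective_energy_keV)
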