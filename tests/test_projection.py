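"""Siddon ray tracing, Beer-Lambert transmission, AEC exposure, noise."""

import numpy as np
import pytest

from steersim.errors import InvalidParameterError
from steersim.phantom import ADIPOSE, DENSE, LESION
from steersim.projection import (AcquisitionGeometry, ExposureSettings,
                                 MaterialTable, aec_exposure,
                                 line_integral_image, mu_volume, ngt_central,
                                 project, siddon_raypath)

from conftest import slab_phantom

TABLE = MaterialTable()


def sampling_oracle(geometry, pixel_index, phantom, n_samples=10_000):
    """Per-voxel intersection lengths by uniform sampling of the in-box chord.

    The source-to-pixel segment is first clipped to the phantom bounding box;
    the 10^4 sample points are spread over that chord and binned by voxel, so
    the per-voxel length error is bounded by twice the sample spacing."""
    p0 = np.asarray(geometry.source_position_mm, dtype=float)
    p1 = geometry.pixel_center_mm(*pixel_index).astype(float)
    d = p1 - p0
    origin = phantom.origin_mm + [0, 0, geometry.air_gap_mm]
    dims = np.array(phantom.shape)
    hi = origin + dims * phantom.voxel_pitch_mm
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = (origin - p0) / d
        t1 = (hi - p0) / d
    tmin = float(np.maximum(np.nanmin([t0, t1], axis=0), 0.0).max())
    tmax = float(np.minimum(np.nanmax([t0, t1], axis=0), 1.0).min())
    if tmax <= tmin:
        return {}
    ts = tmin + (tmax - tmin) * (np.arange(n_samples) + 0.5) / n_samples
    pts = p0 + ts[:, None] * d
    idx = np.floor((pts - origin) / phantom.voxel_pitch_mm).astype(int)
    inside = (idx >= 0).all(axis=1) & (idx < dims).all(axis=1)
    chord = (tmax - tmin) * np.linalg.norm(d)
    out = {}
    for i in idx[inside]:
        out[tuple(i)] = out.get(tuple(i), 0) + chord / n_samples
    return out


class TestSiddon:
    def test_axis_aligned_ray_lengths(self):
        # vertical parallel-beam ray: source directly above a pixel centre
        ph = slab_phantom([ADIPOSE] * 10, pitch=1.0)
        geom = AcquisitionGeometry(
            source_position_mm=(0.5, 4.5, 700.0),
            detector_size_mm=(8.0, 8.0), detector_element_mm=(1.0, 1.0),
            air_gap_mm=0.0)
        path = siddon_raypath(geom, (4, 4), ph)   # pixel centre (0.5, 4.5)
        assert len(path) == 10
        assert all(l == pytest.approx(1.0, abs=1e-9) for _, l in path)

    def test_chord_length_conservation(self, random_label_phantom):
        geom = ngt_central(element_scale=30.0)
        rng = np.random.default_rng(1)
        p0 = np.asarray(geom.source_position_mm)
        checked = 0
        while checked < 30:
            iv = int(rng.integers(0, geom.n_pixels[0]))
            iu = int(rng.integers(0, geom.n_pixels[1]))
            path = siddon_raypath(geom, (iv, iu), random_label_phantom)
            if not path:
                continue
            total = sum(l for _, l in path)
            p1 = geom.pixel_center_mm(iv, iu)
            d = p1 - p0
            # analytic chord through the axis-aligned bounding box
            origin = random_label_phantom.origin_mm + [0, 0, geom.air_gap_mm]
            hi = origin + 32.0
            with np.errstate(divide="ignore"):
                t0 = (origin - p0) / d
                t1 = (hi - p0) / d
            tmin = np.maximum(np.minimum(t0, t1), 0).max()
            tmax = np.minimum(np.maximum(t0, t1), 1).min()
            chord = max(tmax - tmin, 0) * np.linalg.norm(d)
            assert total == pytest.approx(chord, rel=1e-9)
            checked += 1

    def test_against_dense_sampling_oracle(self, random_label_phantom):
        geom = ngt_central(element_scale=30.0)
        rng = np.random.default_rng(7)
        pitch = random_label_phantom.voxel_pitch_mm
        for _ in range(100):
            iv = int(rng.integers(0, geom.n_pixels[0]))
            iu = int(rng.integers(0, geom.n_pixels[1]))
            path = dict(siddon_raypath(geom, (iv, iu), random_label_phantom))
            oracle = sampling_oracle(geom, (iv, iu), random_label_phantom)
            for vox in set(path) | set(oracle):
                a = path.get(vox, 0.0)
                b = oracle.get(vox, 0.0)
                assert abs(a - b) <= 0.02 * pitch

    def test_ray_missing_volume_is_empty(self, random_label_phantom):
        geom = ngt_central(element_scale=30.0)
        # far corner pixel: ray passes well outside the 32 mm cube
        assert siddon_raypath(geom, (geom.n_pixels[0] - 1, 0),
                              random_label_phantom) == []

    def test_fast_projector_matches_raypath(self, random_label_phantom):
        geom = ngt_central(element_scale=30.0)
        integ = line_integral_image(random_label_phantom, geom)
        mu = mu_volume(random_label_phantom)
        rng = np.random.default_rng(3)
        for _ in range(25):
            iv = int(rng.integers(0, geom.n_pixels[0]))
            iu = int(rng.integers(0, geom.n_pixels[1]))
            ref = sum(mu[i] * l
                      for i, l in siddon_raypath(geom, (iv, iu),
                                                 random_label_phantom))
            assert integ[iv, iu] == pytest.approx(ref, abs=1e-9)


class TestProject:
    def _parallel_geom(self, nx=8, ny=8):
        return AcquisitionGeometry(
            source_position_mm=(0.5, 4.5, 1e7),   # quasi-parallel beam
            detector_size_mm=(nx, ny), detector_element_mm=(1.0, 1.0),
            air_gap_mm=0.0)

    def test_homogeneous_slab_beer_lambert(self):
        t = 12
        ph = slab_phantom([ADIPOSE] * t, pitch=1.0)
        geom = self._parallel_geom()
        exposure = ExposureSettings(photons_per_pixel_air=1000.0)
        img = project(ph, geom, exposure, TABLE)
        expected = 1000.0 * np.exp(-TABLE.mu_adipose * t)
        assert img.pixels[4, 4] == pytest.approx(expected, rel=1e-6)

    def test_air_pixel_reads_unattenuated_count(self, random_label_phantom):
        geom = ngt_central(element_scale=30.0)
        exposure = ExposureSettings(photons_per_pixel_air=500.0)
        img = project(random_label_phantom, geom, exposure, TABLE)
        assert img.pixels[geom.n_pixels[0] - 1, 0] == pytest.approx(500.0)

    def test_lesion_attenuation_mixing(self):
        # single lesion voxel with w = 0.20 over an adipose column
        ph = slab_phantom([ADIPOSE] * 5, pitch=1.0)
        ph.labels[0, 4, 2] = LESION
        ph.lesion_weight[0, 4, 2] = 0.20
        geom = self._parallel_geom()
        img = project(ph, geom, ExposureSettings(1000.0), TABLE)
        mu_mix = 0.8 * TABLE.mu_adipose + 0.2 * TABLE.mu_dense
        expected = 1000.0 * np.exp(-(4 * TABLE.mu_adipose + mu_mix))
        assert img.pixels[4, 0] == pytest.approx(expected, rel=1e-9)

    def test_log_linearity_of_line_integral(self):
        ph1 = slab_phantom([DENSE] * 6, pitch=1.0)
        ph2 = slab_phantom([DENSE] * 12, pitch=1.0)
        ph2.cnd_mm = ph1.cnd_mm
        geom = self._parallel_geom()
        l1 = line_integral_image(ph1, geom, TABLE)[4, 4]
        l2 = line_integral_image(ph2, geom, TABLE)[4, 4]
        assert l2 == pytest.approx(2 * l1, rel=1e-9)

    def test_lesion_never_increases_signal(self, small_phantom):
        geom = ngt_central(element_scale=30.0)
        without = small_phantom.copy()
        without.labels[without.labels == LESION] = ADIPOSE
        without.lesion_weight[...] = 0.0
        exposure = ExposureSettings(1000.0)
        with_les = project(small_phantom, geom, exposure, TABLE).pixels
        no_les = project(without, geom, exposure, TABLE).pixels
        assert np.all(with_les <= no_les + 1e-9)

    def test_poisson_noise_reproducible_and_calibrated(self,
                                                       random_label_phantom):
        geom = ngt_central(element_scale=10.0)
        exposure = ExposureSettings(photons_per_pixel_air=800.0)
        a = project(random_label_phantom, geom, exposure, TABLE, noise_seed=9)
        b = project(random_label_phantom, geom, exposure, TABLE, noise_seed=9)
        assert np.array_equal(a.pixels, b.pixels)
        mean = project(random_label_phantom, geom, exposure, TABLE).pixels
        air = np.abs(mean - 800.0) < 1e-6
        assert air.sum() >= 10_000
        counts = a.pixels[air]
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_missing_material_invariant(self):
        with pytest.raises(Exception):
            MaterialTable(mu_air=0.1, mu_adipose=0.05, mu_skin=0.08,
                          mu_dense=0.084)


class TestAEC:
    def test_monotone_in_thickness(self):
        lo = aec_exposure(30.0, 0.3)
        hi = aec_exposure(70.0, 0.3)
        assert hi.photons_per_pixel_air > lo.photons_per_pixel_air

    def test_monotone_in_density(self):
        lo = aec_exposure(50.0, 0.2)
        hi = aec_exposure(50.0, 0.6)
        assert hi.photons_per_pixel_air > lo.photons_per_pixel_air

    def test_invalid_thickness(self):
        with pytest.raises(InvalidParameterError):
            aec_exposure(0.0, 0.3)

    def test_target_band_behind_breast_centre(self):
        # oracle: project each cohort phantom and read behind its centroid
        import steersim as ss
        from steersim.phantom import CohortConfig
        cfg = CohortConfig(size=4, voxel_pitch_mm=1.0)
        manifest, phantoms = ss.build_cohort(cfg, master_seed=5)
        good = manifest.records[~manifest.records["failed"]]
        geom = ngt_central(element_scale=30.0)
        target = 200.0
        for ph, (_, rec) in zip(phantoms, good.iterrows()):
            exposure = aec_exposure(rec["cbt_mm"], rec["vbd"],
                                    target_count=target)
            img = project(ph, geom, exposure, TABLE)
            cen = ph.voxel_centers_mm(ph.labels >= ADIPOSE).mean(axis=0)
            mag = geom.magnification(cen[2] + geom.air_gap_mm)
            iu = int((cen[0] * mag + geom.detector_size_mm[0] / 2)
                     / geom.detector_element_mm[0])
            iv = int(cen[1] * mag / geom.detector_element_mm[1])
            patch = img.pixels[max(iv - 2, 0):iv + 3, max(iu - 2, 0):iu + 3]
            assert 0.5 * target <= patch.mean() <= 2.0 * target
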