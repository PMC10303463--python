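"""Seeded 3D gradient-lattice ("Perlin") noise.

Classic Perlin noise with a seeded permutation table, evaluated in a fully
vectorised fashion, plus fractal (octave-summed) noise used to synthesise
breast parenchyma texture. Values are roughly in [-1, 1]; only the ranks
matter downstream because tissue is assigned by quantile thresholding.
"""

from __future__ import annotations

import numpy as np

# 12 edge-of-cube gradient directions (Improved Perlin noise gradient set).
_GRADS = np.array(
    [
        [1, 1, 0], [-1, 1, 0], [1, -1, 0], [-1, -1, 0],
        [1, 0, 1], [-1, 0, 1], [1, 0, -1], [-1, 0, -1],
        [0, 1, 1], [0, -1, 1], [0, 1, -1], [0, -1, -1],
    ],
    dtype=np.float64,
)


def _permutation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    p = rng.permutation(256)
    return np.concatenate([p, p]).astype(np.int64)


def _fade(t: np.ndarray) -> np.ndarray:
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def _corner_dot(perm: np.ndarray, ix, iy, iz, dx, dy, dz) -> np.ndarray:
    h = perm[perm[perm[ix & 255] + (iy & 255)] + (iz & 255)] % 12
    g = _GRADS[h]
    return g[..., 0] * dx + g[..., 1] * dy + g[..., 2] * dz


def perlin3d(points: np.ndarray, seed: int) -> np.ndarray:
    """Evaluate single-octave Perlin noise at ``points`` (..., 3), lattice units."""
    pts = np.asarray(points, dtype=np.float64)
    i0 = np.floor(pts).astype(np.int64)
    f = pts - i0
    ix, iy, iz = i0[..., 0], i0[..., 1], i0[..., 2]
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]

    u, v, w = _fade(fx), _fade(fy), _fade(fz)
    perm = _permutation(seed)

    n000 = _corner_dot(perm, ix, iy, iz, fx, fy, fz)
    n100 = _corner_dot(perm, ix + 1, iy, iz, fx - 1, fy, fz)
    n010 = _corner_dot(perm, ix, iy + 1, iz, fx, fy - 1, fz)
    n110 = _corner_dot(perm, ix + 1, iy + 1, iz, fx - 1, fy - 1, fz)
    n001 = _corner_dot(perm, ix, iy, iz + 1, fx, fy, fz - 1)
    n101 = _corner_dot(perm, ix + 1, iy, iz + 1, fx - 1, fy, fz - 1)
    n011 = _corner_dot(perm, ix, iy + 1, iz + 1, fx, fy - 1, fz - 1)
    n111 = _corner_dot(perm, ix + 1, iy + 1, iz + 1, fx - 1, fy - 1, fz - 1)

    x00 = n000 + u * (n100 - n000)
    x10 = n010 + u * (n110 - n010)
    x01 = n001 + u * (n101 - n001)
    x11 = n011 + u * (n111 - n011)
    y0 = x00 + v * (x10 - x00)
    y1 = x01 + v * (x11 - x01)
    return y0 + w * (y1 - y0)


def fractal_noise(
    points_mm: np.ndarray,
    octaves: int,
    base_frequency_mm: float,
    persistence: float,
    lacunarity: float,
    seed: int,
) -> np.ndarray:
    """Octave-summed Perlin noise at physical coordinates (..., 3) in mm.

    Octave ``o`` contributes amplitude ``persistence**o`` at spatial frequency
    ``base_frequency_mm * lacunarity**o``; each octave gets an independent
    seeded permutation so lattice artefacts do not align across scales.
    """
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    pts = np.asarray(points_mm, dtype=np.float64)
    out = np.zeros(pts.shape[:-1], dtype=np.float64)
    amp = 1.0
    freq = base_frequency_mm
    for o in range(octaves):
        out += amp * perlin3d(pts * freq, seed=seed + 1013 * o)
        amp *= persistence
        freq *= lacunarity
    return out
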