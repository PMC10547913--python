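"""Brute-force reference implementations used only by the tests.

Each oracle is written as a direct loop over the defining formula, kept
deliberately independent of the vectorized implementations it checks.
"""

from __future__ import annotations

import numpy as np


def ml_bruteforce(data: np.ndarray, boundary: str = "replicate") -> np.ndarray:
    """Triple-loop 3D modified Laplacian."""
    nx, ny, nz = data.shape

    def at(x, y, z):
        if boundary == "replicate":
            x = min(max(x, 0), nx - 1)
            y = min(max(y, 0), ny - 1)
            z = min(max(z, 0), nz - 1)
        elif not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
            return 0.0
        return float(data[x, y, z])

    out = np.zeros_like(data, dtype=float)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                c = 2.0 * at(x, y, z)
                out[x, y, z] = (
                    abs(c - at(x - 1, y, z) - at(x + 1, y, z))
                    + abs(c - at(x, y - 1, z) - at(x, y + 1, z))
                    + abs(c - at(x, y, z - 1) - at(x, y, z + 1))
                )
    return out


def block_ranges_bruteforce(shape, n):
    """Enumerate block slices by stepping each axis with stride 2n+1."""
    edge = 2 * n + 1
    ranges = []
    for x0 in range(0, shape[0], edge):
        for y0 in range(0, shape[1], edge):
            for z0 in range(0, shape[2], edge):
                ranges.append(
                    (
                        slice(x0, min(x0 + edge, shape[0])),
                        slice(y0, min(y0 + edge, shape[1])),
                        slice(z0, min(z0 + edge, shape[2])),
                    )
                )
    return ranges


def sml_bruteforce(ml: np.ndarray, n: int) -> np.ndarray:
    """Per-block ML sums via explicit voxel loops."""
    edge = 2 * n + 1
    counts = tuple(-(-s // edge) for s in ml.shape)
    out = np.zeros(counts)
    for bi in range(counts[0]):
        for bj in range(counts[1]):
            for bk in range(counts[2]):
                total = 0.0
                for x in range(bi * edge, min((bi + 1) * edge, ml.shape[0])):
                    for y in range(bj * edge, min((bj + 1) * edge, ml.shape[1])):
                        for z in range(bk * edge, min((bk + 1) * edge, ml.shape[2])):
                            total += float(ml[x, y, z])
                out[bi, bj, bk] = total
    return out


def mf_bruteforce(bv: np.ndarray, mode: str = "unanimous6") -> np.ndarray:
    """Single-pass consistency verification by explicit neighbourhood scan."""
    out = bv.copy()
    shape = bv.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                v = bv[i, j, k]
                if v == 0.5:
                    continue
                opposite = 1.0 - v
                neighbours = []
                for di, dj, dk in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0),
                    (0, -1, 0), (0, 0, 1), (0, 0, -1),
                ):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if 0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]:
                        neighbours.append(bv[ii, jj, kk])
                disagreeing = sum(1 for nb in neighbours if nb == opposite)
                if mode == "unanimous6":
                    if len(neighbours) == 6 and disagreeing == 6:
                        out[i, j, k] = opposite
                elif disagreeing >= 4:
                    out[i, j, k] = opposite
    return out


def gaussian_smooth_bruteforce(
    data: np.ndarray, sigma: float, radius: int
) -> np.ndarray:
    """Windowed normalized Gaussian smoothing by direct summation."""
    nx, ny, nz = data.shape
    out = np.zeros_like(data, dtype=float)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                num = den = 0.0
                for xp in range(max(0, x - radius), min(nx, x + radius + 1)):
                    for yp in range(max(0, y - radius), min(ny, y + radius + 1)):
                        for zp in range(max(0, z - radius), min(nz, z + radius + 1)):
                            d2 = (x - xp) ** 2 + (y - yp) ** 2 + (z - zp) ** 2
                            g = np.exp(-d2 / (2.0 * sigma**2))
                            num += g * data[xp, yp, zp]
                            den += g
                out[x, y, z] = num / den
    return out


def _gaussian_kernel2d(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    r = size // 2
    k = np.arange(-r, r + 1, dtype=float)
    g1 = np.exp(-(k**2) / (2.0 * sigma**2))
    g2 = np.outer(g1, g1)
    return g2 / g2.sum()


def ssim_valid_window(
    img1: np.ndarray, img2: np.ndarray, data_range: float,
    k1: float = 0.01, k2: float = 0.03,
) -> float:
    """Gaussian-weighted SSIM averaged over fully-interior 11x11 windows."""
    w = _gaussian_kernel2d()
    r = w.shape[0] // 2
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    vals = []
    img1 = np.asarray(img1, float)
    img2 = np.asarray(img2, float)
    for i in range(r, img1.shape[0] - r):
        for j in range(r, img1.shape[1] - r):
            a = img1[i - r : i + r + 1, j - r : j + r + 1]
            b = img2[i - r : i + r + 1, j - r : j + r + 1]
            mu_a = float((w * a).sum())
            mu_b = float((w * b).sum())
            var_a = float((w * a * a).sum()) - mu_a**2
            var_b = float((w * b * b).sum()) - mu_b**2
            cov = float((w * a * b).sum()) - mu_a * mu_b
            vals.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
            )
    return float(np.mean(vals))


def cross_entropy_bruteforce(
    source: np.ndarray, fused: np.ndarray, bins: int
) -> float:
    """CE by direct per-bin summation with add-one smoothing."""

    def norm(img):
        img = np.asarray(img, float)
        lo, hi = img.min(), img.max()
        return np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)

    hs, _ = np.histogram(norm(source), bins=bins, range=(0, 1))
    hf, _ = np.histogram(norm(fused), bins=bins, range=(0, 1))
    total = 0.0
    for cs, cf in zip(hs, hf):
        ps = (cs + 1) / (hs.sum() + bins)
        pf = (cf + 1) / (hf.sum() + bins)
        total += ps * np.log2(ps / pf)
    return total
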