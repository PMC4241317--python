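"""Synthetic test inputs: phantoms and simulated k-space acquisitions.

These stand in for clinical scans so the whole pipeline can be exercised
without any external data: an analytic Shepp-Logan ellipse phantom
(piecewise-constant anatomy), a seeded textured phantom (smooth regions plus
oriented sinusoidal texture and thin curvilinear structures, emulating
vessel-rich anatomy), and a patch-wise exactly-sparse phantom for
coefficient-recovery experiments.  Acquisition is simulated by masking the
unitary centered 2D DFT and adding zero-mean complex Gaussian noise whose
``sigma`` is the per-channel (real and imaginary) standard deviation.
Phantom intensities are scaled to [0, 255] to match the 255-peak PSNR.
"""

from __future__ import annotations

import numpy as np

from .operators import KSpaceData, SamplingMask, aggregate_patches, fft2c

__all__ = [
    "shepp_logan",
    "piecewise_texture_phantom",
    "dict_sparse_phantom",
    "simulate_acquisition",
]

# modified Shepp-Logan ellipse table: (intensity, a, b, x0, y0, angle_deg)
_SHEPP_LOGAN_ELLIPSES = [
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.874, 0.0, -0.0184, 0.0),
    (-0.2, 0.11, 0.31, 0.22, 0.0, -18.0),
    (-0.2, 0.16, 0.41, -0.22, 0.0, 18.0),
    (0.1, 0.21, 0.25, 0.0, 0.35, 0.0),
    (0.1, 0.046, 0.046, 0.0, 0.1, 0.0),
    (0.1, 0.046, 0.046, 0.0, -0.1, 0.0),
    (0.1, 0.046, 0.023, -0.08, -0.605, 0.0),
    (0.1, 0.023, 0.023, 0.0, -0.606, 0.0),
    (0.1, 0.023, 0.046, 0.06, -0.605, 0.0),
]


def shepp_logan(size: int) -> np.ndarray:
    """Modified Shepp-Logan ellipse phantom, real-valued, scaled to
    [0, 255]."""
    if size < 32:
        raise ValueError("size must be >= 32")
    coords = np.linspace(-1.0, 1.0, size)
    # image row index runs top-to-bottom: flip y
    y, x = np.meshgrid(-coords, coords, indexing="ij")
    img = np.zeros((size, size))
    for level, a, b, x0, y0, phi_deg in _SHEPP_LOGAN_ELLIPSES:
        phi = np.deg2rad(phi_deg)
        xr = (x - x0) * np.cos(phi) + (y - y0) * np.sin(phi)
        yr = -(x - x0) * np.sin(phi) + (y - y0) * np.cos(phi)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += level
    img = np.clip(img, 0.0, None)
    return img * (255.0 / img.max())


def piecewise_texture_phantom(size: int, seed: int = 0) -> np.ndarray:
    """Seeded phantom mixing piecewise-smooth regions, oriented sinusoidal
    textures and thin curvilinear structures; scaled into [0, 255] with mean
    pinned near 120."""
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng(seed)
    coords = np.linspace(-1.0, 1.0, size)
    y, x = np.meshgrid(coords, coords, indexing="ij")

    # piecewise-smooth base: nearest-seed (Voronoi) regions at random levels
    n_regions = 6
    cx = rng.uniform(-1, 1, n_regions)
    cy = rng.uniform(-1, 1, n_regions)
    levels = rng.uniform(60.0, 190.0, n_regions)
    d = (x[..., None] - cx) ** 2 + (y[..., None] - cy) ** 2
    region = np.argmin(d, axis=-1)
    img = levels[region]

    # oriented sinusoidal texture confined to two of the regions
    for ridx in rng.choice(n_regions, size=2, replace=False):
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(8.0, 20.0)
        tex = 25.0 * np.sin(2 * np.pi * freq * (x * np.cos(theta) + y * np.sin(theta)))
        img = np.where(region == ridx, img + tex, img)

    # thin curvilinear structures (vessel-like sine tracks, ~1 px wide)
    for _ in range(4):
        amp = rng.uniform(0.1, 0.4)
        freq = rng.uniform(1.0, 3.0)
        off = rng.uniform(-0.6, 0.6)
        bright = rng.uniform(200.0, 255.0)
        t = np.linspace(-1, 1, 4 * size)
        r = np.clip(((off + amp * np.sin(2 * np.pi * freq * t) + 1) / 2 * (size - 1)),
                    0, size - 1).astype(int)
        c = np.clip(((t + 1) / 2 * (size - 1)), 0, size - 1).astype(int)
        if rng.uniform() < 0.5:
            r, c = c, r
        img[r, c] = bright

    img = img - img.mean() + 120.0
    return np.clip(img, 0.0, 255.0)


def dict_sparse_phantom(
    size: int, D: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Image whose non-overlapping ``s x s`` tiles are exact ``k``-sparse
    combinations of the dictionary atoms; returns (image, true coefficient
    matrix).  ``extract_patches(image, s, s)`` equals ``D @ Gamma_true``
    exactly by construction."""
    M, J = D.shape
    side = int(round(np.sqrt(M)))
    if side * side != M:
        raise ValueError("dictionary atoms must be square patches")
    if size % side:
        raise ValueError(f"size {size} must be a multiple of the patch side {side}")
    if k > J:
        raise ValueError(f"sparsity k={k} exceeds atom count J={J}")
    rng = np.random.default_rng(seed)
    n_tiles = (size // side) ** 2
    dtype = complex if np.iscomplexobj(D) else float
    Gamma = np.zeros((J, n_tiles), dtype=dtype)
    for l in range(n_tiles):
        support = rng.choice(J, size=k, replace=False)
        mags = rng.uniform(1.0, 2.0, size=k)
        if np.iscomplexobj(D):
            phases = np.exp(2j * np.pi * rng.uniform(size=k))
            Gamma[support, l] = mags * phases
        else:
            Gamma[support, l] = mags * rng.choice([-1.0, 1.0], size=k)
    patches = D @ Gamma
    image = aggregate_patches(patches, (size, size), side, side)
    return image, Gamma


def simulate_acquisition(
    u: np.ndarray, mask: SamplingMask, sigma: float = 0.0, seed: int = 0
) -> KSpaceData:
    """Simulate CS acquisition: subsample the unitary centered 2D DFT of
    ``u`` on the mask and add i.i.d. complex Gaussian noise (per-channel
    standard deviation ``sigma``) on the sampled cells only."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    u = np.asarray(u)
    if u.shape != mask.shape:
        raise ValueError(f"image shape {u.shape} != mask shape {mask.shape}")
    samples = np.where(mask.indicator, fft2c(u), 0.0)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        q = mask.n_sampled
        noise = rng.normal(0.0, sigma, q) + 1j * rng.normal(0.0, sigma, q)
        samples = samples.copy()
        samples[mask.indicator] += noise
    return KSpaceData(samples=samples, mask=mask, noise_sigma=float(sigma))
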