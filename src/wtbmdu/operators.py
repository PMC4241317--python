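"""Linear operators of the acquisition and patch model.

The forward model is ``f = F_p u + n`` where ``F_p`` is the partially
sampled, *unitary*, centered 2D discrete Fourier transform (DC at the grid
center) and ``n`` is complex Gaussian noise.  Patch extraction ``R`` pulls
every stride-``r`` overlapping ``s``-by-``s`` patch out of the image with
periodic (wrap-around) boundaries, so that the aggregation adjoint satisfies
``R^T R = omega * I`` exactly with ``omega = (s/r)**2``.

Conventions fixed here (results are invariant to them, reproducibility is
not): patch offsets are enumerated in row-major order over the image, and
each patch is vectorized in column-major (Fortran) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingMask",
    "KSpaceData",
    "fft2c",
    "ifft2c",
    "fourier_encode",
    "fourier_adjoint",
    "make_mask",
    "extract_patches",
    "aggregate_patches",
    "patch_overlap_factor",
]

MASK_KINDS = ("random2d", "radial", "cartesian1d", "spiral")


@dataclass
class SamplingMask:
    """Boolean k-space sampling indicator in centered frequency coordinates.

    ``fraction`` is the realized sampled fraction (count of True cells over
    total cells); the DC cell is always sampled.
    """

    indicator: np.ndarray
    kind: str
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.indicator.ndim != 2:
            raise ValueError("mask indicator must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.indicator.shape

    @property
    def fraction(self) -> float:
        return float(self.indicator.mean())

    @property
    def n_sampled(self) -> int:
        return int(self.indicator.sum())


@dataclass
class KSpaceData:
    """Acquired k-space samples stored on the full grid, zero off-mask.

    ``noise_sigma`` is the standard deviation of both the real and the
    imaginary noise channel, so the expected noise energy over the Q sampled
    cells is ``2 * sigma**2 * Q`` and the corresponding l2 noise bound is
    ``sigma * sqrt(2 Q)``.
    """

    samples: np.ndarray
    mask: SamplingMask
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.shape != self.mask.shape:
            raise ValueError(
                f"samples shape {self.samples.shape} != mask shape {self.mask.shape}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        # enforce the off-mask-zero invariant
        self.samples = np.where(self.mask.indicator, self.samples, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape

    def noise_bound(self, scaled: bool = True) -> float:
        """l2 bound on the noise: sigma*sqrt(2Q) (default) or plain sigma."""
        if scaled:
            return float(self.noise_sigma * np.sqrt(2.0 * self.mask.n_sampled))
        return float(self.noise_sigma)


def fft2c(u: np.ndarray) -> np.ndarray:
    """Unitary centered 2D DFT (DC at ``(N_r//2, N_c//2)``)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(u), norm="ortho"))


def ifft2c(f: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(f), norm="ortho"))


def fourier_encode(u: np.ndarray, mask: SamplingMask) -> KSpaceData:
    """Apply the partial Fourier encoding ``F_p``: unitary centered DFT,
    then zero the unsampled cells."""
    u = np.asarray(u)
    if u.shape != mask.shape:
        raise ValueError(f"image shape {u.shape} != mask shape {mask.shape}")
    samples = np.where(mask.indicator, fft2c(u), 0.0)
    return KSpaceData(samples=samples, mask=mask)


def fourier_adjoint(f: KSpaceData) -> np.ndarray:
    """Adjoint ``F_p^H``: inverse unitary centered DFT of the zero-filled
    grid.  With a partial mask this is the zero-filled reconstruction."""
    return ifft2c(np.where(f.mask.indicator, f.samples, 0.0))


# ---------------------------------------------------------------------------
# sampling-mask generation
# ---------------------------------------------------------------------------


def _center(shape: tuple[int, int]) -> tuple[int, int]:
    return shape[0] // 2, shape[1] // 2


def _radial_weights(shape: tuple[int, int], decay: float) -> np.ndarray:
    """Variable-density law: polynomially decaying probability with distance
    from DC, ``w = (1 - d)^decay`` on normalized distance ``d in [0, 1]``."""
    cr, cc = _center(shape)
    rr, cc_ = np.meshgrid(np.arange(shape[0]) - cr, np.arange(shape[1]) - cc,
                          indexing="ij")
    d = np.sqrt(rr**2 + cc_**2)
    d = d / max(d.max(), 1.0)
    return np.maximum(1.0 - d, 1e-12) ** decay


def _weighted_choice_without_replacement(
    weights: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a weighted sample of exactly ``n`` items (Efraimidis-
    Spirakis exponential-key scheme)."""
    keys = rng.exponential(size=weights.size) / weights.ravel()
    return np.argpartition(keys, n - 1)[:n]


def _random2d_mask(shape, fraction, decay, rng):
    n_target = int(round(fraction * shape[0] * shape[1]))
    w = _radial_weights(shape, decay)
    idx = _weighted_choice_without_replacement(w, n_target, rng)
    m = np.zeros(shape[0] * shape[1], dtype=bool)
    m[idx] = True
    return m.reshape(shape)

def _cartesian1d_mask(shape, fraction, decay, rng):
    # full readout (horizontal) lines; phase-encode rows drawn by the same
    # variable-density law collapsed to 1D
    n_rows = max(1, int(round(fraction * shape[0])))
    cr = shape[0] // 2
    d = np.abs(np.arange(shape[0]) - cr) / max(cr, 1)
    w = np.maximum(1.0 - d, 1e-12) ** decay
    rows = _weighted_choice_without_replacement(w, n_rows, rng)
    m = np.zeros(shape, dtype=bool)
    m[rows, :] = True
    m[cr, :] = True
    return m

def _rasterize_line(shape, angle):
    """Digital line through DC at the given angle (cells hit by dense
    sampling of the continuous line, rounded to the grid)."""
    cr, cc = _center(shape)
    half = int(np.ceil(np.hypot(*shape)))
    t = np.linspace(-half, half, 4 * half + 1)
    r = np.round(cr + t * np.sin(angle)).astype(int)
    c = np.round(cc + t * np.cos(angle)).astype(int)
    keep = (r >= 0) & (r < shape[0]) & (c >= 0) & (c < shape[1])
    return r[keep], c[keep]

def _radial_mask_n(shape, n_spokes):
    m = np.zeros(shape, dtype=bool)
    for k in range(n_spokes):
        r, c = _rasterize_line(shape, np.pi * k / n_spokes)
        m[r, c] = True
    return m

def _spiral_arm(shape, phase, turns, density_power):
    cr, cc = _center(shape)
    rmax = min(cr, cc)
    theta = np.linspace(0.0, 2 * np.pi * turns, int(200 * turns * np.pi))
    radius = rmax * (theta / theta[-1]) ** density_power
    r = np.round(cr + radius * np.sin(theta + phase)).astype(int)
    c = np.round(cc + radius * np.cos(theta + phase)).astype(int)
    keep = (r >= 0) & (r < shape[0]) & (c >= 0) & (c < shape[1])
    return r[keep], c[keep]

def _spiral_mask_n(shape, n_arms, turns, density_power):
    m = np.zeros(shape, dtype=bool)
    for k in range(n_arms):
        r, c = _spiral_arm(shape, 2 * np.pi * k / n_arms, turns, density_power)
        m[r, c] = True
    return m


def _fit_count(build, target_fraction, n_max):
    """Smallest unit count whose realized fraction reaches the target, or the
    closer of the two bracketing counts."""
    prev_frac, prev_n = 0.0, 0
    for n in range(1, n_max + 1):
        frac = build(n).mean()
        if frac >= target_fraction:
            if prev_n and abs(prev_frac - target_fraction) < abs(frac - target_fraction):
                return prev_n
            return n
        prev_frac, prev_n = frac, n
    raise ValueError(
        f"target fraction {target_fraction} unreachable with {n_max} units"
    )


def make_mask(
    kind: str,
    shape: tuple[int, int],
    fraction: float | None = None,
    accel: float | None = None,
    seed: int = 0,
    *,
    decay: float = 3.0,
    n_spokes: int | None = None,
    n_arms: int | None = None,
    spiral_turns: float = 8.0,
    spiral_density_power: float = 2.0,
) -> SamplingMask:
    """Generate a k-space sampling mask of one of the four trajectory
    families: variable-density 2D random, pseudo-radial (digital spokes
    through DC), 1D-random Cartesian phase encoding, and a Cartesian
    rasterization of variable-density spiral arms.

    Exactly one of ``fraction`` (sampled fraction, in (0, 1]) or ``accel``
    (acceleration factor = 1/fraction) must be given, except for the
    deterministic kinds where an explicit ``n_spokes``/``n_arms`` may be
    passed instead.  The DC cell is always sampled.  Masks are reproducible
    from (kind, shape, parameters, seed).
    """
    if kind not in MASK_KINDS:
        raise ValueError(f"unknown mask kind {kind!r}; choose from {MASK_KINDS}")
    if accel is not None:
        if fraction is not None:
            raise ValueError("give either fraction or accel, not both")
        fraction = 1.0 / accel
    if fraction is not None and not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    shape = (int(shape[0]), int(shape[1]))
    if kind in ("radial", "spiral") and shape[0] != shape[1]:
        raise ValueError(f"{kind} masks require a square grid")

    params: dict = {"fraction_target": fraction, "decay": decay}
    rng = np.random.default_rng(seed)

    if fraction == 1.0:
        ind = np.ones(shape, dtype=bool)
    elif kind == "random2d":
        if fraction is None:
            raise ValueError("random2d requires a target fraction")
        ind = _random2d_mask(shape, fraction, decay, rng)
    elif kind == "cartesian1d":
        if fraction is None:
            raise ValueError("cartesian1d requires a target fraction")
        ind = _cartesian1d_mask(shape, fraction, decay, rng)
    elif kind == "radial":
        if n_spokes is None:
            if fraction is None:
                raise ValueError("radial requires fraction or n_spokes")
            n_spokes = _fit_count(
                lambda n: _radial_mask_n(shape, n), fraction, 4 * shape[0]
            )
        ind = _radial_mask_n(shape, n_spokes)
        params["n_spokes"] = n_spokes
    else:  # spiral
        if n_arms is None:
            if fraction is None:
                raise ValueError("spiral requires fraction or n_arms")
            n_arms = _fit_count(
                lambda n: _spiral_mask_n(shape, n, spiral_turns, spiral_density_power),
                fraction,
                8 * shape[0],
            )
        ind = _spiral_mask_n(shape, n_arms, spiral_turns, spiral_density_power)
        params["n_arms"] = n_arms
        params["turns"] = spiral_turns
        params["density_power"] = spiral_density_power

    ind[_center(shape)] = True  # DC always acquired
    return SamplingMask(indicator=ind, kind=kind, seed=seed, params=params)


# ---------------------------------------------------------------------------
# patch extraction / aggregation
# ---------------------------------------------------------------------------


def _patch_indices(shape, side, stride):
    n_r, n_c = shape
    ci = np.arange(0, n_r, stride)
    cj = np.arange(0, n_c, stride)
    # column-major vectorization inside the patch
    m = np.arange(side * side)
    di, dj = m % side, m // side
    rows = (ci[:, None, None, None] + di[None, None, None, :]) % n_r
    cols = (cj[None, :, None, None] + dj[None, None, None, :]) % n_c
    rows = np.broadcast_to(rows, (ci.size, cj.size, 1, side * side))
    cols = np.broadcast_to(cols, (ci.size, cj.size, 1, side * side))
    return rows.reshape(-1, side * side), cols.reshape(-1, side * side)


def extract_patches(
    u: np.ndarray, side: int, stride: int, periodic: bool = True
) -> np.ndarray:
    """Column-stack every stride-``stride`` overlapping ``side``x``side``
    patch of ``u`` (periodic wrap at borders) into an ``(side**2, L)``
    matrix, ``L = (N_r/stride)*(N_c/stride)``.

    Patch offsets run in row-major order over the image; within a patch,
    pixels are vectorized column-major.
    """
    u = np.asarray(u)
    if u.ndim != 2:
        raise ValueError("expected a 2D image")
    if not periodic:
        raise NotImplementedError("only periodic patch extraction is supported")
    if u.shape[0] % stride or u.shape[1] % stride:
        raise ValueError(
            f"stride {stride} must divide image shape {u.shape} (periodic mode)"
        )
    rows, cols = _patch_indices(u.shape, side, stride)
    return u[rows, cols].T.copy()


def aggregate_patches(
    patches: np.ndarray,
    shape: tuple[int, int],
    side: int,
    stride: int,
    periodic: bool = True,
) -> np.ndarray:
    """Adjoint of :func:`extract_patches`: add every patch back at its
    offset.  ``aggregate(extract(u)) == (side/stride)**2 * u`` exactly."""
    patches = np.asarray(patches)
    if not periodic:
        raise NotImplementedError("only periodic patch aggregation is supported")
    if shape[0] % stride or shape[1] % stride:
        raise ValueError(f"stride {stride} must divide image shape {shape}")
    n_patches = (shape[0] // stride) * (shape[1] // stride)
    if patches.shape != (side * side, n_patches):
        raise ValueError(
            f"patch matrix shape {patches.shape} inconsistent with image shape "
            f"{shape}, side {side}, stride {stride}"
        )
    rows, cols = _patch_indices(shape, side, stride)
    out = np.zeros(shape, dtype=np.result_type(patches.dtype, float))
    np.add.at(out, (rows.ravel(), cols.ravel()), patches.T.ravel())
    return out


def patch_overlap_factor(side: int, stride: int) -> float:
    """The overlap constant omega = (side/stride)**2 in R^T R = omega*I."""
    return (side / stride) ** 2
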