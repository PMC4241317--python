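"""Image-quality metrics: PSNR on a 255 peak and the high-frequency error
norm (HFEN).

Complex images are compared by modulus.  By default the reference magnitude
is affinely mapped onto [0, 255] and the *same* map is applied to the test
image, so the 255-peak PSNR formula is meaningful regardless of the source
scale; pass ``normalize=False`` to compare raw magnitudes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["MetricReport", "psnr", "hfen", "rmse", "log_kernel", "evaluate_pair"]

PSNR_CAP_DB = 300.0


@dataclass
class MetricReport:
    psnr_db: float
    hfen: float
    hfen_normalized: float
    rmse: float

    def to_dict(self) -> dict:
        return asdict(self)


def _magnitudes(reference: np.ndarray, test: np.ndarray, normalize: bool):
    reference = np.abs(np.asarray(reference)).astype(float)
    test = np.abs(np.asarray(test)).astype(float)
    if reference.shape != test.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs test {test.shape}"
        )
    if normalize:
        lo, hi = reference.min(), reference.max()
        scale = 255.0 / (hi - lo) if hi > lo else 1.0
        reference = (reference - lo) * scale
        test = (test - lo) * scale
    return reference, test


def rmse(reference: np.ndarray, test: np.ndarray, normalize: bool = True) -> float:
    """Root-mean-square magnitude error (after the shared [0,255] map)."""
    ref, tst = _magnitudes(reference, test, normalize)
    return float(np.sqrt(np.mean((ref - tst) ** 2)))


def psnr(reference: np.ndarray, test: np.ndarray, normalize: bool = True) -> float:
    """Peak signal-to-noise ratio, ``20 log10(255 / RMSE)`` in dB.

    Identical images give the cap value (300 dB) rather than infinity.
    """
    err = rmse(reference, test, normalize)
    if err == 0.0:
        return PSNR_CAP_DB
    return float(min(20.0 * np.log10(255.0 / err), PSNR_CAP_DB))


def log_kernel(size: int = 15, sigma: float = 1.5) -> np.ndarray:
    """Rotationally symmetric Laplacian-of-Gaussian filter taps.

    Same construction as the classic image-processing toolbox filter: a
    normalized Gaussian modulated by ``(r^2 - 2 sigma^2)/sigma^4``, then
    mean-subtracted so the taps sum to zero (the filter kills constants).
    """
    half = (size - 1) / 2.0
    x = np.arange(size) - half
    xx, yy = np.meshgrid(x, x, indexing="ij")
    r2 = xx**2 + yy**2
    g = np.exp(-r2 / (2.0 * sigma**2))
    g /= g.sum()
    h = g * (r2 - 2.0 * sigma**2) / sigma**4
    return h - h.mean()


def hfen(
    reference: np.ndarray,
    test: np.ndarray,
    normalize: bool = True,
    normalized: bool = False,
    size: int = 15,
    sigma: float = 1.5,
) -> float:
    """High-frequency error norm: l2 norm of the difference of the
    Laplacian-of-Gaussian-filtered images (15x15 taps, sigma = 1.5,
    zero-padded borders).  With ``normalized=True`` the value is divided by
    the norm of the filtered reference."""
    ref, tst = _magnitudes(reference, test, normalize)
    kernel = log_kernel(size, sigma)
    diff = fftconvolve(tst - ref, kernel, mode="same")
    value = float(np.linalg.norm(diff))
    if normalized:
        ref_norm = float(np.linalg.norm(fftconvolve(ref, kernel, mode="same")))
        return value / ref_norm if ref_norm > 0 else np.inf
    return value


def evaluate_pair(
    reference: np.ndarray, test: np.ndarray, normalize: bool = True
) -> MetricReport:
    """PSNR, HFEN (absolute and normalized) and RMSE for one image pair."""
    return MetricReport(
        psnr_db=psnr(reference, test, normalize),
        hfen=hfen(reference, test, normalize),
        hfen_normalized=hfen(reference, test, normalize, normalized=True),
        rmse=rmse(reference, test, normalize),
    )
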