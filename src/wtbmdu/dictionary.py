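"""Patch dictionary: DCT initialization and gradient-step updating.

The dictionary ``D`` is an ``M x J`` matrix of unit-norm atoms, ``M = s**2``
pixels per patch and ``J = K*M`` atoms (``K`` the overcompleteness).  It is
adapted to the image being reconstructed by small gradient steps along the
augmented-Lagrangian objective, ``D <- D + xi * Y Gamma^H``, followed by
per-atom renormalization.  The conjugate transpose is used (rather than the
plain transpose) so that the step is the true gradient of the real-valued
objective when the data are complex; for real data the two coincide.
"""

from __future__ import annotations

import numpy as np

__all__ = ["init_dct_dictionary", "update_dictionary", "gram_spectral_radius"]

_DEGENERATE_NORM = 1e-12


def _dct_basis(side: int) -> np.ndarray:
    """Orthonormal DCT-II basis vectors as columns of an s x s matrix."""
    n = np.arange(side)
    k = np.arange(side)
    basis = np.cos(np.pi * (2 * n[:, None] + 1) * k[None, :] / (2 * side))
    basis[:, 0] *= np.sqrt(1.0 / side)
    basis[:, 1:] *= np.sqrt(2.0 / side)
    return basis


def _overcomplete_dct_1d(side: int, n_freq: int) -> np.ndarray:
    """Sampled-cosine frames with ``n_freq >= side`` frequencies, the usual
    overcomplete-DCT construction: non-DC atoms are mean-removed and all are
    normalized."""
    t = np.arange(side)
    atoms = np.cos(np.pi * t[:, None] * np.arange(n_freq)[None, :] / n_freq)
    atoms[:, 1:] -= atoms[:, 1:].mean(axis=0, keepdims=True)
    return atoms / np.linalg.norm(atoms, axis=0, keepdims=True)


def init_dct_dictionary(M: int, K: int = 1, complex_mode: bool = False) -> np.ndarray:
    """Initial ``M x K*M`` dictionary of (overcomplete) 2D-DCT atoms.

    ``K = 1`` gives the orthonormal separable 2D-DCT basis on ``s x s``
    patches (``s = sqrt(M)``); ``K > 1`` samples ``ceil(sqrt(K*M))`` cosine
    frequencies per axis, forms outer products and keeps the first ``K*M``
    normalized columns.  In complex mode every atom is multiplied by
    ``(1 + 1j)/sqrt(2)`` (same DCT in the real and imaginary parts, still
    unit norm).
    """
    side = int(round(np.sqrt(M)))
    if side * side != M:
        raise ValueError(f"M={M} is not a perfect square patch size")
    if K < 1 or int(K) != K:
        raise ValueError(f"overcompleteness K must be a positive integer, got {K}")
    if K == 1:
        b = _dct_basis(side)
    else:
        b = _overcomplete_dct_1d(side, int(np.ceil(np.sqrt(K * M))))
    D = np.kron(b, b)[:, : K * M]
    D = D / np.linalg.norm(D, axis=0, keepdims=True)
    if complex_mode:
        D = D.astype(complex) * ((1.0 + 1.0j) / np.sqrt(2.0))
    return D


def update_dictionary(
    D: np.ndarray, Y: np.ndarray, Gamma: np.ndarray, xi: float
) -> np.ndarray:
    """One gradient step ``D + xi * Y Gamma^H`` with unit-norm renormalization.

    Atoms whose updated norm falls below 1e-12 keep their previous value
    instead of being divided by (near) zero.
    """
    if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(Gamma))):
        raise ValueError("non-finite entries in dictionary update inputs")
    new = D + xi * (Y @ Gamma.conj().T)
    norms = np.linalg.norm(new, axis=0)
    degenerate = norms < _DEGENERATE_NORM
    safe = np.where(degenerate, 1.0, norms)
    new = new / safe[None, :]
    if degenerate.any():
        new[:, degenerate] = D[:, degenerate]
    return new


def gram_spectral_radius(D: np.ndarray) -> float:
    """Largest eigenvalue of ``D^H D`` (exact, via the dense Gram matrix —
    patch dictionaries are small)."""
    gram = D.conj().T @ D
    return float(np.linalg.eigvalsh(gram)[-1].real)
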