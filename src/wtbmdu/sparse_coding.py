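"""Inner-level sparse coding of image patches under the learned dictionary.

Each patch ``R_l u`` is modelled as ``D alpha_l + z_l`` with a sparse
coefficient vector ``alpha_l`` and a small residual ``z_l`` penalized by
``(lambda/2)||z_l||^2``.  The constraint ``z_l = R_l u - D alpha_l`` is
enforced by an augmented-Lagrangian (split-Bregman) scheme with penalty
``beta`` and multipliers ``y_l``:

    L = sum_l ||alpha_l||_1 + (lambda/2)||z_l||^2
        + (beta/2)||R_l u - D alpha_l - z_l + y_l/beta||^2,

with multiplier ascent ``Y <- Y + beta (Ru - Z - D Gamma)``.

The coefficient block is solved by one ISTA step per sweep.  Three update
rules are provided:

* ``code_step_tbmdu`` — plain l1: complex soft-thresholding with a uniform
  threshold (the baseline method);
* ``code_step_wl1`` — reweighted l1: per-entry thresholds scaled by weights
  ``W = 1/(|alpha|^(1-p) + eps)``, the linear local approximation of the
  lp quasi-norm (0 < p <= 1);
* ``code_step_wl2`` — reweighted l2: the closed-form minimizer of the
  weighted ridge surrogate with ``W = 1/(|alpha|^(2-p) + eps)``.

Both weight rules are nonincreasing in ``|alpha|``: small coefficients are
penalized harder, pushing them to exact zero while large ones survive —
this is what makes the lp (p<1) relaxation sharper than plain l1.  ``eps``
guards the division and follows a geometric continuation schedule.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "shrink",
    "intermediate_y",
    "compute_weights",
    "epsilon_schedule",
    "code_step_tbmdu",
    "code_step_wl1",
    "code_step_wl2",
    "update_z",
    "update_multiplier",
    "code_patches",
]


def shrink(g: np.ndarray, tau) -> np.ndarray:
    """Complex soft-thresholding: magnitude reduced by ``tau``, phase kept.

    Equals ``g * max(|g|-tau, 0) / (max(|g|-tau, 0) + tau)`` elementwise
    (with value 0 at g = 0), i.e. ``(g/|g|) * max(|g|-tau, 0)``; for real
    input this is the ordinary soft threshold.  ``tau`` may be a scalar or
    an array of per-entry thresholds, all >= 0.
    """
    tau = np.asarray(tau)
    if np.any(tau < 0):
        raise ValueError("shrink threshold must be nonnegative")
    g = np.asarray(g)
    mag = np.abs(g)
    kept = np.maximum(mag - tau, 0.0)
    denom = np.where(mag > 0, mag, 1.0)
    return g * (kept / denom)


def intermediate_y(
    D: np.ndarray,
    Gamma: np.ndarray,
    B: np.ndarray,
    Y: np.ndarray,
    lam: float,
    beta: float,
) -> np.ndarray:
    """Intermediate variable ``y' = T0 (-D Gamma + B + Y/beta)`` with
    ``T0 = lambda*beta/(lambda+beta)``, which packages the z- and
    multiplier-coupled residual the coefficient step descends along."""
    if lam + beta == 0:
        raise ValueError("lambda + beta must be nonzero")
    t0 = lam * beta / (lam + beta)
    return t0 * (-(D @ Gamma) + B + Y / beta)


def compute_weights(
    Gamma: np.ndarray, p: float, eps_t: float, variant: str
) -> np.ndarray:
    """Reweighting matrix from the previous coefficient iterate.

    ``variant='L1'``: ``1/(|alpha|**(1-p) + eps_t)`` (linear local
    approximation); ``variant='L2'``: ``1/(|alpha|**(2-p) + eps_t)``
    (quadratic local approximation).  Entries lie in (0, 1/eps_t] and are
    nonincreasing in |alpha|.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if eps_t < 0:
        raise ValueError("eps_t must be nonnegative")
    if variant == "L1":
        expo = 1.0 - p
    elif variant == "L2":
        expo = 2.0 - p
    else:
        raise ValueError(f"variant must be 'L1' or 'L2', got {variant!r}")
    # eps_t = 0 is admitted as the exact-limit case (with p = 1 it gives the
    # unweighted reduction; with p < 1 dead coefficients get infinite weight,
    # i.e. stay frozen at zero)
    with np.errstate(divide="ignore"):
        return 1.0 / (np.abs(Gamma) ** expo + eps_t)


def epsilon_schedule(t: int, eps0: float = 5.0, decay: float = 0.02) -> float:
    """Continuation value ``eps_t = eps0 * (1-decay)**t`` — shrunk by 2% per
    inner iteration from an initial 5, tightening the weights toward the
    true lp penalty."""
    if t < 0 or int(t) != t:
        raise ValueError("t must be a nonnegative integer")
    return float(eps0 * (1.0 - decay) ** t)


def _ista_step(Gamma, D, y_imm, lam, beta, gamma):
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    c = (lam + beta) / (gamma * lam * beta)
    return Gamma + c * (D.conj().T @ y_imm), c


def code_step_tbmdu(Gamma, D, y_imm, lam, beta, gamma):
    """Plain-l1 coefficient update: one ISTA sweep, uniform threshold
    ``(lambda+beta)/(gamma*lambda*beta)``."""
    step, c = _ista_step(Gamma, D, y_imm, lam, beta, gamma)
    return shrink(step, c)


def code_step_wl1(Gamma, D, y_imm, lam, beta, gamma, W):
    """Reweighted-l1 coefficient update: same gradient step as the plain
    rule, per-entry threshold scaled by ``W``."""
    if W.shape != Gamma.shape:
        raise ValueError(f"weight shape {W.shape} != coefficient shape {Gamma.shape}")
    step, c = _ista_step(Gamma, D, y_imm, lam, beta, gamma)
    return shrink(step, c * W)


def code_step_wl2(Gamma, D, y_imm, lam, beta, gamma, W):
    """Reweighted-l2 coefficient update: exact minimizer of the weighted
    ridge surrogate,
    ``(gamma*Gamma + (lambda+beta)/(lambda*beta) * D^H y') /
    (gamma + (lambda+beta)/(lambda*beta) * W)`` entrywise."""
    if W.shape != Gamma.shape:
        raise ValueError(f"weight shape {W.shape} != coefficient shape {Gamma.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    ratio = (lam + beta) / (lam * beta)
    denom = gamma + ratio * W
    assert np.all(denom > 0)
    return (gamma * Gamma + ratio * (D.conj().T @ y_imm)) / denom


def update_z(Ru, D, Gamma, Y, lam, beta):
    """Closed-form auxiliary-residual update: the quadratic minimizer
    ``Z = (beta (Ru - D Gamma) + Y) / (lambda + beta)``."""
    return (beta * (Ru - D @ Gamma) + Y) / (lam + beta)


def update_multiplier(Y, Ru, Z, D, Gamma, beta):
    """Augmented-Lagrangian multiplier ascent
    ``Y <- Y + beta (Ru - Z - D Gamma)``."""
    return Y + beta * (Ru - Z - D @ Gamma)


def code_patches(
    patches: np.ndarray,
    D: np.ndarray,
    lam: float = 100.0,
    beta: float = 1.0,
    gamma: float | None = None,
    n_iter: int = 100,
    variant: str = "tbmdu",
    p: float = 0.5,
    eps0: float = 5.0,
    decay: float = 0.02,
) -> np.ndarray:
    """Sparse-code a fixed patch matrix (no image or dictionary update).

    Runs ``n_iter`` augmented-Lagrangian sweeps of (coefficients, residual,
    multiplier) with the chosen coefficient rule and returns the ``J x L``
    coefficient matrix.  Useful for coding experiments and support-recovery
    checks where the dictionary is known.
    """
    from .dictionary import gram_spectral_radius

    if gamma is None:
        gamma = 1.05 * gram_spectral_radius(D)
    J, L = D.shape[1], patches.shape[1]
    Gamma = np.zeros((J, L), dtype=np.result_type(D.dtype, patches.dtype, float))
    Z = np.zeros_like(patches, dtype=Gamma.dtype)
    Y = np.zeros_like(Z)
    for t in range(n_iter):
        B = patches - Z
        y_imm = intermediate_y(D, Gamma, B, Y, lam, beta)
        if variant == "tbmdu":
            Gamma = code_step_tbmdu(Gamma, D, y_imm, lam, beta, gamma)
        elif variant == "wtbmdu_l1":
            W = compute_weights(Gamma, p, epsilon_schedule(t, eps0, decay), "L1")
            Gamma = code_step_wl1(Gamma, D, y_imm, lam, beta, gamma, W)
        elif variant == "wtbmdu_l2":
            W = compute_weights(Gamma, p, epsilon_schedule(t, eps0, decay), "L2")
            Gamma = code_step_wl2(Gamma, D, y_imm, lam, beta, gamma, W)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        Z = update_z(patches, D, Gamma, Y, lam, beta)
        Y = update_multiplier(Y, patches, Z, D, Gamma, beta)
    return Gamma
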