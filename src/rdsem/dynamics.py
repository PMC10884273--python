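"""Stationary first-order vector-autoregression algebra shared across modules."""

from __future__ import annotations

import numpy as np
from .exceptions import ConfigError


def spectral_radius(phi: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(phi))))


def stationary_cov(phi: np.ndarray, sigma_u: np.ndarray) -> np.ndarray:
    """Stationary covariance of eps_t = Phi eps_{t-1} + u_t, u ~ N(0, Sigma_u).

    Solves the discrete Lyapunov equation Sigma = Phi Sigma Phi' + Sigma_u in
    vec form, vec(Sigma) = (I - Phi (x) Phi)^{-1} vec(Sigma_u).  Requires
    spectral radius of Phi strictly below one.
    """
    phi = np.asarray(phi, dtype=float)
    sigma_u = np.asarray(sigma_u, dtype=float)
    if spectral_radius(phi) >= 1.0 - 1e-10:
        raise ConfigError(f"non-stationary Phi (spectral radius {spectral_radius(phi):.4f})")
    p = phi.shape[0]
    vec = np.linalg.solve(np.eye(p * p) - np.kron(phi, phi), sigma_u.ravel())
    cov = vec.reshape(p, p)
    return 0.5 * (cov + cov.T)


def stationary_cov_batched(phi: np.ndarray, sigma_u: np.ndarray) -> np.ndarray:
    """Vectorized stationary covariances for stacked (n, p, p) Phi / Sigma_u.

    Uses the vec form with batched linear solves; entries with spectral
    radius >= 1 come back as NaN.
    """
    phi = np.asarray(phi, dtype=float)
    sigma_u = np.asarray(sigma_u, dtype=float)
    n, p, _ = phi.shape
    kron = np.einsum("nij,nkl->nikjl", phi, phi).reshape(n, p * p, p * p)
    lhs = np.eye(p * p)[None] - kron
    rad = np.max(np.abs(np.linalg.eigvals(phi)), axis=1)
    out = np.full((n, p, p), np.nan)
    ok = rad < 1.0 - 1e-10
    if ok.any():
        vec = np.linalg.solve(lhs[ok], sigma_u[ok].reshape(-1, p * p, 1))
        cov = vec.reshape(-1, p, p)
        out[ok] = 0.5 * (cov + np.swapaxes(cov, 1, 2))
    return out
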