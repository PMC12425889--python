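"""Thin-plate-spline interpolation shared by constraint prediction and repair.

The interpolant for each output component is

    s(x) = sum_i w_i * phi(|x - x_i|) + a0 + a . x,    phi(r) = r^2 log r

with the usual side conditions (kernel weights orthogonal to constants and
to the source coordinates), which make the map reproduce affine
transformations exactly.  A small ridge term on the kernel block trades
exact interpolation for robustness when the sources are degenerate
(coplanar/collinear).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["ThinPlateSpline", "fit_tps", "tps_kernel"]


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """phi(r) = r^2 log r with phi(0) = 0."""
    r = np.asarray(r, dtype=np.float64)
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


@dataclass
class ThinPlateSpline:
    """A fitted TPS map R^3 -> R^d.

    ``kernel_coefficients`` is ``(m, d)``; ``affine_part`` is ``(4, d)``
    (constant row first, then the 3x d linear block).
    """

    control_sources: np.ndarray
    control_targets: np.ndarray
    kernel_coefficients: np.ndarray
    affine_part: np.ndarray
    ridge: float

    def __call__(self, query: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(query, dtype=np.float64))
        K = tps_kernel(cdist(q, self.control_sources))
        P = np.hstack([np.ones((q.shape[0], 1)), q])
        out = K @ self.kernel_coefficients + P @ self.affine_part
        if np.asarray(query).ndim == 1:
            return out[0]
        return out

    @property
    def side_condition_residual(self) -> float:
        """max |P^T w|: zero when the orthogonality conditions hold."""
        P = np.hstack(
            [np.ones((self.control_sources.shape[0], 1)), self.control_sources]
        )
        return float(np.abs(P.T @ self.kernel_coefficients).max())


def _solve_tps(
    sources: np.ndarray, targets: np.ndarray, ridge: float
) -> tuple[np.ndarray, np.ndarray]:
    m = sources.shape[0]
    K = tps_kernel(cdist(sources, sources))
    P = np.hstack([np.ones((m, 1)), sources])
    A = np.zeros((m + 4, m + 4))
    A[:m, :m] = K + ridge * np.eye(m)
    A[:m, m:] = P
    A[m:, :m] = P.T
    b = np.zeros((m + 4, targets.shape[1]))
    b[:m] = targets
    sol = np.linalg.solve(A, b)
    return sol[:m], sol[m:]


def fit_tps(
    sources: np.ndarray, targets: np.ndarray, ridge: float = 0.0
) -> ThinPlateSpline:
    """Fit a TPS from ``sources`` (m x 3) to ``targets`` (m x d), m >= 5.

    At ``ridge = 0`` the fit interpolates the controls exactly provided the
    sources are in general position (not all coplanar).  A singular or
    numerically unreliable system triggers one automatic retry with
    ``ridge = 1e-10 * (mean pairwise distance)^2``; if that also fails the
    system is solved in the least-squares sense.
    """
    sources = np.asarray(sources, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if targets.ndim == 1:
        targets = targets[:, None]
    m = sources.shape[0]
    if m < 5:
        raise ValueError(f"TPS fit needs at least 5 points, got {m}")
    if sources.shape[0] != targets.shape[0]:
        raise ValueError("sources and targets lengths differ")

    d_mean = float(cdist(sources, sources).mean())
    scale = max(d_mean, 1e-300)

    def attempt(rdg: float) -> ThinPlateSpline | None:
        try:
            w, a = _solve_tps(sources, targets, rdg)
        except np.linalg.LinAlgError:
            return None
        model = ThinPlateSpline(sources, targets, w, a, rdg)
        if not np.isfinite(w).all() or not np.isfinite(a).all():
            return None
        # reject fits that fail to reproduce their own controls
        resid = np.abs(model(sources) - targets).max()
        tol = max(1e-6 * scale, 10.0 * rdg)
        if rdg == 0.0 and resid > tol:
            return None
        return model

    model = attempt(ridge)
    if model is None:
        bumped = 1e-10 * scale**2 if ridge == 0.0 else 10.0 * ridge
        import logging

        logging.getLogger(__name__).warning(
            "TPS system singular at ridge=%g; retrying with ridge=%g",
            ridge,
            bumped,
        )
        model = attempt(bumped)
    if model is None:
        # final fallback: least squares on the bumped system
        K = tps_kernel(cdist(sources, sources))
        P = np.hstack([np.ones((m, 1)), sources])
        A = np.zeros((m + 4, m + 4))
        A[:m, :m] = K
        A[:m, m:] = P
        A[m:, :m] = P.T
        b = np.zeros((m + 4, targets.shape[1]))
        b[:m] = targets
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        model = ThinPlateSpline(sources, targets, sol[:m], sol[m:], ridge)
    return model
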