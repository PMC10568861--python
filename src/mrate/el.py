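"""Empirical-likelihood calibration weights for one treatment arm.

The weights maximize prod_i w_i subject to w_i >= 0, sum w_i = 1 and the
moment constraints sum_i w_i ghat(X_i) = 0, where ghat stacks the centered
candidate-model values (propensities minus their full-sample means, and
counterfactual outcome predictions minus theirs).  Via Lagrange duality the
solution is

    w_i = (1/n_arm) * 1 / (1 + rho' g_i),

with rho the minimizer of the convex dual F(rho) = -sum_i log(1 + rho' g_i)
over the open region {rho : 1 + rho' g_i > 0 for all i}; the gradient of F
set to zero is exactly the stationarity equation sum_i g_i/(1+rho'g_i) = 0.
F is minimized by damped Newton iterations with feasibility-preserving step
halving.  A solution exists iff the zero vector lies in the convex hull of
the arm's {g_i}; when it does not, the line search stalls or the iteration
cap is hit and a :class:`ConvexHullViolation` is raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data import Dataset, EmptyArmError, EstimationError
from .models import FittedCandidates

__all__ = [
    "ConstraintSystem",
    "ELSolution",
    "ConvexHullViolation",
    "build_constraints",
    "solve_lagrange",
    "el_weights",
]

GRAD_TOL = 1e-10     # max-norm of the mean stationarity equation
MAX_ITER = 50
RANK_TOL = 1e-10     # relative tolerance for redundant-column detection
RIDGE = 1e-10        # fallback ridge when the Newton system is singular


class ConvexHullViolation(EstimationError):
    """No EL solution: the calibration targets lie outside the convex hull
    of the arm's candidate-model values."""


@dataclass
class ConstraintSystem:
    """Centered constraint rows g(X) for the subjects of one arm."""

    G: np.ndarray  # (n_arm, d)
    arm: Literal["treated", "control"]

    @property
    def n_arm(self) -> int:
        return self.G.shape[0]

    @property
    def d(self) -> int:
        return self.G.shape[1]


@dataclass
class ELSolution:
    rho: np.ndarray
    weights: np.ndarray
    converged: bool
    iterations: int
    max_constraint_residual: float
    dropped_columns: tuple[int, ...] = ()


def build_constraints(fc: FittedCandidates, data: Dataset, arm: str) -> ConstraintSystem:
    """Assemble G for one arm: PS columns first, then OR columns, spec order.

    Treated rows are (pi^l(X_i) - theta1^l, ..., m1^k(X_i) - eta1^k); control
    rows use (1 - pi^l) - theta0^l and m0^k - eta0^k.  The centering targets
    are full-sample averages, so the arm-restricted rows need not average to
    zero — that is exactly what calibration corrects.
    """
    if arm == "treated":
        mask = data.Z == 1
        ps_part = fc.ps_hat[mask] - fc.theta1
        or_part = fc.m1_hat[mask] - fc.eta1
    elif arm == "control":
        mask = data.Z == 0
        ps_part = (1.0 - fc.ps_hat[mask]) - fc.theta0
        or_part = fc.m0_hat[mask] - fc.eta0
    else:
        raise ValueError(f"arm must be 'treated' or 'control', got {arm!r}")
    if not mask.any():
        raise EmptyArmError(f"{arm} arm is empty")
    return ConstraintSystem(G=np.hstack([ps_part, or_part]), arm=arm)


def _drop_redundant_columns(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank-revealing QR: keep an independent subset of columns.

    Returns (kept column indices, reduced matrix).  Near-duplicate candidate
    models (e.g. two similar PS fits) otherwise make the Newton system
    numerically singular.
    """
    from scipy.linalg import qr

    if G.shape[1] == 0:
        return np.arange(0), G
    _, R, piv = qr(G, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] <= RANK_TOL:
        rank = 0
    else:
        rank = int((diag > RANK_TOL * diag[0]).sum())
    keep = np.sort(piv[:rank])
    return keep, G[:, keep]


def solve_lagrange(cs: ConstraintSystem) -> ELSolution:
    """Damped Newton minimization of the convex dual F(rho).

    Starts at rho = 0 (uniform weights); each step is halved until the
    iterate stays feasible (1 + rho'g_i >= 1/n_arm^2) and F does not
    increase.  Convergence: max-norm of (1/n_arm) sum g_i/(1+rho'g_i)
    below ``GRAD_TOL``.
    """
    n, d_full = cs.G.shape
    if n == 0:
        raise EmptyArmError(f"{cs.arm} arm is empty")
    if 0 < n <= d_full:
        warnings.warn(
            f"{cs.arm} arm has n={n} <= d={d_full} constraints; EL solution unreliable",
            stacklevel=2,
        )

    keep, G = _drop_redundant_columns(cs.G)
    dropped = tuple(int(i) for i in range(d_full) if i not in set(keep.tolist()))
    d = G.shape[1]
    buffer = 1.0 / n**2

    rho = np.zeros(d)
    denom = np.ones(n)
    F = 0.0
    mean_grad = G.mean(axis=0) if d else np.zeros(0)
    it = 0
    converged = bool(d == 0 or np.abs(mean_grad).max() <= GRAD_TOL)

    while not converged and it < MAX_ITER:
        it += 1
        inv = 1.0 / denom
        grad = -(G.T @ inv)                       # gradient of F
        H = (G * inv[:, None] ** 2).T @ G         # Hessian of F (PSD)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H + RIDGE * np.eye(d), -grad, rcond=None)[0]
        t = 1.0
        moved = False
        while t >= 1e-12:
            cand = rho + t * step
            cand_denom = 1.0 + G @ cand
            if cand_denom.min() >= buffer:
                cand_F = -np.log(cand_denom).sum()
                if cand_F <= F + 1e-12 * max(1.0, abs(F)):
                    rho, denom, F = cand, cand_denom, cand_F
                    moved = True
                    break
            t /= 2.0
        if not moved:
            break
        mean_grad = (G / denom[:, None]).mean(axis=0)
        if np.abs(mean_grad).max() <= GRAD_TOL:
            converged = True

    if not converged:
        raise ConvexHullViolation(
            f"EL solver failed on the {cs.arm} arm (n={n}, d={d_full}, "
            f"iterations={it}, residual={np.abs(mean_grad).max():.3g}): calibration "
            f"targets likely outside the convex hull of the candidate values"
        )

    weights = 1.0 / (n * denom)
    rho_full = np.zeros(d_full)
    rho_full[keep] = rho
    residual = float(np.abs(weights @ cs.G).max()) if d_full else 0.0
    return ELSolution(
        rho=rho_full,
        weights=weights,
        converged=True,
        iterations=it,
        max_constraint_residual=residual,
        dropped_columns=dropped,
    )


def el_weights(cs: ConstraintSystem) -> ELSolution:
    """Solve and validate: positive weights summing to 1 that hit every
    calibration constraint to within 1e-6."""
    sol = solve_lagrange(cs)
    w = sol.weights
    if w.min() <= 0 or abs(w.sum() - 1.0) > 1e-8:
        raise ConvexHullViolation(
            f"invalid EL weights on the {cs.arm} arm "
            f"(min={w.min():.3g}, sum-1={w.sum() - 1.0:.3g})"
        )
    if sol.max_constraint_residual > 1e-6:
        raise ConvexHullViolation(
            f"EL constraint residual {sol.max_constraint_residual:.3g} > 1e-6 "
            f"on the {cs.arm} arm"
        )
    return sol
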