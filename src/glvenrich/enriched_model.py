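"""The enriched model: a partial GLV model plus an embedded discrepancy.

The discrepancy operator acts inside the governing equations,

    dx/dt = P(x) + diag(x) delta0 + diag(|dx/dt|) delta1,

with delta0 <= 0 (1/time) and delta1 <= 0 (dimensionless), so that every
component of the correction is nonpositive — consistent with purely
competitive interactions among the omitted species.  Because |dx/dt| appears
on the right-hand side the system is implicit in the derivative, but it
decouples componentwise: with g_i = P_i(x) + delta_i0 x_i,

    dx_i/dt = g_i / (1 - delta_i1)   if g_i > 0,
    dx_i/dt = g_i / (1 + delta_i1)   if g_i < 0,
    dx_i/dt = 0                      if g_i = 0.

For -1 < delta_i1 <= 0 both factors are positive, so the derivative keeps the
sign of g_i and the resolution is the unique consistent solution.  At
delta_i1 <= -1 the fixed-point equation has no consistent solution for
g_i < 0 and the model is undefined; such parameters are rejected.

delta0 shifts the equilibrium to x_eq = -A^{-1}(r + delta0); delta1 rescales
the speed of approach on each fixed-sign regime without moving the
equilibrium.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .glv_models import (
    NONNEG_TOL,
    GLVModel,
    Trajectory,
    _integrate,
    equilibrium,
    glv_rhs,
)

__all__ = [
    "DiscrepancyParams",
    "EnrichedModel",
    "UnsolvableDiscrepancyError",
    "resolve_derivative",
    "enriched_rhs",
    "enriched_equilibrium",
    "simulate_enriched",
    "simulate_enriched_batch",
    "sign_change_diagnostic",
]


class UnsolvableDiscrepancyError(ValueError):
    """Raised when some delta1 <= -1: the implicit derivative equation has
    no consistent solution on the descending branch."""


@dataclasses.dataclass(frozen=True)
class DiscrepancyParams:
    """Discrepancy coefficients (delta0, delta1), one pair per species.

    delta0 multiplies the state (units 1/time), delta1 the absolute
    derivative (dimensionless).  All entries must be <= 0; delta1 must
    additionally exceed -1 for the enriched system to be well defined.
    """

    delta0: np.ndarray
    delta1: np.ndarray

    def __post_init__(self) -> None:
        d0 = np.atleast_1d(np.asarray(self.delta0, dtype=float))
        d1 = np.atleast_1d(np.asarray(self.delta1, dtype=float))
        if d0.shape != d1.shape or d0.ndim != 1:
            raise ValueError("delta0 and delta1 must be vectors of equal length")
        if np.any(d0 > 0) or np.any(d1 > 0):
            raise ValueError("discrepancy parameters must be <= 0")
        if np.any(d1 <= -1):
            raise UnsolvableDiscrepancyError(
                "discrepancy operator unsolvable: delta1 entries must be > -1"
            )
        object.__setattr__(self, "delta0", d0)
        object.__setattr__(self, "delta1", d1)

    @property
    def s(self) -> int:
        return self.delta0.shape[0]

    # Parameter-vector layout used throughout calibration: [delta0, delta1].
    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.delta0, self.delta1])

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "DiscrepancyParams":
        theta = np.asarray(theta, dtype=float)
        if theta.ndim != 1 or theta.size % 2:
            raise ValueError("theta must be a flat vector of even length")
        s = theta.size // 2
        return cls(delta0=theta[:s], delta1=theta[s:])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"delta0": self.delta0.tolist(), "delta1": self.delta1.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscrepancyParams":
        d = json.loads(Path(path).read_text())
        return cls(delta0=np.asarray(d["delta0"]), delta1=np.asarray(d["delta1"]))


@dataclasses.dataclass(frozen=True)
class EnrichedModel:
    partial: GLVModel
    disc: DiscrepancyParams

    def __post_init__(self) -> None:
        if self.disc.s != self.partial.S:
            raise ValueError(
                f"discrepancy has {self.disc.s} components, "
                f"partial model has {self.partial.S} species"
            )

    @property
    def s(self) -> int:
        return self.partial.S


def resolve_derivative(g: np.ndarray, delta1: np.ndarray) -> np.ndarray:
    """Solve v = g + delta1 * |v| componentwise.

    Valid for delta1 in (-1, 0]; the returned v has the sign of g.
    """
    g = np.asarray(g, dtype=float)
    delta1 = np.asarray(delta1, dtype=float)
    if np.any(delta1 <= -1):
        raise UnsolvableDiscrepancyError(
            "discrepancy operator unsolvable: delta1 entries must be > -1"
        )
    return np.where(g > 0, g / (1.0 - delta1), g / (1.0 + delta1))


def enriched_rhs(em: EnrichedModel, x: np.ndarray) -> np.ndarray:
    """Derivative of the enriched system at state ``x``."""
    g = glv_rhs(em.partial, x) + em.disc.delta0 * np.asarray(x, dtype=float)
    return resolve_derivative(g, em.disc.delta1)


def enriched_equilibrium(em: EnrichedModel) -> np.ndarray:
    """x_eq = -A^{-1}(r + delta0); delta1 does not move the equilibrium."""
    shifted = GLVModel(A=em.partial.A, r=em.partial.r + em.disc.delta0)
    return equilibrium(shifted)


def _batch_rhs(em: EnrichedModel, X: np.ndarray) -> np.ndarray:
    """Vectorized enriched RHS for a stack of states, shape (n, s)."""
    A, r = em.partial.A, em.partial.r
    G = X * (r + X @ A.T) + X * em.disc.delta0
    d1 = em.disc.delta1
    return np.where(G > 0, G / (1.0 - d1), G / (1.0 + d1))


def simulate_enriched(
    em: EnrichedModel,
    x0: np.ndarray,
    times: np.ndarray,
    solver_opts: Mapping[str, Any] | None = None,
) -> Trajectory:
    """Integrate the enriched system over ``times`` (same contract as
    :func:`glvenrich.glv_models.simulate`)."""
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial concentrations must be nonnegative")
    states = _integrate(lambda t, x: enriched_rhs(em, x), x0, times, solver_opts)
    lo = states.min()
    if lo < -NONNEG_TOL:
        raise RuntimeError(
            f"trajectory reached {lo:.3g} < -{NONNEG_TOL:g}; check solver tolerances"
        )
    return Trajectory(times=np.asarray(times, dtype=float), states=states,
                      provenance=f"enriched(s={em.s})")


def simulate_enriched_batch(
    em: EnrichedModel,
    X0: np.ndarray,
    times: np.ndarray,
    solver_opts: Mapping[str, Any] | None = None,
) -> np.ndarray:
    """Integrate the enriched system from many initial conditions at once.

    The enriched RHS couples nothing across trajectories, so the stacked
    system is block-independent and one adaptive solve serves all scenarios
    (the step size adapts to the stiffest of them; the result is the same to
    solver tolerance).  Returns an array of shape (n, T, s).
    """
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    if np.any(X0 < 0):
        raise ValueError("initial concentrations must be nonnegative")
    n, s = X0.shape
    flat = _integrate(
        lambda t, z: _batch_rhs(em, z.reshape(n, s)).ravel(),
        X0.ravel(),
        times,
        solver_opts,
    )
    out = flat.reshape(len(times), n, s).transpose(1, 0, 2)
    if out.min() < -NONNEG_TOL:
        raise RuntimeError("batch trajectory went negative; check solver tolerances")
    return out


def sign_change_diagnostic(
    traj: Trajectory, deadband: float | None = None
) -> np.ndarray:
    """Latest time at which each species' derivative changes sign.

    Derivatives are central finite differences on the trajectory grid.
    Returns one value per species: the last grid time where the derivative
    sign flips, or NaN if the derivative never changes sign.  Near an
    equilibrium the finite-difference derivative rattles around zero at
    solver-noise amplitude; derivatives smaller than ``deadband`` (default
    1e-7 times the trajectory's largest magnitude) count as zero and do not
    register as sign changes.
    """
    if traj.times.size < 3:
        raise ValueError("need at least 3 trajectory points")
    d = np.gradient(traj.states, traj.times, axis=0)
    if deadband is None:
        deadband = 1e-7 * max(np.abs(traj.states).max(), 1.0)
    sgn = np.sign(np.where(np.abs(d) < deadband, 0.0, d))
    out = np.full(traj.states.shape[1], np.nan)
    for i in range(sgn.shape[1]):
        col = sgn[:, i]
        nz = col[col != 0]
        if nz.size < 2:
            continue
        idx_nz = np.flatnonzero(col)
        flips = idx_nz[1:][nz[1:] != nz[:-1]]
        if flips.size:
            out[i] = traj.times[flips[-1]]
    return out
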