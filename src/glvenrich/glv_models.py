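"""Core generalized Lotka-Volterra (GLV) machinery.

The GLV equations describe concentrations x(t) of S interacting species,

    dx/dt = diag(x) (r + A x),

with growth-rate vector r (1/time) and interaction matrix A whose entry
``A[i, j]`` gives the per-capita effect of species j on species i
(1/(concentration * time)).  A single :class:`GLVModel` container serves both
as a "detailed" model (the full S-species ground truth) and as a "partial"
model (an s-species reduction of it): the two differ only in how they were
obtained, not in structure.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "GLVModel",
    "Trajectory",
    "StabilityReport",
    "SolverError",
    "glv_rhs",
    "equilibrium",
    "simulate",
    "is_stable",
    "DEFAULT_SOLVER_OPTS",
]

#: Default integrator settings: a stiff-capable adaptive method with tight
#: tolerances so that equilibria are resolved well below the 1e-8
#: nonnegativity guard.
DEFAULT_SOLVER_OPTS: dict[str, Any] = {
    "method": "LSODA",
    "rtol": 1e-8,
    "atol": 1e-10,
}

#: Trajectories may dip this far below zero before we call it a solver
#: misconfiguration.  GLV dynamics preserve nonnegativity analytically.
NONNEG_TOL = 1e-8


class SolverError(RuntimeError):
    """ODE integration failed; carries the time at which it failed."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclasses.dataclass(frozen=True)
class GLVModel:
    """A GLV model, fully determined by (A, r).

    Parameters
    ----------
    A : (S, S) array
        Interaction matrix.  Models produced by this package's generator are
        symmetric, entrywise negative and strictly diagonally dominant, which
        guarantees a stable positive equilibrium; hand-built models need not
        satisfy those properties.
    r : (S,) array
        Intrinsic growth rates.
    """

    A: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got shape {A.shape}")
        if r.ndim != 1 or r.shape[0] != A.shape[0]:
            raise ValueError(
                f"r must be a vector of length {A.shape[0]}, got shape {r.shape}"
            )
        if not (np.isfinite(A).all() and np.isfinite(r).all()):
            raise ValueError("A and r must be finite")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "r", r)

    @property
    def S(self) -> int:
        """Number of species."""
        return self.A.shape[0]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {"A": self.A.tolist(), "r": self.r.tolist(), "S": self.S}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GLVModel":
        return cls(A=np.asarray(d["A"], dtype=float), r=np.asarray(d["r"], dtype=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "GLVModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """A simulated solution: one row of ``states`` per time point.

    ``provenance`` records which model produced it (free-form label).
    """

    times: np.ndarray
    states: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if states.shape[0] != times.shape[0]:
            raise ValueError("states must have one row per time point")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"x{i + 1}": self.states[:, i] for i in range(self.states.shape[1])}
        return pd.DataFrame({"time": self.times, **cols})

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "Trajectory":
        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c != "time"]
        return cls(df["time"].to_numpy(), df[xcols].to_numpy(), provenance)


@dataclasses.dataclass(frozen=True)
class StabilityReport:
    stable: bool
    eigenvalues: np.ndarray

    def __bool__(self) -> bool:
        return self.stable


def glv_rhs(model: GLVModel, x: np.ndarray) -> np.ndarray:
    """Evaluate dx/dt = diag(x)(r + A x).  Exact algebra, no clipping."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.S,):
        raise ValueError(f"state has shape {x.shape}, expected ({model.S},)")
    if not np.isfinite(x).all():
        raise ValueError("state must be finite")
    return x * (model.r + model.A @ x)


def equilibrium(model: GLVModel) -> np.ndarray:
    """Interior equilibrium x_eq = -A^{-1} r, computed by linear solve."""
    cond = np.linalg.cond(model.A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"interaction matrix is singular or near-singular (cond={cond:.3g})"
        )
    return np.linalg.solve(model.A, -model.r)


def is_stable(model: GLVModel) -> StabilityReport:
    """True iff every eigenvalue of A has strictly negative real part.

    For the symmetric matrices produced by the generator this coincides with
    all eigenvalues being strictly negative reals.
    """
    if np.allclose(model.A, model.A.T):
        eig = np.linalg.eigvalsh(model.A)
    else:
        eig = np.linalg.eigvals(model.A)
    return StabilityReport(stable=bool(np.all(np.real(eig) < 0)), eigenvalues=eig)


def _integrate(rhs, x0: np.ndarray, times: np.ndarray, solver_opts=None):
    """Shared solve_ivp wrapper with the package's failure semantics."""
    opts = dict(DEFAULT_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing grid of >= 2 points")
    if times[0] < 0:
        raise ValueError("times must start at t >= 0")
    sol = solve_ivp(rhs, (times[0], times[-1]), np.asarray(x0, dtype=float),
                    t_eval=times, **opts)
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else float(times[0])
        raise SolverError(f"ODE solver failed at t={t_fail:.4g}: {sol.message}", t_fail)
    return sol.y.T


def simulate(
    model: GLVModel,
    x0: np.ndarray,
    times: np.ndarray,
    solver_opts: Mapping[str, Any] | None = None,
) -> Trajectory:
    """Integrate the GLV system from ``x0`` over the grid ``times``.

    Raises :class:`SolverError` on integration failure and ``RuntimeError``
    if the trajectory dips below -1e-8: GLV preserves nonnegativity, so a
    violation indicates solver misconfiguration rather than model behaviour.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial concentrations must be nonnegative")
    states = _integrate(lambda t, x: x * (model.r + model.A @ x), x0, times,
                        solver_opts)
    lo = states.min()
    if lo < -NONNEG_TOL:
        raise RuntimeError(
            f"trajectory reached {lo:.3g} < -{NONNEG_TOL:g}; "
            "check solver tolerances"
        )
    return Trajectory(times=np.asarray(times, dtype=float), states=states,
                      provenance=f"glv(S={model.S})")
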