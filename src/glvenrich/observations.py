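"""Synthetic noisy observations of detailed-model trajectories.

Observations y_ijk are taken from detailed-model trajectories of the s
retained species (species i, observation time j, initial-condition scenario
k), with additive Gaussian measurement noise of known variance.  Scenarios
are split scenario-wise into a calibration block (the first n_phi_c) and a
validation block (the rest).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .glv_models import GLVModel, simulate

__all__ = [
    "Scenario",
    "ObservationSet",
    "sample_scenarios",
    "generate_observations",
    "generate_enriched_observations",
    "partition",
    "DEFAULT_T_FINAL",
]

#: Default simulation horizon; the model classes studied here equilibrate
#: well before t=10.
DEFAULT_T_FINAL = 10.0


@dataclasses.dataclass(frozen=True)
class Scenario:
    """One initial-condition scenario.

    ``phi`` holds the initial concentrations of the s retained species (the
    quantity the enriched model is started from); ``x0_full`` the full
    detailed-model initial state, whose first s entries are ``phi``.  The
    unretained entries are drawn from the same lognormal stream as phi and
    stored here so runs are reproducible.
    """

    phi: np.ndarray
    x0_full: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        full = np.atleast_1d(np.asarray(self.x0_full, dtype=float))
        if np.any(phi <= 0) or np.any(full <= 0):
            raise ValueError("initial concentrations must be strictly positive")
        if full.size < phi.size or not np.array_equal(full[: phi.size], phi):
            raise ValueError("x0_full must extend phi")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "x0_full", full)


def sample_scenarios(
    n_phi: int,
    dim: int,
    seed: int | np.random.Generator | None = None,
    full_dim: int | None = None,
) -> list[Scenario]:
    """Draw ``n_phi`` scenarios with i.i.d. logN(0, 1) entries.

    ``dim`` is the number of retained species; ``full_dim`` (default ``dim``)
    the detailed-model dimension.  All ``full_dim`` entries come from one
    stream, the first ``dim`` forming phi.
    """
    if n_phi < 1:
        raise ValueError("n_phi must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    full_dim = dim if full_dim is None else full_dim
    if full_dim < dim:
        raise ValueError("full_dim must be >= dim")
    out = []
    for k in range(n_phi):
        x0 = rng.lognormal(mean=0.0, sigma=1.0, size=full_dim)
        out.append(Scenario(phi=x0[:dim], x0_full=x0, index=k))
    return out


@dataclasses.dataclass(frozen=True)
class ObservationSet:
    """Noisy observations on a complete (species, time, scenario) grid.

    ``values`` has shape (s, T, n_phi); ``times`` the T observation instants;
    ``n_phi_c`` how many leading scenarios belong to the calibration split.
    """

    values: np.ndarray
    times: np.ndarray
    scenarios: tuple[Scenario, ...]
    sigma_eps_sq: float
    n_phi_c: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be (s, T, n_phi)")
        if t.shape != (v.shape[1],):
            raise ValueError("times length must match values' time axis")
        if len(self.scenarios) != v.shape[2]:
            raise ValueError("one scenario per values column required")
        if self.sigma_eps_sq < 0:
            raise ValueError("sigma_eps_sq must be >= 0")
        if not 0 <= self.n_phi_c <= v.shape[2]:
            raise ValueError("n_phi_c out of range")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "scenarios", tuple(self.scenarios))

    @property
    def s(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def n_phi(self) -> int:
        return self.values.shape[2]

    @property
    def n_obs(self) -> int:
        return self.values.size

    def to_dataframe(self) -> pd.DataFrame:
        s, T, n_phi = self.values.shape
        i, j, k = np.meshgrid(np.arange(s), np.arange(T), np.arange(n_phi),
                              indexing="ij")
        return pd.DataFrame(
            {
                "scenario": k.ravel(),
                "species": i.ravel(),
                "time_index": j.ravel(),
                "time": self.times[j.ravel()],
                "value": self.values.ravel(),
                "split": np.where(k.ravel() < self.n_phi_c, "calibration",
                                  "validation"),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """CSV table plus a JSON metadata sidecar (<path>.meta.json)."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {
            "sigma_eps_sq": self.sigma_eps_sq,
            "T": self.T,
            "n_phi_c": self.n_phi_c,
            "times": self.times.tolist(),
            "scenarios": [sc.x0_full.tolist() for sc in self.scenarios],
            "s": self.s,
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def generate_observations(
    detailed: GLVModel,
    scenarios: Sequence[Scenario],
    s: int,
    T: int,
    sigma_eps_sq: float,
    seed: int | np.random.Generator | None = None,
    n_phi_c: int | None = None,
    t_final: float = DEFAULT_T_FINAL,
    solver_opts: Mapping[str, Any] | None = None,
) -> ObservationSet:
    """Simulate the detailed model per scenario and observe the first s
    species at T uniform instants on (0, t_final], plus N(0, sigma_eps_sq)
    noise.

    t=0 is excluded: the initial condition is known exactly.  Noise is left
    untruncated (slightly negative observed values near zero concentrations
    are kept) so the data model matches the Gaussian likelihood used in
    calibration.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 1 <= s <= detailed.S:
        raise ValueError("s out of range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.linspace(t_final / T, t_final, T)
    grid = np.concatenate([[0.0], times])
    vals = np.empty((s, T, len(scenarios)))
    for k, sc in enumerate(scenarios):
        if sc.x0_full.size != detailed.S:
            raise ValueError(
                f"scenario {sc.index} has dimension {sc.x0_full.size}, "
                f"detailed model needs {detailed.S}"
            )
        traj = simulate(detailed, sc.x0_full, grid, solver_opts)
        vals[:, :, k] = traj.states[1:, :s].T
    if sigma_eps_sq > 0:
        vals = vals + rng.normal(0.0, np.sqrt(sigma_eps_sq), size=vals.shape)
    if n_phi_c is None:
        n_phi_c = len(scenarios)
    return ObservationSet(values=vals, times=times, scenarios=tuple(scenarios),
                          sigma_eps_sq=sigma_eps_sq, n_phi_c=n_phi_c)


def generate_enriched_observations(
    em,
    scenarios: Sequence[Scenario],
    T: int,
    sigma_eps_sq: float,
    seed: int | np.random.Generator | None = None,
    n_phi_c: int | None = None,
    t_final: float = DEFAULT_T_FINAL,
    solver_opts: Mapping[str, Any] | None = None,
) -> ObservationSet:
    """Observations whose ground truth is an *enriched* model.

    Same observation protocol as :func:`generate_observations`, but the
    trajectories come from the enriched system itself (started from each
    scenario's phi).  This is the self-consistency control: data generated
    from the fitted model class, for which posterior-predictive gamma-values
    are asymptotically uniform.
    """
    from .enriched_model import simulate_enriched_batch

    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.linspace(t_final / T, t_final, T)
    grid = np.concatenate([[0.0], times])
    X0 = np.stack([sc.phi for sc in scenarios])
    Y = simulate_enriched_batch(em, X0, grid, solver_opts)  # (n_phi, T+1, s)
    vals = Y[:, 1:, :].transpose(2, 1, 0)
    if sigma_eps_sq > 0:
        vals = vals + rng.normal(0.0, np.sqrt(sigma_eps_sq), size=vals.shape)
    if n_phi_c is None:
        n_phi_c = len(scenarios)
    return ObservationSet(values=vals.copy(), times=times,
                          scenarios=tuple(scenarios),
                          sigma_eps_sq=sigma_eps_sq, n_phi_c=n_phi_c)


def partition(obs: ObservationSet, n_phi_c: int) -> tuple[ObservationSet, ObservationSet]:
    """Scenario-wise split: the first ``n_phi_c`` scenarios form the
    calibration set, the remainder the validation set."""
    if not 1 <= n_phi_c < obs.n_phi:
        raise ValueError(f"n_phi_c must be in [1, {obs.n_phi - 1}], got {n_phi_c}")
    cal = ObservationSet(
        values=obs.values[:, :, :n_phi_c],
        times=obs.times,
        scenarios=obs.scenarios[:n_phi_c],
        sigma_eps_sq=obs.sigma_eps_sq,
        n_phi_c=n_phi_c,
    )
    val = ObservationSet(
        values=obs.values[:, :, n_phi_c:],
        times=obs.times,
        scenarios=obs.scenarios[n_phi_c:],
        sigma_eps_sq=obs.sigma_eps_sq,
        n_phi_c=0,
    )
    return cal, val
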