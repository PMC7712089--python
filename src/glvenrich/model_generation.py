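"""Random generation of stable detailed GLV models and their reductions.

A detailed model is sampled so that its interaction matrix is symmetric,
entrywise strictly negative and strictly diagonally dominant — hence all
eigenvalues are negative and the interior equilibrium is stable.  Off-diagonal
interaction magnitudes B_ij are lognormal; each diagonal entry is a lognormal
slack *added to* the sum of that species' off-diagonal magnitudes, which is
what forces strict dominance.  The growth rate is the same for every species:
the largest diagonal magnitude.

The partial model keeps the first s species: the leading principal submatrix
of A and the first s growth rates.  Principal submatrices of symmetric,
negative, strictly diagonally dominant matrices inherit all three properties,
so every partial model is itself stable.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .glv_models import GLVModel

__all__ = ["GeneratorConfig", "sample_detailed_model", "subsample_partial_model"]


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Hyperparameters of the random detailed-model class.

    ``sigma_B_sq`` and ``sigma_C_sq`` are the variances of the underlying
    normals of the lognormal draws for off-diagonal magnitudes and diagonal
    slack respectively (logN(0, sigma^2) throughout).
    """

    S: int
    sigma_B_sq: float = 1.0
    sigma_C_sq: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if int(self.S) != self.S or self.S < 2:
            raise ValueError("S must be an integer >= 2")
        if self.sigma_B_sq <= 0 or self.sigma_C_sq <= 0:
            raise ValueError("variances must be positive")
        object.__setattr__(self, "S", int(self.S))


def sample_detailed_model(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> GLVModel:
    """Draw one stable detailed model.

    Draw order is fixed (upper triangle of B row-major, then the diagonal
    slack) so a given seed reproduces the model bit-for-bit.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    S = cfg.S
    sig_B = float(np.sqrt(cfg.sigma_B_sq))
    sig_C = float(np.sqrt(cfg.sigma_C_sq))

    B = np.zeros((S, S))
    iu, ju = np.triu_indices(S, k=1)  # row-major upper triangle
    B[iu, ju] = rng.lognormal(mean=0.0, sigma=sig_B, size=iu.size)
    B = B + B.T

    # Diagonal = lognormal slack + column sum of off-diagonal magnitudes
    # (column vs row sum is immaterial: B is symmetric).  The deterministic
    # floor is what guarantees strict diagonal dominance.
    slack = rng.lognormal(mean=0.0, sigma=sig_C, size=S)
    C_diag = slack + B.sum(axis=0)

    A = -(B + np.diag(C_diag))
    r = np.full(S, C_diag.max())
    return GLVModel(A=A, r=r)


def subsample_partial_model(detailed: GLVModel, s: int) -> GLVModel:
    """Partial model on the first ``s`` of the detailed model's S species."""
    if int(s) != s or not 1 <= s < detailed.S:
        raise ValueError(f"s must be an integer in [1, {detailed.S - 1}], got {s}")
    s = int(s)
    return GLVModel(A=detailed.A[:s, :s].copy(), r=detailed.r[:s].copy())
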