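"""Parameter bookkeeping for model reduction and enrichment.

Reducing an S-species GLV model to s species discards the S^2 - s^2
interaction terms touching omitted species plus their S - s growth rates;
enrichment adds back only the 2s discrepancy coefficients.  The relative
model complexity is the ratio added/omitted, which stays far below one even
for mild reductions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["ComplexityReport", "count_terms", "complexity_sweep"]


@dataclasses.dataclass(frozen=True)
class ComplexityReport:
    S: int
    s: int
    terms_omitted: int
    terms_added: int
    relative_complexity: float
    alpha: float
    detailed_total: int  # S^2 + S parameters in the full model
    detailed_nonlinear: int  # the S^2 interaction terms
    partial_total: int  # s^2 + s parameters kept


def count_terms(S: int, s: int) -> ComplexityReport:
    """Exact term counts for an (S -> s) reduction with 2s-term enrichment."""
    if int(S) != S or int(s) != s or not 1 <= s < S:
        raise ValueError(f"need integers 1 <= s < S, got S={S}, s={s}")
    S, s = int(S), int(s)
    omitted = S**2 - s**2 + (S - s)
    added = 2 * s
    return ComplexityReport(
        S=S,
        s=s,
        terms_omitted=omitted,
        terms_added=added,
        relative_complexity=added / omitted,
        alpha=s / S,
        detailed_total=S**2 + S,
        detailed_nonlinear=S**2,
        partial_total=s**2 + s,
    )


def complexity_sweep(S_list: Iterable[int], out: str | Path | None = None) -> pd.DataFrame:
    """Relative complexity for every s = 1..S-1 of each S.

    Returns (and optionally writes) a table with columns
    S, s, alpha, omitted, added, ratio.
    """
    rows = []
    for S in S_list:
        for s in range(1, int(S)):
            rep = count_terms(S, s)
            rows.append((rep.S, rep.s, rep.alpha, rep.terms_omitted,
                         rep.terms_added, rep.relative_complexity))
    df = pd.DataFrame(rows, columns=["S", "s", "alpha", "omitted", "added", "ratio"])
    if out is not None:
        df.to_csv(out, index=False)
    return df
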