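"""Residue–residue Spearman cross-correlation matrices (CCMs).

Whether the temperature responses of two residues are coupled is probed by
rank correlation of their per-temperature observables across the melt.  For
the shift observable each residue contributes its vector of per-step Δδ
values at consecutive temperature points (D1, D2, ...; optionally the
cumulative ∑Δδ instead); for the intensity observable, its per-temperature
PI values.  Spearman's rho between a pair is computed on their overlapping
temperatures by the classical formula

    rho = 1 - 6 * sum(d_i^2) / (n (n^2 - 1))

where d_i is the rank difference at observation i; when ties occur the
documented fallback is the Pearson correlation of mid-ranks, which reduces
to the formula exactly in the tie-free case.  The resulting symmetric matrix
is thresholded ("gated") for display: cells with rho strictly inside the
gate interval are masked as noise, the defaults following the conventional
choices of (-0.6, 0.6) for Δδ matrices and (-0.95, 0.95) for PI matrices
(PI correlations run systematically higher).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intensity import IntensityProfile
from .shifts import ResidueShiftMetrics

__all__ = [
    "DEFAULT_DELTA_GATE",
    "DEFAULT_PI_GATE",
    "MIN_PAIR_OBSERVATIONS",
    "CorrelationMatrix",
    "spearman_rho",
    "build_ccm",
    "gate_matrix",
]

DEFAULT_DELTA_GATE = (-0.6, 0.6)
DEFAULT_PI_GATE = (-0.95, 0.95)
#: pairs overlapping at fewer temperatures than this are low-confidence
MIN_PAIR_OBSERVATIONS = 4


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho matrix with per-pair bookkeeping.

    ``rho`` and ``n_obs`` are square DataFrames indexed by residue; ``rho``
    holds NaN where a pair has fewer than two overlapping observations.
    ``ties`` marks pairs computed through the mid-rank fallback.  ``gate``
    and ``gated`` are populated by :func:`gate_matrix`; in a gated matrix
    the masked cells of ``rho`` are NaN (low-confidence pairs with
    ``n_obs < MIN_PAIR_OBSERVATIONS`` are masked too) while the ungated
    original is retained in ``rho_full``.
    """

    observable: str
    rho: pd.DataFrame
    n_obs: pd.DataFrame
    ties: pd.DataFrame
    gate: tuple[float, float] | None = None
    gated: bool = False
    rho_full: pd.DataFrame | None = None

    @property
    def residues(self) -> list[int]:
        return list(self.rho.index)


def spearman_rho(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, int, bool]:
    """Spearman rank correlation of two paired vectors.

    Pairs in which either member is NaN are dropped.  Tie-free data use the
    classical ``1 - 6 sum(d^2) / (n(n^2-1))`` formula on integer ranks; data
    with ties fall back to the Pearson correlation of mid-ranks.  Returns
    ``(rho, n, had_ties)`` with ``rho = nan`` when fewer than two complete
    pairs remain or either vector is constant.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("input vectors differ in length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = int(xa.size)
    if n < 2:
        return math.nan, n, False
    rx = stats.rankdata(xa, method="average")
    ry = stats.rankdata(ya, method="average")
    has_ties = np.unique(xa).size < n or np.unique(ya).size < n
    if not has_ties:
        d = rx - ry
        rho = 1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1))
        return rho, n, False
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return math.nan, n, True
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, n, True


def _delta_vectors(
    metrics: Mapping[int, ResidueShiftMetrics], cumulative: bool
) -> pd.DataFrame:
    rows = {}
    for res, m in metrics.items():
        rows[res] = m.cumulative_delta if cumulative else m.step_delta
    return pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)


def _pi_vectors(profiles: Mapping[int, IntensityProfile]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        {res: p.pi_series for res, p in profiles.items()}, orient="index"
    ).sort_index(axis=1)


def build_ccm(
    data: Mapping[int, ResidueShiftMetrics] | Mapping[int, IntensityProfile],
    observable: str,
    residues: Sequence[int] | None = None,
    *,
    cumulative: bool = False,
) -> CorrelationMatrix:
    """Pairwise Spearman CCM over a residue subset.

    ``observable`` is ``'delta'`` (vectors of per-step Δδ, or of cumulative
    ∑Δδ with ``cumulative=True``) or ``'pi'`` (per-temperature PI).
    ``residues`` restricts the matrix (the usual choice being the
    90th-percentile residues of the respective observable); by default all
    residues in ``data`` enter.  Correlations are computed on
    pairwise-complete temperatures; the diagonal is exactly 1 wherever a
    residue has at least two observations.
    """
    if observable == "delta":
        vectors = _delta_vectors(data, cumulative)  # type: ignore[arg-type]
    elif observable == "pi":
        vectors = _pi_vectors(data)  # type: ignore[arg-type]
    else:
        raise ValueError(f"unknown observable {observable!r}")
    if residues is not None:
        residues = [r for r in residues if r in vectors.index]
        if not residues:
            raise ValueError("residue subset is empty (or disjoint from data)")
        vectors = vectors.loc[residues]
    vectors = vectors.sort_index()
    res_list = list(vectors.index)
    k = len(res_list)
    rho = np.full((k, k), np.nan)
    n_obs = np.zeros((k, k), dtype=int)
    ties = np.zeros((k, k), dtype=bool)
    values = vectors.to_numpy()
    for i in range(k):
        for j in range(i, k):
            r, n, t = spearman_rho(values[i], values[j])
            if i == j and n >= 2:
                r = 1.0  # exact unit diagonal regardless of ties
            rho[i, j] = rho[j, i] = r
            n_obs[i, j] = n_obs[j, i] = n
            ties[i, j] = ties[j, i] = t
    idx = pd.Index(res_list, name="residue")
    return CorrelationMatrix(
        observable=observable,
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        n_obs=pd.DataFrame(n_obs, index=idx, columns=idx),
        ties=pd.DataFrame(ties, index=idx, columns=idx),
    )


def gate_matrix(
    ccm: CorrelationMatrix,
    low: float | None = None,
    high: float | None = None,
) -> CorrelationMatrix:
    """Mask weak correlations for display.

    Cells with ``low < rho < high`` (strict interior) are set to NaN, as are
    low-confidence pairs overlapping at fewer than
    :data:`MIN_PAIR_OBSERVATIONS` temperatures.  Defaults are
    :data:`DEFAULT_DELTA_GATE` for Δδ matrices and :data:`DEFAULT_PI_GATE`
    for PI matrices.  Values exactly at a gate edge are retained.  The
    ungated matrix is preserved in ``rho_full``.
    """
    default = DEFAULT_DELTA_GATE if ccm.observable == "delta" else DEFAULT_PI_GATE
    lo = default[0] if low is None else float(low)
    hi = default[1] if high is None else float(high)
    if lo >= hi:
        raise ValueError(f"gate low must be < high, got ({lo}, {hi})")
    rho = ccm.rho.copy()
    interior = (rho > lo) & (rho < hi)
    low_conf = ccm.n_obs < MIN_PAIR_OBSERVATIONS
    rho[interior | low_conf] = np.nan
    return CorrelationMatrix(
        observable=ccm.observable,
        rho=rho,
        n_obs=ccm.n_obs,
        ties=ccm.ties,
        gate=(lo, hi),
        gated=True,
        rho_full=ccm.rho.copy(),
    )
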