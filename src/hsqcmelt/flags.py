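"""Normal-distribution percentile flagging of ∑Δδ and PI outliers.

The residue population's ∑Δδ values at a given temperature are approximately
normally distributed; the residues of interest are the upper-tail outliers.
A normal distribution is fitted (sample mean, sample standard deviation with
ddof = 1) and the p-th percentile threshold taken as

    threshold = mean + z(p) * sd,      z(p) = Phi^-1(p / 100)

A residue is flagged at level p when its value lies strictly above the
threshold.  ∑Δδ is flagged per temperature (one fitted normal per
temperature point); PI is flagged against a single normal fitted to the
pooled set of every residue-temperature PI observation, a residue being
flagged when its maximum PI exceeds that pooled threshold.  A separate
ranking lists the residues with the largest percentage change in PI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intensity import IntensityProfile
from .shifts import ResidueShiftMetrics

__all__ = [
    "NormalThreshold",
    "PercentileTable",
    "normal_threshold",
    "flag_sum_delta",
    "flag_pi",
    "top_percent_change",
]


@dataclass(frozen=True)
class NormalThreshold:
    """Fitted normal and the derived upper-percentile threshold."""

    mean: float
    variance: float
    level: float
    threshold: float


@dataclass
class PercentileTable:
    """Flagged residues per temperature at each configured percentile level.

    ``flags[level][temperature]`` is the sorted list of residues strictly
    above that level's threshold at that temperature; ``thresholds`` keeps
    the fitted :class:`NormalThreshold` per (level, temperature) for
    reporting.  Levels are nested by construction: the 95 set is a subset of
    the 90 set at every temperature.
    """

    observable: str
    levels: tuple[float, ...]
    flags: dict[float, dict[float, list[int]]] = field(default_factory=dict)
    thresholds: dict[tuple[float, float], NormalThreshold] = field(
        default_factory=dict
    )

    def flagged_anywhere(self, level: float) -> list[int]:
        """Residues flagged at ``level`` at one or more temperatures."""
        out: set[int] = set()
        for residues in self.flags[level].values():
            out.update(residues)
        return sorted(out)

    def flag_counts(self, level: float) -> dict[int, int]:
        """residue -> number of temperatures at which it was flagged."""
        counts: dict[int, int] = {}
        for residues in self.flags[level].values():
            for r in residues:
                counts[r] = counts.get(r, 0) + 1
        return counts


def normal_threshold(values: Sequence[float], level: float) -> NormalThreshold:
    """Fit a normal to ``values`` and return its upper ``level`` percentile.

    Uses the sample mean and the n-1 sample standard deviation.  A
    degenerate sample (all values identical) yields threshold = mean with a
    warning, so that nothing can lie strictly above it.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError(f"need >= 2 values to fit a normal, got {vals.size}")
    if not 0.0 < level < 100.0:
        raise ValueError(f"percentile level must be in (0, 100), got {level}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            "degenerate distribution (zero variance); percentile threshold "
            "collapses to the mean",
            stacklevel=2,
        )
        return NormalThreshold(mean, 0.0, level, mean)
    z = float(stats.norm.ppf(level / 100.0))
    return NormalThreshold(mean, sd**2, level, mean + z * sd)


def flag_sum_delta(
    metrics: Mapping[int, ResidueShiftMetrics],
    levels: Sequence[float] = (90.0, 95.0),
) -> PercentileTable:
    """Flag ∑Δδ outliers at each temperature point of the melt.

    At every temperature with at least two residues carrying a cumulative
    value, a normal is fitted to that temperature's ∑Δδ values across
    residues and the residues strictly above each level's threshold are
    flagged.  The first temperature of the grid carries ∑Δδ = 0 for every
    residue and is degenerate by construction; it simply flags nobody.
    """
    levels = tuple(sorted(float(l) for l in levels))
    table = PercentileTable(observable="sum_delta", levels=levels)
    temps: set[float] = set()
    for m in metrics.values():
        temps.update(m.cumulative_delta)
    for level in levels:
        table.flags[level] = {}
    for t in sorted(temps):
        values = {
            res: m.cumulative_delta[t]
            for res, m in metrics.items()
            if t in m.cumulative_delta
        }
        if len(values) < 2:
            continue
        arr = np.array(list(values.values()))
        with warnings.catch_warnings():
            if arr.std(ddof=1) == 0.0:
                warnings.simplefilter("ignore")  # expected at the grid start
            fits = {level: normal_threshold(arr, level) for level in levels}
        for level, fit in fits.items():
            table.thresholds[(level, t)] = fit
            table.flags[level][t] = sorted(
                res for res, v in values.items() if v > fit.threshold
            )
    return table


def flag_pi(
    profiles: Mapping[int, IntensityProfile], level: float = 90.0
) -> tuple[list[int], NormalThreshold]:
    """Flag residues whose maximum PI exceeds the pooled percentile threshold.

    One normal is fitted to the pooled set of all PI observations of all
    residues across the melt (each residue-temperature value enters once;
    missing points contribute nothing), and a residue is flagged when its
    ``max_pi`` lies strictly above the pooled ``level`` threshold.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 intensity profiles")
    pooled = np.concatenate(
        [np.fromiter(p.pi_series.values(), dtype=float) for p in profiles.values()]
    )
    fit = normal_threshold(pooled, level)
    flagged = sorted(
        res for res, p in profiles.items() if p.max_pi > fit.threshold
    )
    return flagged, fit


def top_percent_change(
    profiles: Mapping[int, IntensityProfile], k: int = 15
) -> list[tuple[int, float]]:
    """The ``k`` residues with the largest percentage change in PI.

    Sorted by percent change descending; ties broken by residue index
    ascending (deterministic).  Returns ``(residue, percent_change)`` pairs;
    if the cohort is smaller than ``k`` the whole cohort is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        ((res, p.percent_change) for res, p in profiles.items()),
        key=lambda item: (-item[1], item[0]),
    )
    return ranked[:k]
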