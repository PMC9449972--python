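"""Chemical-shift trajectory metrics: per-step Δδ, cumulative ∑Δδ, linearity.

A residue's cross-peak traces a path in the 2D (1H, 15N) shift plane as the
temperature is ramped.  The per-step distance Δδ between consecutive
observed temperatures is the weighted Euclidean distance

    Δδ = sqrt( ΔδH² + (w · ΔδN)² )

with ``w`` the nitrogen scaling weight (default 0.14, the community-standard
CSP scaling that maps the broad 15N dispersion onto the 1H scale; ``w = 1``
gives the raw ppm distance).  ∑Δδ at a temperature is the running sum of the
steps up to it, zero at the first observed temperature — the cumulative
distance the peak has travelled, a per-residue drift statistic.  Gaps in the
series are bridged by a single step between the flanking observed positions,
assigned to the later temperature.

Trajectory shape is summarised by a scale-invariant linearity score: the RMS
perpendicular deviation of the intermediate points from the first→last chord
divided by the total path length.  A straight march scores 0; a score above
the configurable threshold (default 0.15) classifies the trajectory as
nonlinear, i.e. the peak visits intermediate environments off the direct
route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .peaks import PeakRecord, TemperatureSeries

__all__ = [
    "DEFAULT_NITROGEN_WEIGHT",
    "DEFAULT_LINEARITY_THRESHOLD",
    "ResidueShiftMetrics",
    "delta_shift",
    "cumulative_shift",
    "classify_trajectory",
    "compute_shift_metrics",
]

DEFAULT_NITROGEN_WEIGHT = 0.14
DEFAULT_LINEARITY_THRESHOLD = 0.15


@dataclass
class ResidueShiftMetrics:
    """Per-residue shift-trajectory summary.

    ``step_delta[T]`` is the Δδ step ending at temperature ``T``;
    ``cumulative_delta[T]`` the ∑Δδ up to ``T`` (0 at the first observed
    temperature).  ``linearity_score`` and ``trajectory_class`` are filled
    when the residue has at least three observed positions.
    """

    residue_index: int
    step_delta: dict[float, float] = field(default_factory=dict)
    cumulative_delta: dict[float, float] = field(default_factory=dict)
    linearity_score: float | None = None
    trajectory_class: str | None = None

    @property
    def total_delta(self) -> float:
        """∑Δδ at the last observed temperature."""
        if not self.cumulative_delta:
            return 0.0
        return self.cumulative_delta[max(self.cumulative_delta)]


def delta_shift(
    p1: PeakRecord,
    p2: PeakRecord,
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
) -> float:
    """Weighted 2D chemical-shift distance between two peaks of one residue."""
    if p1.residue_index != p2.residue_index:
        raise ValueError(
            f"delta_shift across residues {p1.residue_index} != {p2.residue_index}"
        )
    if nitrogen_weight <= 0:
        raise ValueError("nitrogen_weight must be > 0")
    dh = p2.delta_h - p1.delta_h
    dn = nitrogen_weight * (p2.delta_n - p1.delta_n)
    return float(np.hypot(dh, dn))


def cumulative_shift(
    series: TemperatureSeries,
    residue: int,
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
) -> ResidueShiftMetrics:
    """Per-step Δδ and cumulative ∑Δδ for one residue.

    Steps run between consecutive *observed* temperatures: a missing interior
    point is bridged by one step between the flanking observed positions
    (the distance actually travelled, not an interpolation), assigned to the
    later temperature.  ∑Δδ at the first observed temperature is 0.
    """
    obs = series.observed(residue)
    if len(obs) < 2:
        raise ValueError(
            f"residue {residue}: insufficient points "
            f"({len(obs)} observed, need >= 2)"
        )
    metrics = ResidueShiftMetrics(residue_index=residue)
    running = 0.0
    metrics.cumulative_delta[obs[0].temperature] = 0.0
    for prev, cur in zip(obs, obs[1:]):
        step = delta_shift(prev, cur, nitrogen_weight)
        running += step
        metrics.step_delta[cur.temperature] = step
        metrics.cumulative_delta[cur.temperature] = running
    return metrics


def classify_trajectory(
    positions: Sequence[tuple[float, float]],
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
    threshold: float = DEFAULT_LINEARITY_THRESHOLD,
) -> tuple[float, str]:
    """Score how far a peak trajectory departs from a straight line.

    ``positions`` are (δH, δN) pairs in temperature order; the 15N axis is
    scaled by ``nitrogen_weight`` before any geometry.  The score is the RMS
    perpendicular distance of the intermediate points from the first→last
    chord, divided by the total path length — dimensionless, and invariant
    under rotation, translation and uniform scaling of the trajectory.
    Degenerate cases: zero path length scores 0 (a stationary peak is
    linear); a closed path (first point = last point) measures deviations
    from the start point instead of from an undefined chord.
    """
    if len(positions) < 3:
        raise ValueError("need >= 3 positions to classify a trajectory")
    pts = np.asarray(positions, dtype=float)
    pts[:, 1] *= nitrogen_weight
    segs = np.diff(pts, axis=0)
    path_length = float(np.linalg.norm(segs, axis=1).sum())
    if path_length == 0.0:
        return 0.0, "linear"
    chord = pts[-1] - pts[0]
    chord_len = float(np.linalg.norm(chord))
    inner = pts[1:-1] - pts[0]
    if chord_len == 0.0:
        dists = np.linalg.norm(inner, axis=1)
    else:
        # perpendicular distance via the 2D cross product
        dists = np.abs(inner[:, 0] * chord[1] - inner[:, 1] * chord[0]) / chord_len
    score = float(np.sqrt(np.mean(dists**2)) / path_length)
    trajectory_class = "nonlinear" if score > threshold else "linear"
    return score, trajectory_class


def compute_shift_metrics(
    series: TemperatureSeries,
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
    linearity_threshold: float = DEFAULT_LINEARITY_THRESHOLD,
) -> dict[int, ResidueShiftMetrics]:
    """:func:`cumulative_shift` plus trajectory classification, all residues.

    Residues with fewer than two observed temperatures are silently omitted
    (they carry no step information); classification additionally needs
    three observed positions.
    """
    out: dict[int, ResidueShiftMetrics] = {}
    for res in series.residues:
        obs = series.observed(res)
        if len(obs) < 2:
            continue
        m = cumulative_shift(series, res, nitrogen_weight)
        if len(obs) >= 3:
            m.linearity_score, m.trajectory_class = classify_trajectory(
                [(p.delta_h, p.delta_n) for p in obs],
                nitrogen_weight,
                linearity_threshold,
            )
        out[res] = m
    return out
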