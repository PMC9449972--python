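"""Per-residue peak-intensity (PI) statistics over the thermal series.

HSQC peak intensity reflects local dynamics and population: over a thermal
ramp below the global melting transition, PI typically rises with
temperature (increasing mobility, bulk magnetisation), plateaus, then falls
as unfolding/aggregation sets in — a shape well described by a second-order
polynomial in temperature.  Three summaries are computed per residue: the
descriptive quadratic trend fit, the maximum PI over the melt (a proxy for
how dynamic the residue becomes), and the percentage change from the PI at
the start of the melt to that maximum (how much its dynamics change).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .peaks import TemperatureSeries

__all__ = [
    "IntensityProfile",
    "fit_pi_trend",
    "percent_change",
    "pi_summary",
    "compute_intensity_profiles",
]


@dataclass
class IntensityProfile:
    """Intensity summary of one residue across the melt.

    ``quad_coeffs`` are (a2, a1, a0) of the least-squares quadratic
    ``PI(T') = a2 T'^2 + a1 T' + a0`` in the centred temperature
    ``T' = T - (T_min + T_max)/2`` over the residue's observed range;
    ``r_squared`` is its coefficient of determination.  ``percent_change``
    is ``(max_pi - start_pi) / start_pi * 100``.
    """

    residue_index: int
    pi_series: dict[float, float]
    quad_coeffs: tuple[float, float, float] | None
    r_squared: float | None
    max_pi: float
    max_pi_temperature: float
    start_pi: float
    percent_change: float


def fit_pi_trend(
    temperatures: Sequence[float], intensities: Sequence[float]
) -> tuple[tuple[float, float, float], float]:
    """Ordinary least-squares quadratic PI(T) fit in a centred basis.

    The temperature axis is centred at the midpoint of its observed range
    before fitting, which decorrelates the coefficients and makes ``a1 = 0``
    for data symmetric about the midpoint.  Returns ``((a2, a1, a0), R²)``;
    the fit is descriptive, no residue is excluded on its account.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size != y.size:
        raise ValueError("temperatures and intensities differ in length")
    if t.size < 3:
        raise ValueError(f"need >= 3 points for a quadratic fit, got {t.size}")
    tc = t - (t.min() + t.max()) / 2.0
    # numpy polynomial fit returns coefficients in ascending order
    coeffs = np.polynomial.polynomial.polyfit(tc, y, deg=2)
    fitted = np.polynomial.polynomial.polyval(tc, coeffs)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    a0, a1, a2 = (float(c) for c in coeffs)
    return (a2, a1, a0), r2


def percent_change(start_pi: float, max_pi: float) -> float:
    """Percentage change from the start-of-melt PI to the maximum PI."""
    if start_pi <= 0:
        raise ValueError(
            f"percentage change undefined for start_pi = {start_pi} (must be > 0)"
        )
    return (max_pi - start_pi) / start_pi * 100.0


def pi_summary(series: TemperatureSeries, residue: int) -> IntensityProfile:
    """All intensity statistics for one residue.

    The "start of the melt" is the residue's first *observed* temperature
    (the missingness filter upstream caps how far that can drift from the
    grid start).  The maximum is taken over observed values; ties go to the
    lowest temperature.
    """
    obs = series.observed(residue)
    if len(obs) < 3:
        raise ValueError(
            f"residue {residue}: need >= 3 observed temperatures, got {len(obs)}"
        )
    temps = [p.temperature for p in obs]
    pis = [p.intensity for p in obs]
    i_max = int(np.argmax(pis))
    start_pi = pis[0]
    max_pi = pis[i_max]
    coeffs, r2 = fit_pi_trend(temps, pis)
    return IntensityProfile(
        residue_index=residue,
        pi_series=dict(zip(temps, pis)),
        quad_coeffs=coeffs,
        r_squared=r2,
        max_pi=max_pi,
        max_pi_temperature=temps[i_max],
        start_pi=start_pi,
        percent_change=percent_change(start_pi, max_pi),
    )


def compute_intensity_profiles(
    series: TemperatureSeries,
) -> dict[int, IntensityProfile]:
    """:func:`pi_summary` for every residue with at least three observations."""
    out: dict[int, IntensityProfile] = {}
    for res in series.residues:
        if len(series.observed(res)) >= 3:
            out[res] = pi_summary(series, res)
    return out
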