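"""Synthetic thermal-series peak lists with ground-truth labels.

The generator emulates the statistical structure of an assigned
``15N–1H`` HSQC thermal series of a folded protein below its global melting
transition, so that every downstream stage (trajectory metrics, percentile
flags, cross-correlation, end-to-end recovery) can be tested without raw
spectra:

* a 295–323 K grid in 2 K steps (15 points) by default;
* per-residue linear chemical-shift drift with temperature (amide
  temperature coefficients of a few ppb/K), giving the bulk of residues a
  linear ∑Δδ–temperature relationship with totals mostly below ~0.2 Δppm
  at the top of the ramp;
* localized two-state (logistic) transitions near 305–307 K for a minority
  of residues, sized so that their total ∑Δδ overshoots the population's
  90th-percentile threshold by ~50%;
* peak intensities following a concave quadratic in temperature peaking
  around 305–313 K, with a small set of high-dynamics residues whose
  maximum PI is several-fold the population's;
* a correlated group of residues sharing one latent transition (common
  midpoint/width, per-member amplitude jitter) plus independent noise;
* peak disappearance: listed temperatures omitted per residue (the
  analysis-side filter drops residues missing more than three points).

Randomness comes exclusively from :class:`numpy.random.Generator` seeded
with PCG64 — identical (scenarios, seed) input yields bit-identical output
on any platform.  Shift noise is additive (ppm), intensity noise
multiplicative (fractional), matching how position and intensity
uncertainties scale in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .peaks import PeakRecord, TemperatureSeries, assemble_series

__all__ = [
    "DEFAULT_TEMPERATURES",
    "Transition",
    "ResidueScenario",
    "GroundTruth",
    "generate_series",
    "make_correlated_group",
    "default_cohort",
]

#: the default thermal ramp: 295..323 K in 2 K steps
DEFAULT_TEMPERATURES: tuple[float, ...] = tuple(float(t) for t in range(295, 325, 2))

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Transition:
    """A localized two-state (logistic) conformational transition.

    The shift contribution at temperature T is
    ``amplitude * expit((T - midpoint) / width)`` on each axis.
    """

    midpoint: float  # K
    width: float  # K
    amplitude_h: float  # ppm
    amplitude_n: float  # ppm

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("transition width must be > 0")


@dataclass(frozen=True)
class ResidueScenario:
    """Generating parameters for one residue's thermal series."""

    residue_index: int
    residue_type: str = "A"
    base_h: float = 8.3  # ppm at the first grid temperature
    base_n: float = 120.0
    drift_h: float = 0.0  # ppm per K
    drift_n: float = 0.0
    transition: Transition | None = None
    pi_peak_temperature: float = 307.0  # K
    pi_peak_value: float = 1.0e6  # arbitrary units
    pi_curvature: float = 2.0e3  # units per K^2 (concave fall-off)
    noise_sd_shift_h: float = 0.0  # ppm, additive
    noise_sd_shift_n: float = 0.0
    noise_sd_pi: float = 0.0  # fractional, multiplicative
    missing_temperatures: tuple[float, ...] = ()
    correlated_group: int | None = None
    high_dynamics: bool = False

    def __post_init__(self):
        if self.pi_peak_value <= 0:
            raise ValueError("pi_peak_value must be > 0")
        if min(self.noise_sd_shift_h, self.noise_sd_shift_n, self.noise_sd_pi) < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def shift_at(self, t: float, t0: float) -> tuple[float, float]:
        """Noise-free (δH, δN) at temperature ``t`` (``t0`` = ramp start)."""
        dh = self.base_h + self.drift_h * (t - t0)
        dn = self.base_n + self.drift_n * (t - t0)
        if self.transition is not None:
            s = expit((t - self.transition.midpoint) / self.transition.width)
            dh += self.transition.amplitude_h * s
            dn += self.transition.amplitude_n * s
        return dh, dn

    def pi_at(self, t: float) -> float:
        """Noise-free PI at temperature ``t`` (floored just above zero)."""
        value = self.pi_peak_value - self.pi_curvature * (t - self.pi_peak_temperature) ** 2
        return max(value, 1e-9 * self.pi_peak_value)


@dataclass
class GroundTruth:
    """What was planted, per residue, for recovery scoring."""

    scenarios: dict[int, ResidueScenario]

    @property
    def transitioning(self) -> set[int]:
        """Residues carrying any transition (incl. correlated-group members)."""
        return {
            r for r, s in self.scenarios.items() if s.transition is not None
        }

    @property
    def high_dynamics(self) -> set[int]:
        """Residues planted with an outlying peak intensity."""
        return {r for r, s in self.scenarios.items() if s.high_dynamics}

    @property
    def correlated_groups(self) -> dict[int, list[int]]:
        groups: dict[int, list[int]] = {}
        for r, s in self.scenarios.items():
            if s.correlated_group is not None:
                groups.setdefault(s.correlated_group, []).append(r)
        return {g: sorted(m) for g, m in groups.items()}

    def label(self, residue: int) -> str:
        s = self.scenarios[residue]
        if s.correlated_group is not None:
            return f"correlated_group:{s.correlated_group}"
        if residue in self.high_dynamics:
            return "high_dynamics"
        if s.transition is not None:
            return "transitioning"
        if abs(s.drift_h) > 0 or abs(s.drift_n) > 0:
            return "drifting"
        return "none"


def generate_series(
    scenarios: Sequence[ResidueScenario],
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    seed: int | np.random.Generator = 0,
) -> tuple[TemperatureSeries, GroundTruth]:
    """Simulate a full temperature series from residue scenarios.

    Noise draws are consumed residue-by-residue in input order from a
    PCG64 generator, independent of each residue's missingness pattern,
    so listing a temperature as missing removes the record without
    perturbing any other residue's values.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    indices = [s.residue_index for s in scenarios]
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        raise ValueError(f"duplicate residue_index in scenarios: {dupes}")
    temps = sorted(float(t) for t in temperatures)
    t0 = temps[0]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    records: list[PeakRecord] = []
    for sc in scenarios:
        eps_h = rng.normal(0.0, 1.0, len(temps))
        eps_n = rng.normal(0.0, 1.0, len(temps))
        eps_pi = rng.normal(0.0, 1.0, len(temps))
        missing = {float(t) for t in sc.missing_temperatures}
        for k, t in enumerate(temps):
            if t in missing:
                continue
            dh, dn = sc.shift_at(t, t0)
            dh += sc.noise_sd_shift_h * eps_h[k]
            dn += sc.noise_sd_shift_n * eps_n[k]
            pi = sc.pi_at(t) * (1.0 + sc.noise_sd_pi * eps_pi[k])
            records.append(
                PeakRecord(
                    residue_index=sc.residue_index,
                    residue_type=sc.residue_type,
                    temperature=t,
                    delta_h=dh,
                    delta_n=dn,
                    intensity=max(pi, 0.0),
                )
            )
    series = assemble_series(records)
    truth = GroundTruth({s.residue_index: s for s in scenarios})
    return series, truth


def make_correlated_group(
    residues: Sequence[int],
    transition: Transition,
    seed: int | np.random.Generator = 0,
    *,
    group_id: int = 1,
    amplitude_jitter: float = 0.1,
    perturbation_scale: float = 0.5,
    template: ResidueScenario | None = None,
) -> list[ResidueScenario]:
    """Scenarios for residues sharing one latent transition.

    Every member carries the same transition midpoint and width; the
    amplitudes are scaled per member by ``1 + amplitude_jitter * z``, and
    each member's own independent drift is drawn at ``perturbation_scale``
    times the population scale — the group is one latent concerted mode
    plus *small* independent perturbations.  Other parameters are copied
    from ``template`` (or module defaults).  Each member's measurement
    noise remains independent, drawn later by :func:`generate_series`.
    """
    if len(residues) < 2:
        raise ValueError("a correlated group needs k >= 2 residues")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    base = template or ResidueScenario(residue_index=0)
    out = []
    for res in residues:
        scale = 1.0 + amplitude_jitter * float(rng.normal())
        member_transition = Transition(
            midpoint=transition.midpoint,
            width=transition.width,
            amplitude_h=transition.amplitude_h * scale,
            amplitude_n=transition.amplitude_n * scale,
        )
        out.append(
            ResidueScenario(
                residue_index=res,
                residue_type=base.residue_type,
                base_h=base.base_h + float(rng.normal(0.0, 0.3)),
                base_n=base.base_n + float(rng.normal(0.0, 3.0)),
                drift_h=base.drift_h + float(rng.normal(0.0, perturbation_scale * 0.003)),
                drift_n=base.drift_n + float(rng.normal(0.0, perturbation_scale * 0.02)),
                transition=member_transition,
                pi_peak_temperature=base.pi_peak_temperature,
                pi_peak_value=base.pi_peak_value,
                pi_curvature=base.pi_curvature,
                noise_sd_shift_h=base.noise_sd_shift_h,
                noise_sd_shift_n=base.noise_sd_shift_n,
                noise_sd_pi=base.noise_sd_pi,
                correlated_group=group_id,
            )
        )
    return out


def default_cohort(
    n_residues: int = 100,
    n_transitioning: int = 5,
    n_high_dynamics: int = 5,
    correlated_group_size: int = 4,
    seed: int | np.random.Generator = 0,
    *,
    transition_midpoint: float = 306.0,
) -> list[ResidueScenario]:
    """The standard simulated cohort used throughout the test suites.

    One hundred residues by default: a drifting baseline population, five
    residues with an independent localized transition (midpoints jittered
    around ``transition_midpoint`` within the 305–307 K window, matching a
    minor native-ensemble rearrangement), five high-dynamics residues whose
    peak intensity is three-fold the population's, one four-member group
    sharing a latent transition, and a sprinkle of realistic missingness
    (a few residues lose 1–3 points; two residues disappear for more than
    three points and are meant to be dropped by the analysis filter).

    Parameter scales (documented in the methods note): amide drift a few
    ppb/K so that population ∑Δδ totals sit mostly below 0.2 Δppm at
    323 K; transition amplitudes sized so an affected residue's total ∑Δδ
    overshoots the population's 90th-percentile threshold by about half;
    shift noise 0.002 ppm (1H) / 0.02 ppm (15N); intensity noise 3%.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_special = n_transitioning + n_high_dynamics + correlated_group_size
    if n_special + 2 > n_residues:
        raise ValueError("cohort too small for the requested special residues")
    all_res = list(range(1, n_residues + 1))
    special = rng.choice(all_res, size=n_special + 2, replace=False)
    trans_res = sorted(int(r) for r in special[:n_transitioning])
    hidyn_res = sorted(
        int(r) for r in special[n_transitioning : n_transitioning + n_high_dynamics]
    )
    group_res = sorted(
        int(r)
        for r in special[
            n_transitioning + n_high_dynamics : n_transitioning
            + n_high_dynamics
            + correlated_group_size
        ]
    )
    lost_res = sorted(int(r) for r in special[n_special:])

    noise = dict(noise_sd_shift_h=0.002, noise_sd_shift_n=0.02, noise_sd_pi=0.03)
    temps = np.array(DEFAULT_TEMPERATURES)

    def base_fields():
        peak = float(1.0e6 * rng.lognormal(0.0, 0.2))
        return dict(
            residue_type=_AA[int(rng.integers(len(_AA)))],
            base_h=float(rng.uniform(7.0, 9.5)),
            base_n=float(rng.uniform(105.0, 130.0)),
            drift_h=float(rng.normal(0.0, 0.003)),
            drift_n=float(rng.normal(0.0, 0.02)),
            pi_peak_temperature=float(rng.uniform(305.0, 313.0)),
            pi_peak_value=peak,
            pi_curvature=float(rng.uniform(0.0015, 0.0025)) * peak,
            **noise,
        )

    def random_transition() -> Transition:
        # amplitude split between the axes; total weighted size ~0.2 ppm
        sign_h = rng.choice([-1.0, 1.0])
        sign_n = rng.choice([-1.0, 1.0])
        return Transition(
            midpoint=float(rng.uniform(transition_midpoint - 1.5,
                                       transition_midpoint + 1.5)),
            width=float(rng.uniform(1.2, 2.0)),
            amplitude_h=float(sign_h * rng.uniform(0.14, 0.22)),
            amplitude_n=float(sign_n * rng.uniform(0.9, 1.4)),
        )

    scenarios: list[ResidueScenario] = []
    group_members = set(group_res)
    group_scenarios = {
        s.residue_index: s
        for s in make_correlated_group(
            group_res,
            Transition(
                midpoint=transition_midpoint,
                width=1.5,
                amplitude_h=0.18,
                amplitude_n=1.15,
            ),
            seed=rng,
            template=ResidueScenario(residue_index=0, **noise),
        )
    }
    for res in all_res:
        if res in group_members:
            scenarios.append(group_scenarios[res])
            continue
        fields = base_fields()
        transition = random_transition() if res in trans_res else None
        high_dynamics = res in hidyn_res
        if high_dynamics:
            fields["pi_peak_value"] *= 3.0
            fields["pi_curvature"] *= 3.0
        missing: tuple[float, ...] = ()
        if res in lost_res:
            # peak lost mid-melt: more than three points missing
            missing = tuple(float(t) for t in temps[-5:])
        elif rng.uniform() < 0.10:
            k = int(rng.integers(1, 4))
            missing = tuple(
                float(t) for t in rng.choice(temps[1:], size=k, replace=False)
            )
        scenarios.append(
            ResidueScenario(
                residue_index=res,
                transition=transition,
                missing_temperatures=missing,
                high_dynamics=high_dynamics,
                **fields,
            )
        )
    return scenarios
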