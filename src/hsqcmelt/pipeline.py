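"""End-to-end orchestration: simulate, analyze, report.

`run_analyze` drives the full residue-level analysis of a thermal HSQC
series — assembly and missingness filtering, Δδ/∑Δδ trajectory metrics,
intensity statistics, percentile flagging, cross-correlation matrices and
(optionally) structure mapping — and writes a reproducible report bundle:

* ``residue_metrics.tsv`` — per-residue ∑Δδ per temperature, linearity,
  max PI, percentage PI change;
* ``percentile_flags.tsv`` — the per-temperature 90th/95th-percentile
  ∑Δδ table, the pooled-PI flags and the top-k %PI ranking;
* ``ccm_delta.tsv`` / ``ccm_pi.tsv`` (and ``*_gated.tsv``) — correlation
  matrices over the flagged subsets;
* ``clusters.tsv`` and ``sum_delta_bfactor.pdb`` — when a structure is
  supplied;
* ``manifest.json`` — configuration, package/library versions and SHA-256
  checksums of the inputs.

`recovery_experiment` is the pipeline's self-check: it simulates cohorts
with planted transitions, high-dynamics residues and a correlated group,
reruns the analysis blind, and scores how reliably the planted residues are
recovered by the percentile flags and the gated CCM.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import build_ccm, gate_matrix
from .flags import flag_pi, flag_sum_delta, top_percent_change
from .intensity import compute_intensity_profiles
from .peaks import (
    TemperatureSeries,
    assemble_series,
    filter_missing,
    read_peak_table,
    temperature_from_filename,
    write_peak_table,
)
from .shifts import (
    DEFAULT_LINEARITY_THRESHOLD,
    DEFAULT_NITROGEN_WEIGHT,
    compute_shift_metrics,
)
from .structure import (
    DEFAULT_CLUSTER_CUTOFF,
    DEFAULT_PROBE_RADIUS_NM,
    export_bfactor_map,
    read_structure,
    sasa,
    spatial_clusters,
)
from .synthetic import default_cohort, generate_series

logger = logging.getLogger("hsqcmelt")

__all__ = ["RunConfig", "run_analyze", "run_simulate", "recovery_experiment"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, overridable from a YAML file."""

    inputs: list[str] = field(default_factory=list)
    dialect: str = "tsv"
    residue_offset: int = 0
    max_missing: int = 3
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT
    linearity_threshold: float = DEFAULT_LINEARITY_THRESHOLD
    percentile_levels: tuple[float, float] = (90.0, 95.0)
    pi_level: float = 90.0
    top_k: int = 15
    delta_gate: tuple[float, float] | None = None
    pi_gate: tuple[float, float] | None = None
    ccm_cumulative: bool = False
    structure_path: str | None = None
    structure_chain: str | None = None
    structure_offset: int = 0
    probe_radius_nm: float = DEFAULT_PROBE_RADIUS_NM
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF
    seed: int = 0
    n_residues: int = 100
    output_dir: str = "hsqcmelt_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a config file; keyword overrides win over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        for name in ("percentile_levels", "delta_gate", "pi_gate"):
            value = getattr(cfg, name)
            if isinstance(value, list):
                setattr(cfg, name, tuple(value))
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_series(config: RunConfig) -> TemperatureSeries:
    """Read and assemble the input peak lists named by the config."""
    records = []
    for name in config.inputs:
        if config.dialect == "sparky":
            t = temperature_from_filename(name)
            records.extend(
                read_peak_table(
                    name, "sparky", temperature=t,
                    residue_offset=config.residue_offset,
                )
            )
        else:
            records.extend(
                read_peak_table(
                    name, "tsv", residue_offset=config.residue_offset
                )
            )
    return assemble_series(records)


def run_analyze(
    config: RunConfig, series: TemperatureSeries | None = None
) -> dict[str, Any]:
    """Run the full analysis and write the report bundle.

    ``series`` may be passed directly (e.g. straight from the simulator);
    otherwise the peak lists in ``config.inputs`` are read.  Returns the
    in-memory results keyed like the output files.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if series is None:
        series = load_series(config)
    n_before = len(series.residues)
    series = filter_missing(series, config.max_missing)
    logger.info(
        "analyze: %d residues retained of %d (max_missing=%d)",
        len(series.residues), n_before, config.max_missing,
    )

    metrics = compute_shift_metrics(
        series, config.nitrogen_weight, config.linearity_threshold
    )
    profiles = compute_intensity_profiles(series)
    sum_delta_table = flag_sum_delta(metrics, config.percentile_levels)
    pi_flagged, pi_fit = flag_pi(profiles, config.pi_level)
    top_changes = top_percent_change(profiles, config.top_k)

    # CCMs over the respective 90th-percentile residues, as in a standard
    # perturbation-series analysis; fall back to all residues when the
    # flagged subset is too small to correlate.
    base_level = min(config.percentile_levels)
    delta_subset = sum_delta_table.flagged_anywhere(base_level)
    if len(delta_subset) < 2:
        delta_subset = list(metrics)
    pi_subset = pi_flagged if len(pi_flagged) >= 2 else list(profiles)
    ccm_delta = build_ccm(
        metrics, "delta", delta_subset, cumulative=config.ccm_cumulative
    )
    ccm_pi = build_ccm(profiles, "pi", pi_subset)
    gate_d = config.delta_gate or (None, None)
    gate_p = config.pi_gate or (None, None)
    ccm_delta_gated = gate_matrix(ccm_delta, *gate_d)
    ccm_pi_gated = gate_matrix(ccm_pi, *gate_p)

    results: dict[str, Any] = {
        "series": series,
        "metrics": metrics,
        "profiles": profiles,
        "sum_delta_table": sum_delta_table,
        "pi_flagged": pi_flagged,
        "pi_threshold": pi_fit,
        "top_percent_change": top_changes,
        "ccm_delta": ccm_delta,
        "ccm_delta_gated": ccm_delta_gated,
        "ccm_pi": ccm_pi,
        "ccm_pi_gated": ccm_pi_gated,
    }

    _write_metrics_table(out_dir / "residue_metrics.tsv", series, results)
    _write_flag_tables(out_dir / "percentile_flags.tsv", results, config)
    for name, ccm in (
        ("ccm_delta", ccm_delta),
        ("ccm_delta_gated", ccm_delta_gated),
        ("ccm_pi", ccm_pi),
        ("ccm_pi_gated", ccm_pi_gated),
    ):
        header = f"# observable={ccm.observable} gated={ccm.gated} gate={ccm.gate}\n"
        with open(out_dir / f"{name}.tsv", "w") as fh:
            fh.write(header)
            ccm.rho.to_csv(fh, sep="\t", float_format="%.6f")

    if config.structure_path:
        model = read_structure(
            config.structure_path,
            offset=config.structure_offset,
            chain=config.structure_chain,
        )
        flagged = sorted(
            set(delta_subset) | set(pi_flagged)
            | {res for res, _ in top_changes}
        )
        present = [r for r in flagged if r in set(model.residues)]
        clusters = spatial_clusters(model, present, config.cluster_cutoff)
        areas = sasa(model, config.probe_radius_nm)
        results["structure"] = model
        results["clusters"] = clusters
        results["sasa"] = areas
        with open(out_dir / "clusters.tsv", "w") as fh:
            fh.write(
                f"# single-linkage clusters, cutoff={clusters.cutoff} A, "
                f"selection={clusters.selection}\n"
            )
            fh.write("cluster\tresidue\tsasa_nm2\n")
            for ci, members in enumerate(clusters.clusters, start=1):
                for res in members:
                    fh.write(
                        f"{ci}\t{res}\t{areas.per_residue.get(res, float('nan')):.3f}\n"
                    )
        total_map = {
            res: m.total_delta for res, m in metrics.items()
        }
        export_bfactor_map(model, total_map, out_dir / "sum_delta_bfactor.pdb")

    manifest = {
        "package": "hsqcmelt",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": config.to_dict(),
        "inputs": {
            str(p): _sha256(Path(p))
            for p in list(config.inputs)
            + ([config.structure_path] if config.structure_path else [])
            if Path(p).exists()
        },
        "n_residues_retained": len(series.residues),
        "temperatures": series.temperatures,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _write_metrics_table(path: Path, series, results) -> None:
    metrics = results["metrics"]
    profiles = results["profiles"]
    temps = series.temperatures
    with open(path, "w") as fh:
        fh.write("# per-residue melt metrics; sum_delta columns in Dppm\n")
        cols = ["residue", "trajectory_class", "linearity_score",
                "max_pi", "max_pi_temperature", "percent_change_pi"]
        cols += [f"sum_delta_{t:g}K" for t in temps]
        fh.write("\t".join(cols) + "\n")
        for res in series.residues:
            m = metrics.get(res)
            p = profiles.get(res)
            row = [
                str(res),
                m.trajectory_class if m and m.trajectory_class else "NA",
                f"{m.linearity_score:.4f}" if m and m.linearity_score is not None else "NA",
                f"{p.max_pi:.6g}" if p else "NA",
                f"{p.max_pi_temperature:g}" if p else "NA",
                f"{p.percent_change:.2f}" if p else "NA",
            ]
            for t in temps:
                if m and t in m.cumulative_delta:
                    row.append(f"{m.cumulative_delta[t]:.5f}")
                else:
                    row.append("NA")
            fh.write("\t".join(row) + "\n")


def _write_flag_tables(path: Path, results, config: RunConfig) -> None:
    table = results["sum_delta_table"]
    with open(path, "w") as fh:
        fh.write("# percentile flags; one row per (observable, level, temperature)\n")
        fh.write("observable\tlevel\ttemperature_K\tthreshold\tresidues\n")
        for level in table.levels:
            for t in sorted(table.flags[level]):
                thr = table.thresholds[(level, t)].threshold
                residues = ",".join(map(str, table.flags[level][t])) or "-"
                fh.write(f"sum_delta\t{level:g}\t{t:g}\t{thr:.5f}\t{residues}\n")
        fit = results["pi_threshold"]
        residues = ",".join(map(str, results["pi_flagged"])) or "-"
        fh.write(
            f"pi_pooled\t{fit.level:g}\tall\t{fit.threshold:.6g}\t{residues}\n"
        )
        fh.write("# top percentage-change-in-PI ranking\n")
        fh.write("rank\tresidue\tpercent_change\n")
        for rank, (res, pc) in enumerate(results["top_percent_change"], start=1):
            fh.write(f"{rank}\t{res}\t{pc:.2f}\n")


def run_simulate(config: RunConfig) -> Path:
    """Simulate a cohort and write TSV peak lists plus the ground truth.

    Writes ``simulated_peaks.tsv`` (consumable by `run_analyze`) and
    ``ground_truth.tsv`` listing every scenario parameter and label.
    Returns the output directory.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenarios = default_cohort(n_residues=config.n_residues, seed=config.seed)
    series, truth = generate_series(scenarios, seed=config.seed + 1)
    write_peak_table(series.iter_records(), out_dir / "simulated_peaks.tsv")
    with open(out_dir / "ground_truth.tsv", "w") as fh:
        fh.write("# generating scenario per residue\n")
        fields = [f.name for f in dataclasses.fields(scenarios[0])]
        fh.write("label\t" + "\t".join(fields) + "\n")
        for sc in scenarios:
            values = [getattr(sc, f) for f in fields]
            fh.write(
                truth.label(sc.residue_index)
                + "\t"
                + "\t".join(str(v) for v in values)
                + "\n"
            )
    return out_dir


def _rates(predicted: set[int], positives: set[int], cohort: set[int]
           ) -> tuple[float, float]:
    negatives = cohort - positives
    tp = len(predicted & positives)
    tn = len(negatives - predicted)
    sens = tp / len(positives) if positives else float("nan")
    spec = tn / len(negatives) if negatives else float("nan")
    return sens, spec


def recovery_experiment(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_residues: int = 100,
    *,
    level: float = 90.0,
) -> dict[str, float]:
    """Planted-signal recovery rates of the full pipeline.

    For each seed a fresh cohort is simulated (planted transitions,
    high-dynamics residues, one correlated group), analysed blind, and
    scored:

    * ``sum_delta_*`` — residues flagged at ``level`` for ∑Δδ at the final
      temperature vs the residues planted with a transition;
    * ``pi_*`` — residues flagged by the pooled-PI threshold vs the planted
      high-dynamics residues;
    * ``ccm_*`` — pairs above the Δδ gate in the all-residue CCM: pairs
      within the planted correlated group are positives; pairs with at
      least one transition-free member are negatives (two residues that
      independently transition at nearby temperatures are genuinely
      rank-correlated, so such pairs are excluded from the negative set).

    Returns mean sensitivity/specificity over seeds.
    """
    acc: dict[str, list[float]] = {k: [] for k in (
        "sum_delta_sensitivity", "sum_delta_specificity",
        "pi_sensitivity", "pi_specificity",
        "ccm_sensitivity", "ccm_specificity",
    )}
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        scenarios = default_cohort(n_residues=n_residues, seed=rng)
        series, truth = generate_series(scenarios, seed=rng)
        series = filter_missing(series, 3)
        retained = set(series.residues)

        metrics = compute_shift_metrics(series)
        table = flag_sum_delta(metrics, (level,))
        final_t = series.temperatures[-1]
        flagged_delta = set(table.flags[level].get(final_t, []))
        sens, spec = _rates(
            flagged_delta, truth.transitioning & retained, retained
        )
        acc["sum_delta_sensitivity"].append(sens)
        acc["sum_delta_specificity"].append(spec)

        profiles = compute_intensity_profiles(series)
        flagged_pi, _ = flag_pi(profiles, level)
        sens, spec = _rates(
            set(flagged_pi), truth.high_dynamics & retained, retained
        )
        acc["pi_sensitivity"].append(sens)
        acc["pi_specificity"].append(spec)

        ccm = build_ccm(metrics, "delta")
        gated = gate_matrix(ccm)
        lo, hi = gated.gate
        rho = ccm.rho
        group = sorted(
            set.union(set(), *(set(m) for m in truth.correlated_groups.values()))
            & retained
        )
        transitioning = truth.transitioning & retained
        tp = fn = tn = fp = 0
        residues = list(rho.index)
        for a_idx, a in enumerate(residues):
            for b in residues[a_idx + 1:]:
                r = rho.loc[a, b]
                above = bool(np.isfinite(r) and (r >= hi or r <= lo))
                in_group = a in group and b in group
                if in_group:
                    tp += above
                    fn += not above
                elif a not in transitioning or b not in transitioning:
                    fp += above
                    tn += not above
        acc["ccm_sensitivity"].append(tp / (tp + fn) if tp + fn else float("nan"))
        acc["ccm_specificity"].append(tn / (tn + fp) if tn + fp else float("nan"))
    return {k: float(np.nanmean(v)) for k, v in acc.items()}
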