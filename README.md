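# hsqcmelt

Residue-level analysis of variable-temperature ¹⁵N–¹H HSQC peak lists.

## The problem

A folded protein held just below its global melting temperature does not sit
still: parts of its native ensemble redistribute, loops loosen, and local
conformational transitions fire long before anything unfolds globally.  A
series of assigned 2D ¹⁵N–¹H HSQC spectra recorded along a thermal ramp
(e.g. 295–323 K in 2 K steps) captures this residue by residue: every
backbone amide contributes one cross-peak whose *position* (δ¹H, δ¹⁵N, in
ppm) reports its microchemical environment and whose *intensity* (PI)
reports its local dynamics.

`hsqcmelt` turns per-temperature peak lists (plain TSV or Sparky-style
`.list` files) into the per-residue statistics such a study needs, for NMR
spectroscopists and protein-stability researchers:

* **Δδ and ∑Δδ** — the weighted 2D shift distance travelled per temperature
  step, Δδ = √(ΔδH² + (w·ΔδN)²) with w = 0.14 by default, and its running
  sum from the start of the ramp (zero at the first observed temperature).
  Trajectories are classified linear/nonlinear by a scale-invariant
  chord-deviation score.
* **Intensity statistics** — a descriptive quadratic PI(T) trend, the
  maximum PI over the melt, and the percentage change
  (PIₘₐₓ − PI₀)/PI₀ × 100.
* **Percentile outliers** — a normal distribution is fitted per temperature
  to the population's ∑Δδ (and pooled over the melt for PI) and residues
  strictly above μ + Φ⁻¹(p)·σ are flagged at the 90th/95th percentile.
* **Cross-correlation matrices** — Spearman's ρ = 1 − 6Σdᵢ²/(n(n²−1))
  between residue pairs over the melt (per-step Δδ vectors, or PI), with
  display gates of ±0.6 (Δδ) and ±0.95 (PI).
* **Structure mapping** — per-residue Shrake–Rupley SASA (0.14 nm probe),
  minimum side-chain distances, single-linkage spatial clusters of flagged
  residues, and export of any metric into a PDB B-factor column.
* **A synthetic-data generator** — cohorts with planted linear drifts,
  localized two-state transitions near 305–307 K, quadratic PI profiles,
  correlated groups and realistic missingness, with ground-truth labels, so
  the whole pipeline is testable end to end without raw spectra.

Residues missing at more than three temperature points are excluded from
analysis, matching standard practice for peaks that disappear or become
coincident during a melt.

## Worked example

Simulate a 25-residue cohort and analyse it blind:

```bash
hsqcmelt simulate --seed 3 --n-residues 25 --output-dir demo
hsqcmelt analyze --input demo/simulated_peaks.tsv --output-dir demo_out
```

```
INFO filter_missing: dropped 2 residue(s) with > 3 missing temperature points: [21, 25]
INFO analyze: 23 residues retained of 25 (max_missing=3)
analyzed 23 residues over 15 temperatures; bundle written to demo_out
```

Two residues lost more than three points mid-melt and were filtered out.
`demo_out/percentile_flags.tsv` then shows, at the final temperature, the
fitted-normal 90th-percentile threshold and the flagged outliers:

```
sum_delta  90  323  0.31673  9,12,13
```

i.e. residues 9, 12 and 13 travelled further than μ + 1.28σ of the cohort's
∑Δδ distribution at 323 K — these are the planted transitions.  The
percentage-change ranking at the bottom of the same file starts

```
rank  residue  percent_change
1     11       293.67
2     2        133.32
```

residue 11's peak intensity almost quadrupled from the start of the melt to
its maximum.  `residue_metrics.tsv` holds the per-residue detail (trajectory
class, linearity score, max PI and its temperature, ∑Δδ at every
temperature), and `ccm_delta_gated.tsv` the Spearman matrix with |ρ| < 0.6
masked.  With `--structure-path <pdb>` the bundle additionally contains
single-linkage clusters of the flagged residues, per-residue SASA, and a
PDB with ∑Δδ written into the B-factor column.

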