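# Methods

This note records the models, conventions and numerical choices behind
`hsqcmelt`, and what the synthetic-data experiments do and do not show.

## Observables and conventions

**Chemical-shift distance.**  A residue's cross-peak position is a point
(δH, δN) in ppm.  The distance between two positions is the weighted
Euclidean norm Δδ = √(ΔδH² + (w·ΔδN)²).  The nitrogen weight w maps the
~5-fold broader ¹⁵N dispersion onto the ¹H scale; the default w = 0.14 is
the community-standard chemical-shift-perturbation scaling, and w = 1
(raw ppm distance) is selectable.  All percentile analyses in one run use
a single declared weight.  Δδ is a true metric on peak positions
(symmetric, zero only for identical positions, triangle inequality), which
the test suite property-checks.

**Cumulative shift ∑Δδ.**  Steps are taken between consecutive *observed*
temperatures.  ∑Δδ at the first observed temperature is 0; at temperature
T it is the sum of all steps up to T, hence non-decreasing.  A missing
interior point is bridged by one step between the flanking observed
positions — the distance actually travelled — assigned to the later
temperature; no positions are interpolated.

**Referencing.**  Each spectrum's ¹H axis is zeroed to the TSP signal by
subtracting its apparent shift o.  With indirect referencing enabled
(default), the ¹⁵N zero frequency is recomputed as Ξ times the corrected
¹H reference frequency; in ppm units Ξ cancels and the ¹⁵N axis moves by
δ′ = (δ − o)/(1 + o·10⁻⁶), i.e. by the same ppm offset to first order.
Because the offset is a per-temperature constant, it cancels in every Δδ
step; it is retained in `reference_offsets` for provenance.

**Numbering.**  The pipeline's canonical numbering is the mature protein
sequence.  All readers take an integer offset applied on read
(`pipeline = file + offset`), so structure files renumbered from 1 and
peak lists in any convention meet in one internal scheme.

**Trajectory linearity.**  The score is the RMS perpendicular deviation of
the intermediate points from the first→last chord (in the weighted ppm
plane), divided by the total path length.  It is dimensionless and
invariant under rotation, translation and uniform scaling.  A stationary
peak scores 0; a closed path (first = last point) measures deviation from
the start point since the chord is undefined.  The default nonlinearity
threshold is 0.15: a straight two-segment right angle scores ≈ 0.35, mild
curvature scores a few hundredths, so 0.15 separates "visits intermediate
environments off the direct route" from noise-level wobble.  The threshold
is configurable and reported with every run.

## Percentile flags

The population of ∑Δδ values at a fixed temperature is treated as normal:
μ and σ are the sample mean and n−1 standard deviation, and the p-th
percentile threshold is μ + Φ⁻¹(p/100)·σ.  Flagging is strictly above the
threshold, so a degenerate population (σ = 0, e.g. the ramp's first
temperature where every ∑Δδ is 0) flags nobody and emits a warning.  The
95% set is nested in the 90% set by construction.  For intensity, one
normal is fitted to the pooled set of every residue-temperature PI value
(each observation once; missing points contribute nothing) and a residue
is flagged when its *maximum* PI exceeds the pooled threshold.  Note that
under the pooled rule a residue's maximum is intrinsically an upper-tail
statistic, so even a homogeneous cohort flags a nonzero fraction; the rule
is kept because it is the field's convention for "relatively dynamic"
residues, and the recovery experiments quantify its false-positive rate
(≈ 2% under the default cohort).

The percentage change in PI, (PIₘₐₓ − PI₀)/PI₀ × 100, uses the residue's
first observed temperature as the start of the melt (the missingness
filter caps how far that can drift).  The top-k ranking breaks ties by
ascending residue index.

## Cross-correlation matrices

Spearman's ρ between two residues is computed over their overlapping
temperatures.  Tie-free data use the classical 1 − 6Σdᵢ²/(n(n²−1))
formula on integer ranks; ties fall back to the Pearson correlation of
mid-ranks (which reduces to the formula exactly when tie-free), and the
pair is flagged.  The Δδ matrix correlates per-step Δδ vectors (D₁, D₂, …)
by default; cumulative ∑Δδ vectors are selectable but are nearly always
monotone and hence trivially correlated, which is why steps are the
default.  Cells with fewer than 4 overlapping temperatures are masked as
low-confidence when gating.  Gates mask the strict interior (−0.6, 0.6)
for Δδ and (−0.95, 0.95) for PI — PI rank correlations run systematically
higher because every residue shares the global rise-plateau-fall intensity
trend — and values exactly at a gate edge are retained.

## Structure analysis

**SASA.**  Shrake–Rupley with a deterministic golden-spiral (Fibonacci)
point lattice: every atom's sphere of radius (r_vdW + probe) is sampled
with the same seedless 960-point set; a point is accessible iff outside
every other atom's expanded sphere; each accessible point carries an equal
share of 4π(r_vdW + probe)².  The probe radius is 0.14 nm (water); radii
are a packaged Bondi-type table with a 1.70 Å fallback (warned) for
unknown elements.  Areas are reported in nm².  Determinism makes results
bit-reproducible, at the cost of only approximate rotation invariance:
at 960 points the whole-chain area is rotation-stable to < 0.5%,
per-residue areas to a few percent, and the isolated-atom area matches
the closed form 4π(r+probe)² to < 0.5%.  The implementation is
cross-checked in the tests against Biopython's independent Shrake–Rupley.

**Distances and clusters.**  Inter-residue distance is the minimum
pairwise distance over a declared atom selection; the default
`side_chain_heavy` (heavy atoms outside the N/CA/C/O backbone, glycine
falling back to Cα) matches how side-chain contacts are discussed in
structural work; `all_heavy` and `CA` are selectable.  Flagged residues
are clustered by single linkage: connected components of the graph with
an edge where the distance is ≤ cutoff (default 6.0 Å).  This makes
"the flagged residues form k structural clusters" a parameterised,
testable statement rather than a visual judgement.  Lowering the cutoff
can only refine the partition.

**B-factor export.**  Any per-residue metric can be written into the
B-factor column of a copy of the input PDB (two decimals, sentinel −1.00
for residues without a value) for inspection in molecular viewers.

## Synthetic data: what it emulates

Each residue's noise-free trajectory is
δ(T) = base + drift·(T − T₀) + amplitude·logistic((T − midpoint)/width),
with additive Gaussian position noise, and
PI(T) = peak − curvature·(T − T_peak)² with multiplicative (fractional)
intensity noise — additive for positions and multiplicative for
intensities because that is how the respective measurement uncertainties
scale.  The logistic is the simplest two-state shape for a localized
conformational transition.  All randomness flows from a seeded PCG64
generator (`numpy.random.default_rng`); identical inputs give
bit-identical series on any platform, and a residue's missingness pattern
does not perturb any other residue's draws.

The default 100-residue cohort fixes the study conditions: a 295–323 K
grid in 2 K steps; drifts of a few ppb/K per axis (drift_h ~ N(0, 0.003),
drift_n ~ N(0, 0.02) ppm/K) so that ~90% of baseline residues end below
0.2 Δppm total ∑Δδ; five independent transitions with midpoints in
305–307 K, widths 1.2–2.0 K and amplitudes (0.14–0.22 ppm ¹H,
0.9–1.4 ppm ¹⁵N) sized so an affected residue's total overshoots the
population's 90th-percentile threshold by about half; PI peaking at
305–313 K with a 40–60% fall-off toward the grid ends and a lognormal
(σ = 0.2) spread of peak heights; five high-dynamics residues at
three-fold peak intensity; one four-member group sharing a latent
transition (common midpoint/width, ±10% amplitude jitter, member drifts
at half the population scale — one concerted mode plus small independent
perturbations); position noise 0.002/0.02 ppm, intensity noise 3%; ~10%
of residues missing 1–3 points and two residues losing five points (to
be dropped by the filter).

**Recovery scoring.**  Each simulated cohort is analysed blind and scored:
∑Δδ flags at the final temperature against the planted transition
carriers, pooled-PI flags against the planted high-dynamics residues, and
above-gate Δδ-CCM pairs against the planted group.  For the CCM
specificity, pairs in which both members carry *independent* transitions
are excluded from the negative set: two residues that genuinely transition
at nearby temperatures are genuinely rank-correlated, so calling such a
pair a false positive would score the method down for detecting a real
property of the data (coincidental co-transition, as opposed to a shared
mode).  Over 100 seeded cohorts, all six sensitivity/specificity rates
come out ≥ 0.93 (`scripts/acceptance.py` recomputes them).

**What passing does not show.**  The generator draws independent Gaussian
noise per point; real melts have correlated baseline drift, temperature-
dependent linewidths, peak overlap that biases positions before a peak is
lost entirely, and referencing residuals.  Missingness here is random or
terminal, whereas real disappearance is biased toward exchange-broadened
(i.e. interesting) residues.  Transition shapes are symmetric logistics;
real local transitions can be multi-state.  Recovery rates on this
generator therefore demonstrate internal consistency of the pipeline at
realistic signal-to-noise, not field performance on any particular
protein.

## Problem sizes and determinism

The test suite and the acceptance script run the recovery experiment at
100 cohorts × 100 residues × 15 temperatures, which completes in about
two minutes on one CPU; single-pair and single-residue checks use
closed-form or brute-force oracles.  Every stochastic test is seeded, and
hypothesis-based property tests run derandomised.

## Known limitations

* The percentile machinery assumes approximately normal populations; for
  heavy-tailed ∑Δδ distributions the fitted-normal threshold is more
  permissive than an empirical quantile.
* Spearman ρ over ≤ 15 temperatures has a null standard deviation of
  ~0.28, hence the ±0.6 gate; individual above-gate pairs are suggestive,
  not significant, and no multiplicity correction is applied (the gate is
  a display device, as in the source analyses this package supports).
* SASA ranks burial reliably, but absolute per-residue values depend on
  the radii table, sampling density and the absence of ensemble averaging;
  comparisons to ensemble-based reference values should allow a generous
  band (the benchmark uses ±0.08 nm²).
* The PDB writer round-trips through Biopython and keeps one chain/model;
  insertion codes and altlocs beyond the first are not preserved.
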