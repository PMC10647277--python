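# Methods

## Model

The scratch assay is represented as a 2-D square lattice with spacing δ
(one cell diameter). The state of a site is empty or occupied; no site ever
holds two cells. The initial configuration has a cell-free central band of
`round(b0/δ)` columns (the wound) flanked by two reservoirs, each half the
wound width (rounded up), seeded by independent per-site occupation with
probability f = min(1, ρδ²). Densities above confluence (ρδ² > 1, which
occurs for some published cell-line densities) are clamped to full coverage
with a warning. Rows are periodic; columns end at the reservoir edges. By
default the lattice is square (rows = total columns); the row count is
configurable and is a resolution choice, not a physical one.

### Update rule

Cells act asynchronously: each sweep visits every site occupied at the
start of the sweep exactly once, in a fresh random permutation, against the
live grid (a cell sees the moves of cells visited before it; daughters
created during a sweep first act in the next sweep). Sequential update
removes target conflicts by construction. For the visited cell a uniform
λ ∈ [0, 1] decides the action: migration if λ < Pm, division otherwise,
with Pm = (1/Tm)/(1/Tm + 1/Td) and Pd = 1 − Pm — the two processes behave
as parallel resistances, the faster one dominating.

The target is a single uniform draw from the cell's 3×3 block (its own
site included). The directional stimulus from the opposite wound edge is
modelled by removing the two backward-diagonal options for cells strictly
left/right of the fixed initial wound midline ("from 9 to 7" options;
which two sites are dropped is configurable, as is disabling the bias).
**The action succeeds only when the drawn site is vacant**; drawing an
occupied site (or the cell's own) does nothing that sweep, and a cell with
no vacant neighbour is quiescent (contact inhibition). This blocked draw
makes transport an excluded random walk. The alternative rule — drawing
uniformly among the *vacant* candidates only — is available
(`target_selection="empty"`) but makes fronts ballistic, with front
velocities of order δ/Δt ≈ 100–270 µm/h for typical parameters, an order
of magnitude above the measured 5–60 µm/h range of scratch-assay fronts;
the blocked rule reproduces the measured kinetics and is the default.

### Time step

One sweep corresponds to Δt = (1/Tm + 1/Td)⁻¹ hours, so the per-sweep
action probabilities are exactly rate × Δt for both processes
(Pm = Δt/Tm, Pd = Δt/Td). For migration-dominated conditions Δt ≈ Tm.

### Reservoir boundary

The first and last columns emulate unbounded surrounding tissue: after each
sweep, every boundary vacancy *generated during the simulation* (i.e. every
boundary site that has ever been occupied and is now empty) is repopulated.
Early in a simulation the reservoir therefore supplies cells at the seeding
density; as its never-occupied sites are colonised it ratchets toward
confluence, so the late-stage supply becomes independent of the initial
density. The alternative (`refill_mode="density"`) refills each boundary
vacancy stochastically with probability f, pinning the reservoir at the
seeding density for all time; it makes the time to complete closure depend
on ρ much more strongly.

### Wound-area measure

In vitro the wound is detected by image analysis as the contiguous
cell-free region. The in-silico default mirrors that: A = δ² × (number of
empty sites in 8-connected empty components that intersect the initial
wound band), ignoring single-site components — an isolated vacancy is
smaller than one cell and invisible to an edge detector. Closure
(T_closure) is the first time this area reaches zero. A second measure
(`method="runs"`: per-row maximal empty runs through the wound midline) is
provided for comparison; it collapses as soon as pioneer cells cross the
midline and therefore overestimates closure rates roughly threefold on
dense calibration conditions, so it is not the default.

## Closure kinetics

α is minus the OLS slope of A/A₀ against t from t = 0 up to the first
sample at or below A/A₀ = 0.1 (the whole curve if never reached): the
decline is close to linear in that window and the flat closed tail would
otherwise bias the slope. T_half is linearly interpolated between the
bracketing samples; T_closure requires measured area exactly zero and is
undefined (not zero, not infinite) for runs that do not close within the
horizon. The front velocity is reported as v = αb₀/2: two symmetric fronts
sharing the areal closure rate, consistent with the published v range given
the α and b₀ ranges. Simulated-vs-measured curves are compared by Pearson
correlation after linear interpolation of the simulated curve onto the
experimental time points.

## Calibration anchor

With the defaults above, the dense HT-1080 condition (ρ = 2.9·10⁻³ cells/µm²,
b₀ = 371 µm, Td = 24 h, Tm = 0.075 h, δ = 20 µm) yields mean α ≈ 0.117–0.12 /h
and mean T_closure ≈ 9.3 h over 20 seeds, against measured values of
0.128 /h and ~9 h. These numbers are recomputed by the test suite and by
`scripts/acceptance.py`, never hard-coded.

## Global sensitivity analysis

(ρ, Tm, Td) are sampled by Latin hypercube (one draw per equal-probability
stratum per marginal; scipy's sampler) inside their physiological ranges
(ρ ∈ [10⁻⁶, 10⁻³] cells/µm², Tm ∈ [0.005, 0.5] h, Td ∈ [12, 40] h), with
the purely geometric δ = 20 µm and b₀ = 575 µm fixed at their mid-range
values. Each set is simulated once and summarised by (α, T_half,
T_closure). Outputs are regressed on the inputs by OLS; **inputs and
outputs are z-scored first**, because raw-scale coefficients of parameters
with different units are incomparable and the downstream ranking would be
meaningless without standardisation. The procedure is replicated (10
independent LHS sets) to obtain coefficient distributions; per output, a
one-way ANOVA across the three |β| distributions is followed by Tukey HSD
at 95%, parameters are ordered by mean |β|, and Tukey-indistinguishable
neighbours share the better rank. Rows with undefined outputs (runs not
closing within the 96 h analysis horizon, ~5% of the box; longer horizons
leave them unchanged) are excluded from that output's regression and
counted. Replicate coefficients with p ≥ 0.05 are retained but flagged.

At 10 × 100 samples the ranking is: Tm rank 1 for α, T_half and T_closure
(by a wide margin, ANOVA p < 10⁻¹²); for T_half, ρ rank 2 and Td rank 3;
for α, ρ and Td tie. For T_closure this implementation finds ρ marginally
but significantly ahead of Td (mean |β| ≈ 0.18 vs 0.15) — the initial cell
count retains a small influence on completing closure. The reverse order
has been reported for this assay; the ordering of these two small,
similar-sized effects is sensitive to unpublished details of the original
area measure and boundary handling, and we report ours as measured.

## Scaling law

The sweep draws Φ = Tm/Td log-uniformly over the physiological span
[10⁻⁴, 0.5] (Td, ρ uniform in their ranges, Tm = Φ·Td; δ, b₀ fixed), which
covers the span evenly on a log scale and reaches the poorly-motile,
proliferation-dominated regime. α = a·Φ⁻ᵇ is fitted by OLS of ln α on
ln Φ — exact linearisation, and multiplicative noise is roughly
homoscedastic in log space; standard errors come from the regression (the
prefactor's by the delta method). Every run with measured α > 0 enters the
fit regardless of whether it closed within the horizon: "closed" is a
censoring artifact of the 48 h default horizon for slow conditions, and
dropping censored runs would delete the high-Φ wing and steepen the fit;
non-closing counts are reported alongside. A 300-simulation sweep gives
a ≈ (1.0–1.4)·10⁻³ 1/h and b ≈ 0.66–0.70 across seeds (r² ≈ 0.75–0.85),
and for Φ > 0.1 the fitted curve systematically under-predicts the
simulated rates — in that regime proliferation adds closure beyond the
power-law extrapolation.

The critical-Φ analysis runs matched pairs (shared seed) with the
proliferation branch enabled vs suppressed (Pm unchanged) on a fully
covered lattice — so the comparison isolates proliferation kinetics rather
than cell supply — and reports ε(Φ) = |α_full − α_knockout|/α_full averaged
over ≥20 seeds per grid point. ε grows monotonically with Φ. At the default
10% threshold the critical Φ comes out near 4·10⁻³: closure of a 575 µm
wound takes ~10² sweeps, so even a per-sweep division probability of
Φ ≈ 4·10⁻³ accumulates ~0.4 divisions per cell, a ~20% share of the filled
area. A published critical value of 10⁻² corresponds, under this model, to
tolerating an α change of roughly 40%; the threshold is a configuration
knob, and the default is kept at the stricter 10%.

## Synthetic experiment fixtures

`make_synthetic_experiment` generates A/A₀ curves of the form
max(0, 1 − αt) plus Gaussian noise clipped to [0, 1.05], emulating the
image-derived readout of a real assay (linear decline, bounded support,
measurement noise). It does not emulate early lag phases, curvature near
closure, or spatially correlated detection errors, so recovery tests on
these fixtures validate the fitting pipeline, not the image analysis of
real micrographs. Real measured curves can be supplied as 2-column CSV.

## Numerical and engineering choices

- The sweep kernel is numba-compiled; all randomness is drawn in Python
  from one seeded numpy Generator per simulation and passed to the kernel,
  so a simulation is a deterministic function of (parameters, seed), and
  batch runs derive child seeds from a master seed via `SeedSequence`.
- Target-choice index is `int(u · m)` over the m options enumerated in
  fixed row-major order; ties at u = 1 clamp to the last option.
- Degenerate inputs fail loudly: non-positive times/geometry raise domain
  or configuration errors; fits require ≥3 points and non-degenerate
  designs; comparisons require ≥3 overlapping time points.
- Diagonal moves cover δ√2 but count as one step — the standard lattice-CA
  approximation.
- Default horizons: 48 h for single runs and sweeps (a typical assay
  duration), 96 h for the GSA's T_closure regressions.

## Known limitations

- No chemoattractant fields, ECM mechanics, contact guidance, cell
  spreading/shape change, or 3-D geometry; single cell type per run.
- The power-law prefactor sits ~1.5–2× below the published 2·10⁻³ at
  mid-sweep densities (the exponent agrees); it depends on the sweep's
  density mix, for which no single canonical choice exists.
- Sub-confluent seeding makes the component area measure slightly
  non-monotone over the first few sweeps (rearrangements open measurable
  two-site gaps next to the band); the effect is ≤0.5% of A₀.
- The assay readout is closure kinetics only; single-cell tracks,
  persistence and velocity distributions are outside scope.
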