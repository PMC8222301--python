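# Methods

## Event model and preprocessing

The raw unit is a bubble detection with a timestamp at seconds
resolution. All internal arithmetic is in integer epoch seconds (UTC);
sub-second input is floored. Bubbles are pooled into release events by
an **anchored-window rule**: the first unassigned bubble opens an event
stamped at its own time, and every later bubble within
`pool_interval_s` (default 10 s, boundary inclusive) of that anchor
joins it. We read "within a 10-s period" as a fixed-length period from
the burst's first bubble; the alternative gap-chaining semantics (merge
while consecutive gaps stay within the interval) is provided as
`PoolingConfig(mode="gap")` since the original convention is ambiguous.
Anchored pooling is idempotent and monotone in the interval (more
pooling never yields more events); both properties are tested.

Analysis windows are tiled from midnight UTC of each day — windows are
clock-aligned, avoiding an arbitrary phase — with lengths restricted to
divisors of 86,400 s (the canonical set is 1, 5, 30 min and 1, 2, 4,
6 h). Event offsets inside a window are 1-based integers
`ceil(t − start)` clamped to `[1, W]`, matching the support of the null
simulator. Windows with fewer than `min_events = 2` events are excluded
but counted, and windows intersecting a declared data-gap interval are
dropped entirely (real deployments lose days to instrument failure; a
gap is config, not inference). Partitioning conserves events:
analyzed + too-small + gap-masked counts always sum to the total.

## The S-CON test

For sorted offsets T₁…Tₙ the per-event connectivity is
cᵢ = #{j > i : T_j − Tᵢ ≤ Δ} (sort order breaks ties, so two events in
the same second are connected at lag 0 — the null's integer placements
produce exactly such ties, and observed data must be scored
identically). The statistic is c̄ = Σcᵢ/n, the number of sub-Δ pairs
over n. Connectivity never reaches past the window edge; the null has
the same truncation, so the comparison is unbiased.

The null simulates B placements of n integers iid uniform (with
replacement) on [1, W], sorts each, and scores c̄ the same way. The
critical value is the ⌈pB⌉-th order statistic of the B draws (the 950th
of 1000 at p = 0.95) — one fixed convention, chosen for exact
reproducibility. Rejection requires the observed c̄ to be **strictly**
larger, so an observed statistic of zero can never reject. Per-window
generators are seeded from `(master_seed, W, Δ, window_start)`, so
adding or removing windows from a sweep never perturbs other windows'
results, and a sweep is bit-reproducible under its master seed.

Numerics: the batch null scorer counts sub-Δ pairs by an n×n broadcast
for n ≤ 64 and by per-row binary search above (identical results; the
cutover is purely a memory trade-off). A property test checks the
vectorized counter against an O(n²) double loop on random instances.

### Operating characteristics

The statistic lives on the lattice {0, 1/n, 2/n, …}, and at the 95th
percentile the null CDF jumps by several percent per lattice step, so
the test is inherently conservative: with Poisson(15)-occupancy 30-min
windows its true type-I error is ≈ 0.035 rather than 0.05 (computed
semi-analytically by combining per-n null CDFs with the exact
distribution of the 950th order statistic, and confirmed by direct
simulation). No percentile or tie-handling convention moves a
lattice-valued statistic onto the nominal level; the price is a little
power, never anti-conservatism. Power against self-exciting clustering
rises steeply with the branching ratio and saturates near 1 when the
offspring delay scale (10 s) is well inside Δ.

## Synthetic generators

The generators define the study conditions the tests run under; they
are first-class, tested code.

* **Homogeneous Poisson** (`gen_homogeneous_poisson`): exponential
  inter-arrivals, floored to integer seconds. This is the null model.
* **Diel intensity** (`gen_diel_poisson`): thinning against the peak of
  a piecewise λ(t) in events/hour — constant low day rate (default
  0.2/h), a Gaussian dusk pulse (height 25/h, width 0.5 h, centred
  0.75 h after nightfall), and either an exponential night ramp peaking
  `peak_lead_hours` (default 1.5 h) before dawn with a linear decline
  to the day rate ("early_period") or a raised-cosine dome across the
  night ("late_period_dome"). Night defaults are clock hours 14.75 →
  7.2 (the early-winter fjord's sun times); no astronomy is computed.
  Defaults give a few hundred events per night, comparable to a busy
  field night. A χ² test at n ≈ 10⁵ confirms the empirical hourly
  histogram matches the configured λ.
* **Self-exciting clustering** (`gen_clustered`): the branching
  construction of a subcritical Hawkes-type process — immigrants from a
  constant-rate or diel baseline; each event spawns
  Poisson(branching_ratio) offspring at exponential delays (mean
  `kernel_decay_s`, default 10 s), recursively, truncated at the span
  end. Expected count is immigrants/(1 − η). The mutual-stimulation
  hypothesis names no specific process; this is the standard minimal
  choice and is confined to this module. Immigrant and offspring
  streams use separate child seeds, so η = 0 reproduces the baseline
  stream bit-for-bit.
* **Bubble bursts** (`gen_bubble_bursts`): each event expands to k ≥ 1
  bubbles in [t, t + span] with the first exactly at t and span ≤ 10 s,
  so 10-s pooling inverts the expansion exactly whenever inter-event
  gaps exceed the pooling interval (warned otherwise).
* **Abundance coupling** (`gen_abundance_series`): given 30-min counts
  N, log S_A = (log N − a)/b + e with AR(1) noise (φ = 0.4 by default).
  When `noise_sd` is unset it is solved in closed form from
  σ² = Var(log N)(1 − r²)/(r² b²) so the forward regression of log N on
  log S_A explains r² ≈ `target_r2` (default 0.12) of the count
  variance. Zero-count intervals get S_A = NaN (the log link is
  undefined there) and are counted.

What the generators do **not** emulate: detection efficiency and trace
misclassification, inhomogeneity of the rate *within* short windows,
day-to-day parameter drift, tidal/weather covariates, and any spatial
or beam geometry. Passing tests therefore demonstrate the statistical
machinery is correct under the assumed structure, not that field data
satisfy that structure.

## Abundance control

Counts on a half-open 30-min grid aligned to midnight (boundary events
belong to the later cell) are regressed on S_A, both natural-log
transformed (log base only rescales coefficients). Rows with a zero in
either variable are dropped before the transform — the count is logged,
and a `zero_policy="offset"` (+1) alternative is available. The fit is
iterated feasible GLS: estimate φ from the lag-1 autocorrelation of the
current residuals, Prais-Winsten-transform (the first row is kept with
weight √(1 − φ²)), refit by OLS, and iterate to |Δφ| < 1e-8 (max 100
iterations; non-convergence raises with diagnostics). With φ fixed at 0
the fit *is* OLS, exactly — a tested identity. The slope test is
F = t² on (1, n − 2) df. GLS has no canonical R², so "variance
explained" is declared as the squared Pearson correlation between
fitted and observed response. The fit agrees with R's
`nlme::gls(correlation = corAR1())` (maximum likelihood rather than
iterated FGLS) to well under a percent on the slope in the
cross-validation test.

One caveat the tests make visible: when the response series is itself
strongly autocorrelated (diel counts are), AR(1) whitening changes the
estimand relative to plain OLS under the errors-in-variables coupling
above, attenuating the slope; the variance-explained target is the
stable quantity, and slope recovery is asserted in the well-specified
regression setting.

## Problem sizes and test design

The acceptance-grade checks run at: 2,000 windows for the type-I error;
1,000 random instances for oracle equivalence; 300 windows per
branching ratio in {0, 0.2, 0.4, 0.6, 0.8} for power; a 16-day diel
clustered stream for the window-length sweep; and 100 seeds at 422
usable intervals for the abundance ensemble. Monotonicity assertions on
Monte-Carlo rejection rates allow adjacent estimates to tie within two
binomial standard errors, since saturated rates (≈100%) jitter by a few
windows. All tests are fixed-seed; hypothesis property tests are
derandomized.

## Known limitations

* The test assumes a constant rate *within* a window; at multi-hour
  lengths a smoothly varying diel rate alone (no interaction between
  fish) already produces rejections — that is the intended reading of
  the window-length sweep, not a defect, but it means single long-window
  rejections do not distinguish mutual stimulation from shared external
  drivers.
* The conservatism described above means the realized level is ≈ 0.035,
  not 0.05, for mid-teens occupancy.
* Pooling semantics (anchored vs gap) and window phase (clock-aligned
  vs data-aligned) are conventions, both exposed in config; results at
  the tens-of-seconds scale can shift slightly between them.
* The Kolmogorov–Smirnov style alternative for windows with ≥ 5 events
  is out of scope, as is everything upstream of timestamps (echogram
  processing, trace extraction, S_A noise filtering).
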