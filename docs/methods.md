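# Methods

This note documents the model, the numerical choices, the synthetic-data
generator, and the known limits of what the package's tests demonstrate.

## Signaling model

The analysis treats each region's BOLD response as proportional to its total
input signaling.  With regions indexed by r and directed connections s → r:

* `S_input[r] = Σ_s D[s→r] · S_output[s] + Σ_l D[l→r] · latent[l]`, where the
  D values are nonnegative input fractions that sum to 1 over each region's
  incoming connections (network edges plus latent inputs).
* Output signaling is the input converted by a signed per-connection factor
  B; collecting DB = D·B into `M_output`, output obeys the self-consistent
  linear fixed point `(I − M_output)·S_output = L_out·latents`, solved
  exactly (no iteration).  The solve requires a dissipative network:
  spectral radius of `M_output` below 1 (guarded at 0.97 during fitting;
  violations raise with the radius named).

Positive DB is excitatory (more input produces more output), negative DB
inhibitory.  DB is the reported connectivity statistic; D and B are not
separately identifiable from time series, so D is fixed by an equal split
over each region's incoming connections and B carries the signal.  This is
a first-order linear description of interacting regions: no hemodynamic
deconvolution, no time-varying or nonlinear coupling, and signaling within
a region is not modeled.

### Network fixtures

The bundled 14-region brain network encodes the directed connections named
in the study tables and text.  Two structural requirements drove minimal
anatomy-based completions, documented here as the package's own choices:
every region must receive at least one input (otherwise its modeled input is
identically zero), and every region must also send at least one connection —
with BOLD modeled as input signaling, an edge into a pure "sink" region has
exactly zero influence on any observable, so its B would be arbitrary.  The
completions are textbook pathways: Hypo→VTA, VTA→NAcc (with the NAcc→VTA
return), FOrb→AC, HG→IC, Hippo→Hypo and PAG→LC in the brain network;
Thal→Hypo, PAG→NRM, PAG→NGc, C6RD→DRt, NTS→LC, NGc→C6RD and DRt→C6RD in the
brainstem/cord network.  Users can supply any network as a JSON/YAML file;
validation reports all violations at once.

## Fitting and identifiability

The objective `Σ_regions Σ_time (observed − S_input)²` is minimized over the
per-connection B values and the latent time courses, alternating exact
linear least-squares latent steps with quasi-Newton (L-BFGS-B) gradient
steps in B.  The latent step is fused into every objective evaluation
(variable projection), so by the envelope theorem the analytic gradient of
the profiled objective in B equals the partial gradient at the optimal
latents; the per-iteration objective trajectory is recorded and is
non-increasing.  Five seeded random restarts guard against local minima.

Two identifiability devices are essential and are deliberate design
decisions:

1. **Basis-restricted latents.**  Completely free latent time courses admit
   an exact gauge: any invertible remixing of the latents can be absorbed
   into the connection weights without changing the fit.  Each latent is
   therefore estimated inside its own temporal basis, built from the
   paradigm: an event group (hemodynamically convolved impulses at the
   inform cue and at stimulation onset/offset), a block group (stimulation
   and anticipation boxcars; a sustained post-inform component in No-Pain
   runs), and a slow-arousal group (a saturating 1 − exp(−t/τ) early
   component plus low-order cosines).  The groups are assigned disjointly
   across latents (round-robin), which removes the remixing gauge; the fixed
   direct-input weighting of each latent's target region pins scale and
   sign.  The hemodynamic kernel is a gamma shape peaking near 5 s
   (configurable width); no undershoot term.
2. **Gauge-fixing ridge.**  Even with restricted latents, rank-L latent
   dynamics leave exactly flat directions wherever a region's afferents have
   linearly dependent output signals (unavoidable when a region has more
   parents than there are latents, or when single-parent chains make parent
   outputs collinear).  Model output is strictly invariant along these
   directions, so no amount of data distinguishes them.  A small ridge on B
   (default 1e-5 of the data sum of squares) selects the minimal-norm
   representative of each observationally equivalent class, making the
   reported solution unique, deterministic under seed, and comparable across
   datasets.  |B| is additionally box-bounded at 3 (a dissipative,
   physiologically plausible range).  Null-distribution generation defaults
   to a stronger stabilizing ridge (1e-3): pure-noise fits otherwise park
   weakly constrained factors at the bounds, inflating and off-centering the
   null; when strict group-vs-null comparability is needed the same
   configuration should be used on both sides (the type-1 calibration
   routine does exactly that).

The generator's ground-truth weights are expressed in the same minimal-norm
gauge ("canonicalized") via a simulate-then-refit fixed-point iteration, so
simulate→fit recovery is well defined.  On the small bundled networks the
noiseless closed loop recovers every DB within 1e-3; the 14-region brain
network sits much closer to its identifiability limit and recovers with a
median error below 2e-3 but worst-case near 1e-2 (optimizer precision in a
near-flat valley).  Under noise, weakly identified connections scatter
widely — that is a property of the model class, not of the optimizer, and it
is precisely what the null-simulation significance calibration absorbs.

Fit target: the run-averaged time course per participant and condition
(per-run fitting is a config flag).  Time courses are mean-centered
(percent-signal-change convention) before fitting.  Convergence: relative
objective change below 1e-6 (default), at most 500 iterations per restart.

## Preparation and clustering

Initial volumes with variable T1-weighting are replaced (not dropped, to
preserve time-since-run-start) by the first subsequent value: 3 volumes for
brain data (TR 2 s), 2 for brainstem/cord (TR 6.75 s).  Raw intensities are
converted to percent signal change about the within-run mean, which makes
extraction invariant to scanner gain.  Each region's voxels are partitioned
into k = 5 sub-regions by k-means on standardized voxel time courses (10
restarts, seed 0); "approximately equal volume" is monitored by a balance
warning (max/min size > 3) rather than enforced, since k-means cannot
guarantee it.  Whether the original procedure clustered on time courses,
coordinates, or both is not stated; time courses are the documented default
because the downstream use is time-course fitting.

## Sub-region search

One sub-region per region enters the network fit; the search for the
best-fitting combination is greedy coordinate descent on the categorical
grid: from a seeded random combination, regions are swept in canonical
order, each trying all k choices with the others fixed (ties keep the
incumbent), until a full sweep yields no improvement; 10 random starts by
default, best kept, full re-fit per candidate with caching.  The winning
combination is frozen (hash-stamped JSON) and downstream analyses refuse a
differing selection unless overridden; brain and brainstem/cord analyses
share the frozen choices for common regions.

## Significance

Per-connection null distributions come from applying the identical fit to
datasets of i.i.d. standard-normal time courses of matching dimensions
(10,000 repetitions at study scale; 1,000 as the desk default, configurable
down for tests).  Group DB values are compared to the null per connection
with a Welch two-sample T (two-tailed, Welch–Satterthwaite df), and
family-wise error is Bonferroni-controlled: per-connection alpha =
alpha / n_connections (0.05/32 = 0.0015625; 0.05/52 ≈ 0.00096).  The
empirical family-wise error of the complete chain under the null is
verified to lie in [0.01, 0.10] at nominal 0.05 with 200 simulated families
(binomial tolerance).  Statistical power is connection-dependent: strongly
identified connections detect a DB of 0.5 with n = 15 essentially always,
while weakly identified connections have honestly wide nulls and little
power.

## Time-course features

* **Initial rise**: mean over a plateau window (default 40–60 s, ending
  before the 60-s inform cue) minus the value at the first retained volume.
  The companion *starting point* is the first retained value of the
  mean-centered course, the convention in which a genuine rise appears as a
  negative start (roughly 0 to −1 % signal change); both are reported to
  avoid sign ambiguity.  The exact window bounds are a package default, all
  configurable.
* **Event responses**: maximum over the 15 s following stimulation onset or
  offset minus the mean over the preceding 10 s (standard hemodynamic
  latency); undefined and flagged for No-Pain runs.
* **Baseline alignment** for group overlays shifts one course vertically to
  match starting values; differences between aligned courses are invariant
  to any common offset.

## Group statistics

Two-way ANCOVA (`value ~ group * covariate`) with Type II sums of squares
(robust to unbalanced groups; Type I available), F-tests for the group,
covariate and interaction effects, per-group R² as the squared within-group
Pearson correlation.  A zero interaction sum of squares reports p = 1.
Correlations are Pearson; two-group contrasts (e.g. medication status) are
Welch tests.  Uncorrected p-values are reported alongside the Bonferroni
threshold rather than silently re-thresholded, mirroring the dual-threshold
reporting convention of the tables this chain emulates.

## Pupillometry

Traces are 500-Hz pixel-area series with white/black reference screens at
both ends of each trial, used only for QC (expected ordering
black > task > white).  Blink dropouts (area at or below half the trace
median) are linearly interpolated when ≤ 0.5 s, else marked missing; trials
over 50% missing are unusable.  Group summaries are per-trial task-period
means averaged within group, with the percent difference between groups;
time-locked averages are computed on a common paradigm clock by linear
interpolation.  No pixel-to-millimeter calibration is attempted.

## Synthetic-data generator

The generator's defaults are the emulated study conditions: 4.5-minute runs
(135 brain volumes at TR 2 s; 40 brainstem/cord volumes at TR 6.75 s), the
inform cue at 1 minute, a 30-s stimulation block (10 contacts of 1.5 s,
onsets every 3 s) from 2 minutes in Pain runs, groups of 20 FM-like and 17
HC-like participants with 5 runs per condition, i.i.d. Gaussian noise of
0.2% signal change, and ground-truth DB values taken from the reported
group-average connectivity magnitudes (canonicalized into the fit's gauge;
mid-range 0.3 for the anatomy-completion edges, 0.5 for latent inputs).

The initial rise is modeled as an additive exogenous component
`a·(1 − exp(−t/τ))` common to all regions, with τ = 40/3 s (~95% saturation
by 40 s), HC-like amplitude 0.4% and an FM-like multiplier of 2 — matching
its interpretation as a widespread, possibly hormonally mediated arousal
signal rather than network-propagated signaling.  The group multiplier also
scales the saturating component of the latent drive.  Because the rise is
exogenous, the cross-module forward-equation oracle applies to the network
component, which the simulator exposes separately; connectivity-recovery
experiments disable the rise (it is a separate phenomenon studied by the
features module).  Pupil traces use task-period mean areas of 1540 (HC-like)
and 1920 (FM-like) pixel units — a ~25% difference — with similar
stimulation peaks in both groups, start-of-run dilation, and optional blink
dropouts.

What passing tests do *not* show about real data: the generator draws its
latents from the same temporal basis class the fitter uses, its noise is
white (physiological noise is assumed removed upstream), voxels within a
sub-region differ only by noise, and there is no motion, drift, or
registration error.  Recovery results are therefore internal consistency
checks of the chain, not evidence about reproducing any particular empirical
connectivity table.

## Determinism and provenance

Every stochastic step takes an explicit seed and is bit-reproducible;
pipeline outputs carry a config hash, the seed, and the defaults in effect.
Problem sizes used by the test suite and the acceptance script (e.g. 20
recovery datasets, 200 null families, 500 ANCOVA simulations, 1-participant
fits on 5-run averages) are desk-scale choices that keep the full chain
runnable in minutes on one core; all are configurable upward.
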