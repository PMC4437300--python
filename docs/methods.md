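# Methods

This note records the models the package implements, the defaults and the
reasoning behind them, what the synthetic-data layer does and does not
emulate, and the numerical choices that affect results.

## Spike-train features

Spikes are upward crossings of a voltage threshold (default 0 mV) with a
1 ms refractory period; times are reported at the crossing sample relative
to step onset. The recording hardware's detection criterion is not part of
the feature definitions, so the threshold is a parameter; 0 mV cleanly
separates action potentials from subthreshold dynamics at the usual −65 mV
baseline.

Feature conventions:

* **Accommodating ratio** — mean of the last five ISIs over the mean of
  the first five, per sweep; the reported value is the *maximum* over
  qualifying sweeps (injected current < 400 pA and more than 10 spikes in
  the step). "More than 10 spikes per second" is read as more than 10
  spikes within the 1 s step of that sweep.
* **Spike delay and rheobase** — rheobase is the smallest depolarizing
  amplitude eliciting at least one spike; the delay is the first-spike
  latency on that sweep only. Step duration is taken from sweep metadata,
  so delays longer than 1 s are representable with 2 s steps.
* **Maximal CV of ISI ratios** — ratios r_i = ISI_{i+1}/ISI_i per sweep;
  CV is the sample (n−1) standard deviation over the mean, maximized over
  sweeps with at least two ratios.
* **Input resistance** — steady-state voltage change over the injected
  −25 or −50 pA current. "Steady state" is the mean of the final 200 ms of
  the step (exclusive of the off sample); with a ~20 ms membrane time
  constant the trace is fully settled there.

A feature that cannot be computed is reported as missing with a reason and
is never imputed; cells with missing retained features are excluded from
clustering and listed in the classification report.

## Cell classification

The taxonomy pipeline is uniformity filter → min-max normalization → Ward
agglomeration → analyst-chosen cut.

* **Uniformity filter.** Each feature is rescaled to its observed
  [min, max] range and tested against the standard uniform law with the
  exact one-sample Kolmogorov–Smirnov test at α = 0.05. Estimating the
  range from the data anchors the empirical CDF at both ends, making the
  test conservative; this circularity is accepted because the filter's
  purpose is only to discard structure-free features. Constant features
  are dropped as degenerate. If everything is dropped the pipeline stops
  with an explicit error rather than clustering on nothing.
* **Ward linkage.** Implemented directly on cluster centroids and sizes:
  the merge cost is the increase in total within-cluster error sum of
  squares, |A||B|/(|A|+|B|)·‖c_A − c_B‖². Merge heights are these ESS
  increases, *not* their square roots — this makes dendrograms directly
  comparable to an exhaustive oracle that recomputes ESS from cluster
  members (the test suite does exactly that for n ≤ 7, and also checks
  that heights equal scipy's Ward heights squared over two). Equal-cost
  merges are resolved toward the lexicographically smallest (oldest) pair
  of cluster indices, so results are platform-independent.
* **Cut.** k is a required analyst input (k = 4 for the four-type
  basolateral cohort, k = 2 for the central-amygdala cohorts); clusters
  are numbered by decreasing size. No automatic k selection is offered.

## Channel biophysics

* **Patch geometry.** Nucleated patches are modelled as prolate spheroids
  of revolution about the measured major axis: with semi-axes a = major/2,
  b = minor/2 and eccentricity e = √(1 − b²/a²),
  S = 2πb² + 2πab·arcsin(e)/e, handled analytically in the sphere limit.
  The general-ellipsoid Knud Thomsen approximation (p = 1.6075) is
  available as a config switch; for typical patch aspect ratios the two
  differ by well under 2 %. Capacitance uses 1 µF/cm² of specific membrane
  capacitance, i.e. 0.01 pF/µm².
* **Current density.** The peak is the signed extremum inside the agonist
  pulse relative to the pre-pulse baseline; the default direction is
  inward (minimum), matching Na⁺ influx at negative holding potentials,
  with an outward option. Density is |peak|/capacitance.
* **Fits.** All three nonlinear models (desensitization, Hill, run-down)
  use scipy's bounded trust-region least squares with xtol = ftol = gtol
  = 1e-10. Initialization: decay time from the first 1/e crossing of the
  detrended data; Hill pH₅₀ from the pH whose response is nearest
  half-maximum, Hill coefficient from 1. The Hill amplitude A is fitted
  rather than assuming the most acidic test response is maximal. The Hill
  model is parameterized in pH₅₀ = −log₁₀(EC₅₀), which conditions the
  optimization better than molar EC₅₀ and is prediction-equivalent.
  Non-decaying desensitization traces (decay time at the bound) and
  constant or increasing run-down series are flagged non-convergent
  instead of raising.
* **Reversal potential.** A second-order polynomial is least-squares
  fitted to the I–V points; the reversal is the real root inside the data
  span, nearest the observed sign change when the parabola has two real
  roots. No in-span root is an error that reports both roots.
* **Nernst reference.** E = (RT/F)·ln([Na]ₒ/[Na]ᵢ) in mV. Temperature
  defaults to 298 K (room-temperature recording); with the standard
  solutions (135 mM out, 14 mM in counting both Na⁺ sources of the
  internal) this gives ≈58 mV, and ≈60.5 mV at 310 K. Published
  near-61 mV references are consistent with the warmer value; the
  temperature is therefore an explicit parameter rather than a constant.
* **Tachyphylaxis.** The plateau is left free (fitted as the exponential
  offset), not constrained to [0, 1]; constraining it is a one-line bound
  change but was not adopted since noiseless fits recover planted plateaus
  exactly anyway.

## LTP quantification

Sessions fail QC when the series resistance deviates from its initial
value by strictly more than 20 % (the discard rule is written as ">20 %",
so exactly 20 % passes), or when the linear trend of baseline amplitudes
exceeds 5 % of the baseline mean per minute. A missing series-resistance
log makes QC indeterminate, which does not pass. The baseline window
defaults to the 5 min immediately preceding HFS; the stimulus coinciding
with the HFS time is counted as a baseline response. The magnitude is
100 × the mean baseline-normalized amplitude at post-HFS times in
[25, 30] min, endpoints inclusive.

ΔLTP% compares potentiation above baseline: with P = magnitude − 100,
ΔLTP = 100·(P_wt − P_ko)/P_wt. This convention is chosen because complete
abolition of LTP (knockout at 100 %) must map to a 100 % reduction, which
a raw-magnitude ratio does not satisfy; the ratio convention is available
by flag. ΔLTP is undefined (reported as missing with a reason) when the
wild type shows no potentiation. The density–ΔLTP correlation is computed
on whatever points the caller supplies (per cell or per synapse-level
group mean) by Pearson product-moment r with the regression F-test.

## Freezing scores

An immobility bout qualifies only if its *full* duration exceeds 2 s;
qualification is decided before intersecting the bout with an epoch, so a
3 s bout straddling an epoch edge contributes its in-epoch part to both
epochs. Abutting or overlapping bouts are merged before the duration test.
This rule also makes epoch-splitting exactly additive, which the property
suite exploits. For day-1 conditioning the scored windows are habituation
and the 1 min inter-trial observation periods (freezing "between trials");
tone epochs are kept in the protocol but excluded from the summary. Cue
trials on day 2 are scored over the 20 s tone plus the 1 min observation.

## Statistics

Exact p-values come from complete enumeration: all C(n+m, n) group
assignments for the rank-sum test (used when n+m ≤ 16), all 2ⁿ sign
patterns for the signed-rank test (n ≤ 20), all multinomial rank
partitions for Kruskal–Wallis (total n ≤ 10). Exact p-values are exact
multiples of 1/#outcomes; two-sided p doubles the smaller tail, capped at
1. Enumeration is used only on tie-free data; otherwise midrank statistics
with tie-corrected, continuity-corrected normal (or χ²) approximations are
used, and the result carries an `exact=False` flag. Zero differences in
the signed-rank test are dropped (Wilcoxon convention, not Pratt). At the
enumeration cutoffs the approximation tracks the exact null to within
about 0.02 absolute (measured over tie-free draws at n+m = 12–16), tight
enough that the boundary choice does not change any decision at
conventional α. The regression F-statistic is (n−2)·r²/(1−r²) on (1, n−2)
degrees of freedom; perfectly collinear data report F = ∞ and a
machine-floor p-value explicitly marked as a bound.

## Synthetic data: what it emulates, and what it does not

All generators draw from `numpy` Generator streams split from a single
seed by a call counter (`SeedSequence((seed, k))` for the k-th call), so a
fresh config with the same seed replays byte-identical outputs on any
platform.

* **Step families.** Spikes are stereotyped 2 ms triangular
  depolarizations to +30 mV whose 0 mV upstroke crossing lands exactly on
  the planted spike time; only spike times matter downstream, so waveform
  realism (AP width, AHP, threshold dynamics) is deliberately absent.
  Accommodating trains use geometric ISIs, so the planted late/early ISI
  ratio is recovered in closed form; stuttering and bursting phenotypes
  use burst/gap templates with configurable jitter, since the source
  phenotype descriptions are qualitative and fix no generative model.
  Passive responses charge exponentially (τ_m = 20 ms) toward R·I, so the
  hyperpolarizing steps encode the planted input resistance exactly in
  their final 200 ms.
* **Cohorts.** Per-cell feature values are drawn Normal(type mean, type
  SD) and truncated to valid ranges; ground-truth labels are retained.
  The two-population central-amygdala cohort takes its means from the
  published group values and its SDs as SEM·√n. Default per-type counts
  of the 72-cell basolateral cohort (26/20/12/14) are a package choice;
  only the total and the four types are published. All dispersions are
  user-overridable.
* **Currents, dose–response, I–V, run-down.** Exact closed forms of the
  fitted models plus additive Gaussian noise, so zero-noise round trips
  through the fit operations are exact to optimizer tolerance (1e-6
  relative is asserted throughout). The I–V generator places the planted
  reversal as the unique in-span root and rejects curvatures that would
  put the parabola's second root inside the span.
* **LTP series.** A step function (baseline, then plateau) with
  multiplicative Gaussian amplitude noise of configurable CV — a Gaussian
  approximation to what is more plausibly log-normal — and a linearly
  drifting series-resistance log for exercising QC. No EPSP kinetics, no
  induction dynamics, no slow post-HFS decay.
* **Freezing.** Alternating exponential freeze/move renewal process per
  epoch, with the gap scale set so the expected frozen fraction matches
  the requested one; bouts are clipped to epochs. Because sub-2 s bouts
  are generated but do not score, realized percentages sit a few points
  below the planted fractions — a deliberate property used by the tests.

Passing tests therefore demonstrate that the *analysis definitions* are
implemented correctly and are mutually consistent with the generators'
closed forms; they do not demonstrate robustness to real-data features the
generators omit (electrode artifacts, drift, bursty noise, non-Gaussian
dispersion, correlated features).

## Problem sizes and known limitations

The test suite and the headline-number script run at desk scale by
design: 100-seed sweeps for the classification and behavior expectation
checks, 1000-run calibrations for test size, 10 kHz traces of 1–2 s. The
Ward implementation recomputes pairwise merge costs per step (O(n³) with
vectorized inner loops), which is ample for cohorts of ≤ a few hundred
cells but not for thousands.

Under the SEM-reconstructed dispersions, the two central-amygdala delay
populations overlap substantially (the early-spiking SD is ≈438 ms);
two-cluster label agreement with ground truth then averages ≈94 % over
seeds — and even the Bayes-optimal threshold with the planted densities
known would reach only ≈96 % — so the later cluster's mean delay is
biased a few tens of ms low relative to the planted 1769 ms. This is a
property of the Gaussian emulation, not of the clustering code: the
populations it mimics are described as non-overlapping in vivo.
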