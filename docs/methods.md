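# Methods

This note documents the model implemented by `mupoolsim`, the conventions
and numerical choices behind it, what the synthetic firing generator does
and does not emulate, and the known limits of quantitative agreement with
the reference study whose design it replicates.

## Pool parameterisation

The packaged pool (`mupoolsim/data/motor_units.csv`) lists 57 motor units
of the rat medial gastrocnemius — 8 S, 23 FR, 26 FF — with, per unit:
contraction time `Tc` (ms), half-relaxation time `Thr` (ms), twitch
duration `Ttw` (ms), peak twitch force `Fmax` (mN), maximal fused-tetanus
force `Fmftf` (mN), and minimum / mean / maximum rhythmic firing rates
(Hz). Units are indexed 1–57 in recruitment order: type blocks S, FR, FF,
each sorted by increasing `Fmax`. The loader validates positivity,
`minfr < meanfr < maxfr`, `Fmax < Fmftf`, `Ttw >= Tc`, the 8/23/26
composition and the within-type force ordering.

## Excitation, recruitment and rate coding

The drive is expressed in percent of maximal excitation. The generic
signal builder produces a logarithmic rise
`e(t) = level·log(1 + shape·t/rise)/log(1 + shape)` (default shape 9,
rise 1000 ms), a constant plateau, and a time-mirrored fall. Only the
steady state is analysed, so the ramp curvature affects no reported
statistic; the `shape` parameter is exposed for completeness.

Scenario runs use a plateau of 3000 ms (1000–4000 ms of the 4000-ms
record) so that the analysed 2000–4000 ms window sees maximal drive
throughout; the mirrored fall lies beyond the simulated record. A
rise/plateau/fall of 1000/2000/1000 ms would place the falling limb inside
the analysis window, slowing every unit's firing over its last second and
biasing all steady-state statistics; the plateau extension is therefore a
deliberate design choice, anchored to the requirement that the analysis
window be stationary.

Recruitment thresholds are evenly spaced over (0, 90%] along the pool
order, so the last unit is recruited at 90% drive — about 230 ms before
the plateau under the default ramp. The instantaneous rate is 0 below
threshold, `minfr` at threshold, and linear in drive up to `meanfr` at
100% — pinning every unit's steady-state rate at its mean rhythmic rate.
`maxfr` is carried in the data model but unused by this rate law.

## Spike-train generation

Each unit is an independent renewal process: successive interpulse
intervals (IPIs) are uniform on `[1000/rate − j, 1000/rate + j]` with
jitter `j = 4` ms. Design details:

* the first pulse sits at the first supra-threshold sample plus a uniform
  phase within one IPI, preventing spurious cross-unit alignment at
  recruitment;
* times accumulate in continuous ms and are rounded to the 1-ms grid at
  the end (the analysis stores binary series at 1 kHz); rounding the
  accumulated times widens the observable IPI range by at most 1 ms on
  each side of the continuous bounds;
* a rounding collision pushes the later pulse +1 ms, preserving the pulse
  count;
* randomness comes from per-unit substreams keyed `(seed, unit index)`,
  so a firing set is bit-reproducible from its seed and adding or
  removing units does not perturb the others.

## Synchronization transform

A pair transform moves target pulses onto reference pulses when their
offset is within ±Δt ms. Conventions, chosen for determinism:

* each target pulse is assigned to its *nearest* reference pulse; ties at
  equal distance resolve to the earlier reference pulse;
* at most one target pulse may occupy a reference pulse — the nearest
  claimant wins, equal-distance claims go to the earlier target, losers
  stay in place (this also makes post-shift duplicate times impossible);
* a move may not carry a pulse across the 2000 or 4000 ms boundary in
  either direction, so pulse counts inside and outside the analysis
  window are conserved exactly;
* pulses are only moved — never created, deleted or merged.

The four pair-selection methods are fixed tables over the pool indices.
Methods 1 and 2 are chained: each pair's reference is the target of the
previous pair *after* its modification, implemented by processing pairs
in order against the current state. Methods 3 and 4 never modify a
reference, so processing order is immaterial there. Cross-type pairs are
never synchronized.

## Synchronization indices

* `corMU` is computed on 2000-sample binary series (2000–4000 ms). An
  all-zero series yields 0 by convention (it cannot occur for the
  packaged pool at full drive, but the metric must be total).
* Cross intervals use integer-ms arithmetic, so the central histogram bin
  (±0.5 ms) reduces to exact equality of grid times. Equidistant partner
  pulses resolve to the earlier partner — a tie never lands in the
  central bin, so the tie rule cannot bias CISI.
* The cross-interval histogram spans bin centres −15..+15 ms; intervals
  outside contribute to no bin, so bin values sum to 1 exactly when all
  intervals fall within the support.
* CISI for a unit averages the central-bin probability over all 56
  partners, including cross-type partners; type-level CISI aggregates
  average the per-unit values over the units of that type. corMU
  aggregates average over unordered pairs — within-type pairs for the
  type columns, all 1596 pairs for the "all" column. The all-pairs
  convention is what makes the "all" column sit below the within-type
  columns after strong within-type synchronization (dilution by
  unsynchronized cross-type pairs).
* Reported spreads are sample standard deviations (ddof = 1).

For independent renewal trains the expected central-bin probability is
about 1 ms divided by the partner's mean IPI; with the packaged rates
(pool mean 50.8 Hz) this predicts a non-synchronized CISI near 5%, which
the simulations reproduce.

## Twitch surrogate and force

The reference study computed forces with a six-parameter twitch function
and regression-driven variable twitch parameters inside each tetanus;
neither the function nor the regressions are in the public record, so the
force model here is a declared surrogate calibrated to the four published
anchors per unit (`Tc`, `Fmax`, `Thr`, `Ttw`). Two analytic shapes are
provided:

* **lognormal** (default): `f(t) = Fmax·exp(−ln²(t/Tc)/(2s²))` with
  `s = ln(1 + Thr/Tc)/√(2 ln 2)`. Peak exactly `Fmax` at `Tc`, half-decay
  exactly `Thr` after the peak, smooth sigmoidal onset (all derivatives
  vanish at t = 0).
* **gamma**: `f(t) = Fmax·(t/Tc)^m·exp(m(1 − t/Tc))`, `m` solved in
  closed form from `Thr` (`m = ln 2/(u − 1 − ln u)`, `u = 1 + Thr/Tc`,
  accepted on [0.05, 8]). For this pool every fitted `m` is below 1, so
  the onset has infinite slope; this classic form is retained for
  comparison, but its sharp onset leaks high-frequency power into force
  spectra, which is why it is not the default.

Both are truncated at `Ttw` (residual step ≤ f(Ttw)). A train produces
the linear superposition of twitches; per-unit saturation is
`F = Fmftf·tanh(L/Fmftf)` — smooth, monotone, identity-like for small
forces (twitch/tetanus ratios in this pool are ≤ 0.3, so isolated
twitches compress < 3%) and capped at `Fmftf`. Linear mode (`saturate
off`) is retained. Type and muscle traces are exact sample-wise sums.

**Known structural limitation.** With a fixed twitch shape anchored at
peak `Fmax` and linear summation, units with large `Fmftf/Fmax` (up to
8.5 here) cannot approach `Fmftf` at physiological rates — the real
system bridges the twitch and tetanus scales through activity-dependent
potentiation, which the surrogate deliberately omits. Consequences:
absolute force statistics are not quantitatively comparable to the
reference study (its own surrogate-independence holds only for the
synchronization indices, which depend on firing alone — non-synchronized
CISI shifts by far less than a point between twitch shapes); and
steady-state operating points sit below fusion, so per-pulse force ripple
at the units' firing rates (30–70 Hz) survives into the spectra. The
latter is why the mean spectral frequency, which falls with
synchronization in the reference study, instead *rises* here under
Method 4: moving all units of a type onto one fast reference creates a
spectral line at the reference rate that a fixed twitch kernel passes.
The directional force properties that do not hinge on ripple suppression
— mean-force invariance, growth of rmsF/rangeF/maxF with the window, the
VAF decline and the type ordering of the non-synchronized mean spectral
frequency — are reproduced and tested.

## Spectral conventions

The PSD is computed on the 2000-sample steady-state window after mean
subtraction, with a rectangular window, zero-padded to 2048 FFT points
(Δf = 0.49 Hz), one-sided, DC bin excluded. Mean subtraction is required
for the mean spectral frequency to describe the oscillatory component: a
force with a ~4000 mN static level would otherwise bury the oscillation
under leakage from the DC line. The mean frequency is the PSD-weighted
average over bins 1..1024; an all-zero spectrum yields an undefined
marker rather than a number.

Trend correlations (used for the synchronization-vs-force-parameter
table) are Pearson coefficients over four points per method: the
non-synchronized baseline followed by the three window levels, matching
curves of CISI against each force parameter.

## Replication scale and determinism

The experiment grid is 13 scenarios (baseline + 4 methods × 3 windows).
Aggregates use 10 seeds; the synchronized scenarios of a seed reuse that
seed's baseline firing set, since synchronization is a deterministic
transform of it. The full 10-seed grid completes in well under a minute
on one CPU. Every artifact is bit-reproducible from (configuration,
seed); VAF is always computed against the same-seed baseline, hence
exactly 100% for the baseline itself.

Monotonicity checks on seed-averaged force statistics allow a slack of
0.5% of the baseline value: the quantities compared are stochastic means,
and strict inequalities on them would fail on sampling noise an order of
magnitude smaller than the effects under test.

## What the generator does and does not emulate

The firing generator reproduces the study conditions: stationary renewal
firing at the tabulated mean rates with uniform ±4 ms IPI jitter, size-
principle recruitment, and deterministic pulse-moving synchronization.
It does not model motoneuron membrane dynamics, synaptic noise or common
drive fluctuations, rate adaptation, doublets, derecruitment hysteresis,
or any dependence between units beyond the imposed pulse moves. Passing
tests therefore certify the metrics and transforms on clean renewal
trains, not robustness to the richer variability of recorded discharge
patterns.

A further caveat concerns quantitative agreement with the reference
study's index values: its reported steady-state pulse counts (about
100/140/111 pulses per 2 s for S/FR/FF units) exceed what its own stated
IPI rule implies from the tabulated mean rates (about 75/106/106), and
its non-synchronized index values (corMU 6.1%, CISI 6.2%) are consistent
with the higher counts, not the stated rule. This package implements the
stated rule, and its baseline indices (corMU ≈ 5.0%, CISI ≈ 5.1%) agree
with the analytic expectation under that rule. The same rate gap lowers
the synchronized within-type correlations (a ±6 ms window captures a
smaller fraction of each reference IPI at the lower rates), so
quantitative index agreement is close for the S-type and Method-3
scenarios but systematically below the reference values for the
fast-type Method-1/2/4 scenarios. The directional structure — ordering
across methods, growth with the window, five-fold CISI gain under
Method 4 — is reproduced throughout.

## Degenerate inputs and error behaviour

Empty trains binarize to all-zero series; an empty partner in the
analysis window yields an empty cross-interval set, which CISI counts as
zero coincidence; histograms and central-bin probabilities on empty sets
raise. IPI histograms need at least two window pulses and return a
missing-value marker otherwise. Zero-variance references make VAF
undefined (`None`), as does an all-zero spectrum for the mean frequency.
Schedules referencing absent units, self-pairs, windows below 1 ms,
non-positive signal durations and malformed pool tables all raise with
the offending unit or column named.
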