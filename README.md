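# mupoolsim

Motor-unit pool simulation of short-term synchronization and force
variability in the rat medial gastrocnemius muscle.

`mupoolsim` is for neurophysiologists and modellers who want to study how
coincident firing of motor units (MUs) shapes isometric muscle force — the
mechanistic substrate of physiological tremor. It simulates a pool of 57
MUs (8 slow S, 23 fast fatigue-resistant FR and 26 fast fatigable FF
units, parameterised from electrophysiological recordings), imposes
controlled levels of short-term synchrony on their spike trains, and
quantifies the consequences for the force of each MU type and of the
whole muscle.

## Model

* **Drive and recruitment.** A common excitation signal (percent of
  maximal drive) rises along a smooth logarithmic ramp, holds a plateau at
  100% covering the analysed steady state (2000–4000 ms), and falls
  symmetrically. Units are recruited by the size principle — within each
  type in order of increasing peak twitch force — at evenly spaced
  thresholds; the instantaneous firing rate grows linearly from `minfr` at
  threshold to `meanfr` at full drive.
* **Stochastic firing.** Each unit fires as a renewal process: interpulse
  intervals are drawn uniformly within ±4 ms of `1000/meanfr`, accumulated
  in continuous time and rounded to the 1-ms grid (fs = 1 kHz).
* **Imposed synchronization.** For a pair (reference MU1, target MU2),
  every MU2 pulse within ±Δt ms of its nearest MU1 pulse is moved onto
  that pulse (one target pulse per reference pulse; moves never cross the
  steady-state boundary, so pulse counts are conserved). Windows
  Δt = 2, 4, 6 ms emulate weak, modest and strong synchrony. Four
  pair-selection methods operate strictly within MU types:
  chained recruitment-order neighbours (Method 1), chained firing-rate
  neighbours (Method 2), unique groups of four (Method 3), and all units
  of a type onto its first-recruited unit (Method 4).
* **Synchronization indices.**
  `corMU = 100·Σ a_i b_i / √(Σ a_i² · Σ b_i²)` on 1-ms binary firing
  series — the coincidence count normalised by the geometric mean of the
  pulse counts; and `CISI`, the cross-interval synchronization index: the
  probability, averaged over all 56 partners, that a reference pulse
  coincides (|CI| < 0.5 ms) with the partner's nearest pulse.
* **Force.** Each unit's twitch is an analytic waveform anchored to its
  measured contraction time `Tc` (peak force exactly `Fmax`),
  half-relaxation time `Thr` and twitch duration `Ttw`; pulse trains
  superpose twitches linearly and saturate smoothly at the maximal
  fused-tetanus force via `F = Fmftf·tanh(L/Fmftf)`. Steady-state traces
  are summarised by `meanF`, `maxF`, `rangeF`, `rmsF`, the variance
  accounted for against the non-synchronized force
  (`VAF = 100·(1 − var(FS−FNS)/var(FNS))`), and the PSD-weighted mean
  spectral frequency (FFT over 2048 points, 0.49 Hz resolution).

## Worked example

Strong synchronization of every unit onto the first-recruited unit of its
type (Method 4, ±6 ms window):

```sh
$ mupool simulate --method 4 --window 6 --seed 1
scenario M4_dt6, seed 1

synchronization indices (mean +/- SD):
     corMU_mean  corMU_sd  CISI_mean  CISI_sd
S         23.37     11.21       7.51     1.79
FR        54.69     11.37      25.91     1.50
FF        56.15     10.16      29.21     1.55
all       24.43     24.58      24.83     7.39

force parameters over the steady state:
          meanF    rmsF  rangeF     maxF     VAF  meanfreq
S        137.44    3.22   20.95   148.96   59.32     30.95
FR      1015.99   36.62  206.43  1105.47 -140.42     39.91
FF      2481.19   98.75  597.09  2728.54 -142.46     44.74
muscle  3634.61  103.29  602.56  3907.34 -141.59     45.98

pulses shifted: 6779
```

Reading the output: within-type pairwise `corMU` jumps from ~5% (the
non-synchronized baseline) to 55–56% for the fast types, and `CISI`
rises about five-fold. The mean muscle force (`meanF`, mN) is essentially
unchanged from the baseline, but its fluctuation (`rmsF`) grows by ~75%,
the min–max excursion (`rangeF`) by ~65%, and `VAF` turns strongly
negative — the synchronized force departs from the baseline trace by more
than twice the baseline variance. The weak S units synchronize least
because their long interpulse intervals leave most pulses outside the
±6 ms window.

The full experiment grid (non-synchronized baseline plus 4 methods ×
3 windows, aggregated over seeds):

```sh
mupool replicate --seeds 10 --out results/grid
```

writes per-scenario firing and force tables plus seed-averaged summary
tables of both indices, the six force parameters, and the correlation of
each force parameter's window trend with the CISI trend. Synchronization
indices can also be computed for externally supplied firing tables
(CSV rows of `mu_index, pulse_time_ms`) with `mupool metrics`.

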