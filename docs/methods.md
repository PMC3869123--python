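# Methods

`synapse-modes` quantifies the two modes of neuromuscular transmission —
synchronous (phase-locked to the presynaptic action potential) and
asynchronous (delayed, persistent) — and the propagating intracellular
calcium source that drives the asynchronous mode, from paired voltage-clamp
recordings and two-channel ROI fluorescence. Because no raw recordings of
the zebrafish CaP–muscle preparation are publicly deposited, the package
ships a seeded generator that emulates that preparation; every analysis
routine is validated by parameter recovery against it.

## The generative model

### Stimulus and morphology

A paired experiment consists of a 100 Hz, 20 s stimulus train (spikes
exactly 10 ms apart) delivered to a motor neuron whose morphology is
generated as an SWC tree: soma, an 80 µm (arc length) axon to a *reference
node* — the distance-zero landmark at the ventral notochord edge — a short
segment to the main branch point, and a main branch carrying 10–15 bouton
ROIs at arc distances spanning ~5–150 µm from the reference. Segment
lengths are constructed exactly, so bouton arc distances are known to
machine precision; analysis distances are always recomputed from the SWC
polyline (piecewise-linear arc length, not chord distance), mirroring
filament-tracer measurements. ROI-to-node attachment is by explicit id in a
sidecar CSV; nearest-node snapping is deliberately not attempted.

### Two-component bouton calcium

Free calcium at a bouton is modelled above a 0.1 µM rest as the sum of

* a **fast component** (amplitude 0.45 µM × `pq_scale`) rising as a
  saturating exponential from stimulus onset — the P/Q-type channel calcium
  that drives synchronous release. `pq_scale` is 1 for control, 0 for
  ω-conotoxin GVIA block, 0.3 for the hypomorphic P/Q mutant;
* a **bulk component** (amplitude 0.45 µM) that arrives as a constant-speed
  kinematic front: axon and branch-point ROIs at `wave_onset` after
  stimulus start, boutons additionally delayed by `d / wave_speed` with `d`
  the arc distance from the reference node. Under TTX the front instead
  originates at the soma and travels at 3 µm/s.

The front is an arrival-time model, not a reaction–diffusion PDE: the
measurable content of the data is a quasi-linear onset-vs-distance
relation, and the model implements exactly that measurable structure. Each
ROI also receives a gamma-distributed (shape 3) local response delay (mean
0.1 s at 0.5 mM EGTA) representing bouton-to-bouton heterogeneity in front
invasion and calcium handling; without it, simulated onsets are
unrealistically uniform (SD ~0.01 s vs ~0.16 s in real boutons) and
regression p-values on control data misbehave.

EGTA, the slow calcium chelator, acts entirely through the calibration
table: raising it from 0.5 to 5 mM slows the front (74 → 35 µm/s), delays
its initiation (0.53 → 3.60 s), and slows local accumulation (`tau_fast`
0.6 → 1.4 s, local lag 0.05 → 0.45 s). The 25 mM entry is qualitative — it
reproduces the near-total block with strongly delayed onset seen in the one
surviving recording at that concentration, and should not be used for
quantitative recovery.

After stimulus termination both components decay with `tau_off` = 8 s,
**except** in the killswitch regime (stimulus truncated early), where the
already-launched front keeps propagating, and under TTX, where the
sustained depolarisation maintains the source. This is what makes distal
bouton calcium — and release — peak after the stimulus has ended.

### Indicator model

The green channel reports calcium through saturable binding,
`F = F_rest + F_max·[Ca]/([Ca]+kd)`, with kd = 345 nM (Fluo-4) or 2.3 µM
(Fluo-5F); the red channel is a constant volume fill. Shot noise is
Gaussian with SD ∝ √F. Frames are 33 ms apart (1 s stacks under TTX).
Saturation is why the low-affinity dye reports an equal-or-later 20% rise
at identical calcium, reproducing the dye-control experiment without any
dye-specific kinetics.

### Release

*Synchronous*: per spike, a Bernoulli release with probability
`p0 · pq_scale · exp(−t/τ_dep)` (p0 = 0.85, τ_dep = 2 s) and latency
jitter ~N(0.5 ms, 0.5 ms) clipped to [0.1, 2] ms.

*Asynchronous*: an inhomogeneous Poisson process whose rate is
`r_max · mean_b(s_b(t)) · R(t)`, where `s_b = x^h/(x^h + K^h)` is a
cooperative Hill transform (h = 5, K = 0.5) of bouton *b*'s normalised bulk
calcium and `R(t) = exp(−k·∫mean(s))` is a deterministically depleting
vesicle pool (k = 0.25). Events are allocated to boutons in proportion to
their instantaneous drive, so release onset tracks the local front arrival
— the mechanism behind the release/calcium coincidence. The Hill form was
chosen over a linear supra-threshold rate deliberately: high calcium
cooperativity of neuromuscular release is classical physiology, and it is
what lets the same model produce both the steeply rising, pool-limited
release time course (time-to-peak 3.4 s control / 10.5 s toxin at 5 mM
EGTA) and a release half-rise that coincides with the calcium half-rise to
within 0.4 s; a linear-threshold rate cannot do both, because depletion
makes its half-rise lead the calcium signal by ~0.5 s.

Both modes draw amplitudes from one truncated normal (mean 637 pA,
CV 0.25) — the reference-population fact that asynchronous and spontaneous quanta
are indistinguishable is thus true by construction, and the analysis is
tested for *recovering* it. Quantal currents are inward biexponentials
`(1−e^(−t/τr))·e^(−t/τd)` (τr = 0.3 ms, τd = 1.0 ms — not reported for
this synapse; chosen for fast NMJ endplate currents), linearly superposed
at 20 kHz with 5 pA Gaussian noise. A 0.25 Hz spontaneous background runs
throughout.

The synaptopHluorin generator is simpler: per-bouton green fluorescence
proportional to the cumulative release count (vesicular reporter exposed to
neutral pH on fusion; non-decaying within a trial), no red channel.

## The analysis procedures

* **Event detection** — rectified, 0.2 ms-boxcar-smoothed current; peaks
  > 4× the pre-stimulus noise SD, ≥ 1 ms apart. Amplitude is measured on
  the *signed* smoothed trace against the pre-event trough (minimum over
  [peak−2.5 ms, peak−0.4 ms]): a mean or median baseline is biased by
  rectified noise and, for closely spaced events, by the preceding decay
  tail.
* **Classification** — latency to the preceding spike; synchronous iff
  ≤ 3 ms (≪ the 10 ms inter-stimulus interval, ≫ the sub-millisecond
  jitter). Events with no preceding spike are asynchronous; with no train
  at all, spontaneous. A hard floor follows from this rule: asynchronous
  events are uniform in stimulus phase, so window/ISI = 30% of within-train
  asynchronous events (and charge) are unavoidably attributed to the
  synchronous window. Per-event mode confusion is therefore floor-limited
  for asynchronous events no matter the noise level; the package's
  invariant tests assert sub-5% error for *synchronous* events, where
  timing is genuinely discriminative, and bound the asynchronous
  mislabelling by the analytic floor. The same floor caps the measured
  asynchronous charge share in toxin-treated simulations at ~74–78%
  against a ground-truth share of ~100%.
* **Charge decomposition** — trapezoidal integral of |I| per bin (1 s
  default, 0.5 s for coincidence), split by the union of
  [spike, spike+3 ms] intervals; `async = total − sync` enforces
  conservation identically. Time-to-peak is the centre of the maximal
  total-charge bin, ties to the earlier bin.
* **Quantal fit** — fixed-width histogram (50 pA), three-parameter Gaussian
  by Poisson-weighted least squares (σ = √count) with bounded parameters;
  unweighted fitting is ~1.5× less efficient and can diverge on sparse
  histograms.
* **Ratios and onsets** — ΔF/F₀ and ΔG/R per their definitions; onset is
  the first sustained (≥3 frames) crossing of 20% (or 50%) of the 5-frame
  smoothed trial maximum after stimulus start. ROIs whose smoothed peak is
  below 5× the baseline SD are excluded as non-responsive (the real
  experiment selected ROIs by postsynaptic α-bungarotoxin colocalisation,
  which has no synthetic counterpart). "Maximum" means the smoothed trial
  maximum; a plateau-mean alternative would differ only under strong late
  relaxation.
* **Wave velocity** — OLS of onset time on arc distance over
  bouton-compartment ROIs (axon/branch ROIs are excluded: their arrival is
  distance-independent); velocity = 1/slope, and the slope's p-value is the
  distance-independence test for control data. Single-cell fits can drop
  the most proximal point (`exclude_first`), the convention for cells whose
  first ROI sits at the front's initiation site.
* **Coincidence** — the same fractional-rise estimator applied to the
  per-half-second asynchronous charge course and to the unweighted mean
  ΔG/R over responsive boutons; both 50% crossings are linearly
  interpolated between samples, since whole-bin quantisation of a 0.5 s
  series would add a systematic ~0.25 s. The charge series is compared as
  a *rate* (per-bin) time course; a cumulative-charge variant would place
  its 50% point at the median release time, which measures something else.

## Calibration

Front speeds, onsets, quantal amplitude and indicator constants are fixed
to the published values for this preparation (74/35 µm/s, kd's, 637 pA).
The free dynamic constants — `tau_bulk`, `tau_fast`, local lag, Hill (K,
h), depletion k, synchronous p0 and τ_dep, and the wave onsets — were
calibrated once against the published onset and time-to-peak table
(20%-rise means; time-to-peak 3.4/10.5 s at 5 mM and 2.88/4.88 s at
0.5 mM EGTA) and then frozen in `calibrations.yaml`. At published-scale
replicate counts the frozen defaults give: time-to-peak 3.8 ± 0.5 s
(control) and 10.1 ± 0.8 s (toxin) at 5 mM; pooled 20%-rise 2.17 ± 0.58 s
(toxin, Fluo-4, 0.5 mM) and 0.17 s (control); recovered velocities within
a few percent of the configured 74/35 µm/s; release/calcium |Δt₅₀| ≈
0.2 s.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analyses assume —
latency-separable modes, saturable indicators, a kinematic front, pool
depletion — so green tests demonstrate that the procedures recover known
parameters from data of that structure at realistic noise. They do not
validate the biology of real recordings: real data add multi-vesicular
early release, baseline drift and bleaching, movement artefacts,
non-stationary noise, and ROI contamination, none of which are emulated.
The 25 mM EGTA regime and the mild bouton relaxation are qualitative
gestures, not calibrated claims.

## Numerical choices and degenerate inputs

Sampling at 20 kHz (0.05 ms) keeps the 0.3 ms rise time resolved; the
detection deadtime (1 ms) sets a collision-limited recall of ~95% at the
calibrated peak asynchronous rates (~40–60 Hz). Charge conservation is
exact by construction and asserted at 1e-9 pC. Degenerate inputs raise
rather than guess: all-zero charge courses (undefined time-to-peak),
rank-deficient distance designs, non-positive F₀, missing red channels,
sub-minimum event counts for the quantal fit (with advice to pool), and
zero-variance samples in the Welch comparisons (exact-equality fallback).
Problem sizes in tests (desk scale: 3–15 replicates, 12–15 boutons, 20 s
trains) match the published group sizes where the comparison is against a
published mean.
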