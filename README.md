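# synapse-modes

Quantification of **synchronous vs asynchronous neuromuscular
transmission** and of the **propagating calcium source** that drives the
asynchronous mode, for paired voltage-clamp + live-imaging experiments at
the zebrafish CaP motor neuron–muscle synapse (and preparations like it).
It is written for electrophysiologists and imaging labs who have (a)
end-plate current (EPC) traces with a known stimulus train, (b) per-ROI
two-channel fluorescence time series, and (c) an SWC reconstruction of the
neuron — and who want the two release modes separated, charge-quantified,
and related to the spatial spread of intracellular calcium.

Because no raw recordings of this preparation are publicly deposited, the
package also ships a fully seeded synthetic-data generator emulating every
experimental regime (control, ω-conotoxin GVIA, the hypomorphic P/Q mutant,
killswitch truncation, TTX; 0.5/5/25 mM EGTA; Fluo-4/Fluo-5F;
synaptopHluorin). Every analysis routine is validated by parameter recovery
against it.

## What it computes

With spikes at times `t_k` (100 Hz ⇒ inter-stimulus interval 10 ms):

* **Event detection and mode classification.** Quantal events are local
  maxima of the rectified, lightly smoothed current above 4σ of the
  pre-stimulus noise. Each event's latency is `t − max{t_k ≤ t}`; it is
  *synchronous* iff latency ≤ 3 ms, otherwise *asynchronous*.
* **Charge decomposition.** Per time bin (1 s default),
  `Q_total = ∫|I| dt`; `Q_sync` integrates over ∪[t_k, t_k+3 ms];
  `Q_async = Q_total − Q_sync` (conservation exact). *Time-to-peak release*
  is the centre of the maximal-`Q_total` bin.
* **Quantal amplitudes.** Poisson-weighted Gaussian fit to the amplitude
  histogram; Welch tests for amplitude (in)distinguishability between
  event classes.
* **Fluorescence ratios and onsets.** ΔF/F₀ = (F−F₀)/F₀ and
  ΔG/R = (G−G₀)/R̄; the *f-fractional rise time* (f = 20% or 50%) is the
  first sustained crossing of `f·max` of the smoothed series after
  stimulus start.
* **Wave velocity.** OLS of onset time on arc distance `d` (from the SWC
  reconstruction, along the filament) over bouton ROIs:
  `t_onset = t_0 + d/v`; the fitted `1/slope` is the front speed in µm/s,
  and the slope-zero test is the distance-independence check for control
  data.
* **Killswitch and coincidence.** Whether calcium/release persist past a
  truncated stimulus, and `|Δt₅₀|` between the 50%-rise of per-half-second
  asynchronous charge and of the mean bouton ΔG/R in simultaneous
  recordings.

The generator's calibration (packaged YAML) encodes the preparation's
published operating point: quantal mean 637 pA; front speed 74 µm/s at
0.5 mM EGTA and 35 µm/s at 5 mM; indicator kd 345 nM (Fluo-4) / 2.3 µM
(Fluo-5F); release driven by a cooperative (Hill) function of bulk calcium
with a depleting vesicle pool. See `docs/methods.md` for the model.

## Worked example

Simulate one ω-conotoxin-treated cell at 0.5 mM EGTA and run the full
analysis:

```python
from synapse_modes import synthdata as sd, ephys, imaging

cfg = sd.load_calibration("gvia", 0.5, "fluo4")
cell = sd.simulate_cell(cfg, seed=42)

events = ephys.classify_events(ephys.detect_events(cell.trace), cell.stim)
course = ephys.charge_decomposition(cell.trace, cell.stim)
onsets = imaging.onsets_table(cell.rois, fraction=0.2,
                              stim_start_s=cell.stim.start_time_s)
fit = imaging.fit_wave_velocity(onsets)

print(f"events detected:        {len(events)}")
print(f"asynchronous charge:    {100 * course.async_fraction:.1f}%")
print(f"time to peak release:   {ephys.time_to_peak(course):.1f} s")
print(f"wave velocity:          {fit.velocity_um_per_s:.1f} um/s  (r2 = {fit.r2:.2f})")
```

prints

```
events detected:        668
asynchronous charge:    73.3%
time to peak release:   5.5 s
wave velocity:          74.2 um/s  (r2 = 1.00)
```

With synchronous release pharmacologically ablated, nearly all charge is
asynchronous (the ~27% attributed to the synchronous window is the
chance-coincidence floor of a 3 ms window at 100 Hz — see
`docs/methods.md`), release peaks seconds into the train instead of at its
start, and bouton calcium onsets line up on a 74 µm/s front along the
axonal arbor — the configured speed, recovered from the simulated frames.

The same stages are scriptable from the shell:

```sh
synapse-modes simulate --condition gvia --egta 0.5 --seed 42 -o run/
synapse-modes analyze-ephys run/trace.csv --stim run/manifest.json -o out/
synapse-modes analyze-imaging run/rois.csv --morph run/morphology.swc \
    --attach run/attachments.csv -o out/
synapse-modes run --seed 0 -o comparison/   # full multi-condition report
```

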