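"""Seeded stochastic generator for paired-recording and ROI-imaging data.

The generator emulates the zebrafish CaP motor-neuron / fast-muscle
preparation: a 100 Hz, 20 s presynaptic train evokes quantal end-plate
currents released in two modes, and bouton calcium reported by a saturable
indicator rises with a distance-dependent delay set by a propagating front.

Bouton free calcium is modelled as two saturating components above rest:

* a *fast* AP-driven component (amplitude ``fast_amp_uM * pq_scale``) that
  turns on at stimulus onset — this is the P/Q-channel calcium abolished by
  ω-conotoxin GVIA;
* a *bulk* component (amplitude ``bulk_amp_uM``) that arrives as a
  constant-speed kinematic front: axon and branch-point ROIs at
  ``wave_onset_s`` after stimulus start, boutons at ``wave_onset_s + d/v``
  where ``d`` is arc distance from the reference point.

Asynchronous release is an inhomogeneous Poisson process whose rate follows
the supra-threshold bulk component, scaled by a slowly depleting vesicle
pool; synchronous release is a per-spike Bernoulli draw with exponentially
depressing probability and sub-millisecond latency jitter. The front is a
kinematic arrival-time model, not a reaction-diffusion PDE: it implements
exactly what the analysis stage can measure (quasi-linear onset-vs-distance
relations), nothing more.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .core import EPCTrace, GroundTruth, ROITimeSeries, StimulusTrain
from .morphology import (NeuronMorphology, ROIAttachment, SWCNode,
                         attachment_distances)

__all__ = [
    "ConditionConfig", "QuantalModel", "load_calibration", "raw_calibration",
    "make_morphology", "simulate_wave_arrivals", "simulate_fluorescence",
    "simulate_release", "render_epc_trace", "simulate_sph",
    "simulate_cell", "SimulatedCell", "biexp_kernel", "biexp_unit_charge_s",
]

EGTA_LEVELS = (0.5, 5.0, 25.0)


def raw_calibration() -> dict:
    """The packaged calibration YAML as a nested dict."""
    text = (importlib.resources.files("synapse_modes") / "calibrations.yaml"
            ).read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class QuantalModel:
    """Quantal EPC shape and amplitude statistics."""

    mean_amp_pA: float = 637.0
    cv: float = 0.25
    rise_tau_ms: float = 0.3
    decay_tau_ms: float = 1.0
    noise_sd_pA: float = 5.0
    sample_rate_hz: float = 20000.0

    def __post_init__(self) -> None:
        for name in ("mean_amp_pA", "cv", "rise_tau_ms", "decay_tau_ms",
                     "sample_rate_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_pA < 0:
            raise ValueError("noise_sd_pA must be non-negative")


@dataclass(frozen=True)
class ConditionConfig:
    """One experimental regime: condition x [EGTA] x indicator."""

    condition: str = "control"
    egta_mM: float = 0.5
    indicator: str = "fluo4"
    pq_scale: float = 1.0
    wave_speed_um_per_s: float = 74.0
    wave_onset_s: float = 0.6
    tau_bulk_s: float = 2.2
    tau_fast_s: float = 0.6
    lag_s: float = 0.05
    onset_jitter_scale_s: float = 0.1
    rate_scale: float = 1.0
    kd_uM: float = 0.345
    killswitch_end_s: float | None = None
    # shared sub-models
    quantal: QuantalModel = field(default_factory=QuantalModel)
    rest_uM: float = 0.1
    fast_amp_uM: float = 0.45
    bulk_amp_uM: float = 0.45
    tau_off_s: float = 8.0
    relax_frac: float = 0.05
    relax_tau_s: float = 5.0
    sync_p0: float = 0.85
    sync_depress_tau_s: float = 2.0
    sync_latency_mean_ms: float = 0.5
    sync_latency_sd_ms: float = 0.5
    sync_latency_clip_ms: tuple[float, float] = (0.1, 2.0)
    async_rate_max_hz: float = 170.0
    deplete_k: float = 0.3
    spont_rate_hz: float = 0.25
    hill_k: float = 0.45
    hill_h: float = 3.0
    frame_dt_s: float = 0.033
    f_rest_au: float = 50.0
    f_max_au: float = 200.0
    shot_eta: float = 0.3
    red_mean_au: float = 100.0
    red_sd_au: float = 2.0
    ttx_v_slow_um_per_s: float = 3.0

    def __post_init__(self) -> None:
        if self.condition not in ("control", "gvia", "tb204a", "ttx"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.egta_mM not in EGTA_LEVELS:
            raise ValueError(f"egta_mM must be one of {EGTA_LEVELS}")
        if not self.wave_speed_um_per_s > 0:
            raise ValueError("wave_speed must be positive")
        if not 0.0 <= self.pq_scale <= 1.0:
            raise ValueError("pq_scale must lie in [0, 1]")


def load_calibration(condition: str = "control", egta_mM: float = 0.5,
                     indicator: str = "fluo4",
                     **overrides) -> ConditionConfig:
    """Build a :class:`ConditionConfig` from the packaged calibration YAML.

    ``overrides`` replace individual fields (e.g. ``wave_speed_um_per_s=57``
    for the single-cell fixture).
    """
    cal = raw_calibration()
    key = f"{egta_mM:g}"
    if key not in cal["egta"]:
        raise ValueError(f"no calibration for EGTA {egta_mM} mM")
    egta = cal["egta"][key]
    if indicator not in cal["indicators"]:
        raise ValueError(f"unknown indicator {indicator!r}")
    if condition not in cal["conditions"]:
        raise ValueError(f"unknown condition {condition!r}")
    cfg = ConditionConfig(
        condition=condition,
        egta_mM=float(egta_mM),
        indicator=indicator,
        pq_scale=float(cal["conditions"][condition]["pq_scale"]),
        wave_speed_um_per_s=float(egta["wave_speed_um_per_s"]),
        wave_onset_s=float(egta["wave_onset_s"]),
        tau_bulk_s=float(egta["tau_bulk_s"]),
        tau_fast_s=float(egta["tau_fast_s"]),
        lag_s=float(egta["lag_s"]),
        onset_jitter_scale_s=float(egta["onset_jitter_scale_s"]),
        rate_scale=float(egta["rate_scale"]),
        kd_uM=float(cal["indicators"][indicator]["kd_uM"]),
        quantal=QuantalModel(**cal["quantal"]),
        **{k: (tuple(v) if isinstance(v, list) else float(v))
           for k, v in {**_flat(cal["calcium"]), **_flat_release(cal["release"]),
                        **_flat(cal["imaging"])}.items()},
        ttx_v_slow_um_per_s=float(cal["ttx"]["v_slow_um_per_s"]),
    )
    if condition == "ttx":
        cfg = replace(cfg, frame_dt_s=float(cal["ttx"]["frame_dt_s"]))
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def _flat(section: dict) -> dict:
    rename = {"rest_uM": "rest_uM", "fast_amp_uM": "fast_amp_uM",
              "bulk_amp_uM": "bulk_amp_uM", "tau_off_s": "tau_off_s",
              "relax_frac": "relax_frac", "relax_tau_s": "relax_tau_s",
              "frame_dt_s": "frame_dt_s", "f_rest_au": "f_rest_au",
              "f_max_au": "f_max_au", "shot_eta": "shot_eta",
              "red_mean_au": "red_mean_au", "red_sd_au": "red_sd_au"}
    return {rename[k]: v for k, v in section.items() if k in rename}


def _flat_release(section: dict) -> dict:
    return {k: v for k, v in section.items()}


def fixture_config(name: str = "slow_wave_cell") -> tuple[ConditionConfig, int]:
    """A packaged named fixture; returns (config, fixture seed)."""
    fx = raw_calibration()["fixtures"][name]
    cfg = load_calibration(fx["condition"], float(fx["egta_mM"]),
                           fx["indicator"],
                           wave_speed_um_per_s=float(fx["wave_speed_um_per_s"]))
    return cfg, int(fx["seed"])


# ---------------------------------------------------------------------------
# Morphology generation

def make_morphology(seed: int, n_boutons: int = 12,
                    ) -> tuple[NeuronMorphology, list[ROIAttachment]]:
    """Synthetic CaP-like morphology plus ROI attachments.

    Soma at the origin, an 80 µm (arc) axon to the reference node at the
    ventral notochord edge, a short continuation to the main branch point,
    then a main branch carrying ``n_boutons`` bouton nodes at strictly
    increasing arc distances spanning ~5-150 µm from the reference point.
    Segment lengths are exact so stored arc distances are exact.
    """
    if n_boutons < 1:
        raise ValueError("n_boutons must be >= 1")
    rng = np.random.default_rng(seed)
    nodes: list[SWCNode] = []
    nid = 1
    nodes.append(SWCNode(nid, 1, 0.0, 0.0, 0.0, 5.0, -1))  # soma
    soma_id = nid

    def _extend(parent_id: int, length: float, direction: np.ndarray,
                type_code: int, radius: float, n_seg: int) -> int:
        nonlocal nid
        pos = np.array([nodes[parent_id - 1].x, nodes[parent_id - 1].y,
                        nodes[parent_id - 1].z])
        pid = parent_id
        for _ in range(n_seg):
            d = direction + rng.normal(0.0, 0.12, size=3)
            d /= np.linalg.norm(d)
            pos = pos + d * (length / n_seg)
            nid += 1
            nodes.append(SWCNode(nid, type_code, *(float(v) for v in pos),
                                 radius, pid))
            pid = nid
        return pid

    # straight-ish ventral axon: 16 segments x 5 µm = exactly 80 µm of arc
    ref_id = _extend(soma_id, 80.0, np.array([0.0, -1.0, 0.0]), 2, 1.0, 16)
    # short continuation to the main branch point
    branch_id = _extend(ref_id, 10.0, np.array([0.3, -1.0, 0.0]), 2, 1.0, 2)
    arc_to_branch = 10.0

    # bouton arc distances from the reference node, strictly increasing
    d_boutons = np.sort(rng.uniform(5.0, 150.0, size=n_boutons))
    d_boutons += np.arange(n_boutons) * 1e-6  # break exact ties
    attachments: list[ROIAttachment] = [
        ROIAttachment("soma", soma_id, "soma"),
        ROIAttachment("axon_mid", soma_id + 8, "axon"),
        ROIAttachment("branch", branch_id, "branch_point"),
    ]
    # main branch: walk along, dropping bouton nodes at the target arcs
    pid, arc = branch_id, arc_to_branch
    direction = np.array([0.8, -0.6, 0.0])
    for i, target in enumerate(d_boutons):
        if target > arc:
            pid = _extend(pid, target - arc,
                          direction + rng.normal(0, 0.1, 3), 2, 0.8,
                          max(1, int((target - arc) / 8)))
            arc = target
        nid += 1
        # bouton as a zero-offset child marker node (adds no arc length)
        nodes.append(SWCNode(nid, 2, nodes[pid - 1].x, nodes[pid - 1].y,
                             nodes[pid - 1].z, 1.5, pid))
        attachments.append(ROIAttachment(f"bouton_{i:02d}", nid, "bouton"))
    morph = NeuronMorphology(nodes, reference_node=ref_id, soma_node=soma_id)
    return morph, attachments


# ---------------------------------------------------------------------------
# Wave arrivals

def simulate_wave_arrivals(morph: NeuronMorphology,
                           attachments: list[ROIAttachment],
                           cfg: ConditionConfig,
                           stim: StimulusTrain,
                           rng: np.random.Generator | None = None,
                           ) -> dict[str, float]:
    """Absolute arrival time (s) of the slow calcium source at each ROI.

    control: the first spike time everywhere (AP-driven, distance
    independent). gvia/tb204a: axon and branch-point ROIs at
    ``wave_onset_s`` after stimulus start, boutons additionally delayed by
    arc distance / wave speed. ttx: soma-origin front at 3-10 µm/s, delay =
    arc distance from the *soma* / v_slow.

    With an ``rng``, each ROI additionally receives a gamma-distributed
    local response delay (mean ``onset_jitter_scale_s``, shape 3) emulating
    bouton-to-bouton heterogeneity in front invasion and calcium handling;
    without one, arrivals are the exact kinematic times.
    """
    dist = attachment_distances(attachments, morph)
    if cfg.condition == "control":
        t0 = float(stim.spike_times_s[0]) if stim.spike_times_s.size else stim.start_time_s
        out = {r: t0 for r in dist.roi_id}
    elif cfg.condition == "ttx":
        dsoma = attachment_distances(attachments, morph, origin=morph.soma_node)
        v = cfg.ttx_v_slow_um_per_s
        out = {r.roi_id: stim.start_time_s + r.distance_um / v
               for r in dsoma.itertuples()}
    else:
        out = {}
        for r in dist.itertuples():
            t = stim.start_time_s + cfg.wave_onset_s
            if r.compartment == "bouton":
                t += r.distance_um / cfg.wave_speed_um_per_s
            out[r.roi_id] = float(t)
    if rng is not None and cfg.onset_jitter_scale_s > 0:
        for rid in sorted(out):
            out[rid] = out[rid] + float(
                rng.gamma(3.0, cfg.onset_jitter_scale_s / 3.0))
    return out


# ---------------------------------------------------------------------------
# Calcium and fluorescence

def _rise(t: np.ndarray, t_on: float, tau: float) -> np.ndarray:
    """Saturating exponential rise, zero before ``t_on``."""
    x = np.clip(t - t_on, 0.0, None)
    return -np.expm1(-x / tau)


def calcium_series(t: np.ndarray, arrival_s: float, cfg: ConditionConfig,
                   stim: StimulusTrain, compartment: str = "bouton",
                   killswitch: bool = False) -> np.ndarray:
    """Free calcium (µM) at one ROI: rest + fast AP component + bulk front.

    After stimulus end both components decay with ``tau_off_s`` — except in
    the killswitch regime, where the already-launched front keeps
    propagating and the bulk component ignores the truncation.
    """
    fast_amp = cfg.fast_amp_uM * cfg.pq_scale
    if cfg.condition == "ttx":
        fast_amp = 0.0
    fast = fast_amp * _rise(t, stim.start_time_s + cfg.lag_s, cfg.tau_fast_s)
    bulk = cfg.bulk_amp_uM * _rise(t, arrival_s + cfg.lag_s, cfg.tau_bulk_s)
    if compartment == "bouton" and cfg.relax_frac > 0:
        bulk = bulk * (1.0 - cfg.relax_frac
                       * _rise(t, arrival_s + cfg.lag_s + 2 * cfg.tau_bulk_s,
                               cfg.relax_tau_s))
    off = np.where(t > stim.end_time_s,
                   np.exp(-(t - stim.end_time_s) / cfg.tau_off_s), 1.0)
    fast = fast * off
    # the front persists past stimulus end when truncated (killswitch) and
    # under TTX, where a sustained depolarization maintains the source
    if not (killswitch or cfg.condition == "ttx"):
        bulk = bulk * off
    return cfg.rest_uM + fast + bulk


def bulk_drive(t: np.ndarray, arrivals: dict[str, float],
               cfg: ConditionConfig, stim: StimulusTrain,
               bouton_ids: list[str], killswitch: bool = False) -> np.ndarray:
    """Asynchronous-release drive per bouton; shape (n_b, n_t).

    The normalised bulk calcium is passed through a cooperative Hill
    transform, x^h / (x^h + K^h): release requires several calcium ions
    bound to its sensor, so the rate turns on steeply only once the bulk
    component is an appreciable fraction of its plateau and saturates
    above it. Zero before the local front arrival by construction.
    """
    rows = []
    off = np.where(t > stim.end_time_s,
                   np.exp(-(t - stim.end_time_s) / cfg.tau_off_s), 1.0)
    for rid in bouton_ids:
        b = _rise(t, arrivals[rid] + cfg.lag_s, cfg.tau_bulk_s)
        if not (killswitch or cfg.condition == "ttx"):
            b = b * off
        bh = b ** cfg.hill_h
        rows.append(bh / (bh + cfg.hill_k ** cfg.hill_h))
    return np.asarray(rows)


def saturation(ca_uM: np.ndarray | float, kd_uM: float):
    """Fractional indicator binding [Ca]/([Ca]+kd)."""
    return ca_uM / (ca_uM + kd_uM)


def simulate_fluorescence(arrivals: dict[str, float], cfg: ConditionConfig,
                          stim: StimulusTrain, seed: int,
                          duration_s: float = 26.0,
                          compartments: dict[str, str] | None = None,
                          distances: dict[str, float] | None = None,
                          killswitch: bool = False,
                          noiseless: bool = False) -> list[ROITimeSeries]:
    """Two-channel indicator/fill frames for every ROI in ``arrivals``.

    Green = f_rest + f_max * saturation(calcium) + shot noise (Gaussian, SD
    proportional to sqrt(F)); red = constant fill + noise. Frames every
    ``cfg.frame_dt_s`` (33 ms; 1 s stacks in the TTX regime).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    t = np.arange(0.0, duration_s, cfg.frame_dt_s)
    baseline = (0.0, stim.start_time_s)
    out = []
    for rid in sorted(arrivals):
        comp = (compartments or {}).get(rid, "bouton")
        ca = calcium_series(t, arrivals[rid], cfg, stim, comp, killswitch)
        green = cfg.f_rest_au + cfg.f_max_au * saturation(ca, cfg.kd_uM)
        red = np.full_like(green, cfg.red_mean_au)
        if not noiseless:
            green = green + rng.normal(0.0, cfg.shot_eta * np.sqrt(green))
            red = red + rng.normal(0.0, cfg.red_sd_au, size=red.shape)
        out.append(ROITimeSeries(
            roi_id=rid, frame_times_s=t, green=green, red=red,
            baseline_window_s=baseline, compartment=comp,
            distance_um=(distances or {}).get(rid)))
    return out


# ---------------------------------------------------------------------------
# Release and the EPC trace

def simulate_release(stim: StimulusTrain, arrivals: dict[str, float],
                     cfg: ConditionConfig, quantal: QuantalModel,
                     seed: int, duration_s: float = 36.0,
                     bouton_ids: list[str] | None = None,
                     killswitch: bool = False) -> GroundTruth:
    """Draw ground-truth release events for one paired recording.

    Synchronous: per-spike Bernoulli with probability
    ``sync_p0 * pq_scale * exp(-t/sync_depress_tau)`` and truncated-normal
    latency jitter. Asynchronous: inhomogeneous Poisson, rate =
    ``async_rate_max_hz * rate_scale * mean(bulk drive) * pool``, where the
    pool depletes exponentially with integrated drive; events are allocated
    to boutons in proportion to each bouton's instantaneous drive, so
    release onset tracks the local front arrival. A low spontaneous rate
    runs throughout.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 202)))
    if bouton_ids is None:
        bouton_ids = sorted(arrivals)
    rows = []
    # synchronous mode
    if cfg.pq_scale > 0 and stim.spike_times_s.size:
        p = (cfg.sync_p0 * cfg.pq_scale
             * np.exp(-(stim.spike_times_s - stim.start_time_s)
                      / cfg.sync_depress_tau_s))
        fire = rng.random(p.size) < p
        lat = rng.normal(cfg.sync_latency_mean_ms, cfg.sync_latency_sd_ms,
                         size=int(fire.sum()))
        lat = np.clip(lat, *cfg.sync_latency_clip_ms) * 1e-3
        for t_ev, b in zip(stim.spike_times_s[fire] + lat,
                           rng.choice(bouton_ids, size=lat.size)):
            rows.append((float(t_ev), "sync", str(b)))
    # asynchronous mode: thinned per-ms grid
    dt = 1e-3
    t = np.arange(0.0, duration_s, dt)
    drive = bulk_drive(t, arrivals, cfg, stim, bouton_ids, killswitch)
    mean_drive = drive.mean(axis=0)
    pool = np.exp(-cfg.deplete_k * np.cumsum(mean_drive) * dt)
    lam = cfg.async_rate_max_hz * cfg.rate_scale * mean_drive * pool
    counts = rng.poisson(lam * dt)
    for i in np.flatnonzero(counts):
        w = drive[:, i]
        probs = w / w.sum() if w.sum() > 0 else None
        for _ in range(counts[i]):
            b = rng.choice(bouton_ids, p=probs)
            rows.append((float(t[i] + rng.random() * dt), "async", str(b)))
    # spontaneous background (labelled async in ground truth semantics:
    # mode is sync/async per the generator; classification may differ)
    n_spont = rng.poisson(cfg.spont_rate_hz * duration_s)
    for t_ev in rng.random(n_spont) * duration_s:
        rows.append((float(t_ev), "async", str(rng.choice(bouton_ids))))
    amp = rng.normal(quantal.mean_amp_pA, quantal.cv * quantal.mean_amp_pA,
                     size=len(rows))
    amp = np.clip(amp, 1.0, None)  # amplitudes strictly positive
    ev = pd.DataFrame({
        "time_s": [r[0] for r in rows],
        "amplitude_pA": amp,
        "mode": [r[1] for r in rows],
        "roi_id": [r[2] for r in rows],
    }).sort_values("time_s", ignore_index=True)
    return GroundTruth(events=ev, arrivals_s=dict(arrivals))


def biexp_kernel(quantal: QuantalModel, dt_s: float) -> np.ndarray:
    """Unit-peak biexponential (1-exp(-t/τr))·exp(-t/τd) sampled at dt."""
    tr = quantal.rise_tau_ms * 1e-3
    td = quantal.decay_tau_ms * 1e-3
    t = np.arange(0.0, 10.0 * td, dt_s)
    k = (1.0 - np.exp(-t / tr)) * np.exp(-t / td)
    t_peak = tr * np.log1p(td / tr)
    peak = (1.0 - np.exp(-t_peak / tr)) * np.exp(-t_peak / td)
    return k / peak


def biexp_unit_charge_s(quantal: QuantalModel) -> float:
    """Analytic integral (s) of the unit-peak kernel: charge = amp * this."""
    tr = quantal.rise_tau_ms * 1e-3
    td = quantal.decay_tau_ms * 1e-3
    t_peak = tr * np.log1p(td / tr)
    peak = (1.0 - np.exp(-t_peak / tr)) * np.exp(-t_peak / td)
    return (td - 1.0 / (1.0 / tr + 1.0 / td)) / peak


def render_epc_trace(truth: GroundTruth, quantal: QuantalModel,
                     seed: int, duration_s: float = 36.0,
                     sample_rate_hz: float | None = None) -> EPCTrace:
    """Superpose quantal biexponentials (inward, negative) plus noise."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 303)))
    fs = sample_rate_hz or quantal.sample_rate_hz
    dt = 1.0 / fs
    n = int(round(duration_s * fs))
    cur = np.zeros(n)
    kern = biexp_kernel(quantal, dt)
    for t_ev, amp in zip(truth.events.time_s, truth.events.amplitude_pA):
        i0 = int(round(t_ev * fs))
        if i0 >= n:
            continue
        i1 = min(n, i0 + kern.size)
        cur[i0:i1] -= amp * kern[:i1 - i0]
    if quantal.noise_sd_pA > 0:
        cur += rng.normal(0.0, quantal.noise_sd_pA, size=n)
    return EPCTrace(np.arange(n) * dt, cur)


# ---------------------------------------------------------------------------
# synaptopHluorin

def simulate_sph(truth: GroundTruth, bouton_ids: list[str], seed: int,
                 stim: StimulusTrain, duration_s: float = 26.0,
                 frame_dt_s: float = 0.033, f0_au: float = 100.0,
                 df_per_event_au: float = 2.0, noise_sd_au: float = 1.0,
                 noiseless: bool = False) -> list[ROITimeSeries]:
    """Exocytosis reporter: green ∝ cumulative per-bouton release count.

    The signal is non-decaying over the trial (vesicular reporter exposed to
    neutral pH on fusion); no red channel exists for this transgenic probe.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 404)))
    t = np.arange(0.0, duration_s, frame_dt_s)
    out = []
    for rid in bouton_ids:
        ev = truth.events.loc[truth.events.roi_id == rid, "time_s"].to_numpy()
        cum = np.searchsorted(np.sort(ev), t, side="right")
        green = f0_au + df_per_event_au * cum
        if not noiseless:
            green = green + rng.normal(0.0, noise_sd_au, size=t.size)
        out.append(ROITimeSeries(rid, t, green, None,
                                 (0.0, stim.start_time_s), "bouton"))
    return out


# ---------------------------------------------------------------------------
# One-call cell simulation

@dataclass
class SimulatedCell:
    """Everything one simulated experiment produces."""

    cfg: ConditionConfig
    seed: int
    morph: NeuronMorphology
    attachments: list[ROIAttachment]
    stim: StimulusTrain
    arrivals: dict[str, float]
    rois: list[ROITimeSeries]
    truth: GroundTruth
    trace: EPCTrace | None

    @property
    def bouton_ids(self) -> list[str]:
        return [a.roi_id for a in self.attachments if a.compartment == "bouton"]


def simulate_cell(cfg: ConditionConfig, seed: int, n_boutons: int = 12,
                  stim: StimulusTrain | None = None,
                  imaging_duration_s: float | None = None,
                  ephys_duration_s: float = 36.0,
                  with_trace: bool = True,
                  noiseless: bool = False) -> SimulatedCell:
    """Simulate one cell end to end: morphology, front, frames, EPC trace.

    The killswitch protocol is engaged by setting ``cfg.killswitch_end_s``;
    the stimulus is truncated there but the launched front keeps moving.
    """
    ss = np.random.SeedSequence(seed)
    s_morph, s_fluo, s_rel, s_trace, s_wave = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5))
    morph, attachments = make_morphology(s_morph, n_boutons=n_boutons)
    if stim is None:
        stim = StimulusTrain.regular(100.0, 1.0, 20.0)
    killswitch = cfg.killswitch_end_s is not None
    if killswitch:
        stim = stim.truncated(cfg.killswitch_end_s)
    arrivals = simulate_wave_arrivals(morph, attachments, cfg, stim,
                                      rng=np.random.default_rng(s_wave))
    dist = attachment_distances(attachments, morph)
    compartments = dict(zip(dist.roi_id, dist.compartment))
    distances = dict(zip(dist.roi_id, dist.distance_um))
    if imaging_duration_s is None:
        imaging_duration_s = (raw_calibration()["ttx"]["duration_s"]
                              if cfg.condition == "ttx"
                              else stim.end_time_s + 5.0)
    rois = simulate_fluorescence(arrivals, cfg, stim, s_fluo,
                                 duration_s=imaging_duration_s,
                                 compartments=compartments,
                                 distances=distances, killswitch=killswitch,
                                 noiseless=noiseless)
    bouton_ids = [a.roi_id for a in attachments if a.compartment == "bouton"]
    truth = simulate_release(stim, arrivals, cfg, cfg.quantal, s_rel,
                             duration_s=ephys_duration_s,
                             bouton_ids=bouton_ids, killswitch=killswitch)
    trace = None
    if with_trace:
        trace = render_epc_trace(truth, cfg.quantal, s_trace,
                                 duration_s=ephys_duration_s)
    return SimulatedCell(cfg, seed, morph, attachments, stim, arrivals,
                         rois, truth, trace)
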