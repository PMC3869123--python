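"""Shared containers for paired-recording and ROI-imaging data.

Conventions used throughout the package:

* time is in seconds, currents in pA, charge in pC unless stated otherwise,
  distances in µm;
* end-plate currents (EPCs) are inward and therefore *negative* in the raw
  trace; analysis code rectifies to positive magnitudes;
* ROI fluorescence frames are nominally 33 ms apart (the acquisition rate of
  the spinning-disc recordings this package emulates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StimulusTrain:
    """A regular presynaptic stimulus train (default 100 Hz for 20 s)."""

    frequency_hz: float
    start_time_s: float
    end_time_s: float
    spike_times_s: np.ndarray

    @classmethod
    def regular(cls, frequency_hz: float = 100.0, start_time_s: float = 1.0,
                duration_s: float = 20.0) -> "StimulusTrain":
        """Build an evenly spaced train of ``duration_s * frequency_hz`` spikes."""
        n = int(round(duration_s * frequency_hz))
        spikes = start_time_s + np.arange(n) / frequency_hz
        return cls(frequency_hz, start_time_s, start_time_s + duration_s, spikes)

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        object.__setattr__(self, "spike_times_s", t)
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
            isi = np.diff(t)
            if isi.size and np.any(np.abs(isi - 1.0 / self.frequency_hz) > 1e-6):
                raise ValueError("spike spacing inconsistent with frequency")
        if not self.start_time_s < self.end_time_s:
            raise ValueError("start_time_s must precede end_time_s")

    @property
    def isi_s(self) -> float:
        return 1.0 / self.frequency_hz

    def truncated(self, end_time_s: float) -> "StimulusTrain":
        """Stimulus cut short at ``end_time_s`` (the 'killswitch' protocol)."""
        keep = self.spike_times_s[self.spike_times_s < end_time_s]
        if keep.size == 0:
            raise ValueError("truncation removes every spike")
        return StimulusTrain(self.frequency_hz, self.start_time_s,
                             float(end_time_s), keep)


@dataclass
class EPCTrace:
    """Voltage-clamp end-plate current trace (inward currents negative)."""

    time_s: np.ndarray
    current_pa: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        if self.time_s.shape != self.current_pa.shape:
            raise ValueError("time and current arrays differ in length")

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / self.dt_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "current_pA": self.current_pa})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EPCTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["current_pA"].to_numpy())

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_s", data=self.time_s)
            f.create_dataset("current_pA", data=self.current_pa)

    @classmethod
    def from_hdf5(cls, path) -> "EPCTrace":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["time_s"][...], f["current_pA"][...])


@dataclass
class ROITimeSeries:
    """Two-channel fluorescence time series for one ROI.

    ``green`` is the indicator channel, ``red`` the volume fill (may be None
    for synaptopHluorin recordings, which have no fill normalisation).
    """

    roi_id: str
    frame_times_s: np.ndarray
    green: np.ndarray
    red: np.ndarray | None
    baseline_window_s: tuple[float, float]
    compartment: str = "bouton"
    distance_um: float | None = None

    def __post_init__(self) -> None:
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red is not None:
            self.red = np.asarray(self.red, dtype=float)
            if self.red.shape != self.green.shape:
                raise ValueError("green/red length mismatch")
        dt = np.diff(self.frame_times_s)
        if np.any(dt <= 0):
            raise ValueError("frame times must be strictly increasing")
        if dt.size and (dt.max() - dt.min()) > 0.01 * dt.mean():
            raise ValueError("frame spacing must be uniform within 1%")
        t0, t1 = self.baseline_window_s
        if not t0 < t1:
            raise ValueError("baseline window is empty")


def roi_series_to_frame(series: list[ROITimeSeries]) -> pd.DataFrame:
    """Tidy long-format table (roi_id, frame_time_s, green, red)."""
    parts = []
    for s in series:
        parts.append(pd.DataFrame({
            "roi_id": s.roi_id,
            "frame_time_s": s.frame_times_s,
            "green": s.green,
            "red": s.red if s.red is not None else np.nan,
            "compartment": s.compartment,
            "distance_um": np.nan if s.distance_um is None else s.distance_um,
        }))
    return pd.concat(parts, ignore_index=True)


def roi_series_from_frame(df: pd.DataFrame,
                          baseline_window_s: tuple[float, float]) -> list[ROITimeSeries]:
    out = []
    for roi_id, g in df.groupby("roi_id", sort=False):
        red = g["red"].to_numpy()
        dist = g["distance_um"].iloc[0] if "distance_um" in g else np.nan
        out.append(ROITimeSeries(
            roi_id=str(roi_id),
            frame_times_s=g["frame_time_s"].to_numpy(),
            green=g["green"].to_numpy(),
            red=None if np.all(np.isnan(red)) else red,
            baseline_window_s=baseline_window_s,
            compartment=str(g["compartment"].iloc[0]) if "compartment" in g else "bouton",
            distance_um=None if np.isnan(dist) else float(dist),
        ))
    return out


@dataclass
class GroundTruth:
    """Simulated release events with true mode labels, plus wave arrivals.

    ``events`` columns: time_s, amplitude_pA, mode ('sync'|'async'),
    roi_id (release bouton). ``arrivals_s`` maps roi_id -> calcium front
    arrival time. Used only as a test/validation oracle.
    """

    events: pd.DataFrame
    arrivals_s: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"time_s", "amplitude_pA", "mode", "roi_id"}
        if not need.issubset(self.events.columns):
            raise ValueError(f"ground-truth events need columns {sorted(need)}")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def charge_by_mode(self, unit_charge_pc_per_pa: float) -> dict[str, float]:
        """Per-mode charge assuming every event carries the quantal kernel."""
        q = self.events.groupby("mode")["amplitude_pA"].sum() * unit_charge_pc_per_pa
        return {m: float(q.get(m, 0.0)) for m in ("sync", "async")}
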