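"""Shared containers and errors for the beat-to-beat analysis pipeline.

The common currency of the HRV/BRS stages is a :class:`BeatSeries` — one
record per heartbeat carrying the RR interval (ms) and, when finger
plethysmography is available, systolic/diastolic/mean pressure (mmHg).
Spectral stages consume a :class:`TachogramWindow`, a uniformly resampled
2-minute RR signal.  Pulse-wave-velocity stages consume a
:class:`WaveformPair` (two synchronously sampled pressure waveforms plus the
inter-site path distance), and calorimetry a :class:`GasTrace` of 1-minute
binned VO2/VCO2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "QualityError",
    "BeatSeries",
    "TachogramWindow",
    "WaveformPair",
    "GasTrace",
]


class QualityError(RuntimeError):
    """A signal segment failed a data-quality precondition.

    Raised when a window is unusable (too many edited beats, coverage gap,
    no steady state, too few baroreflex sequences ...) rather than when the
    caller passed malformed arguments.
    """


@dataclass
class BeatSeries:
    """Per-beat record stream: times (s), RR intervals (ms), optional pressures.

    ``beat_time_s`` must be strictly increasing; for unedited beats
    ``rr_ms[i] ~= 1000 * (beat_time_s[i] - beat_time_s[i-1])``.
    ``flags`` marks beats identified as ectopic/artifactual; ``meta`` carries
    provenance (participant, condition, timepoint, generator ground truth).
    """

    beat_time_s: np.ndarray
    rr_ms: np.ndarray
    sbp_mmhg: Optional[np.ndarray] = None
    dbp_mmhg: Optional[np.ndarray] = None
    map_mmhg: Optional[np.ndarray] = None
    flags: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beat_time_s = np.asarray(self.beat_time_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.beat_time_s.shape != self.rr_ms.shape:
            raise ValueError("beat_time_s and rr_ms must have equal length")
        if self.beat_time_s.size and np.any(np.diff(self.beat_time_s) <= 0):
            bad = int(np.argmax(np.diff(self.beat_time_s) <= 0)) + 1
            raise ValueError(f"beat_time_s not strictly increasing at row {bad}")
        if np.any(self.rr_ms <= 0):
            raise ValueError("rr_ms must be positive")
        for name in ("sbp_mmhg", "dbp_mmhg", "map_mmhg"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.rr_ms.shape:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)
        if self.flags is None:
            self.flags = np.zeros(self.rr_ms.shape, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)

    def __len__(self) -> int:
        return int(self.rr_ms.size)

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.flags))

    def slice_time(self, start_s: float, end_s: float) -> "BeatSeries":
        """Beats with ``start_s <= beat_time_s <= end_s`` (flags preserved)."""
        m = (self.beat_time_s >= start_s) & (self.beat_time_s <= end_s)
        kw = {}
        for name in ("sbp_mmhg", "dbp_mmhg", "map_mmhg"):
            v = getattr(self, name)
            kw[name] = None if v is None else v[m]
        return BeatSeries(
            beat_time_s=self.beat_time_s[m],
            rr_ms=self.rr_ms[m],
            flags=self.flags[m],
            meta=dict(self.meta),
            **kw,
        )

    def copy(self) -> "BeatSeries":
        return replace(
            self,
            beat_time_s=self.beat_time_s.copy(),
            rr_ms=self.rr_ms.copy(),
            sbp_mmhg=None if self.sbp_mmhg is None else self.sbp_mmhg.copy(),
            dbp_mmhg=None if self.dbp_mmhg is None else self.dbp_mmhg.copy(),
            map_mmhg=None if self.map_mmhg is None else self.map_mmhg.copy(),
            flags=self.flags.copy(),
            meta=dict(self.meta),
        )


@dataclass
class TachogramWindow:
    """Uniformly resampled RR signal for one analysis window.

    ``values_ms`` holds ``fs_hz * window_len_s`` samples starting at
    ``start_s``; ``n_edited`` counts beats removed/bridged upstream.
    """

    fs_hz: float
    values_ms: np.ndarray
    start_s: float = 0.0
    window_len_s: float = 120.0
    n_edited: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values_ms = np.asarray(self.values_ms, dtype=float)
        n_expected = self.fs_hz * self.window_len_s
        if abs(n_expected - round(n_expected)) > 1e-9:
            raise ValueError("fs_hz * window_len_s must be an integer sample count")
        if self.values_ms.size != int(round(n_expected)):
            raise ValueError(
                f"expected {int(round(n_expected))} samples, got {self.values_ms.size}"
            )
        if not np.all(np.isfinite(self.values_ms)):
            raise ValueError("window contains non-finite samples")


@dataclass
class WaveformPair:
    """Two synchronously sampled pressure waveforms plus the path distance."""

    fs_hz: float
    proximal: np.ndarray
    distal: np.ndarray
    distance_m: float
    site_pair: str = "cf"  # cf | cr | cd
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        if self.proximal.shape != self.distal.shape:
            raise ValueError("proximal and distal waveforms must have equal length")
        if self.fs_hz < 100:
            raise ValueError("sampling rate below 100 Hz is too coarse for foot timing")
        if self.distance_m <= 0:
            raise ValueError("distance_m must be positive")


@dataclass
class GasTrace:
    """1-minute binned gas-exchange trace (flows in mL/min, HR in bpm).

    ``phase`` labels each bin with the session phase (rest / class /
    recovery ...), mirroring the evaluator's phase marks.
    """

    t_min: np.ndarray
    vo2_ml_min: np.ndarray
    vco2_ml_min: np.ndarray
    hr_bpm: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.vo2_ml_min = np.asarray(self.vo2_ml_min, dtype=float)
        self.vco2_ml_min = np.asarray(self.vco2_ml_min, dtype=float)
        if not (self.t_min.shape == self.vo2_ml_min.shape == self.vco2_ml_min.shape):
            raise ValueError("t_min, vo2, vco2 must have equal length")
        if np.any(self.vo2_ml_min < 0) or np.any(self.vco2_ml_min < 0):
            raise ValueError("gas flows must be non-negative")
        if self.hr_bpm is not None:
            self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=object)

    def __len__(self) -> int:
        return int(self.t_min.size)

    @property
    def rer(self) -> np.ndarray:
        """Respiratory exchange ratio VCO2/VO2 per bin."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.vco2_ml_min / self.vo2_ml_min
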