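"""Foot-to-foot pulse wave velocity, pulse pressure and carotid calibration.

Transit time between two simultaneously recorded pressure waveforms is
measured foot-to-foot: the foot of each pulse is located by the
intersecting-tangent construction (the crossing of the horizontal line
through the diastolic minimum with the tangent at the point of maximal
systolic upstroke), with sub-sample precision from a local quadratic fit
of the derivative peak.  PWV is the inter-site distance divided by the
mean transit time; the carotid-femoral path distance is conventionally
scaled by 0.8 to account for the opposed propagation directions.

Central systolic pressure is obtained by linearly rescaling the raw
carotid waveform so that its minimum maps to diastolic pressure and its
time average to mean arterial pressure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.signal import find_peaks

from .core import QualityError, WaveformPair

__all__ = [
    "PWVResult",
    "PressureSummary",
    "detect_feet",
    "transit_and_pwv",
    "pulse_pressure",
    "calibrate_carotid",
    "screen_bp",
    "CF_DISTANCE_CORRECTION",
]

#: carotid-femoral path-length correction factor
CF_DISTANCE_CORRECTION = 0.8


@dataclass(frozen=True)
class PWVResult:
    transit_time_s: float
    transit_times_s: tuple
    corrected_distance_m: float
    pwv_m_s: float
    n_beats_used: int
    valid: bool  # >= 10 matched beats


@dataclass(frozen=True)
class PressureSummary:
    sbp_mmhg: float
    dbp_mmhg: float
    map_mmhg: float
    pp_mmhg: float
    csbp_mmhg: Optional[float] = None
    map_source: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.dbp_mmhg < self.map_mmhg < self.sbp_mmhg:
            raise ValueError("pressures must satisfy DBP < MAP < SBP")


def _quadratic_vertex(y0: float, y1: float, y2: float) -> float:
    """Sub-sample offset of the extremum of a parabola through three
    equally spaced points (offset relative to the middle point)."""
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))


def detect_feet(
    wave: np.ndarray, fs_hz: float, method: str = "tangent"
) -> List[float]:
    """Per-beat foot times (s) of a periodic pressure waveform.

    Beats are segmented by cycle minima between successive systolic peaks;
    ``method='tangent'`` uses the intersecting-tangent foot, the
    alternative ``'d2max'`` uses the maximum of the second derivative.
    """
    w = np.asarray(wave, dtype=float)
    amp = float(np.ptp(w))
    if w.size < 3 or amp < 1e-9 or amp < 1e-6 * max(1.0, abs(float(np.mean(w)))):
        raise QualityError("flat or near-constant signal: no pulse feet")

    # systolic peaks; distance guard at 0.3 s keeps dicrotic bumps out
    peaks, _ = find_peaks(w, prominence=0.5 * amp, distance=max(1, int(0.3 * fs_hz)))
    if peaks.size < 2:
        raise QualityError("fewer than 2 beats visible")

    dw = np.gradient(w) * fs_hz
    d2w = np.gradient(dw) * fs_hz
    feet: List[float] = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        seg_min = p0 + int(np.argmin(w[p0:p1]))  # diastolic minimum of cycle
        if p1 - seg_min < 3:
            continue
        if method == "d2max":
            m = seg_min + int(np.argmax(d2w[seg_min:p1]))
            if not 0 < m < w.size - 1:
                continue
            dm = _quadratic_vertex(d2w[m - 1], d2w[m], d2w[m + 1])
            feet.append((m + dm) / fs_hz)
            continue
        # intersecting tangent
        m = seg_min + int(np.argmax(dw[seg_min:p1]))
        if not 0 < m < w.size - 1:
            continue
        dm = _quadratic_vertex(dw[m - 1], dw[m], dw[m + 1])
        # derivative and value at the sub-sample upstroke point
        slope = dw[m] - 0.25 * (dw[m - 1] - dw[m + 1]) * dm  # parabola value
        a, b = (m, m + 1) if dm >= 0 else (m - 1, m)
        frac = dm if dm >= 0 else 1.0 + dm
        val = (1 - frac) * w[a] + frac * w[b]
        base = w[seg_min]
        if slope <= 0:
            continue
        t_up = (m + dm) / fs_hz
        feet.append(t_up - (val - base) / slope)
    if not feet:
        raise QualityError("no usable pulse feet found")
    return feet


def transit_and_pwv(
    pair: WaveformPair,
    correction: Optional[float] = None,
    min_beats: int = 10,
    method: str = "tangent",
) -> PWVResult:
    """Foot-to-foot transit time and PWV for a waveform pair.

    Proximal and distal feet are matched by order: each proximal foot is
    paired with the first distal foot following it.  ``correction``
    defaults to 0.8 for the carotid-femoral site pair and 1.0 otherwise.
    Fewer than ``min_beats`` matched beats yields a result flagged
    invalid; a non-positive mean transit raises (site order error).
    """
    if correction is None:
        correction = CF_DISTANCE_CORRECTION if pair.site_pair == "cf" else 1.0
    feet_p = np.array(detect_feet(pair.proximal, pair.fs_hz, method=method))
    feet_d = np.array(detect_feet(pair.distal, pair.fs_hz, method=method))

    transits: List[float] = []
    for fp in feet_p:
        k = int(np.searchsorted(feet_d, fp))
        if k >= feet_d.size:
            break
        transits.append(float(feet_d[k] - fp))
    if not transits:
        raise QualityError("no matched proximal/distal beat pairs")
    mean_tt = float(np.mean(transits))
    if mean_tt <= 0:
        raise ValueError(
            "non-positive mean transit time: check proximal/distal site order"
        )
    corrected = pair.distance_m * correction
    return PWVResult(
        transit_time_s=mean_tt,
        transit_times_s=tuple(transits),
        corrected_distance_m=corrected,
        pwv_m_s=corrected / mean_tt,
        n_beats_used=len(transits),
        valid=len(transits) >= min_beats,
    )


def pulse_pressure(sbp_mmhg: float, dbp_mmhg: float) -> float:
    """Pulse pressure SBP - DBP (mmHg)."""
    if sbp_mmhg <= dbp_mmhg:
        raise ValueError("SBP must exceed DBP")
    return float(sbp_mmhg - dbp_mmhg)


def calibrate_carotid(
    wave: np.ndarray,
    fs_hz: float,
    map_mmhg: float,
    dbp_mmhg: float,
    min_duration_s: float = 15.0,
    map_source: str = "unspecified",
) -> PressureSummary:
    """Calibrate a raw (arbitrary-unit) carotid waveform against MAP/DBP.

    Linear rescale a*x + b such that the waveform minimum maps to DBP and
    the time average to MAP; central systolic pressure is the rescaled
    maximum.  Requires at least ``min_duration_s`` of signal.
    """
    w = np.asarray(wave, dtype=float)
    if w.size / fs_hz < min_duration_s:
        raise ValueError(
            f"need >= {min_duration_s} s of carotid signal for calibration"
        )
    if map_mmhg <= dbp_mmhg:
        raise ValueError("MAP must exceed DBP")
    wmin, wmean, wmax = float(np.min(w)), float(np.mean(w)), float(np.max(w))
    if wmean - wmin < 1e-12 * max(1.0, abs(wmean)):
        raise QualityError("flat waveform: mean equals minimum, cannot calibrate")
    a = (map_mmhg - dbp_mmhg) / (wmean - wmin)
    b = dbp_mmhg - a * wmin
    csbp = a * wmax + b
    return PressureSummary(
        sbp_mmhg=csbp,
        dbp_mmhg=float(dbp_mmhg),
        map_mmhg=float(map_mmhg),
        pp_mmhg=csbp - float(dbp_mmhg),
        csbp_mmhg=csbp,
        map_source=map_source,
    )


def screen_bp(sbp_mmhg: float, dbp_mmhg: float) -> bool:
    """Resting-hypertension eligibility screen.

    Ineligible iff SBP > 140 mmHg or DBP > 90 mmHg (strict inequalities:
    exactly 140/90 passes).  Returns True when eligible.
    """
    return not (sbp_mmhg > 140.0 or dbp_mmhg > 90.0)
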