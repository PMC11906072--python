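"""Indirect-calorimetry energy expenditure and VO2peak adjudication.

Resting energy expenditure (REE) comes from the Weir equation applied to
the mean flows of a 5-minute steady-state window (coefficient of
variation of VO2 and VCO2 <= 10%, mean RER within 0.7-1.0), searched
between the 5th and 15th minute of the resting measurement with the first
5 minutes discarded; when several windows qualify, the one with the
lowest REE is taken.  Session energetics: TEE is the per-minute Weir
energy summed over a phase; AEE = TEE - (REE over the phase + 0.1*TEE),
the 10% term approximating the thermic effect of food.  Intensity is
expressed in measured-REE METs and reserve percentages; VO2peak is the
highest 10-second average in the last minute of an incremental test,
accepted when at least two adjudication criteria hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .core import GasTrace, QualityError

__all__ = [
    "EnergyResult",
    "VO2PeakResult",
    "weir_ree",
    "weir_kcal_min",
    "find_steady_state",
    "session_energy",
    "intensity_metrics",
    "adjudicate_vo2peak",
]

#: Weir coefficients: kcal/day from mL/min flows, urinary nitrogen ignored
_WEIR_O2 = 3.94
_WEIR_CO2 = 1.11
_WEIR_SCALE = 1.44


def weir_ree(vo2_ml_min: float, vco2_ml_min: float) -> float:
    """Energy expenditure (kcal/day) = 1.44 * (3.94*VO2 + 1.11*VCO2)."""
    if np.any(np.asarray(vo2_ml_min) <= 0):
        raise ValueError("VO2 must be positive")
    if np.any(np.asarray(vco2_ml_min) < 0):
        raise ValueError("VCO2 must be non-negative")
    return _WEIR_SCALE * (_WEIR_O2 * vo2_ml_min + _WEIR_CO2 * vco2_ml_min)


def weir_kcal_min(vo2_ml_min: float, vco2_ml_min: float) -> float:
    """Per-minute Weir energy (kcal/min)."""
    return weir_ree(vo2_ml_min, vco2_ml_min) / 1440.0


@dataclass(frozen=True)
class EnergyResult:
    tee_kcal: float
    ree_over_session_kcal: float
    aee_kcal: float
    duration_min: float
    negative_aee: bool
    mets_series: Optional[np.ndarray] = None
    rer_series: Optional[np.ndarray] = None


@dataclass(frozen=True)
class VO2PeakResult:
    vo2peak_ml_kg_min: float
    vo2peak_l_min: Optional[float]
    hrmax_bpm: float
    criteria_met: Dict[str, bool]
    accepted: bool


def find_steady_state(
    trace: GasTrace,
    win_min: int = 5,
    cv_max: float = 0.10,
    rer_lo: float = 0.7,
    rer_hi: float = 1.0,
    search: Tuple[float, float] = (5.0, 15.0),
) -> Tuple[Tuple[float, float], float]:
    """Locate the steady-state window and its Weir REE.

    All ``win_min``-long windows of consecutive 1-min bins inside
    ``search`` are scored; a window qualifies iff CV(VO2) <= cv_max,
    CV(VCO2) <= cv_max and mean RER in [rer_lo, rer_hi].  Among qualifying
    windows the one with the lowest REE wins (conservative rule).  Returns
    ``((start_min, end_min), ree_kcal_day)``; raises
    :class:`QualityError` when no window qualifies.
    """
    # bin i covers [i, i+1) min; recover integer start minutes from centers
    starts_min = np.round(trace.t_min - 0.5).astype(int)
    if trace.t_min[-1] < search[0] + win_min:
        raise QualityError("trace does not cover the search interval")

    best: Optional[Tuple[Tuple[float, float], float]] = None
    for i in range(len(trace) - win_min + 1):
        w_start = starts_min[i]
        w_end = starts_min[i + win_min - 1] + 1
        if w_start < search[0] or w_end > search[1]:
            continue
        vo2 = trace.vo2_ml_min[i : i + win_min]
        vco2 = trace.vco2_ml_min[i : i + win_min]
        cv_o2 = np.std(vo2, ddof=1) / np.mean(vo2)
        cv_co2 = np.std(vco2, ddof=1) / np.mean(vco2)
        rer = float(np.mean(vco2 / vo2))
        if cv_o2 > cv_max or cv_co2 > cv_max or not rer_lo <= rer <= rer_hi:
            continue
        ree = weir_ree(float(np.mean(vo2)), float(np.mean(vco2)))
        if best is None or ree < best[1]:
            best = ((float(w_start), float(w_end)), ree)
    if best is None:
        raise QualityError(
            "no 5-min steady state (CV <= 10%, RER 0.7-1.0) in the search window"
        )
    return best


def session_energy(
    trace: GasTrace,
    ree_kcal_day: float,
    phase: str,
    rest_vo2_ml_min: Optional[float] = None,
) -> EnergyResult:
    """TEE, REE-over-phase and AEE for one labelled session phase.

    TEE sums the per-minute Weir energy over the phase bins;
    AEE = TEE - (REE_over_phase + 0.1*TEE).  Negative AEE is permitted but
    flagged.  ``rest_vo2_ml_min`` enables the METs series.
    """
    if trace.phase is None:
        raise ValueError("trace carries no phase marks")
    sel = trace.phase == phase
    if not np.any(sel):
        raise ValueError(f"phase mark {phase!r} absent from trace")
    vo2 = trace.vo2_ml_min[sel]
    vco2 = trace.vco2_ml_min[sel]
    duration = float(np.count_nonzero(sel))  # 1-min bins
    tee = float(np.sum(weir_ree(vo2, vco2) / 1440.0))
    ree_over = ree_kcal_day * duration / 1440.0
    aee = tee - (ree_over + 0.1 * tee)
    mets = vo2 / rest_vo2_ml_min if rest_vo2_ml_min else None
    with np.errstate(divide="ignore", invalid="ignore"):
        rer = vco2 / vo2
    return EnergyResult(
        tee_kcal=tee,
        ree_over_session_kcal=ree_over,
        aee_kcal=aee,
        duration_min=duration,
        negative_aee=aee < 0,
        mets_series=mets,
        rer_series=rer,
    )


def intensity_metrics(
    trace: GasTrace,
    rest_vo2_ml_min: float,
    rest_hr_bpm: Optional[float] = None,
    hrmax_bpm: Optional[float] = None,
    vo2peak_ml_min: Optional[float] = None,
) -> Dict[str, np.ndarray]:
    """Per-minute METs, %VO2 reserve and %HR reserve.

    METs use the participant's measured resting VO2 (not the 3.5 mL/kg/min
    convention).  Reserve percentages are 100*(value - rest)/(max - rest);
    values outside [0, 100] are reported as-is with an ``out_of_range``
    flag, never clipped.
    """
    if rest_vo2_ml_min <= 0:
        raise ValueError("rest_vo2 must be positive")
    out: Dict[str, np.ndarray] = {"mets": trace.vo2_ml_min / rest_vo2_ml_min}
    if vo2peak_ml_min is not None:
        if vo2peak_ml_min <= rest_vo2_ml_min:
            raise ValueError("vo2peak must exceed resting VO2")
        out["pct_vo2_reserve"] = (
            100.0
            * (trace.vo2_ml_min - rest_vo2_ml_min)
            / (vo2peak_ml_min - rest_vo2_ml_min)
        )
    if hrmax_bpm is not None and rest_hr_bpm is not None:
        if trace.hr_bpm is None:
            raise ValueError("trace carries no HR")
        if hrmax_bpm <= rest_hr_bpm:
            raise ValueError("HRmax must exceed resting HR")
        out["pct_hr_reserve"] = (
            100.0 * (trace.hr_bpm - rest_hr_bpm) / (hrmax_bpm - rest_hr_bpm)
        )
    out["out_of_range"] = np.zeros(len(trace), dtype=bool)
    for key in ("pct_vo2_reserve", "pct_hr_reserve"):
        if key in out:
            out["out_of_range"] |= (out[key] < 0) | (out[key] > 100)
    return out


def age_predicted_hrmax(age_years: float) -> float:
    """Age-predicted maximal heart rate, 220 - age."""
    return 220.0 - age_years


def adjudicate_vo2peak(
    vo2_ml_kg_min: np.ndarray,
    hr_bpm: np.ndarray,
    rer: np.ndarray,
    rpe: np.ndarray,
    age_years: float,
    body_mass_kg: Optional[float] = None,
    stage_delta_vo2_ml_kg_min: Optional[float] = None,
    observer_exhaustion: bool = False,
    bin_s: float = 10.0,
) -> VO2PeakResult:
    """VO2peak from 10-second averaged test data with criterion counting.

    ``vo2peak`` is the highest 10-s VO2 within the final 60 s of effort.
    Criteria: (1) max HR >= ~90% of age-predicted HRmax (220 - age);
    (2) VO2 plateau: consecutive-stage increase below 2.0 mL/kg/min
    (supplied by the caller as ``stage_delta_vo2_ml_kg_min``); (3) peak
    RPE >= 18; (4) peak RER >= 1.1; (5) observer judgment of exhaustion.
    Accepted iff at least two criteria hold.
    """
    vo2 = np.asarray(vo2_ml_kg_min, dtype=float)
    n_last = int(round(60.0 / bin_s))
    if vo2.size < n_last:
        raise ValueError("need at least 60 s of 10-s averaged data")
    vo2peak = float(np.max(vo2[-n_last:]))
    hrmax = float(np.max(hr_bpm))
    criteria = {
        "hr_near_age_predicted": hrmax >= 0.9 * age_predicted_hrmax(age_years),
        "vo2_plateau": (
            stage_delta_vo2_ml_kg_min is not None
            and stage_delta_vo2_ml_kg_min < 2.0
        ),
        "rpe_ge_18": float(np.max(rpe)) >= 18.0,
        "rer_ge_1_1": float(np.max(rer)) >= 1.1,
        "observer_exhaustion": bool(observer_exhaustion),
    }
    return VO2PeakResult(
        vo2peak_ml_kg_min=vo2peak,
        vo2peak_l_min=(
            vo2peak * body_mass_kg / 1000.0 if body_mass_kg is not None else None
        ),
        hrmax_bpm=hrmax,
        criteria_met=criteria,
        accepted=sum(criteria.values()) >= 2,
    )
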