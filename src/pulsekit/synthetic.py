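"""Synthetic physiological signals with known ground truth.

Every generator takes an explicit spec dataclass carrying its own integer
seed, and records the quantities the downstream estimators are supposed to
recover (band power of an RR oscillation, baroreflex gain, wave transit
delay, resting energy expenditure, fixed trial effects) in the output
``meta``/``attrs``.  No generator touches global random state.

These signals are deliberately minimal: sinusoidal LF/HF modulation of the
RR tachogram, triangular pressure ramps for the baroreflex, an analytic
two-bump beat template for the pressure waves, and step-shaped gas traces.
They exercise the estimators; they do not simulate cardiovascular
physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import BeatSeries, GasTrace, WaveformPair

__all__ = [
    "RRGenSpec",
    "BaroGenSpec",
    "WaveGenSpec",
    "GasGenSpec",
    "TrialGenSpec",
    "generate_rr",
    "generate_baro_beats",
    "generate_wave_pair",
    "generate_gas_trace",
    "generate_trial_table",
]


# ---------------------------------------------------------------------------
# RR tachograms

@dataclass(frozen=True)
class RRGenSpec:
    """RR tachogram with prescribed LF/HF oscillations and ectopic beats.

    Amplitudes are in ms; a sinusoid of amplitude A contributes A^2/2 ms^2
    of band power, which is the generator's spectral ground truth.
    """

    duration_s: float = 300.0
    mean_rr_ms: float = 800.0
    lf_amp_ms: float = 0.0
    lf_freq_hz: float = 0.10
    hf_amp_ms: float = 0.0
    hf_freq_hz: float = 0.25
    noise_sd_ms: float = 0.0
    ectopic_rate_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be positive")
        if self.lf_amp_ms < 0 or self.hf_amp_ms < 0 or self.noise_sd_ms < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if not 0.04 <= self.lf_freq_hz <= 0.15:
            raise ValueError("lf_freq_hz must lie in the LF band 0.04-0.15 Hz")
        if not 0.15 <= self.hf_freq_hz <= 0.4:
            raise ValueError("hf_freq_hz must lie in the HF band 0.15-0.4 Hz")
        if self.ectopic_rate_per_min < 0:
            raise ValueError("ectopic_rate_per_min must be non-negative")


def generate_rr(spec: RRGenSpec) -> BeatSeries:
    """Generate a beat series whose RR signal is a two-tone sinusoid + noise.

    RR(t) = mean + lf_amp sin(2 pi f_lf t) + hf_amp sin(2 pi f_hf t) + e,
    evaluated at the running beat time; beat times are cumulative sums of
    RR.  Ectopics are injected as an isolated premature beat at 0.6x the
    local RR followed by a 1.4x compensatory pause (local mean preserved).
    Ground truth (tone powers, injected ectopic indices) is stored in
    ``meta['truth']``.
    """
    rng = np.random.default_rng(spec.seed)
    rr: List[float] = []
    t = 0.0
    while True:
        r = (
            spec.mean_rr_ms
            + spec.lf_amp_ms * np.sin(2 * np.pi * spec.lf_freq_hz * t)
            + spec.hf_amp_ms * np.sin(2 * np.pi * spec.hf_freq_hz * t)
        )
        if spec.noise_sd_ms > 0:
            r += rng.normal(0.0, spec.noise_sd_ms)
        if r <= 200.0:
            raise ValueError(
                "spec produces a non-physiological RR interval <= 200 ms"
            )
        if t + r / 1000.0 > spec.duration_s + 1e-12:
            break
        rr.append(r)
        t += r / 1000.0

    rr_arr = np.array(rr)
    ect_idx: List[int] = []
    if spec.ectopic_rate_per_min > 0:
        n_ect = rng.poisson(spec.ectopic_rate_per_min * spec.duration_s / 60.0)
        candidates = np.arange(6, rr_arr.size - 7)
        rng.shuffle(candidates)
        for i in candidates:
            if n_ect == 0:
                break
            if all(abs(i - j) >= 3 for j in ect_idx):
                ect_idx.append(int(i))
                n_ect -= 1
        for i in ect_idx:
            local = rr_arr[i]
            rr_arr[i] = 0.6 * local
            rr_arr[i + 1] = 1.4 * local
        if np.any(rr_arr <= 200.0):
            raise ValueError("ectopic injection produced RR <= 200 ms")

    times = np.cumsum(rr_arr) / 1000.0
    truth = {
        "lf_power_ms2": spec.lf_amp_ms**2 / 2.0,
        "hf_power_ms2": spec.hf_amp_ms**2 / 2.0,
        "ectopic_indices": sorted(ect_idx),
        "spec": spec,
    }
    return BeatSeries(beat_time_s=times, rr_ms=rr_arr, meta={"truth": truth})


# ---------------------------------------------------------------------------
# Coupled SBP-RR beats for the sequence method

@dataclass(frozen=True)
class BaroGenSpec:
    """Alternating SBP ramps with a linear RR response of known gain."""

    n_beats: int = 300
    gain_ms_per_mmhg: float = 10.0
    ramp_len_beats: int = 4
    ramp_step_mmhg: float = 2.0
    lag_beats: int = 1
    noise_sd_ms: float = 0.0
    base_sbp_mmhg: float = 120.0
    base_rr_ms: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_ms_per_mmhg <= 0:
            raise ValueError("gain must be positive")
        if self.ramp_len_beats < 3:
            raise ValueError("ramp_len_beats must be >= 3")
        if self.ramp_step_mmhg <= 0:
            raise ValueError("ramp_step_mmhg must be positive")
        if self.n_beats < 2 * self.ramp_len_beats:
            raise ValueError("n_beats too small for a single up/down ramp pair")
        if self.lag_beats < 0 or self.noise_sd_ms < 0:
            raise ValueError("lag_beats and noise_sd_ms must be non-negative")


def generate_baro_beats(spec: BaroGenSpec) -> BeatSeries:
    """SBP alternates up/down ramps; RR follows gain * (SBP - base) at a lag.

    Per-beat SBP steps are drawn uniformly from
    [ramp_step, 1.5 * ramp_step], so a sub-threshold ``ramp_step`` (e.g.
    0.5 mmHg against the 1 mmHg detector) stays sub-threshold for every
    beat.  The true gain is stored in ``meta['truth']['gain_ms_per_mmhg']``.
    """
    rng = np.random.default_rng(spec.seed)
    sbp = np.empty(spec.n_beats)
    sbp[0] = spec.base_sbp_mmhg
    direction = 1.0
    step_count = 0
    for i in range(1, spec.n_beats):
        step = rng.uniform(spec.ramp_step_mmhg, 1.5 * spec.ramp_step_mmhg)
        sbp[i] = sbp[i - 1] + direction * step
        step_count += 1
        if step_count == spec.ramp_len_beats:
            direction = -direction
            step_count = 0

    rr = spec.base_rr_ms + spec.gain_ms_per_mmhg * (sbp - spec.base_sbp_mmhg)
    if spec.lag_beats > 0:
        rr = np.concatenate([np.full(spec.lag_beats, rr[0]), rr[: -spec.lag_beats]])
    if spec.noise_sd_ms > 0:
        rr = rr + rng.normal(0.0, spec.noise_sd_ms, rr.shape)
    if np.any(rr <= 200.0):
        raise ValueError("spec produces RR <= 200 ms; reduce gain or ramp span")

    times = np.cumsum(rr) / 1000.0
    truth = {"gain_ms_per_mmhg": spec.gain_ms_per_mmhg, "spec": spec}
    return BeatSeries(beat_time_s=times, rr_ms=rr, sbp_mmhg=sbp, meta={"truth": truth})


# ---------------------------------------------------------------------------
# Pressure waveform pairs

@dataclass(frozen=True)
class WaveGenSpec:
    """Periodic pressure pulse pair with a prescribed transit delay."""

    fs_hz: float = 1000.0
    n_beats: int = 12
    period_s: float = 1.0
    delay_s: float = 0.1
    distance_m: float = 0.875
    dbp_mmhg: float = 80.0
    sbp_mmhg: float = 120.0
    noise_sd: float = 0.0
    site_pair: str = "cf"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz < 100:
            raise ValueError("fs_hz must be >= 100")
        if not 0 < self.delay_s < self.period_s:
            raise ValueError("delay_s must lie in (0, period_s)")
        if self.delay_s < 0.5 / self.fs_hz:
            raise ValueError(
                "delay_s below half a sample period is not resolvable at fs_hz"
            )
        if self.distance_m <= 0:
            raise ValueError("distance_m must be positive")
        if self.sbp_mmhg <= self.dbp_mmhg:
            raise ValueError("sbp must exceed dbp")


def _raw_template(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 1e-9, None)
    b1 = np.exp(-((np.log(u / 0.18)) ** 2) / (2 * 0.35**2))
    b2 = 0.35 * np.exp(-((np.log(u / 0.45)) ** 2) / (2 * 0.25**2))
    return b1 + b2


_TEMPLATE_PEAK = float(np.max(_raw_template(np.linspace(1e-4, 1.0, 20001))))


def _beat_template(u: np.ndarray) -> np.ndarray:
    """Normalized pulse shape on phase u in [0, 1): two log-normal bumps.

    Main systolic bump plus a smaller late (reflected) bump on a diastolic
    baseline; ~0 at onset, max 1.  Physiological realism is not the point —
    a sharp, repeatable systolic upstroke for foot detection is.
    """
    return _raw_template(u) / _TEMPLATE_PEAK


def generate_wave_pair(spec: WaveGenSpec) -> WaveformPair:
    """Proximal waveform from the analytic beat template; distal = same
    template delayed by ``delay_s`` (evaluated at shifted time, hence exact).

    True transit time / PWV are stored in ``meta['truth']``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.n_beats * spec.period_s * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz
    onset_frac = 0.25  # first onset a quarter-period in, so beat 1 has a baseline

    def wave(shift: float) -> np.ndarray:
        u = ((t - onset_frac * spec.period_s - shift) % spec.period_s) / spec.period_s
        w = spec.dbp_mmhg + (spec.sbp_mmhg - spec.dbp_mmhg) * _beat_template(u)
        if spec.noise_sd > 0:
            w = w + rng.normal(0.0, spec.noise_sd, w.shape)
        return w

    proximal = wave(0.0)
    distal = wave(spec.delay_s)
    truth = {
        "delay_s": spec.delay_s,
        "onset_times_s": onset_frac * spec.period_s
        + spec.period_s * np.arange(spec.n_beats),
        "spec": spec,
    }
    return WaveformPair(
        fs_hz=spec.fs_hz,
        proximal=proximal,
        distal=distal,
        distance_m=spec.distance_m,
        site_pair=spec.site_pair,
        meta={"truth": truth},
    )


# ---------------------------------------------------------------------------
# Gas-exchange traces

@dataclass(frozen=True)
class GasGenSpec:
    """1-min binned VO2/VCO2 trace with one embedded steady-state segment.

    Inside [steady_start, steady_start + steady_len) flows are the resting
    values with bounded multiplicative noise (empirical CV <= cv_inside);
    outside, flows are scaled by ``activity_multiplier`` and modulated by a
    deterministic alternating pattern of amplitude 3*cv_outside, so any
    5-min window touching a non-steady bin fails the CV criterion.
    """

    duration_min: int = 20
    rest_vo2_ml_min: float = 250.0
    rest_vco2_ml_min: float = 200.0
    activity_multiplier: float = 1.2
    steady_start_min: int = 7
    steady_len_min: int = 5
    cv_inside: float = 0.02
    cv_outside: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        rer = self.rest_vco2_ml_min / self.rest_vo2_ml_min
        if not 0.7 <= rer <= 1.0:
            raise ValueError("resting RER must lie in [0.7, 1.0]")
        if not self.cv_inside <= 0.10 < self.cv_outside:
            raise ValueError("need cv_inside <= 0.10 < cv_outside")
        if self.steady_start_min < 0 or (
            self.steady_start_min + self.steady_len_min > self.duration_min
        ):
            raise ValueError("steady window must lie inside the trace")
        if self.rest_vo2_ml_min <= 0 or self.rest_vco2_ml_min < 0:
            raise ValueError("resting flows must be positive")


def generate_gas_trace(spec: GasGenSpec) -> GasTrace:
    """Generate the trace; true REE (Weir on the noiseless resting flows)
    is stored in ``meta['truth']['ree_kcal_day']``."""
    from .calorimetry import weir_ree  # local import to avoid cycle

    rng = np.random.default_rng(spec.seed)
    mins = np.arange(spec.duration_min)
    inside = (mins >= spec.steady_start_min) & (
        mins < spec.steady_start_min + spec.steady_len_min
    )
    # bounded noise inside: |e| <= 0.9*cv_inside keeps the sample CV under cv_inside
    e_in = rng.uniform(-0.9 * spec.cv_inside, 0.9 * spec.cv_inside, spec.duration_min)
    swing = 3.0 * spec.cv_outside * np.where(mins % 2 == 0, 1.0, -1.0)
    factor = np.where(
        inside, 1.0 + e_in, spec.activity_multiplier * (1.0 + swing)
    )
    vo2 = spec.rest_vo2_ml_min * factor
    vco2 = spec.rest_vco2_ml_min * factor
    truth = {
        "ree_kcal_day": weir_ree(spec.rest_vo2_ml_min, spec.rest_vco2_ml_min),
        "steady_interval_min": (
            spec.steady_start_min,
            spec.steady_start_min + spec.steady_len_min,
        ),
        "spec": spec,
    }
    return GasTrace(
        t_min=mins.astype(float) + 0.5,
        vo2_ml_min=vo2,
        vco2_ml_min=vco2,
        phase=np.array(["rest"] * spec.duration_min, dtype=object),
        meta={"truth": truth},
    )


# ---------------------------------------------------------------------------
# Crossover trial tables

@dataclass(frozen=True)
class TrialGenSpec:
    """Balanced 2-group x 4-condition x 4-timepoint crossover outcome table.

    ``effect_map`` maps (condition, timepoint, group) cells to additive mean
    shifts; unlisted cells get zero.  Participant intercepts are drawn with
    SD ``between_subject_sd``; residuals with SD ``residual_sd``.
    """

    n_per_group: int = 12
    conditions: Tuple[str, ...] = ("CON", "BIKE", "PP", "GT")
    timepoints: Tuple[str, ...] = ("rest", "10", "20", "30")
    groups: Tuple[str, ...] = ("young", "middle")
    grand_mean: float = 50.0
    between_subject_sd: float = 5.0
    residual_sd: float = 5.0
    effect_map: Tuple[Tuple[Tuple[str, str, str], float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 participants per group")
        if len(self.conditions) != 4 or len(self.timepoints) != 4:
            raise ValueError("design is 4 conditions x 4 timepoints")
        if self.between_subject_sd <= 0 or self.residual_sd <= 0:
            raise ValueError("sds must be positive")

    @property
    def effects(self) -> Dict[Tuple[str, str, str], float]:
        return dict(self.effect_map)


def generate_trial_table(spec: TrialGenSpec) -> pd.DataFrame:
    """Long-format table: one row per participant x condition x timepoint.

    True effects and variance components are recorded in
    ``df.attrs['truth']``.
    """
    rng = np.random.default_rng(spec.seed)
    effects = spec.effects
    rows = []
    for g in spec.groups:
        for p in range(spec.n_per_group):
            pid = f"{g}-{p + 1:02d}"
            intercept = rng.normal(0.0, spec.between_subject_sd)
            for c in spec.conditions:
                for tp in spec.timepoints:
                    y = (
                        spec.grand_mean
                        + intercept
                        + effects.get((c, tp, g), 0.0)
                        + rng.normal(0.0, spec.residual_sd)
                    )
                    rows.append((pid, g, c, tp, y))
    df = pd.DataFrame(
        rows, columns=["participant", "group", "condition", "timepoint", "outcome"]
    )
    df.attrs["truth"] = {
        "effects": effects,
        "between_subject_sd": spec.between_subject_sd,
        "residual_sd": spec.residual_sd,
        "spec": spec,
    }
    return df
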