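"""Readers/writers, session configuration and the end-to-end session runner.

All table formats are plain CSV (comma separator, '.' decimal, mandatory
header).  A session follows the trial layout: supine rest, a 45-minute
class (or seated control), then supine recovery re-evaluated at the 10-,
20- and 30-minute marks; `run_session` strings
preprocess -> HRV -> BRS per window mark, PWV per waveform set and
calorimetry per phase into one tidy long-format results table, logging a
quality record per stage and skipping downstream outcomes of a failed
stage instead of aborting the run.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import brs as brs_mod
from . import calorimetry as cal_mod
from . import hemodynamics as hemo_mod
from . import hrv as hrv_mod
from . import preprocess as prep_mod
from .core import BeatSeries, GasTrace, QualityError, WaveformPair

__all__ = [
    "read_beat_table",
    "write_beat_table",
    "read_waveform_pair",
    "write_waveform_pair",
    "read_gas_trace",
    "write_gas_trace",
    "read_trial_table",
    "write_trial_table",
    "SessionConfig",
    "RunLog",
    "run_session",
    "simulate_session_bundle",
    "DEFAULT_KNOBS",
]

_PRESSURE_COLS = ("sbp_mmhg", "dbp_mmhg", "map_mmhg")


# ---------------------------------------------------------------------------
# Beat tables

def read_beat_table(path) -> BeatSeries:
    """Read a beat table CSV (time_s, rr_ms, optional pressure columns).

    Duplicate-measurement column pairs (``<name>_1``/``<name>_2``) are
    averaged into ``<name>``.  Non-monotone times and non-numeric cells
    raise errors naming the offending row/column.
    """
    df = pd.read_csv(path)
    for base in _PRESSURE_COLS:
        c1, c2 = f"{base}_1", f"{base}_2"
        if c1 in df.columns and c2 in df.columns:
            df[base] = (df[c1] + df[c2]) / 2.0
    for col in ("time_s", "rr_ms"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in df.columns:
        if col in ("time_s", "rr_ms") or col in _PRESSURE_COLS:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: non-numeric cell in {col!r}: {exc}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(f"{path}: time_s not increasing at row {bad[0] + 1}")
    kw = {c: df[c].to_numpy(dtype=float) for c in _PRESSURE_COLS if c in df.columns}
    return BeatSeries(beat_time_s=t, rr_ms=df["rr_ms"].to_numpy(dtype=float), **kw)


def write_beat_table(beats: BeatSeries, path) -> None:
    data = {"time_s": beats.beat_time_s, "rr_ms": beats.rr_ms}
    for c in _PRESSURE_COLS:
        v = getattr(beats, c)
        if v is not None:
            data[c] = v
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Waveform pairs

def read_waveform_pair(path, distance_m: float, site_pair: str = "cf") -> WaveformPair:
    """Waveform CSV with columns t_s, proximal_au, distal_au."""
    df = pd.read_csv(path)
    for col in ("t_s", "proximal_au", "distal_au"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: sampling not uniform")
    return WaveformPair(
        fs_hz=1.0 / dt[0],
        proximal=df["proximal_au"].to_numpy(dtype=float),
        distal=df["distal_au"].to_numpy(dtype=float),
        distance_m=distance_m,
        site_pair=site_pair,
    )


def write_waveform_pair(pair: WaveformPair, path) -> None:
    t = np.arange(pair.proximal.size) / pair.fs_hz
    pd.DataFrame(
        {"t_s": t, "proximal_au": pair.proximal, "distal_au": pair.distal}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gas traces and trial tables

def read_gas_trace(path) -> GasTrace:
    """Gas-trace CSV: t_min, vo2_ml_min, vco2_ml_min, optional hr_bpm, phase."""
    df = pd.read_csv(path)
    for col in ("t_min", "vo2_ml_min", "vco2_ml_min"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return GasTrace(
        t_min=df["t_min"].to_numpy(dtype=float),
        vo2_ml_min=df["vo2_ml_min"].to_numpy(dtype=float),
        vco2_ml_min=df["vco2_ml_min"].to_numpy(dtype=float),
        hr_bpm=df["hr_bpm"].to_numpy(dtype=float) if "hr_bpm" in df.columns else None,
        phase=df["phase"].to_numpy(dtype=object) if "phase" in df.columns else None,
    )


def write_gas_trace(trace: GasTrace, path) -> None:
    data = {
        "t_min": trace.t_min,
        "vo2_ml_min": trace.vo2_ml_min,
        "vco2_ml_min": trace.vco2_ml_min,
    }
    if trace.hr_bpm is not None:
        data["hr_bpm"] = trace.hr_bpm
    if trace.phase is not None:
        data["phase"] = trace.phase
    pd.DataFrame(data).to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"timepoint": str})
    required = {"participant", "group", "condition", "timepoint", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: trial table lacks columns {sorted(missing)}")
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Session configuration, logging, runner

DEFAULT_KNOBS: Dict[str, object] = {
    "fs_hz": 4.0,
    "window_len_s": 120.0,
    "dev_frac": 0.2,
    "max_edit_frac": 0.2,
    "wavelet": "db12",
    "depth": 6,
    "brs_min_len": 3,
    "brs_thr_mmhg": 1.0,
    "brs_thr_ms": 4.0,
    "brs_lag_beats": 1,
    "brs_r2_min": 0.85,
    "brs_min_sequences": 3,
    "ree_search": (5.0, 15.0),
    "class_phase": "class",
}


@dataclass
class SessionConfig:
    """Everything needed to analyse one participant-session."""

    participant: str
    group: str
    condition: str
    marks_s: Dict[str, float]  # timepoint label -> window end time (s)
    beat_file: Optional[str] = None
    wave_files: Dict[str, Dict[str, str]] = field(default_factory=dict)
    # wave_files[timepoint][site] -> csv path
    site_distances_m: Dict[str, float] = field(default_factory=dict)
    gas_file: Optional[str] = None
    knobs: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        marks = list(self.marks_s.values())
        if any(b <= a for a, b in zip(marks, marks[1:])):
            raise ValueError("window marks must be strictly increasing")
        merged = dict(DEFAULT_KNOBS)
        merged.update(self.knobs)
        self.knobs = merged

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def _resolve(p):
            return str((base / p).resolve()) if p else None

        raw["beat_file"] = _resolve(raw.get("beat_file"))
        raw["gas_file"] = _resolve(raw.get("gas_file"))
        raw["wave_files"] = {
            tp: {site: _resolve(p) for site, p in sites.items()}
            for tp, sites in raw.get("wave_files", {}).items()
        }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))


class RunLog:
    """Timestamped per-stage events with quality flags."""

    def __init__(self) -> None:
        self.events: List[dict] = []

    def log(self, stage: str, status: str, **info) -> None:
        self.events.append(
            {
                "time": _dt.datetime.now().isoformat(timespec="seconds"),
                "stage": stage,
                "status": status,
                **info,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events)


def _hrv_brs_window(
    beats: BeatSeries, mark_s: float, knobs: Dict[str, object], log: RunLog
) -> Dict[str, float]:
    """HRV + BRS outcomes for the clean 2-minute window ending at a mark."""
    out: Dict[str, float] = {}
    wlen = float(knobs["window_len_s"])
    start = mark_s - wlen
    # generous trailing margin: deleting ectopic beats shortens the
    # cumulative time base, which must not uncover the window end
    seg = beats.slice_time(start - 15.0, mark_s + 25.0)
    flagged = prep_mod.flag_ectopics(seg, dev_frac=float(knobs["dev_frac"]))
    edited = prep_mod.remove_and_bridge(
        flagged, max_edit_frac=float(knobs["max_edit_frac"])
    )
    log.log(
        "preprocess", "ok",
        n_beats=len(seg), n_edited=int(edited.meta.get("n_edited", 0)),
    )

    in_win = edited.slice_time(start, mark_s)
    td = hrv_mod.time_domain(in_win.rr_ms)
    out.update(
        mean_ibi_ms=td.mean_ibi_ms, ln_ibi=td.ln_ibi,
        sdnn_ms=td.sdnn_ms, ln_sdnn=td.ln_sdnn,
        rmssd_ms=td.rmssd_ms, ln_rmssd=td.ln_rmssd,
        pnn50_pct=td.pnn50_pct,
    )
    window = prep_mod.resample_window(
        edited, start, fs_hz=float(knobs["fs_hz"]), window_len_s=wlen
    )
    sp = hrv_mod.wavelet_band_power(
        window, wavelet=str(knobs["wavelet"]), depth=int(knobs["depth"])
    )
    out.update(
        lf_ms2=sp.lf_ms2, hf_ms2=sp.hf_ms2, ln_lf=sp.ln_lf, ln_hf=sp.ln_hf,
        ln_lf_hf_ratio=sp.ln_lf_hf_ratio,
        lf_nu_pct=sp.lf_nu_pct, hf_nu_pct=sp.hf_nu_pct,
    )
    log.log("hrv", "ok", n_edited=window.n_edited)

    if in_win.sbp_mmhg is not None:
        est = brs_mod.brs_from_beats(
            in_win,
            min_len=int(knobs["brs_min_len"]),
            thr_mmhg=float(knobs["brs_thr_mmhg"]),
            thr_ms=float(knobs["brs_thr_ms"]),
            lag_beats=int(knobs["brs_lag_beats"]),
            r2_min=float(knobs["brs_r2_min"]),
            min_sequences=int(knobs["brs_min_sequences"]),
        )
        out.update(brs_ms_per_mmhg=est.brs_ms_per_mmhg, bei=est.bei)
        log.log("brs", "ok", n_sequences=est.n_sequences, n_ramps=est.n_ramps)
    return out


def run_session(config: SessionConfig) -> pd.DataFrame:
    """Run the full pipeline for one session; returns a tidy results table.

    One row per (outcome, timepoint); a quality failure in one stage is
    logged and that stage's outcomes are skipped, the run continues.  The
    RunLog is attached as ``df.attrs['runlog']``.
    """
    log = RunLog()
    knobs = config.knobs
    rows: List[tuple] = []

    def add(timepoint: str, outcomes: Dict[str, float]) -> None:
        for name, value in outcomes.items():
            rows.append(
                (config.participant, config.group, config.condition,
                 timepoint, name, value)
            )

    beats = None
    if config.beat_file:
        beats = read_beat_table(config.beat_file)
        log.log("read_beats", "ok", n_beats=len(beats))

    for tp, mark in config.marks_s.items():
        if beats is not None:
            log.log("window", "start", timepoint=tp, mark_s=mark)
            try:
                add(tp, _hrv_brs_window(beats, mark, knobs, log))
            except QualityError as exc:
                log.log("window", "quality_error", timepoint=tp, error=str(exc))
        for site, path in config.wave_files.get(tp, {}).items():
            try:
                pair = read_waveform_pair(
                    path, distance_m=config.site_distances_m[site], site_pair=site
                )
                res = hemo_mod.transit_and_pwv(pair)
                add(tp, {f"{site}_pwv_m_s": res.pwv_m_s})
                log.log("pwv", "ok", timepoint=tp, site=site,
                        n_beats=res.n_beats_used, valid=res.valid)
            except QualityError as exc:
                log.log("pwv", "quality_error", timepoint=tp, site=site,
                        error=str(exc))

    if config.gas_file:
        trace = read_gas_trace(config.gas_file)
        try:
            rest_sel = trace.phase == "rest"
            rest_trace = GasTrace(
                t_min=trace.t_min[rest_sel],
                vo2_ml_min=trace.vo2_ml_min[rest_sel],
                vco2_ml_min=trace.vco2_ml_min[rest_sel],
            )
            interval, ree = cal_mod.find_steady_state(
                rest_trace, search=tuple(knobs["ree_search"])
            )
            log.log("calorimetry", "steady_state", interval=interval)
            energy = cal_mod.session_energy(
                trace, ree, phase=str(knobs["class_phase"])
            )
            add("session", {
                "ree_kcal_day": ree,
                "tee_kcal": energy.tee_kcal,
                "aee_kcal": energy.aee_kcal,
            })
            log.log("calorimetry", "ok", negative_aee=energy.negative_aee)
        except QualityError as exc:
            log.log("calorimetry", "quality_error", error=str(exc))

    df = pd.DataFrame(
        rows,
        columns=["participant", "group", "condition", "timepoint",
                 "outcome", "value"],
    )
    df.attrs["runlog"] = log
    return df


# ---------------------------------------------------------------------------
# Synthetic session bundles (fixture generation for tests / demos)

def simulate_session_bundle(
    outdir,
    participant: str = "young-01",
    group: str = "young",
    condition: str = "BIKE",
    seed: int = 0,
) -> SessionConfig:
    """Write a complete synthetic session (beats, waves, gas) to ``outdir``
    and return a ready-to-run :class:`SessionConfig`.

    Beat-to-beat SBP is coupled to RR with a 10 ms/mmHg slope so the
    sequence method has material to work with; waveform pairs embed known
    transit delays; the gas trace embeds a compliant resting steady state
    and a 45-minute class phase.
    """
    from .calorimetry import weir_ree  # noqa: F401  (documentation aid)
    from .synthetic import (
        GasGenSpec, RRGenSpec, WaveGenSpec,
        generate_gas_trace, generate_rr, generate_wave_pair,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    marks = {"rest": 180.0, "post10": 480.0, "post20": 780.0, "post30": 1080.0}
    rr_spec = RRGenSpec(
        duration_s=1120.0, mean_rr_ms=820.0,
        lf_amp_ms=25.0, lf_freq_hz=0.1, hf_amp_ms=30.0, hf_freq_hz=0.25,
        noise_sd_ms=10.0, ectopic_rate_per_min=1.0, seed=int(rng.integers(2**31)),
    )
    beats = generate_rr(rr_spec)
    # SBP tied to RR at ~10 ms/mmHg (lag 0): gives the sequence method
    # concordant ramps without a separate pressure model
    sbp = 118.0 + (beats.rr_ms - rr_spec.mean_rr_ms) / 10.0
    dbp = sbp - 45.0
    beats.sbp_mmhg = sbp
    beats.dbp_mmhg = dbp
    beats.map_mmhg = dbp + 45.0 / 3.0
    beat_path = outdir / "beats.csv"
    write_beat_table(beats, beat_path)

    sites = {"cf": (0.875, 0.100), "cr": (0.50, 0.050), "cd": (1.20, 0.150)}
    wave_files: Dict[str, Dict[str, str]] = {}
    for tp in marks:
        wave_files[tp] = {}
        for site, (dist, delay) in sites.items():
            spec = WaveGenSpec(
                delay_s=delay, distance_m=dist, site_pair=site,
                n_beats=12, noise_sd=0.2, seed=int(rng.integers(2**31)),
            )
            path = outdir / f"wave_{tp}_{site}.csv"
            write_waveform_pair(generate_wave_pair(spec), path)
            wave_files[tp][site] = str(path)

    rest = generate_gas_trace(GasGenSpec(seed=int(rng.integers(2**31))))
    class_mult = 1.0 if condition == "CON" else 8.0
    n_class, n_rec = 45, 30
    noise = rng.normal(1.0, 0.05, n_class + n_rec)
    vo2_rest0 = rest.meta["truth"]["spec"].rest_vo2_ml_min
    vco2_rest0 = rest.meta["truth"]["spec"].rest_vco2_ml_min
    vo2_ext = np.concatenate(
        [vo2_rest0 * class_mult * noise[:n_class], vo2_rest0 * 1.3 * noise[n_class:]]
    )
    vco2_ext = np.concatenate(
        [vco2_rest0 * class_mult * noise[:n_class],
         vco2_rest0 * 1.3 * noise[n_class:]]
    )
    trace = GasTrace(
        t_min=np.concatenate(
            [rest.t_min, rest.t_min[-1] + 0.5 + np.arange(n_class + n_rec) + 0.5]
        ),
        vo2_ml_min=np.concatenate([rest.vo2_ml_min, vo2_ext]),
        vco2_ml_min=np.concatenate([rest.vco2_ml_min, vco2_ext]),
        phase=np.array(
            ["rest"] * len(rest) + ["class"] * n_class + ["recovery"] * n_rec,
            dtype=object,
        ),
    )
    gas_path = outdir / "gas.csv"
    write_gas_trace(trace, gas_path)

    return SessionConfig(
        participant=participant,
        group=group,
        condition=condition,
        marks_s=marks,
        beat_file=str(beat_path),
        wave_files=wave_files,
        site_distances_m={s: d for s, (d, _) in sites.items()},
        gas_file=str(gas_path),
        knobs={"brs_lag_beats": 0},
    )
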