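"""Artifact editing and uniform resampling of RR beat streams.

The spectral HRV stage needs an evenly sampled tachogram; beat streams are
irregular and contaminated by ectopic beats.  The pipeline here is

    flag_ectopics -> remove_and_bridge -> resample_window

i.e. mark beats deviating from a local median, delete them and bridge the
gaps by piecewise-cubic interpolation of the surviving RR-vs-time curve,
then cubic-spline resample a 2-minute window onto a uniform grid
(default 4 Hz, comfortably above twice the 0.4 Hz upper HF edge).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .core import BeatSeries, QualityError, TachogramWindow

__all__ = ["flag_ectopics", "remove_and_bridge", "resample_window"]

#: half-width of the local median window (beats on each side)
_HALF_WIN = 5


def flag_ectopics(beats: BeatSeries, dev_frac: float = 0.2) -> BeatSeries:
    """Flag beats deviating from an 11-beat local median by more than
    ``dev_frac`` (fractional).

    Beat i is flagged iff ``|rr[i] - median(rr[i-5..i+5] \\ {i})| >
    dev_frac * median``.  Returns a flagged copy; the input is not
    modified.  Series shorter than the local window are returned unflagged
    with a warning.
    """
    out = beats.copy()
    n = len(beats)
    if n < 2 * _HALF_WIN + 1:
        warnings.warn(
            f"series of {n} beats is shorter than the {2 * _HALF_WIN + 1}-beat "
            "median window; nothing flagged",
            stacklevel=2,
        )
        return out
    rr = beats.rr_ms
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - _HALF_WIN)
        hi = min(n, i + _HALF_WIN + 1)
        neigh = np.concatenate([rr[lo:i], rr[i + 1 : hi]])
        med = np.median(neigh)
        flags[i] = abs(rr[i] - med) > dev_frac * med
    out.flags = flags
    out.meta["n_flagged"] = int(flags.sum())
    return out


def remove_and_bridge(beats: BeatSeries, max_edit_frac: float = 0.2) -> BeatSeries:
    """Delete flagged beats and bridge each gap by interpolating the
    surrounding unflagged RR-vs-time curve (monotone piecewise cubic).

    Beat times are rebuilt as cumulative RR sums from the first kept beat,
    restoring the rr <-> time invariant.  Aborts with :class:`QualityError`
    when more than ``max_edit_frac`` of beats are flagged (window unusable).
    """
    n = len(beats)
    n_flag = beats.n_flagged
    if n_flag == 0:
        out = beats.copy()
        out.meta.setdefault("n_edited", 0)
        return out
    if n_flag > max_edit_frac * n:
        raise QualityError(
            f"{n_flag}/{n} beats flagged exceeds the {max_edit_frac:.0%} "
            "editing limit; window unusable"
        )

    keep = ~beats.flags
    t_keep = beats.beat_time_s[keep]
    rr_keep = beats.rr_ms[keep].copy()
    orig_idx = np.flatnonzero(keep)
    # a kept beat whose immediate predecessor was removed needs its RR
    # re-estimated: the recorded interval spans the deleted beat(s)
    affected = np.zeros(orig_idx.size, dtype=bool)
    affected[1:] = np.diff(orig_idx) > 1
    if orig_idx[0] > 0:
        affected[0] = False  # no predecessor left to span
    good = ~affected
    if good.sum() < 2:
        raise QualityError("too few clean beats to bridge gaps")
    interp = PchipInterpolator(t_keep[good], rr_keep[good], extrapolate=True)
    rr_keep[affected] = interp(t_keep[affected])

    t_new = t_keep[0] + np.concatenate([[0.0], np.cumsum(rr_keep[1:]) / 1000.0])
    kw = {}
    for name in ("sbp_mmhg", "dbp_mmhg", "map_mmhg"):
        v = getattr(beats, name)
        kw[name] = None if v is None else v[keep]
    meta = dict(beats.meta)
    meta["n_edited"] = int(n_flag)
    return BeatSeries(beat_time_s=t_new, rr_ms=rr_keep, meta=meta, **kw)


def resample_window(
    beats: BeatSeries,
    start_s: float,
    fs_hz: float = 4.0,
    window_len_s: float = 120.0,
    max_gap_s: float = 3.0,
) -> TachogramWindow:
    """Cubic-spline resample RR-vs-beat-time onto a uniform grid.

    The window is ``[start_s, start_s + window_len_s)`` sampled at
    ``fs_hz`` (``fs_hz * window_len_s`` must be an integer).  Beats must
    cover the window fully, with no inter-beat gap larger than
    ``max_gap_s``; otherwise a :class:`QualityError` is raised.
    """
    n_samp = fs_hz * window_len_s
    if abs(n_samp - round(n_samp)) > 1e-9:
        raise ValueError("fs_hz * window_len_s must be an integer sample count")
    end_s = start_s + window_len_s
    t = beats.beat_time_s
    rr = beats.rr_ms
    if t.size < 4:
        raise QualityError("too few beats to fit a cubic spline")
    if t[0] > start_s or t[-1] < end_s:
        raise QualityError(
            f"beats cover [{t[0]:.2f}, {t[-1]:.2f}] s; window "
            f"[{start_s:.2f}, {end_s:.2f}] s not fully covered"
        )
    in_win = (t >= start_s) & (t <= end_s)
    t_span = t[in_win]
    if t_span.size >= 2 and np.max(np.diff(t_span)) > max_gap_s:
        raise QualityError(f"coverage gap exceeds {max_gap_s} s inside the window")

    spline = CubicSpline(t, rr)
    grid = start_s + np.arange(int(round(n_samp))) / fs_hz
    values = spline(grid)
    return TachogramWindow(
        fs_hz=fs_hz,
        values_ms=values,
        start_s=start_s,
        window_len_s=window_len_s,
        n_edited=int(beats.meta.get("n_edited", 0)),
        meta=dict(beats.meta),
    )
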