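"""Spontaneous sequence-method baroreflex sensitivity (BRS).

The sequence method scans beat-to-beat systolic pressure for spontaneous
ramps — runs of >= 3 consecutive same-direction changes each exceeding
1 mmHg — and pairs each ramp with the RR-interval segment at a configurable
beat lag.  When the RR segment moves concordantly with per-beat changes
exceeding 4 ms and the RR-on-SBP regression is tight enough (r^2 >= 0.85
by default), the ramp/RR pair is a baroreflex sequence and its regression
slope estimates the reflex gain in ms/mmHg.  BRS is the mean slope over
valid sequences; the baroreflex effectiveness index (BEI) is the fraction
of ramps that produced a sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import stats

from .core import BeatSeries, QualityError

__all__ = [
    "Ramp",
    "BaroSequence",
    "BRSEstimate",
    "detect_ramps",
    "pair_sequences",
    "estimate_brs",
    "brs_from_beats",
]


@dataclass(frozen=True)
class Ramp:
    start_beat: int
    end_beat: int  # inclusive
    direction: int  # +1 up, -1 down
    deltas_mmhg: tuple

    @property
    def n_beats(self) -> int:
        return self.end_beat - self.start_beat + 1


@dataclass(frozen=True)
class BaroSequence:
    ramp: Ramp
    rr_deltas_ms: tuple
    lag_beats: int
    slope_ms_per_mmhg: float
    r: float


@dataclass(frozen=True)
class BRSEstimate:
    brs_ms_per_mmhg: float
    n_sequences: int
    n_up: int
    n_down: int
    n_ramps: int
    bei: float


def detect_ramps(
    sbp_mmhg: Sequence[float], min_len: int = 3, thr_mmhg: float = 1.0
) -> List[Ramp]:
    """Maximal runs of >= ``min_len`` beats whose consecutive SBP changes
    are same-signed and each exceed ``thr_mmhg`` in magnitude."""
    sbp = np.asarray(sbp_mmhg, dtype=float)
    if sbp.size < min_len:
        return []
    d = np.diff(sbp)
    sign = np.where(d > thr_mmhg, 1, np.where(d < -thr_mmhg, -1, 0))
    ramps: List[Ramp] = []
    i = 0
    while i < sign.size:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < sign.size and sign[j + 1] == sign[i]:
            j += 1
        # diffs i..j -> beats i..j+1
        if (j - i + 2) >= min_len:
            ramps.append(
                Ramp(
                    start_beat=i,
                    end_beat=j + 1,
                    direction=int(sign[i]),
                    deltas_mmhg=tuple(d[i : j + 1]),
                )
            )
        i = j + 1
    return ramps


def pair_sequences(
    ramps: Sequence[Ramp],
    rr_ms: Sequence[float],
    lag_beats: int = 1,
    thr_ms: float = 4.0,
    r2_min: float = 0.85,
    sbp_mmhg: Sequence[float] | None = None,
) -> List[BaroSequence]:
    """Pair each SBP ramp with its lagged RR segment; keep concordant,
    supra-threshold, well-correlated pairs.

    ``sbp_mmhg`` is needed for the regression; when omitted, slopes are
    computed from the cumulative deltas stored on the ramp (equivalent up
    to an additive constant).
    """
    rr = np.asarray(rr_ms, dtype=float)
    sequences: List[BaroSequence] = []
    for ramp in ramps:
        lo = ramp.start_beat + lag_beats
        hi = ramp.end_beat + lag_beats
        if hi >= rr.size:
            continue  # lag pushes segment out of range; ramp skipped
        seg = rr[lo : hi + 1]
        d_rr = np.diff(seg)
        if not np.all(ramp.direction * d_rr > thr_ms):
            continue
        if sbp_mmhg is not None:
            x = np.asarray(sbp_mmhg, dtype=float)[ramp.start_beat : ramp.end_beat + 1]
        else:
            x = np.concatenate([[0.0], np.cumsum(ramp.deltas_mmhg)])
        res = stats.linregress(x, seg)
        if res.rvalue**2 < r2_min:
            continue
        sequences.append(
            BaroSequence(
                ramp=ramp,
                rr_deltas_ms=tuple(d_rr),
                lag_beats=lag_beats,
                slope_ms_per_mmhg=float(res.slope),
                r=float(res.rvalue),
            )
        )
    return sequences


def estimate_brs(
    sequences: Sequence[BaroSequence],
    n_ramps: int,
    min_sequences: int = 3,
) -> BRSEstimate:
    """Mean sequence slope, sequence counts and BEI.

    Raises :class:`QualityError` when fewer than ``min_sequences`` valid
    sequences exist, distinguishing 'no SBP ramps at all' from 'ramps
    without an RR response'.
    """
    if len(sequences) < min_sequences:
        if n_ramps == 0:
            raise QualityError("no SBP ramps detected; pressure signal too flat")
        raise QualityError(
            f"only {len(sequences)} baroreflex sequences among {n_ramps} ramps "
            f"(minimum {min_sequences}); RR response absent or noisy"
        )
    slopes = np.array([s.slope_ms_per_mmhg for s in sequences])
    n_up = sum(1 for s in sequences if s.ramp.direction > 0)
    return BRSEstimate(
        brs_ms_per_mmhg=float(np.mean(slopes)),
        n_sequences=len(sequences),
        n_up=n_up,
        n_down=len(sequences) - n_up,
        n_ramps=int(n_ramps),
        bei=len(sequences) / n_ramps if n_ramps else float("nan"),
    )


def brs_from_beats(
    beats: BeatSeries,
    min_len: int = 3,
    thr_mmhg: float = 1.0,
    thr_ms: float = 4.0,
    lag_beats: int = 1,
    r2_min: float = 0.85,
    min_sequences: int = 3,
) -> BRSEstimate:
    """Convenience wrapper: ramps -> sequences -> estimate on a BeatSeries."""
    if beats.sbp_mmhg is None:
        raise ValueError("BeatSeries carries no SBP; sequence method needs it")
    ramps = detect_ramps(beats.sbp_mmhg, min_len=min_len, thr_mmhg=thr_mmhg)
    seqs = pair_sequences(
        ramps,
        beats.rr_ms,
        lag_beats=lag_beats,
        thr_ms=thr_ms,
        r2_min=r2_min,
        sbp_mmhg=beats.sbp_mmhg,
    )
    return estimate_brs(seqs, n_ramps=len(ramps), min_sequences=min_sequences)
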