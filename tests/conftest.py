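import numpy as np
import pytest

from pulsekit.core import TachogramWindow
from pulsekit.synthetic import RRGenSpec, generate_rr
from pulsekit.preprocess import flag_ectopics, remove_and_bridge, resample_window


def make_tone_window(freq_hz: float, amp_ms: float, fs_hz: float = 4.0,
                     duration_s: float = 120.0) -> TachogramWindow:
    """Directly sampled pure-tone tachogram (no beat sampling involved)."""
    t = np.arange(int(fs_hz * duration_s)) / fs_hz
    values = 800.0 + amp_ms * np.sin(2 * np.pi * freq_hz * t)
    return TachogramWindow(fs_hz=fs_hz, values_ms=values,
                          window_len_s=duration_s)


def tone_window_from_beats(freq_hz: float, amp_ms: float, seed: int,
                           noise_sd_ms: float = 0.0) -> TachogramWindow:
    """Tone tachogram generated as beats and run through the preprocessing
    chain (flag -> bridge -> spline resample), as the pipeline would."""
    if freq_hz < 0.15:
        spec = RRGenSpec(duration_s=130.0, lf_amp_ms=amp_ms, lf_freq_hz=freq_hz,
                         noise_sd_ms=noise_sd_ms, seed=seed)
    else:
        spec = RRGenSpec(duration_s=130.0, hf_amp_ms=amp_ms, hf_freq_hz=freq_hz,
                         noise_sd_ms=noise_sd_ms, seed=seed)
    beats = generate_rr(spec)
    edited = remove_and_bridge(flag_ectopics(beats))
    return resample_window(edited, start_s=edited.beat_time_s[0] + 1.0)


@pytest.fixture(scope="session")
def session_bundle(tmp_path_factory):
    """One synthetic session bundle on disk, shared across IO tests."""
    from pulsekit.io import simulate_session_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    cfg = simulate_session_bundle(outdir, seed=11)
    return cfg
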