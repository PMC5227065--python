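"""Signal conditioning: MUA envelope extraction, LFP filtering, channel QC.

All filters are zero-phase 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), so the latency analysis downstream is not biased by filter
group delay.  The MUA envelope is the classic band-pass (500 Hz-5 kHz) ->
full-wave rectify -> low-pass (200 Hz) chain; the LFP is low-passed below
200 Hz and resampled to 763 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import window_mask

MUA_BAND_HZ = (500.0, 5000.0)
MUA_LOWPASS_HZ = 200.0
LFP_LOWPASS_HZ = 200.0
LFP_FS_HZ = 763.0
SNR_THRESHOLD = 3.0


@dataclass
class ChannelQC:
    """Per-channel signal-to-noise ratio and exclusion flags (SNR < 3)."""

    snr: np.ndarray
    excluded: np.ndarray
    threshold: float = SNR_THRESHOLD


def _butter_sos(kind: str, corners, fs: float):
    return signal.butter(4, corners, btype=kind, fs=fs, output="sos")


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if fs_in == fs_out:
        return x
    frac = Fraction(fs_out / fs_in).limit_denominator(1_000_000)
    # padtype="line" extends edges linearly, avoiding the zero-padding
    # transients a polyphase resampler would otherwise leave on short epochs
    return signal.resample_poly(
        x, frac.numerator, frac.denominator, axis=-1, padtype="line"
    )


def mua_envelope(
    wideband: np.ndarray,
    fs_wb: float,
    fs_out: float = LFP_FS_HZ,
    preamp_correction=None,
) -> np.ndarray:
    """Multi-unit activity envelope from a wideband extracellular signal.

    Band-pass 500 Hz-5 kHz, full-wave rectify, low-pass 200 Hz, resample to
    ``fs_out`` (763 Hz by default so MUA and LFP share a time base).  The
    result is clipped at zero: rectification makes the ideal envelope
    nonnegative and the final low-pass can only undershoot by ringing.

    ``preamp_correction`` is an optional hook ``f(x, fs) -> x`` applied first
    (identity by default); the hardware transfer-function correction is not
    part of this package.
    """
    x = np.asarray(wideband, dtype=float)
    if fs_wb <= 2 * MUA_BAND_HZ[1]:
        raise ValueError(
            f"fs_wb={fs_wb} Hz too low for the {MUA_BAND_HZ[1]} Hz band edge"
        )
    if preamp_correction is not None:
        x = preamp_correction(x, fs_wb)
    sos_bp = _butter_sos("bandpass", MUA_BAND_HZ, fs_wb)
    x = signal.sosfiltfilt(sos_bp, x, axis=-1)
    x = np.abs(x)
    sos_lp = _butter_sos("lowpass", MUA_LOWPASS_HZ, fs_wb)
    x = signal.sosfiltfilt(sos_lp, x, axis=-1)
    return np.maximum(_resample(x, fs_wb, fs_out), 0.0)


def condition_lfp(
    raw: np.ndarray,
    fs: float,
    fs_out: float = LFP_FS_HZ,
    preamp_correction=None,
) -> np.ndarray:
    """Low-pass (<200 Hz) and resample the raw signal to the LFP rate."""
    x = np.asarray(raw, dtype=float)
    if fs < fs_out:
        raise ValueError(f"input rate {fs} Hz below the target {fs_out} Hz")
    if preamp_correction is not None:
        x = preamp_correction(x, fs)
    if fs > 2 * LFP_LOWPASS_HZ:
        sos = _butter_sos("lowpass", LFP_LOWPASS_HZ, fs)
        x = signal.sosfiltfilt(sos, x, axis=-1)
    return _resample(x, fs, fs_out)


def compute_snr(
    mua: np.ndarray,
    times_ms: np.ndarray,
    baseline_window=(-150.0, 0.0),
    peak_search_window=(25.0, 150.0),
    threshold: float = SNR_THRESHOLD,
) -> ChannelQC:
    """Stimulus-evoked SNR per channel on the trial-averaged response.

    SNR = (peak of the trial-averaged response in the search window, above
    the baseline mean) / (s.d. of the trial-averaged activity in the
    pre-stimulus period).  Channels below ``threshold`` (default 3) are
    flagged for exclusion.
    """
    mua = np.asarray(mua, dtype=float)
    if mua.ndim != 3 or mua.shape[0] < 2:
        raise ValueError("need (n_trials >= 2, n_channels, n_time)")
    avg = mua.mean(axis=0)
    mb = window_mask(times_ms, baseline_window)
    mp = window_mask(times_ms, peak_search_window)
    base_mean = avg[:, mb].mean(axis=1)
    base_sd = avg[:, mb].std(axis=1, ddof=1)
    if np.any(base_sd == 0):
        raise ValueError("zero pre-stimulus variance on some channel")
    peak = avg[:, mp].max(axis=1) - base_mean
    snr = peak / base_sd
    return ChannelQC(snr=snr, excluded=snr < threshold, threshold=threshold)


def interpolate_bad_channels(lfp: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    """Replace excluded channels by depth interpolation of good neighbours.

    Interior bad channels get the linear interpolation between the nearest
    good channel on each side; bad channels at the probe ends copy the
    nearest good channel.  Idempotent, and the identity when nothing is
    excluded.
    """
    lfp = np.asarray(lfp, dtype=float)
    excluded = np.asarray(excluded, dtype=bool)
    n_ch = lfp.shape[-2]
    if excluded.size != n_ch:
        raise ValueError("excluded mask length does not match channels")
    good = np.flatnonzero(~excluded)
    if good.size == 0:
        raise ValueError("all channels excluded")
    if excluded.sum() >= 0.5 * n_ch:
        raise ValueError(">= 50% of channels excluded; refusing to interpolate")
    out = lfp.copy()
    for ch in np.flatnonzero(excluded):
        below = good[good < ch]
        above = good[good > ch]
        if below.size and above.size:
            lo, hi = below[-1], above[0]
            w = (ch - lo) / (hi - lo)
            out[..., ch, :] = (1 - w) * lfp[..., lo, :] + w * lfp[..., hi, :]
        elif above.size:  # bad channels at the tip: nearest-neighbour extend
            out[..., ch, :] = lfp[..., above[0], :]
        else:
            out[..., ch, :] = lfp[..., below[-1], :]
    return out
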