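"""Response normalisation, modulation profiles, latency, band power, RF.

The MUA at each site is normalised by subtracting spontaneous activity
(-150-0 ms) and dividing by the peak response (max in 50-90 ms) of that site
in the distractor condition, so modulation values read as fractions of the
visual peak.  Latency is the time the fitted Gaussian + cumulative-Gaussian
curve reaches 33% of its maximum above offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal
from scipy.stats import norm

from .alignment import AlignmentResult
from .core import window_mask


@dataclass(frozen=True)
class AnalysisWindows:
    """Analysis windows in ms relative to stimulus onset."""

    baseline: tuple = (-150.0, 0.0)
    peak: tuple = (50.0, 90.0)
    modulation: tuple = (200.0, 750.0)
    mask_during: tuple = (450.0, 550.0)
    mask_after: tuple = (650.0, 750.0)
    capacity_late: tuple = (900.0, 1150.0)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            start, end = getattr(self, name)
            if not start < end:
                raise ValueError(f"window {name}: start must precede end")


@dataclass
class NormalizedMUA:
    """Baseline-subtracted, peak-normalised MUA with a channel validity mask."""

    values: np.ndarray  # (n_trials, n_channels, n_time)
    valid_channels: np.ndarray
    baseline: np.ndarray
    peak: np.ndarray
    reference_condition: str


@dataclass
class ModulationProfile:
    """Per-channel and per-compartment condition difference over a window."""

    per_channel: np.ndarray
    rel_depth_mm: np.ndarray
    compartment_means: dict
    window_ms: tuple
    pair: tuple
    penetration_id: str = ""


@dataclass
class LatencyFit:
    """Gaussian + cumulative-Gaussian fit of a response time course."""

    params: dict
    latency_ms: float
    rss: float
    r_squared: float


def normalize_mua(
    mua: np.ndarray,
    times_ms: np.ndarray,
    conditions,
    windows: AnalysisWindows = AnalysisWindows(),
    reference_condition: str = "distractor",
) -> NormalizedMUA:
    """Normalise MUA per recording site.

    value -> (value - spontaneous mean) / (reference-condition peak), where
    the spontaneous mean is taken over the baseline window across all trials
    and the peak is the maximum of the reference condition's trial average
    in the peak window, above baseline.  Sites whose reference peak is not
    positive are flagged invalid and excluded from downstream profiles.
    """
    mua = np.asarray(mua, dtype=float)
    conditions = np.asarray(conditions)
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    mb = window_mask(times_ms, windows.baseline)
    mp = window_mask(times_ms, windows.peak)
    baseline = mua[:, :, mb].mean(axis=(0, 2))
    ref_avg = mua[conditions == reference_condition].mean(axis=0)
    peak = ref_avg[:, mp].max(axis=1) - baseline
    valid = peak > 0
    safe_peak = np.where(valid, peak, np.nan)
    values = (mua - baseline[None, :, None]) / safe_peak[None, :, None]
    return NormalizedMUA(
        values=values,
        valid_channels=valid,
        baseline=baseline,
        peak=peak,
        reference_condition=reference_condition,
    )


def modulation_profile(
    norm: NormalizedMUA,
    conditions,
    times_ms: np.ndarray,
    alignment: AlignmentResult,
    window_ms=(200.0, 750.0),
    pair=("target", "distractor"),
    penetration_id: str = "",
) -> ModulationProfile:
    """Window-mean condition difference per channel and compartment.

    The per-channel value is mean(target) - mean(distractor) of the
    normalised MUA over the window; compartment entries are means of their
    member channels (valid channels only).
    """
    conditions = np.asarray(conditions)
    for cond in pair:
        if cond not in conditions:
            raise ValueError(f"condition {cond!r} missing from the trial table")
    m = window_mask(times_ms, window_ms)
    avg = {
        cond: norm.values[conditions == cond][:, :, m].mean(axis=(0, 2))
        for cond in pair
    }
    diff = avg[pair[0]] - avg[pair[1]]
    diff = np.where(norm.valid_channels, diff, np.nan)
    comp_means = {}
    for comp in ("deep", "layer4", "superficial"):
        sel = (alignment.compartment == comp) & norm.valid_channels
        comp_means[comp] = float(diff[sel].mean()) if sel.any() else np.nan
    return ModulationProfile(
        per_channel=diff,
        rel_depth_mm=alignment.rel_depth_mm.copy(),
        compartment_means=comp_means,
        window_ms=tuple(window_ms),
        pair=tuple(pair),
        penetration_id=penetration_id,
    )


# ---------------------------------------------------------------------------
# latency
# ---------------------------------------------------------------------------

def _latency_model(t, offset, a_g, mu_g, sd_g, a_c, mu_c, sd_c):
    return (
        offset
        + a_g * np.exp(-0.5 * ((t - mu_g) / sd_g) ** 2)
        + a_c * norm.cdf((t - mu_c) / sd_c)
    )


def fit_latency(
    response: np.ndarray,
    times_ms: np.ndarray,
    criterion: float = 0.33,
) -> LatencyFit:
    """Fit Gaussian + cumulative Gaussian; latency at 33% of the maximum.

    The latency is the earliest time at which the fitted curve, above its
    fitted offset, reaches ``criterion`` (default 33%) of its maximum within
    the fitted time range; the crossing is located by bisection on the
    continuous model, so resolution is not limited by the sampling grid.
    """
    y = np.asarray(response, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    if y.shape != t.shape:
        raise ValueError("response and times must have the same shape")
    span = t[-1] - t[0]
    offset0 = float(np.median(y[: max(3, y.size // 10)]))
    peak_idx = int(np.argmax(y))
    amp = float(y.max() - offset0)
    if amp <= 0:
        raise ValueError("response contains no rise above its initial level")
    above = np.flatnonzero(y - offset0 >= 0.5 * amp)
    mu0 = float(t[above[0]]) if above.size else float(t[peak_idx])
    p0 = [offset0, amp, float(t[peak_idx]), 10.0, amp / 2, mu0, 10.0]
    lb = [y.min() - abs(amp), 0.0, t[0], 1.0, 0.0, t[0], 1.0]
    ub = [y.max(), 4 * amp, t[-1], span, 4 * amp, t[-1], span]
    p0 = np.clip(p0, lb, ub)
    try:
        popt, _ = optimize.curve_fit(
            _latency_model, t, y, p0=p0, bounds=(lb, ub), maxfev=20000
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"latency fit did not converge (init={p0}): {err}"
        ) from err
    names = ("offset", "a_g", "mu_g", "sd_g", "a_c", "mu_c", "sd_c")
    params = dict(zip(names, popt))
    fine = np.linspace(t[0], t[-1], max(4096, 8 * t.size))
    curve = _latency_model(fine, *popt) - params["offset"]
    peak = curve.max()
    if peak <= 0:
        raise RuntimeError("fitted curve has no maximum above its offset")
    thresh = criterion * peak
    idx = np.flatnonzero(curve >= thresh)
    if idx.size == 0 or idx[0] == 0:
        latency = float(fine[idx[0]] if idx.size else fine[0])
    else:
        f = lambda x: _latency_model(x, *popt) - params["offset"] - thresh
        latency = float(optimize.brentq(f, fine[idx[0] - 1], fine[idx[0]]))
    resid = y - _latency_model(t, *popt)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return LatencyFit(
        params=params,
        latency_ms=latency,
        rss=rss,
        r_squared=1.0 - rss / tss if tss > 0 else np.nan,
    )


# ---------------------------------------------------------------------------
# LFP band power
# ---------------------------------------------------------------------------

def band_power(
    lfp: np.ndarray,
    fs: float,
    band_hz,
    times_ms: np.ndarray | None = None,
    window_ms=None,
) -> np.ndarray:
    """Mean spectral power in a frequency band (Welch estimate).

    Integrates the Welch periodogram over ``band_hz``; with ``times_ms`` and
    ``window_ms`` the estimate is restricted to an analysis window.  Works on
    any array whose last axis is time (e.g. trial x time for per-trial
    power).  Segments are half the window with 50% overlap.
    """
    lo, hi = band_hz
    if not 0 <= lo < hi:
        raise ValueError("band must satisfy 0 <= low < high")
    if hi > fs / 2:
        raise ValueError(f"band edge {hi} Hz beyond Nyquist ({fs / 2} Hz)")
    x = np.asarray(lfp, dtype=float)
    if window_ms is not None:
        if times_ms is None:
            raise ValueError("times_ms required with window_ms")
        x = x[..., window_mask(times_ms, window_ms)]
    nperseg = max(8, x.shape[-1] // 2)
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg, axis=-1)
    sel = (freqs >= lo) & (freqs <= hi)
    if sel.sum() < 2:
        raise ValueError("band too narrow for the spectral resolution")
    return np.trapezoid(psd[..., sel], freqs[sel], axis=-1)


# ---------------------------------------------------------------------------
# receptive-field geometry from moving-bar sweeps
# ---------------------------------------------------------------------------

@dataclass
class RFEstimate:
    """Receptive-field geometry recovered from eight bar sweeps."""

    center_deg: tuple
    width_deg: float
    height_deg: float
    extent_by_axis: dict
    eccentricity_deg: float


def rf_from_bar(
    responses: dict,
    times_ms: np.ndarray,
    origins: dict,
    speed_deg_per_s: float,
    threshold_frac: float = 0.5,
) -> RFEstimate:
    """RF centre and extent from responses to a bar moving in 8 directions.

    For each direction the response onset/offset times (first/last crossing
    of ``threshold_frac`` x max) are mapped to bar positions along the sweep
    axis.  Response latency shifts onset and offset positions in the
    direction of motion, so for each axis the RF edges are the midpoints of
    the onset position from one direction and the offset position from the
    opposing direction: the latency bias cancels.

    Parameters
    ----------
    responses : {direction_deg: ndarray}
        Response time course for each of the eight directions
        0, 45, ..., 315 (direction of bar motion, deg).
    origins : {direction_deg: (x, y)}
        Bar position (deg) at t = 0 for each sweep.
    speed_deg_per_s : float
        Bar speed, constant across sweeps.
    """
    needed = set(range(0, 360, 45))
    missing = needed - set(int(d) % 360 for d in responses)
    if missing:
        raise ValueError(f"missing sweep directions: {sorted(missing)}")
    t_s = np.asarray(times_ms, dtype=float) / 1000.0

    def edge_positions(d):
        y = np.asarray(responses[d], dtype=float)
        thr = threshold_frac * y.max()
        if y.max() <= 0:
            raise ValueError(f"no response for direction {d}")
        above = np.flatnonzero(y >= thr)
        t_on, t_off = t_s[above[0]], t_s[above[-1]]
        u = np.array([np.cos(np.deg2rad(d)), np.sin(np.deg2rad(d))])
        o = np.asarray(origins[d], dtype=float)
        s_on = (o + speed_deg_per_s * t_on * u) @ u
        s_off = (o + speed_deg_per_s * t_off * u) @ u
        return s_on, s_off

    centers, extents = {}, {}
    rows, rhs = [], []
    for d in (0, 45, 90, 135):
        fwd_on, fwd_off = edge_positions(d)
        # the opposing sweep runs along -u; project onto the d axis
        bwd_on, bwd_off = edge_positions((d + 180) % 360)
        bwd_on, bwd_off = -bwd_on, -bwd_off
        low = 0.5 * (fwd_on + bwd_off)
        high = 0.5 * (fwd_off + bwd_on)
        centers[d] = 0.5 * (low + high)
        extents[d] = high - low
        u = np.array([np.cos(np.deg2rad(d)), np.sin(np.deg2rad(d))])
        rows.append(u)
        rhs.append(centers[d])
    center, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return RFEstimate(
        center_deg=(float(center[0]), float(center[1])),
        width_deg=float(extents[0]),
        height_deg=float(extents[90]),
        extent_by_axis={k: float(v) for k, v in extents.items()},
        eccentricity_deg=float(np.hypot(*center)),
    )
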