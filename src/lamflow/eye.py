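"""Microsaccade detection and eye-position condition-balance checks.

Eye position is sampled at 250 Hz.  A microsaccade is a run of at least five
consecutive samples whose speed exceeds five times the speed's standard
deviation; trials containing one are flagged for exclusion.  The balance
check verifies that mean and s.d. of eye position do not differ between
conditions (a small global fixation bias is expected and harmless).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .stats import unpaired_test

MIN_SAMPLES = 5
THRESHOLD_SD = 5.0


@dataclass
class SaccadeEvents:
    """Detected microsaccades for one trial."""

    events: list                 # list of (start, end) sample indices, end exclusive
    peak_speed: np.ndarray       # deg/s, one per event
    excluded: bool
    threshold: float             # deg/s


def detect_microsaccades(
    x: np.ndarray,
    y: np.ndarray,
    fs: float = 250.0,
    threshold_sd: float = THRESHOLD_SD,
    min_samples: int = MIN_SAMPLES,
    baseline_slice: slice | None = None,
) -> SaccadeEvents:
    """Velocity-threshold microsaccade detection on one trial.

    Speed is the magnitude of the central-difference velocity (no
    smoothing).  The threshold is ``threshold_sd`` times the s.d. of the
    speed, computed over the whole trial by default or over
    ``baseline_slice`` (e.g. a pre-cue fixation epoch) when given.  Runs of
    at least ``min_samples`` suprathreshold samples become events; any event
    marks the trial excluded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equally long 1-D traces")
    if x.size < 20:
        raise ValueError("trace too short (< 20 samples)")
    vx = np.gradient(x) * fs
    vy = np.gradient(y) * fs
    speed = np.hypot(vx, vy)
    ref = speed[baseline_slice] if baseline_slice is not None else speed
    sd = ref.std()
    if sd == 0:
        warnings.warn("zero speed variance; no events detectable", stacklevel=2)
        return SaccadeEvents([], np.array([]), False, 0.0)
    thr = threshold_sd * sd
    above = speed > thr
    events, peaks = [], []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_samples:
                events.append((i, j))
                peaks.append(speed[i:j].max())
            i = j
        else:
            i += 1
    return SaccadeEvents(
        events=events,
        peak_speed=np.asarray(peaks),
        excluded=len(events) > 0,
        threshold=float(thr),
    )


def screen_trials(
    eye: np.ndarray, fs: float = 250.0, **kwargs
) -> np.ndarray:
    """Per-trial exclusion flags for an (n_trials, 2, n_samples) eye array."""
    eye = np.asarray(eye, dtype=float)
    return np.array(
        [
            detect_microsaccades(eye[i, 0], eye[i, 1], fs=fs, **kwargs).excluded
            for i in range(eye.shape[0])
        ]
    )


def position_balance_check(
    eye: np.ndarray,
    conditions,
    window: slice | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare eye-position mean and s.d. across conditions.

    Per condition, the per-trial mean and s.d. of x and y inside the
    analysis window are summarised, and every condition pair is compared
    with rank-sum tests, Bonferroni-corrected over all pair x measure
    comparisons.  Returns a tidy table with one row per comparison; the
    per-condition summary is attached as ``df.attrs['summary']``.
    """
    eye = np.asarray(eye, dtype=float)
    conditions = np.asarray(conditions)
    if eye.ndim != 3 or eye.shape[1] != 2:
        raise ValueError("eye must be (n_trials, 2, n_samples)")
    uniq = np.unique(conditions)
    if uniq.size < 2:
        raise ValueError("need at least 2 conditions")
    sl = window if window is not None else slice(None)
    per_trial = {
        "mean_x": eye[:, 0, sl].mean(axis=1),
        "mean_y": eye[:, 1, sl].mean(axis=1),
        "sd_x": eye[:, 0, sl].std(axis=1),
        "sd_y": eye[:, 1, sl].std(axis=1),
    }
    summary = pd.DataFrame(
        {
            "condition": uniq,
            **{
                k: [v[conditions == c].mean() for c in uniq]
                for k, v in per_trial.items()
            },
        }
    )
    pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    n_comp = len(pairs) * len(per_trial)
    rows = []
    for a, b in pairs:
        for measure, v in per_trial.items():
            res = unpaired_test(
                v[conditions == a], v[conditions == b], n_comparisons=n_comp
            )
            rows.append(
                {
                    "condition_a": a,
                    "condition_b": b,
                    "measure": measure,
                    "statistic": res.statistic,
                    "p": res.p,
                    "different": res.p < alpha,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["summary"] = summary
    return out
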