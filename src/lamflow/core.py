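"""Core in-memory containers shared across the pipeline.

Time is expressed in milliseconds relative to stimulus onset throughout the
package; sampling rates are in Hz and channel depths in millimetres along the
probe, with channel 0 at the tip (deepest contact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Conditions recognised by the trial table. "target"/"distractor" refer to a
#: contour element inside the receptive field belonging to the traced (target)
#: or an irrelevant (distractor) curve; the "_adjacent" variants place the
#: curve next to, rather than inside, the receptive field.
CONDITIONS = ("target", "distractor", "target_adjacent", "distractor_adjacent")

#: Task variants: "attention" keeps the stimulus on screen, "memory" removes it
#: after 150 ms, "mask" additionally flashes a checkerboard mask at 400-450 ms,
#: "capacity" delays the cue that identifies the target until 900 ms, and
#: "checkerboard" is the full-field stimulus used for depth alignment.
TASKS = ("attention", "memory", "mask", "capacity", "checkerboard")


@dataclass
class Recording:
    """Trial-structured multichannel recording from one probe penetration.

    Parameters
    ----------
    lfp : ndarray, shape (n_trials, n_channels, n_time)
        Local field potential (arbitrary voltage units).
    mua : ndarray, shape (n_trials, n_channels, n_time)
        Multi-unit activity envelope (nonnegative, arbitrary units).
    times_ms : ndarray, shape (n_time,)
        Sample times in ms relative to stimulus onset (shared by lfp/mua).
    fs_lfp, fs_mua : float
        Sampling rates in Hz.
    channel_depths_mm : ndarray, shape (n_channels,)
        Depth of each contact along the probe, strictly increasing from the
        tip; adjacent contacts are 0.1 mm apart on the 24-channel probe.
    eye : ndarray or None, shape (n_trials, 2, n_eye)
        Horizontal/vertical eye position (deg) sampled at ``fs_eye``.
    wideband : ndarray or None
        Optional raw wideband signal, used only to exercise the MUA
        envelope extraction.
    """

    lfp: np.ndarray
    mua: np.ndarray
    times_ms: np.ndarray
    fs_lfp: float
    fs_mua: float
    channel_depths_mm: np.ndarray
    penetration_id: str = "pen0"
    eye: np.ndarray | None = None
    eye_times_ms: np.ndarray | None = None
    fs_eye: float = 250.0
    wideband: np.ndarray | None = None
    fs_wideband: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.mua = np.asarray(self.mua, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.channel_depths_mm = np.asarray(self.channel_depths_mm, dtype=float)
        if self.lfp.ndim != 3 or self.mua.ndim != 3:
            raise ValueError("lfp and mua must be (n_trials, n_channels, n_time)")
        if self.lfp.shape != self.mua.shape:
            raise ValueError(
                f"lfp shape {self.lfp.shape} != mua shape {self.mua.shape}"
            )
        if self.lfp.shape[2] != self.times_ms.size:
            raise ValueError("times_ms length does not match the time axis")
        if self.lfp.shape[1] != self.channel_depths_mm.size:
            raise ValueError("channel_depths_mm length does not match channels")
        if self.fs_lfp <= 0 or self.fs_mua <= 0:
            raise ValueError("sampling rates must be positive")
        d = np.diff(self.channel_depths_mm)
        if np.any(d <= 0):
            raise ValueError("channel_depths_mm must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[1]

    @property
    def spacing_mm(self) -> float:
        return float(np.median(np.diff(self.channel_depths_mm)))


def make_trial_table(conditions, task: str, correct=None) -> pd.DataFrame:
    """Build the per-trial metadata table.

    One row per trial with columns ``trial``, ``task``, ``condition`` and
    ``correct``; downstream stages may append columns (e.g. eye exclusion).
    """
    conditions = list(conditions)
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; valid tasks: {TASKS}")
    n = len(conditions)
    if correct is None:
        correct = np.ones(n, dtype=bool)
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "task": task,
            "condition": conditions,
            "correct": np.asarray(correct, dtype=bool),
        }
    )


def window_mask(times_ms: np.ndarray, window) -> np.ndarray:
    """Boolean mask selecting ``start <= t < end`` (window in ms)."""
    start, end = window
    if not start < end:
        raise ValueError(f"window start must precede end, got {window}")
    times_ms = np.asarray(times_ms)
    mask = (times_ms >= start) & (times_ms < end)
    if not mask.any():
        raise ValueError(f"window {window} ms contains no samples")
    return mask
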