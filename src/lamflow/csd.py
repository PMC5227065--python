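"""Current-source density estimation and CSD-based statistics.

The one-dimensional CSD is the standard three-point (Mitzdorf) estimator

    CSD(x) = -sigma * [phi(x + h) - 2 phi(x) + phi(x - h)] / h**2

where ``phi`` is the LFP, ``h`` the derivative step (0.2 mm by default, i.e.
two contacts on a 0.1 mm probe) and ``sigma`` the tissue conductivity
(0.4 S/m).  Negative CSD marks a current sink (current flowing toward the
electrode), positive a source.  Channels within ``h`` of either probe end
have no estimate and are masked invalid rather than zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import window_mask


@dataclass(frozen=True)
class CSDParams:
    """Parameters of the second-difference CSD operator.

    ``h_mm`` must be an integer multiple of ``spacing_mm``; the default
    h = 0.2 mm with 0.1 mm contact spacing differentiates across next-nearest
    neighbours.
    """

    h_mm: float = 0.2
    sigma_s_per_m: float = 0.4
    spacing_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_s_per_m <= 0:
            raise ValueError("sigma must be > 0")
        if self.h_mm <= 0 or self.spacing_mm <= 0:
            raise ValueError("h and spacing must be > 0")
        if abs(self.step - self.h_mm / self.spacing_mm) > 1e-9:
            raise ValueError("h_mm must be an integer multiple of spacing_mm")

    @property
    def step(self) -> int:
        """Derivative step in units of contacts."""
        return int(round(self.h_mm / self.spacing_mm))


@dataclass
class CSDMatrix:
    """Channel x time CSD with an interior-channel validity mask.

    Sign convention: negative = sink.  ``values`` holds NaN on channels where
    the operator is undefined (within ``h`` of the probe ends).
    """

    values: np.ndarray
    valid_channels: np.ndarray
    times_ms: np.ndarray | None = None
    units: str = "a.u."
    sink_negative: bool = True
    params: CSDParams | None = None

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_channels]

    @property
    def valid_index(self) -> np.ndarray:
        return np.flatnonzero(self.valid_channels)


@dataclass
class LaminarTemplate:
    """Per-channel weights of a laminar CSD profile.

    Normalised so the strongest sink channel has weight -1 (magnitude 1).
    """

    weights: np.ndarray
    valid_channels: np.ndarray
    norm_factor: float = 1.0
    window_ms: tuple | None = None


def compute_csd(
    lfp: np.ndarray,
    params: CSDParams = CSDParams(),
    times_ms: np.ndarray | None = None,
) -> CSDMatrix:
    """Second spatial difference of a channel x time LFP profile.

    Parameters
    ----------
    lfp : ndarray, shape (n_channels, n_time) or (n_channels,)
        LFP profile ordered from the probe tip (deep) upward.
    params : CSDParams
        Step, conductivity and contact spacing.

    Returns
    -------
    CSDMatrix
        NaN and ``valid_channels=False`` on the ``step`` outermost channels
        at each probe end.
    """
    lfp = np.asarray(lfp, dtype=float)
    squeeze = lfp.ndim == 1
    if squeeze:
        lfp = lfp[:, None]
    n_ch = lfp.shape[0]
    k = params.step
    if n_ch < 2 * k + 1:
        raise ValueError(
            f"need at least {2 * k + 1} channels for h={params.h_mm} mm "
            f"at {params.spacing_mm} mm spacing, got {n_ch}"
        )
    h = params.h_mm
    values = np.full_like(lfp, np.nan)
    interior = slice(k, n_ch - k)
    second_diff = lfp[2 * k:] - 2.0 * lfp[k:-k] + lfp[: n_ch - 2 * k]
    values[interior] = -params.sigma_s_per_m * second_diff / h**2
    valid = np.zeros(n_ch, dtype=bool)
    valid[interior] = True
    if squeeze:
        values = values[:, 0]
    return CSDMatrix(
        values=values,
        valid_channels=valid,
        times_ms=None if times_ms is None else np.asarray(times_ms, float),
        params=params,
    )


def normalize_csd(
    csd: CSDMatrix,
    reference: CSDMatrix,
    stim_window_ms,
    times_ms: np.ndarray | None = None,
) -> CSDMatrix:
    """Normalise a penetration's CSD by the peak |CSD| of a reference.

    The divisor is the maximum absolute CSD across layers during the stimulus
    period of the reference (target-curve) condition, giving dimensionless
    values comparable across penetrations.
    """
    t = times_ms if times_ms is not None else reference.times_ms
    if t is None:
        raise ValueError("times_ms required (none stored on reference)")
    m = window_mask(t, stim_window_ms)
    ref = reference.valid_values[:, m]
    denom = np.nanmax(np.abs(ref))
    if not np.isfinite(denom) or denom == 0:
        raise ValueError("reference CSD is zero in the stimulus window")
    return CSDMatrix(
        values=csd.values / denom,
        valid_channels=csd.valid_channels.copy(),
        times_ms=csd.times_ms,
        units="normalized",
        params=csd.params,
    )


def make_template(csd: CSDMatrix, window_ms, times_ms=None) -> LaminarTemplate:
    """Average laminar profile over a window, scaled to the strongest sink.

    The template is the per-channel time average of the CSD over the
    modulation window, divided by the magnitude of its most negative value so
    that the strongest sink carries weight -1.
    """
    t = times_ms if times_ms is not None else csd.times_ms
    if t is None:
        raise ValueError("times_ms required")
    m = window_mask(t, window_ms)
    profile = csd.values[:, m].mean(axis=1)
    valid_profile = profile[csd.valid_channels]
    if np.allclose(valid_profile, 0.0):
        raise ValueError("window-averaged CSD is identically zero")
    strongest_sink = valid_profile.min()
    if strongest_sink < 0:
        norm = abs(strongest_sink)
    else:  # degenerate all-source profile; fall back to the largest magnitude
        norm = np.abs(valid_profile).max()
    return LaminarTemplate(
        weights=profile / norm,
        valid_channels=csd.valid_channels.copy(),
        norm_factor=norm,
        window_ms=tuple(window_ms),
    )


def ncsd_timecourse(csd: CSDMatrix, template: LaminarTemplate) -> np.ndarray:
    """Inner product of the laminar template with the momentary CSD.

    Returns one value per time point, Sum_channels w_c * CSD(c, t) over valid
    channels; a time course of how strongly the template pattern is expressed.
    """
    if not np.array_equal(csd.valid_channels, template.valid_channels):
        raise ValueError("CSD and template cover different channel sets")
    w = template.weights[template.valid_channels]
    return w @ csd.valid_values


def abs_csd_modulation(
    csd_a: CSDMatrix,
    csd_b: CSDMatrix,
    window_ms,
    times_ms=None,
) -> float:
    """Absolute CSD modulation between two conditions.

    Per valid channel the condition difference is averaged over the window
    first, then its absolute value is taken, then channels are averaged --
    so sinks and sources contribute without cancelling.
    """
    if csd_a.values.shape != csd_b.values.shape:
        raise ValueError("condition CSDs differ in shape")
    if not np.array_equal(csd_a.valid_channels, csd_b.valid_channels):
        raise ValueError("condition CSDs differ in valid channels")
    t = times_ms if times_ms is not None else csd_a.times_ms
    if t is None:
        raise ValueError("times_ms required")
    m = window_mask(t, window_ms)
    diff = (csd_a.valid_values - csd_b.valid_values)[:, m].mean(axis=1)
    return float(np.abs(diff).mean())
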