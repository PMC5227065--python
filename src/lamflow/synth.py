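"""Ground-truth simulator for laminar V1 recordings.

Generates trial-structured LFP, MUA-envelope and eye-position data from a
24-contact laminar probe with known ground truth, emulating the structure of
curve-tracing experiments:

* an early stimulus-evoked current sink in layer 4C with a return source in
  the deep layers (the polarity reversal used for depth alignment),
* per-channel response latencies, earliest in layer 4C and near layer 6,
* condition-dependent sustained modulation (target > distractor), strongest
  in the superficial and deep compartments and weaker in layer 4, stronger
  under attention (stimulus present) than during memory delays,
* modulation-specific CSD sinks in the superficial layers and layer 5,
* a mask-evoked transient that abolishes the modulation at 450-550 ms and
  lets it recover by 650-750 ms, and a capacity variant where modulation
  appears only after a late (900 ms) cue,
* additive Gaussian noise (LFP) and zero-truncated Gaussian noise (MUA).

MUA is simulated directly as a rate envelope because the measured MUA signal
is itself a rectified-and-smoothed envelope; :func:`make_wideband` provides
an AM-carrier wideband signal solely to exercise the envelope extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Recording, make_trial_table
from .csd import CSDParams

PRESETS = ("attention_like", "memory_like", "mask_like", "capacity_like", "null")

#: Sustained target-minus-distractor gain per laminar compartment, as a
#: fraction of the peak response.  Attention values follow the configured
#: (superficial, layer4, deep) = (0.30, 0.10, 0.30) profile; memory values
#: are half that, keeping the modulation weaker without the stimulus while
#: preserving the laminar profile.
_ATTENTION_MOD = {"superficial": 0.30, "layer4": 0.10, "deep": 0.30}
_MEMORY_MOD = {"superficial": 0.15, "layer4": 0.05, "deep": 0.15}

_PRESET_TASK = {
    "attention_like": "attention",
    "memory_like": "memory",
    "mask_like": "mask",
    "capacity_like": "capacity",
    "null": "memory",
}


@dataclass(frozen=True)
class Schedule:
    """Trial event times (ms relative to stimulus onset) for one task."""

    stim_on_ms: float = 0.0
    stim_off_ms: float | None = None  # None: stimulus stays on (attention)
    mask_on_ms: float | None = None
    mask_off_ms: float | None = None
    cue_ms: float | None = None
    trial_end_ms: float = 900.0


def make_schedule(task: str) -> Schedule:
    """Default event schedule for each task variant."""
    if task == "attention":
        return Schedule()
    if task == "memory":
        return Schedule(stim_off_ms=150.0)
    if task == "mask":
        return Schedule(stim_off_ms=150.0, mask_on_ms=400.0, mask_off_ms=450.0)
    if task == "capacity":
        return Schedule(
            stim_off_ms=150.0,
            mask_on_ms=400.0,
            mask_off_ms=450.0,
            cue_ms=900.0,
            trial_end_ms=1250.0,
        )
    if task == "checkerboard":
        return Schedule(stim_off_ms=250.0, trial_end_ms=400.0)
    raise ValueError(f"unknown task {task!r}")


@dataclass(frozen=True)
class SimConfig:
    """Geometry, sampling and trial-count configuration of the simulator."""

    n_channels: int = 24
    spacing_mm: float = 0.1
    fs_lfp: float = 763.0
    fs_eye: float = 250.0
    n_trials_per_condition: int = 30
    task: str = "attention"
    conditions: tuple = ("target", "distractor")
    schedule: Schedule | None = None
    t_start_ms: float = -300.0
    seed: int = 0
    boundary_channel: int = 8
    noise_sd_lfp: float = 0.02
    noise_sd_mua: float = 0.15
    #: multiplicative between-penetration scatter of the modulation gain
    modulation_jitter_sd: float = 0.15
    #: decay constant (ms) of the off-response toward baseline in the tasks
    #: where the stimulus disappears; a free parameter of the stated world
    sustained_tau_ms: float = 300.0
    microsaccade_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be > 0")
        sched = self.schedule if self.schedule is not None else make_schedule(self.task)
        object.__setattr__(self, "schedule", sched)
        _validate_schedule(self.task, sched)
        if not (0 <= self.boundary_channel < self.n_channels - 1):
            raise ValueError("boundary_channel outside the probe")

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.fs_lfp
        n = int(np.floor((self.schedule.trial_end_ms - self.t_start_ms) / dt)) + 1
        return self.t_start_ms + dt * np.arange(n)

    @property
    def eye_times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.fs_eye
        n = int(np.floor((self.schedule.trial_end_ms - self.t_start_ms) / dt)) + 1
        return self.t_start_ms + dt * np.arange(n)


def _validate_schedule(task: str, s: Schedule) -> None:
    if task == "memory" and s.stim_off_ms != 150.0:
        raise ValueError("memory task requires stimulus offset at 150 ms")
    if task in ("mask", "capacity"):
        if s.mask_on_ms is None or s.mask_off_ms is None:
            raise ValueError(f"{task} task requires mask on/off times")
        if task == "mask" and not (
            s.mask_on_ms == 400.0 and s.mask_off_ms - s.mask_on_ms == 50.0
        ):
            raise ValueError("mask task: mask at 400 ms lasting 50 ms")
    if task == "capacity" and s.cue_ms is None:
        raise ValueError("capacity task requires a cue time")


@dataclass
class GroundTruth:
    """The simulator's stated world: the acceptance oracle for recovery tests.

    ``modulation_amplitude`` holds per-compartment sustained
    target-minus-distractor gains (fraction of the peak response) separately
    for the attention and memory task families; ``csd_profile`` the true
    noiseless CSD (channel x time) per condition; ``layer_latencies`` the
    per-channel MUA onset (ms).
    """

    csd_profile: dict
    layer_latencies: np.ndarray
    modulation_amplitude: dict
    boundary_channel: int
    noise_sd: dict
    seed: int
    preset: str
    compartments: np.ndarray = None
    mua_peak: np.ndarray = None
    baseline_rate: float = 0.2
    sustained_frac: float = 0.4
    csd_mod_amplitude: float = 0.5

    def __post_init__(self) -> None:
        att = self.modulation_amplitude["attention"]
        mem = self.modulation_amplitude["memory"]
        for comp in att:
            if not att[comp] >= mem[comp] >= 0:
                raise ValueError(
                    "preset invariant violated: attention >= memory >= 0 "
                    f"for compartment {comp!r}"
                )
        for v in self.noise_sd.values():
            if v < 0:
                raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# forward model: LFP from a known CSD (exact inverse of the CSD operator)
# ---------------------------------------------------------------------------

def lfp_from_csd(
    csd_true: np.ndarray,
    params: CSDParams = CSDParams(),
    boundary_values=(0.0, 0.0),
) -> np.ndarray:
    """Potentials whose second-difference CSD equals ``csd_true``.

    Solves ``-sigma * D2 phi / h**2 = C`` for the interior channels, with the
    potential pinned to ``boundary_values`` at the first and last contact.
    For a derivative step of ``k`` contacts the discrete operator leaves
    ``2k`` degrees of freedom; the two boundary constraints fix two of them
    and the remaining ones are resolved by the minimum-norm solution, which
    keeps the map linear and the roundtrip with :func:`~lamflow.csd.compute_csd`
    exact at interior channels.

    Parameters
    ----------
    csd_true : ndarray, shape (n_channels, n_time) or (n_channels,)
        Desired CSD at every channel; only interior channels (those the CSD
        operator can reach) are enforced.
    boundary_values : pair of scalars or arrays (n_time,)
        Potential at the tip-most and surface-most contact.
    """
    C = np.asarray(csd_true, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("csd_true must be finite")
    squeeze = C.ndim == 1
    if squeeze:
        C = C[:, None]
    n_ch, n_t = C.shape
    k = params.step
    if n_ch < 2 * k + 1:
        raise ValueError("too few channels for the requested step")
    A = _inverse_operator(n_ch, k, params.sigma_s_per_m, params.h_mm)
    b0 = np.broadcast_to(np.asarray(boundary_values[0], float), (n_t,))
    b1 = np.broadcast_to(np.asarray(boundary_values[1], float), (n_t,))
    rhs = np.vstack([C[k: n_ch - k], b0[None, :], b1[None, :]])
    phi = A @ rhs
    return phi[:, 0] if squeeze else phi


def _inverse_operator(n_ch: int, k: int, sigma: float, h: float) -> np.ndarray:
    """Pseudoinverse mapping [interior CSD; phi_0; phi_last] -> phi."""
    n_int = n_ch - 2 * k
    M = np.zeros((n_int + 2, n_ch))
    c = -sigma / h**2
    for row, i in enumerate(range(k, n_ch - k)):
        M[row, i - k] += c
        M[row, i] += -2 * c
        M[row, i + k] += c
    M[n_int, 0] = 1.0
    M[n_int + 1, n_ch - 1] = 1.0
    return np.linalg.pinv(M)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """C1 ramp from 0 at t0 to 1 at t1."""
    x = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def compartments_from_boundary(
    boundary_channel: int, n_channels: int, spacing_mm: float = 0.1
):
    """Per-channel relative depth and compartment label.

    The 4C/5 boundary sits midway between ``boundary_channel`` (the first
    contact below the reversal, deep side) and the next contact up.  Depth
    bands follow the anatomical assignment rule: deep 0.05-0.55 mm below the
    boundary, layer 4 0.05-0.55 mm above, superficial 0.65-1.15 mm above
    (closed at the lower printed bound, open at the upper).
    """
    from .alignment import assign_compartments  # local import, no cycle at load

    ch = np.arange(n_channels)
    rel_depth = (ch - boundary_channel - 0.5) * spacing_mm
    return rel_depth, assign_compartments(rel_depth)


def make_ground_truth(config: SimConfig, preset: str = "attention_like") -> GroundTruth:
    """Populate the stated world for one of the named presets.

    Presets differ in the modulation amplitudes: ``null`` has zero modulation
    everywhere; the others share the laminar profile (superficial/deep >
    layer 4) with attention amplitudes for ``attention_like`` and the weaker
    memory amplitudes for the memory/mask/capacity variants.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid presets: {PRESETS}")
    n_ch = config.n_channels
    b = config.boundary_channel
    rel_depth, comps = compartments_from_boundary(b, n_ch, config.spacing_mm)
    t = config.times_ms

    # per-channel latency: layer 4C and the deepest (layer-6-like) contacts
    # respond first, superficial/deep compartments 8-10 ms later
    lat = np.full(n_ch, 52.0)
    lat[comps == "layer4"] = 40.0
    lat[: max(0, b - 4)] = 40.0  # layer-6-like channels below the deep band
    lat[comps == "deep"] = 48.0
    lat[comps == "superficial"] = 50.0

    if preset == "null":
        mod = {
            "attention": {k: 0.0 for k in _ATTENTION_MOD},
            "memory": {k: 0.0 for k in _MEMORY_MOD},
        }
    else:
        mod = {"attention": dict(_ATTENTION_MOD), "memory": dict(_MEMORY_MOD)}

    # spatial CSD patterns (arbitrary units, negative = sink)
    evoked = np.zeros(n_ch)
    sink_4c = (rel_depth >= 0.05) & (rel_depth < 0.55)
    src_deep = (rel_depth <= -0.05) & (rel_depth > -0.55)
    evoked[sink_4c] = -1.0
    evoked[src_deep] = +0.8
    mod_pat = np.zeros(n_ch)
    mod_pat[comps == "superficial"] = -1.0
    mod_pat[(rel_depth <= -0.05) & (rel_depth > -0.25)] = -0.8  # layer 5
    mod_pat[comps == "layer4"] = +0.6  # return currents avoid layer 4 sinks

    evoked_t = np.exp(-0.5 * ((t - 55.0) / 15.0) ** 2)
    mod_env = _modulation_envelope(t, config)
    # CSD modulation amplitude is task-independent: the synaptic signature is
    # similar with and without the stimulus, unlike the spiking modulation
    csd_mod = 0.0 if preset == "null" else 0.5

    csd_profile = {}
    for cond in config.conditions:
        if cond == "checkerboard":
            prof = np.outer(evoked, evoked_t)
        elif cond.endswith("_adjacent"):
            adj_t = 0.25 * np.exp(-0.5 * ((t - 85.0) / 15.0) ** 2)
            prof = np.outer(evoked, adj_t)
        else:
            prof = np.outer(evoked, evoked_t)
            if cond == "target":
                prof = prof + csd_mod * np.outer(mod_pat, mod_env)
        csd_profile[cond] = prof

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    mua_peak = 1.0 + 0.2 * (rng.random(n_ch) - 0.5)  # fixed per-channel gain

    return GroundTruth(
        csd_profile=csd_profile,
        layer_latencies=lat,
        modulation_amplitude=mod,
        boundary_channel=b,
        noise_sd={"lfp": config.noise_sd_lfp, "mua": config.noise_sd_mua},
        seed=config.seed,
        preset=preset,
        compartments=comps,
        mua_peak=mua_peak,
        csd_mod_amplitude=csd_mod,
    )


def _modulation_envelope(t: np.ndarray, config: SimConfig) -> np.ndarray:
    """Time course of the sustained target-minus-distractor modulation.

    Exactly 1 throughout the task's analysis window so that window means
    recover the configured amplitudes without envelope bias: ramps complete
    before 200 ms (or before 900 ms in the capacity task), the mask gate is
    fully closed over 450-550 ms and fully reopened over 650-750 ms.
    """
    task = config.task
    if task == "capacity":
        env = _smoothstep(t, 850.0, 895.0) * (1.0 - _smoothstep(t, 1155.0, 1200.0))
        return env
    env = _smoothstep(t, 150.0, 195.0) * (1.0 - _smoothstep(t, 755.0, 800.0))
    if task == "mask":
        gate = 1.0 - _smoothstep(t, 410.0, 448.0) + _smoothstep(t, 560.0, 645.0)
        env = env * np.clip(gate, 0.0, 1.0)
    return env


def _sustained_base(t: np.ndarray, config: SimConfig) -> np.ndarray:
    """Condition-independent sustained drive shared by target and distractor."""
    on = _smoothstep(t, 150.0, 195.0)
    if config.task == "attention":
        return on * (1.0 - _smoothstep(t, 755.0, 800.0))
    # stimulus off at 150 ms: activity decays back toward baseline
    decay = np.where(t > 195.0, np.exp(-(t - 195.0) / config.sustained_tau_ms), 1.0)
    return on * decay


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def simulate_session(gt: GroundTruth, config: SimConfig):
    """Simulate one penetration: Recording plus trial table.

    LFP is generated by the exact forward model :func:`lfp_from_csd` applied
    to the condition's true CSD, plus white Gaussian noise per trial and
    channel.  MUA is a rate envelope: baseline + transient at the channel
    latency + sustained component with the condition- and compartment-
    dependent modulation gain, plus zero-truncated Gaussian noise.
    Identical (gt, config) give byte-identical output.
    """
    if config.n_trials_per_condition < 1:
        raise ValueError("n_trials_per_condition must be >= 1")
    t = config.times_ms
    n_ch = config.n_channels
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    params = CSDParams(spacing_mm=config.spacing_mm)

    # per-penetration modulation gain scatter (shared by all compartments)
    gain = max(0.0, 1.0 + config.modulation_jitter_sd * rng.standard_normal())

    task_family = "attention" if config.task == "attention" else "memory"
    mod_amp = gt.modulation_amplitude[task_family]
    comp_amp = np.array(
        [mod_amp.get(c, 0.0) for c in gt.compartments]
    )  # 0 for unassigned channels

    mod_env = _modulation_envelope(t, config)
    sust = _sustained_base(t, config)
    s = config.schedule

    rates = {}
    lfp_clean = {}
    for cond in config.conditions:
        drive = np.zeros((n_ch, t.size))
        if cond == "checkerboard" or not cond.endswith("_adjacent"):
            trans = np.exp(
                -0.5 * ((t[None, :] - (gt.layer_latencies[:, None] + 25.0)) / 10.0) ** 2
            )
            drive += trans
            if cond != "checkerboard":
                drive += gt.sustained_frac * sust[None, :]
                if s.stim_off_ms is not None:
                    off = 0.4 * np.exp(-0.5 * ((t - (s.stim_off_ms + 30.0)) / 12.0) ** 2)
                    drive += off[None, :]
            if cond == "target":
                drive += gain * comp_amp[:, None] * mod_env[None, :]
        else:  # adjacent curve: weak, delayed transient only
            trans = np.exp(
                -0.5 * ((t[None, :] - (gt.layer_latencies[:, None] + 55.0)) / 12.0) ** 2
            )
            drive += 0.25 * trans
        if s.mask_on_ms is not None:
            mask_resp = 1.2 * np.exp(-0.5 * ((t - (s.mask_on_ms + 30.0)) / 18.0) ** 2)
            drive += mask_resp[None, :]
        rates[cond] = gt.baseline_rate + gt.mua_peak[:, None] * drive
        lfp_clean[cond] = lfp_from_csd(gt.csd_profile[cond], params)

    n_per = config.n_trials_per_condition
    conds = [c for c in config.conditions for _ in range(n_per)]
    order = rng.permutation(len(conds))
    conds = [conds[i] for i in order]

    n_trials = len(conds)
    lfp = np.empty((n_trials, n_ch, t.size))
    mua = np.empty((n_trials, n_ch, t.size))
    for i, cond in enumerate(conds):
        lfp[i] = lfp_clean[cond] + gt.noise_sd["lfp"] * rng.standard_normal(
            (n_ch, t.size)
        )
        mua[i] = np.maximum(
            0.0,
            rates[cond] + gt.noise_sd["mua"] * rng.standard_normal((n_ch, t.size)),
        )

    eye_t = config.eye_times_ms
    eye = _simulate_eye(rng, n_trials, eye_t, config)

    correct = rng.random(n_trials) < 0.95
    trials = make_trial_table(conds, config.task, correct)
    rec = Recording(
        lfp=lfp,
        mua=mua,
        times_ms=t,
        fs_lfp=config.fs_lfp,
        fs_mua=config.fs_lfp,
        channel_depths_mm=config.spacing_mm * np.arange(n_ch),
        penetration_id=f"sim-{gt.preset}-{config.seed}",
        eye=eye,
        eye_times_ms=eye_t,
        fs_eye=config.fs_eye,
        meta={"preset": gt.preset, "seed": config.seed, "task": config.task},
    )
    return rec, trials


def _simulate_eye(rng, n_trials: int, eye_t: np.ndarray, config: SimConfig):
    """Fixational jitter around a small (<0.05 deg) lower-left bias.

    Optionally injects a step-like microsaccade excursion in a fraction of
    trials (off by default); realistic saccade kinematics are out of scope.
    """
    n = eye_t.size
    eye = np.empty((n_trials, 2, n))
    kernel = np.ones(5) / 5.0
    for i in range(n_trials):
        for a, bias in enumerate((-0.02, -0.02)):
            jitter = np.convolve(rng.standard_normal(n + 4), kernel, "valid")
            eye[i, a] = bias + 0.03 * jitter
        if config.microsaccade_prob > 0 and rng.random() < config.microsaccade_prob:
            # sustained 1 deg excursion over 8 samples: fast enough to clear
            # five times the speed SD even after it inflates that SD itself
            start = int(rng.integers(n // 4, 3 * n // 4))
            ramp = np.linspace(0.0, 1.0, 9)[1:]
            eye[i, 0, start : start + 8] += ramp[: max(0, n - start)]
            eye[i, 0, start + 8 :] += 1.0
    return eye


def make_wideband(
    envelope: np.ndarray,
    fs_env: float,
    fs_wb: float = 24400.0,
    carrier_hz: float = 1500.0,
) -> np.ndarray:
    """AM-carrier wideband signal whose MUA envelope tracks ``envelope``.

    Upsamples the (nonnegative) envelope to ``fs_wb`` by linear interpolation
    and multiplies it onto a sinusoidal carrier inside the 500 Hz - 5 kHz MUA
    band.  Exists solely to test the envelope extraction.
    """
    env = np.asarray(envelope, dtype=float)
    n_wb = int(round(env.shape[-1] * fs_wb / fs_env))
    t_env = np.arange(env.shape[-1]) / fs_env
    t_wb = np.arange(n_wb) / fs_wb
    up = np.interp(t_wb, t_env, env)
    return up * np.sin(2 * np.pi * carrier_hz * t_wb)
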