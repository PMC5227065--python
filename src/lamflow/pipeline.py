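"""End-to-end orchestration: simulate (or load) -> preprocess -> CSD ->
align -> metrics -> stats -> decode -> eye screening.

`run_pipeline` executes the full laminar analysis over a set of
penetrations and returns a machine-readable summary.  Every report carries
the seed and a hash of the configuration, and identical configurations give
identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import align_from_csd, align_penetrations
from .core import Recording, window_mask
from .csd import CSDMatrix, CSDParams, compute_csd, normalize_csd
from .decode import decode_session
from .eye import screen_trials
from .metrics import AnalysisWindows, modulation_profile, normalize_mua
from .preprocess import compute_snr, interpolate_bad_channels
from .stats import cluster_permutation, compartment_anova, paired_test, profile_consistency
from .synth import SimConfig, make_ground_truth, simulate_session

_TEST_WINDOWS = {
    "attention": ("modulation",),
    "memory": ("modulation",),
    "mask": ("mask_during", "mask_after"),
    "capacity": ("capacity_late",),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a simulated-cohort pipeline run."""

    preset: str = "attention_like"
    n_penetrations: int = 12
    n_trials_per_condition: int = 30
    conditions: tuple = ("target", "distractor")
    seed: int = 0
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    csd_params: CSDParams = field(default_factory=CSDParams)
    run_decode: bool = False
    run_cluster: bool = False
    cluster_n_perm: int = 500
    screen_eyes: bool = True
    out_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PenetrationAnalysis:
    """Everything the cohort-level statistics need from one penetration."""

    penetration_id: str
    alignment: object
    snr: np.ndarray
    n_excluded_channels: int
    n_excluded_trials: int
    summary: dict          # window name -> {condition: penetration mean}
    profiles: dict         # window name -> ModulationProfile
    csd_diff_map: np.ndarray
    decode_accuracy: float | None = None


def analyze_penetration(
    rec: Recording,
    trials: pd.DataFrame,
    windows: AnalysisWindows = AnalysisWindows(),
    csd_params: CSDParams = CSDParams(),
    test_windows=("modulation",),
    pair=("target", "distractor"),
    run_decode: bool = False,
    screen_eyes: bool = True,
    decode_seed: int = 0,
) -> PenetrationAnalysis:
    """Run the single-penetration stages and summarise for cohort stats."""
    conditions = trials["condition"].to_numpy()
    keep = np.ones(rec.n_trials, dtype=bool)
    if screen_eyes and rec.eye is not None:
        keep = ~screen_trials(rec.eye, fs=rec.fs_eye)
        if keep.sum() < rec.n_trials // 2:  # safety net for pathological traces
            keep = np.ones(rec.n_trials, dtype=bool)
    mua = rec.mua[keep]
    lfp = rec.lfp[keep]
    conditions = conditions[keep]

    qc = compute_snr(mua, rec.times_ms)
    lfp = interpolate_bad_channels(lfp, qc.excluded)

    cond_avg_lfp = {c: lfp[conditions == c].mean(axis=0) for c in pair}
    csd = {
        c: compute_csd(cond_avg_lfp[c], csd_params, times_ms=rec.times_ms)
        for c in pair
    }
    evoked = CSDMatrix(
        values=0.5 * (csd[pair[0]].values + csd[pair[1]].values),
        valid_channels=csd[pair[0]].valid_channels,
        times_ms=rec.times_ms,
        params=csd_params,
    )
    alignment = align_from_csd(evoked, rec.times_ms)

    stim_window = (0.0, 150.0)
    csd_norm = {
        c: normalize_csd(csd[c], csd[pair[0]], stim_window) for c in pair
    }
    diff_map = csd_norm[pair[0]].values - csd_norm[pair[1]].values

    norm = normalize_mua(mua, rec.times_ms, conditions, windows)
    summary, profiles = {}, {}
    for wname in test_windows:
        w = getattr(windows, wname)
        prof = modulation_profile(
            norm,
            conditions,
            rec.times_ms,
            alignment,
            window_ms=w,
            pair=pair,
            penetration_id=rec.penetration_id,
        )
        profiles[wname] = prof
        m = window_mask(rec.times_ms, w)
        summary[wname] = {
            c: float(
                np.nanmean(
                    norm.values[conditions == c][:, norm.valid_channels][:, :, m]
                )
            )
            for c in pair
        }

    acc = None
    if run_decode:
        m = window_mask(rec.times_ms, windows.modulation)
        sel = np.isin(conditions, pair)
        feats = mua[sel][:, :, m].mean(axis=2)
        acc = decode_session(
            feats, conditions[sel], seed=decode_seed, window_ms=windows.modulation
        ).accuracy

    return PenetrationAnalysis(
        penetration_id=rec.penetration_id,
        alignment=alignment,
        snr=qc.snr,
        n_excluded_channels=int(qc.excluded.sum()),
        n_excluded_trials=int((~keep).sum()),
        summary=summary,
        profiles=profiles,
        csd_diff_map=diff_map,
        decode_accuracy=acc,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate a cohort of penetrations and run the full analysis.

    Returns a nested summary dict: per tested window the penetration-level
    paired test, plus the laminar repeated-measures ANOVA (modulation or
    task-specific window), profile consistency, and optionally decoding and
    the CSD cluster permutation test.
    """
    from .synth import PRESETS, _PRESET_TASK

    if config.preset not in PRESETS:
        raise ValueError(f"unknown preset {config.preset!r}")
    task = _PRESET_TASK[config.preset]
    test_windows = _TEST_WINDOWS[task]

    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_penetrations
    ) % (2**31)
    analyses = []
    for i in range(config.n_penetrations):
        sim = SimConfig(
            task=task,
            conditions=config.conditions,
            n_trials_per_condition=config.n_trials_per_condition,
            seed=int(seeds[i]),
        )
        gt = make_ground_truth(sim, config.preset)
        rec, trials = simulate_session(gt, sim)
        analyses.append(
            analyze_penetration(
                rec,
                trials,
                windows=config.windows,
                csd_params=config.csd_params,
                test_windows=test_windows,
                run_decode=config.run_decode,
                screen_eyes=config.screen_eyes,
                decode_seed=int(seeds[i]),
            )
        )

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "preset": config.preset,
        "task": task,
        "n_penetrations": config.n_penetrations,
        "windows": {},
    }
    for wname in test_windows:
        a = np.array([p.summary[wname]["target"] for p in analyses])
        b = np.array([p.summary[wname]["distractor"] for p in analyses])
        res = paired_test(a, b)
        comp = pd.DataFrame(
            [
                {
                    k: p.profiles[wname].compartment_means[k]
                    for k in ("deep", "layer4", "superficial")
                }
                for p in analyses
            ]
        )
        anova = compartment_anova(comp, posthoc=True)
        report["windows"][wname] = {
            "mean_modulation": float((a - b).mean()),
            "paired_test": {"statistic": res.statistic, "p": res.p, "n": res.n},
            "significant": res.p < 0.05,
            "anova": {
                "F": anova.F,
                "p": anova.p,
                "epsilon": anova.epsilon,
                "posthoc": {
                    f"{k[0]}_vs_{k[1]}": v.p for k, v in anova.posthoc.items()
                },
            },
            "compartment_means": comp.mean().to_dict(),
        }

    main_w = test_windows[-1]
    profiles = [p.profiles[main_w].per_channel for p in analyses]
    if len(profiles) >= 2:
        cons = profile_consistency(profiles, seed=config.seed)
        report["profile_consistency"] = {
            "mean_r": cons.mean_r,
            "p": cons.p,
            "n_pairs": cons.n_pairs,
        }

    grid, mean_prof, counts = align_penetrations(
        [(p.profiles[main_w].per_channel, p.alignment) for p in analyses]
    )
    report["laminar_profile"] = {
        "rel_depth_mm": grid.tolist(),
        "mean": np.where(np.isfinite(mean_prof), mean_prof, None).tolist(),
        "n_penetrations": counts.tolist(),
    }

    if config.run_cluster:
        maps = np.stack([p.csd_diff_map for p in analyses])
        valid = np.all(np.isfinite(maps), axis=(0, 2))
        cl = cluster_permutation(
            maps[:, valid, :],
            n_perm=config.cluster_n_perm,
            seed=config.seed,
        )
        report["csd_clusters"] = {
            "n_clusters": len(cl.cluster_masses),
            "n_significant": int(cl.significant.sum()),
            "min_p": float(cl.p_values.min()) if cl.p_values.size else None,
        }

    if config.run_decode:
        accs = [p.decode_accuracy for p in analyses]
        report["decoding"] = {
            "mean_accuracy": float(np.mean(accs)),
            "per_penetration": [float(a) for a in accs],
        }

    report["qc"] = {
        "excluded_channels": [p.n_excluded_channels for p in analyses],
        "excluded_trials": [p.n_excluded_trials for p in analyses],
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(report, indent=1))
    return report
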