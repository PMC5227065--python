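"""Penetration-level statistics.

All tests take one value (or one small vector) per penetration, never raw
channels: channels within a penetration are correlated, so averaging across
channels (or compartments) per penetration before testing is what keeps the
tests honest.  Provided are the paired Wilcoxon signed-rank test, the
unpaired rank-sum test for cross-task comparisons, a repeated-measures
one-way ANOVA over the three laminar compartments with Greenhouse-Geisser
correction, laminar-profile consistency correlations with a channel-shuffle
control, and a cluster-based sign-flip permutation test on channel x time
difference maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

_COMPARTMENTS = ("deep", "layer4", "superficial")


@dataclass
class TestResult:
    statistic: float
    p: float
    n: int
    test: str
    n_comparisons: int = 1


@dataclass
class AnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float
    p_uncorrected: float
    n: int
    posthoc: dict | None = None


@dataclass
class ConsistencyResult:
    mean_r: float
    r_values: np.ndarray
    p: float
    n_pairs: int
    mode: str
    shuffled: bool


@dataclass
class ClusterResult:
    """Suprathreshold clusters of a penetration-level t-map."""

    clusters: list            # list of boolean masks (channel x time)
    cluster_masses: np.ndarray
    p_values: np.ndarray
    t_map: np.ndarray
    threshold: float
    n_perm: int
    seed: int

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < 0.05


def paired_test(
    values_a,
    values_b,
    alternative: str = "two-sided",
    n_comparisons: int = 1,
) -> TestResult:
    """Wilcoxon signed-rank test on paired penetration summaries.

    Uses the exact null distribution for small samples and the normal
    approximation otherwise (scipy's ``method='auto'``); an optional
    Bonferroni factor multiplies the p value for multiple comparisons.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be 1-D and equally long")
    if a.size < 5:
        raise ValueError("need at least 5 penetrations")
    if np.allclose(a, b):
        raise ValueError("all paired differences are zero")
    stat, p = sps.wilcoxon(a, b, alternative=alternative, method="auto")
    return TestResult(
        statistic=float(stat),
        p=float(min(1.0, p * n_comparisons)),
        n=a.size,
        test="wilcoxon-signed-rank",
        n_comparisons=n_comparisons,
    )


def unpaired_test(
    values_a,
    values_b,
    alternative: str = "two-sided",
    n_comparisons: int = 1,
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test for cross-task comparisons."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    stat, p = sps.mannwhitneyu(a, b, alternative=alternative)
    return TestResult(
        statistic=float(stat),
        p=float(min(1.0, p * n_comparisons)),
        n=a.size + b.size,
        test="wilcoxon-rank-sum",
        n_comparisons=n_comparisons,
    )


def compartment_anova(
    compartment_means, posthoc: bool = False, gg_mode: str = "mauchly"
) -> AnovaResult:
    """Repeated-measures one-way ANOVA over laminar compartments.

    Parameters
    ----------
    compartment_means : DataFrame or ndarray, shape (n_penetrations, 3)
        One row per penetration with deep / layer4 / superficial means.
    posthoc : bool
        Also run pairwise signed-rank tests, Bonferroni-corrected by 3.
    gg_mode : {"mauchly", "always"}
        When to apply the Greenhouse-Geisser correction for deviations from
        sphericity: only when Mauchly's test rejects sphericity (default; the
        correction is applied "if necessary"), or whenever the estimated
        epsilon < 1.  Under true sphericity the always-on correction is
        measurably conservative, which is why the gated form is the default.
    """
    if isinstance(compartment_means, pd.DataFrame):
        data = compartment_means[list(_COMPARTMENTS)].to_numpy(dtype=float)
    else:
        data = np.asarray(compartment_means, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(_COMPARTMENTS):
        raise ValueError("expected (n_penetrations, 3) compartment means")
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 penetrations")
    if not np.all(np.isfinite(data)):
        raise ValueError("compartment means contain non-finite values")

    import pingouin as pg  # deferred: pingouin import is slow

    df = pd.DataFrame(data, columns=_COMPARTMENTS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.rm_anova(data=df, correction=True)
    res = res.rename(columns={"p-unc": "p_unc", "p-GG-corr": "p_GG_corr"})
    row = res.iloc[0]
    eps = float(row["eps"])
    p_unc = float(row["p_unc"])
    if gg_mode == "mauchly":
        correct = not bool(row["sphericity"])
    elif gg_mode == "always":
        correct = eps < 1.0
    else:
        raise ValueError("gg_mode must be 'mauchly' or 'always'")
    if correct and "p_GG_corr" in res.columns and np.isfinite(row["p_GG_corr"]):
        p = float(row["p_GG_corr"])
        df1, df2 = eps * (k - 1), eps * (k - 1) * (n - 1)
    else:
        p = p_unc
        df1, df2 = float(k - 1), float((k - 1) * (n - 1))
    ph = None
    if posthoc:
        ph = {}
        for i in range(k):
            for j in range(i + 1, k):
                pair = (_COMPARTMENTS[i], _COMPARTMENTS[j])
                ph[pair] = paired_test(data[:, i], data[:, j], n_comparisons=3)
    return AnovaResult(
        F=float(row["F"]),
        df1=df1,
        df2=df2,
        p=p,
        epsilon=eps,
        p_uncorrected=p_unc,
        n=n,
        posthoc=ph,
    )


def profile_consistency(
    profiles,
    mode: str = "within_task",
    other=None,
    shuffle: bool = False,
    seed: int | None = None,
) -> ConsistencyResult:
    """Pairwise Pearson correlation of laminar profiles.

    ``within_task``: all N(N-1)/2 penetration pairs of ``profiles``.
    ``between_task``: the N matched pairs (profiles[i], other[i]), i.e. the
    same penetration recorded in two tasks.  With ``shuffle=True`` the
    channels of the second member of each pair are randomly permuted -- the
    null control that destroys laminar structure while keeping the values.
    Significance of the mean r is a signed-rank test of the pairwise r
    against zero.
    """
    profiles = [np.asarray(p, dtype=float) for p in profiles]
    rng = np.random.default_rng(seed)
    if mode == "within_task":
        if len(profiles) < 2:
            raise ValueError("need >= 2 profiles")
        pairs = [
            (profiles[i], profiles[j])
            for i in range(len(profiles))
            for j in range(i + 1, len(profiles))
        ]
    elif mode == "between_task":
        if other is None or len(other) != len(profiles):
            raise ValueError("between_task mode needs matched 'other' profiles")
        pairs = list(zip(profiles, [np.asarray(p, float) for p in other]))
    else:
        raise ValueError("mode must be 'within_task' or 'between_task'")
    rs = []
    for a, b in pairs:
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if shuffle:
            b = b[rng.permutation(b.size)]
        if a.std() == 0 or b.std() == 0:
            warnings.warn("constant profile in a pair; skipping", stacklevel=2)
            continue
        rs.append(np.corrcoef(a, b)[0, 1])
    rs = np.asarray(rs)
    if rs.size == 0:
        raise ValueError("no valid profile pairs")
    if np.allclose(rs, 0):
        p = 1.0
    else:
        _, p = sps.wilcoxon(rs)
    return ConsistencyResult(
        mean_r=float(rs.mean()),
        r_values=rs,
        p=float(p),
        n_pairs=rs.size,
        mode=mode,
        shuffled=shuffle,
    )


def _t_map(maps: np.ndarray) -> np.ndarray:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _cluster_masses(t: np.ndarray, threshold: float):
    """Contiguous suprathreshold clusters (positive and negative separately)."""
    masks, masses = [], []
    for sign in (1.0, -1.0):
        lab, n_lab = ndimage.label(sign * t > threshold)
        for i in range(1, n_lab + 1):
            mask = lab == i
            masks.append(mask)
            masses.append(t[mask].sum())
    return masks, np.asarray(masses)


def cluster_permutation(
    diff_maps: np.ndarray,
    threshold: float = 2.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test on difference maps.

    A t-map across penetrations is thresholded at |t| > ``threshold``;
    contiguous channel x time clusters are scored by their t mass.  The null
    distribution of the maximum |cluster mass| is built by randomly flipping
    the sign of whole penetrations (valid when the two conditions are
    exchangeable within a penetration); each observed cluster's p is the
    fraction of permutations whose maximum mass reaches it (with add-one
    smoothing), controlling the family-wise error over the map.
    """
    maps = np.asarray(diff_maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("diff_maps must be (n_penetrations, n_channels, n_time)")
    n = maps.shape[0]
    if n < 8:
        raise ValueError("need >= 8 penetrations")
    if n_perm < 100:
        raise ValueError("need >= 100 permutations")
    t_obs = _t_map(maps)
    masks, masses = _cluster_masses(t_obs, threshold)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null_max = np.zeros(n_perm)
    sq = (maps**2).sum(axis=0)  # sign flips leave sums of squares unchanged
    for i in range(n_perm):
        flipped_mean = np.tensordot(signs[i], maps, axes=(0, 0)) / n
        var = (sq - n * flipped_mean**2) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = flipped_mean / np.sqrt(var / n)
        t[~np.isfinite(t)] = 0.0
        _, m = _cluster_masses(t, threshold)
        null_max[i] = np.abs(m).max() if m.size else 0.0

    if masses.size:
        p = (1.0 + (null_max[None, :] >= np.abs(masses)[:, None]).sum(axis=1)) / (
            n_perm + 1.0
        )
    else:
        p = np.array([])
    return ClusterResult(
        clusters=masks,
        cluster_masses=masses,
        p_values=p,
        t_map=t_obs,
        threshold=threshold,
        n_perm=n_perm,
        seed=seed,
    )
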