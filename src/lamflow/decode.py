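"""Single-trial linear decoding of target vs distractor from laminar MUA.

A linear support-vector machine is trained on window-averaged MUA per
recording site (one feature per channel), and its continuous decision values
on held-out trials feed an ROC analysis.  Trials are split 90%/10%
(stratified by class), the split is repeated 10 times with fresh random
splits and the ROC areas are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

log = logging.getLogger(__name__)


@dataclass
class DecodeResult:
    """Cross-validated ROC accuracy of the target/distractor decoder."""

    accuracy: float
    per_repeat: np.ndarray
    n_trials_per_class: dict
    window_ms: tuple | None
    seed: int
    n_repeats: int
    stratified: bool = True


def decode_session(
    features: np.ndarray,
    labels,
    seed: int = 0,
    n_repeats: int = 10,
    test_fraction: float = 0.1,
    C: float = 1.0,
    window_ms=None,
) -> DecodeResult:
    """Cross-validated SVM/ROC decoding for one session.

    Parameters
    ----------
    features : ndarray, shape (n_trials, n_channels)
        Window-averaged MUA per trial and recording site.
    labels : array-like of {two classes}
        Trial labels (e.g. 'target' / 'distractor').
    seed : int
        Controls the random 90/10 splits; identical inputs and seed give
        identical results.

    Notes
    -----
    Splits are stratified by class (whether the original splits were is
    unstated; the choice is recorded on the result).  Features are
    standardised inside each training fold; the SVM regularisation is fixed
    at C=1.  ROC areas come from continuous decision values, not hard
    labels.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if X.shape[0] < 20:
        raise ValueError("need at least 20 trials")
    y_bin = (y == classes[1]).astype(int)
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_fraction, random_state=seed
    )
    aucs = []
    for train, test in splitter.split(X, y_bin):
        if np.unique(y_bin[test]).size < 2:
            # stratification should prevent this; resample if it happens
            log.warning("single-class test split encountered; resampling")
            continue
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        clf.fit(X[train], y_bin[train])
        scores = clf.decision_function(X[test])
        aucs.append(roc_auc_score(y_bin[test], scores))
    per_repeat = np.asarray(aucs)
    return DecodeResult(
        accuracy=float(per_repeat.mean()),
        per_repeat=per_repeat,
        n_trials_per_class=dict(zip(classes.tolist(), counts.tolist())),
        window_ms=tuple(window_ms) if window_ms is not None else None,
        seed=seed,
        n_repeats=n_repeats,
    )


def permutation_significance(
    result: DecodeResult,
    features: np.ndarray,
    labels,
    n_perm: int = 200,
    seed: int = 0,
    n_repeats: int | None = None,
) -> float:
    """Permutation p value for a decoding accuracy.

    Re-runs the decoder on label-permuted data; p is the fraction of
    permuted mean accuracies at or above the observed one, with add-one
    smoothing, so the attainable floor is 1/(n_perm + 1).  ``n_repeats``
    can be reduced below the observed result's to bound the cost.
    """
    if n_perm < 100:
        raise ValueError("need >= 100 permutations")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    reps = n_repeats if n_repeats is not None else result.n_repeats
    count = 0
    for i in range(n_perm):
        perm = rng.permutation(y.size)
        null = decode_session(
            features, y[perm], seed=int(rng.integers(2**31)), n_repeats=reps
        )
        if null.accuracy >= result.accuracy:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)
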