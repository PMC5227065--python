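"""Session container: a directory of arrays with a JSON sidecar.

Layout of a session directory::

    session.json   sampling rates, channel geometry, seeds, provenance
    trials.csv     per-trial metadata (task, condition, correctness, ...)
    lfp.npy        (n_trials, n_channels, n_time)
    mua.npy        (n_trials, n_channels, n_time)
    eye.npy        (n_trials, 2, n_eye)         [optional]
    wideband.npy   raw signal                   [optional]

The sidecar is schema-validated on read; shape mismatches and invalid
fields are rejected with field-level messages.  Processing steps append to
the ``provenance`` list, never rewrite it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording

SCHEMA_VERSION = 1
_ARRAYS = ("lfp", "mua", "eye", "wideband")


def write_session(path, recording: Recording, trials: pd.DataFrame) -> Path:
    """Serialise a Recording and its trial table to a session directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "lfp.npy", recording.lfp)
    np.save(path / "mua.npy", recording.mua)
    if recording.eye is not None:
        np.save(path / "eye.npy", recording.eye)
    if recording.wideband is not None:
        np.save(path / "wideband.npy", recording.wideband)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "penetration_id": recording.penetration_id,
        "fs_lfp": recording.fs_lfp,
        "fs_mua": recording.fs_mua,
        "fs_eye": recording.fs_eye,
        "fs_wideband": recording.fs_wideband,
        "times_ms": recording.times_ms.tolist(),
        "eye_times_ms": (
            None
            if recording.eye_times_ms is None
            else recording.eye_times_ms.tolist()
        ),
        "channel_depths_mm": recording.channel_depths_mm.tolist(),
        "meta": recording.meta,
        "provenance": list(recording.meta.get("provenance", [])),
    }
    (path / "session.json").write_text(json.dumps(sidecar, indent=1))
    trials.to_csv(path / "trials.csv", index=False)
    return path


def _require(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid session: field {field!r}: {msg}")


def read_session(path):
    """Load and validate a session directory.

    Returns
    -------
    (Recording, DataFrame)

    Raises
    ------
    ValueError
        On missing arrays, shape mismatches, nonpositive sampling rates or
        an unknown schema version, naming the offending field.
    """
    path = Path(path)
    sidecar_path = path / "session.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no session.json in {path}")
    sc = json.loads(sidecar_path.read_text())
    _require(
        sc.get("schema_version") == SCHEMA_VERSION,
        "schema_version",
        f"expected {SCHEMA_VERSION}, got {sc.get('schema_version')}",
    )
    for f in ("fs_lfp", "fs_mua", "fs_eye"):
        _require(
            isinstance(sc.get(f), (int, float)) and sc[f] > 0, f, "must be > 0"
        )
    for name in ("lfp", "mua"):
        _require((path / f"{name}.npy").exists(), name, "array file missing")
    lfp = np.load(path / "lfp.npy")
    mua = np.load(path / "mua.npy")
    times = np.asarray(sc["times_ms"], dtype=float)
    depths = np.asarray(sc["channel_depths_mm"], dtype=float)
    _require(lfp.shape == mua.shape, "mua", f"shape {mua.shape} != lfp {lfp.shape}")
    _require(
        lfp.shape[2] == times.size, "times_ms", "length does not match arrays"
    )
    _require(
        lfp.shape[1] == depths.size,
        "channel_depths_mm",
        "length does not match arrays",
    )
    eye = np.load(path / "eye.npy") if (path / "eye.npy").exists() else None
    if eye is not None:
        _require(eye.shape[0] == lfp.shape[0], "eye", "trial count mismatch")
    wb = (
        np.load(path / "wideband.npy")
        if (path / "wideband.npy").exists()
        else None
    )
    trials = pd.read_csv(path / "trials.csv")
    _require(len(trials) == lfp.shape[0], "trials.csv", "row count mismatch")
    rec = Recording(
        lfp=lfp,
        mua=mua,
        times_ms=times,
        fs_lfp=sc["fs_lfp"],
        fs_mua=sc["fs_mua"],
        channel_depths_mm=depths,
        penetration_id=sc.get("penetration_id", "session"),
        eye=eye,
        eye_times_ms=(
            None
            if sc.get("eye_times_ms") is None
            else np.asarray(sc["eye_times_ms"], dtype=float)
        ),
        fs_eye=sc["fs_eye"],
        wideband=wb,
        fs_wideband=sc.get("fs_wideband"),
        meta=sc.get("meta", {}),
    )
    return rec, trials


def append_provenance(path, step: str) -> None:
    """Record a processing step in the sidecar (append-only)."""
    path = Path(path) / "session.json"
    sc = json.loads(path.read_text())
    sc.setdefault("provenance", []).append(step)
    path.write_text(json.dumps(sc, indent=1))
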