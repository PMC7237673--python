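"""Plain-text serialisation: trials, activation matrices, decompositions.

Trials are a CSV (one row per channel, header = channel labels as the index
column) plus a JSON sidecar with sampling rate, gait-event indices,
condition and seed.  Decompositions are a directory of W.csv / H.csv and a
meta.json.  Everything is reproducible text; no binary formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .factorization import SynergyDecomposition
from .preprocessing import ActivationMatrix, RawEMGTrial

__all__ = [
    "write_trial",
    "read_trial",
    "write_activation",
    "read_activation",
    "write_decomposition",
    "read_decomposition",
]


def write_trial(trial: RawEMGTrial, stem: Path | str) -> None:
    """Write <stem>.csv (channels x samples) and <stem>.json sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(trial.signal, index=trial.channel_labels)
    df.index.name = "channel"
    df.to_csv(stem.with_suffix(".csv"), float_format="%.8g")
    sidecar = {
        "fs_hz": trial.fs,
        "events": list(trial.events),
        "condition": trial.condition,
        "seed": trial.seed,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trial(stem: Path | str) -> RawEMGTrial:
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"), index_col="channel")
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    return RawEMGTrial(
        signal=df.to_numpy(dtype=float),
        fs=float(sidecar["fs_hz"]),
        events=tuple(sidecar["events"]),
        channel_labels=[str(c) for c in df.index],
        condition=sidecar.get("condition"),
        seed=sidecar.get("seed"),
    )


def write_activation(act: ActivationMatrix, path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(act.x, index=act.channel_labels)
    df.index.name = "channel"
    df.to_csv(path, float_format="%.10g")


def read_activation(path: Path | str) -> ActivationMatrix:
    df = pd.read_csv(path, index_col="channel")
    return ActivationMatrix(x=df.to_numpy(dtype=float),
                            channel_labels=[str(c) for c in df.index])


def write_decomposition(dec: SynergyDecomposition, directory: Path | str) -> None:
    """Serialise a decomposition as W.csv, H.csv and meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "W.csv", dec.W, delimiter=",")
    np.savetxt(directory / "H.csv", dec.H, delimiter=",")
    meta = {
        "method": dec.method,
        "K": dec.K,
        "offset": None if dec.offset is None else dec.offset.ravel().tolist(),
        "mixing": None if dec.mixing is None else dec.mixing.tolist(),
        "meta": {k: v for k, v in dec.meta.items() if k != "objective_history"},
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def read_decomposition(directory: Path | str) -> SynergyDecomposition:
    directory = Path(directory)
    W = np.atleast_2d(np.loadtxt(directory / "W.csv", delimiter=","))
    H = np.atleast_2d(np.loadtxt(directory / "H.csv", delimiter=","))
    meta = json.loads((directory / "meta.json").read_text())
    offset = meta["offset"]
    offset = None if offset is None else np.asarray(offset, dtype=float).reshape(-1, 1)
    mixing = meta["mixing"]
    mixing = None if mixing is None else np.asarray(mixing, dtype=float)
    x_hat = W @ H + (offset if offset is not None else 0.0)
    return SynergyDecomposition(
        W=W, H=H, method=meta["method"], K=int(meta["K"]),
        x_hat=x_hat, offset=offset, mixing=mixing, meta=meta.get("meta", {}),
    )
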