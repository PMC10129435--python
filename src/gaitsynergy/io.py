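"""Plain-text serialization: CSV for tabular data, JSON for metadata.

File conventions
----------------
recording CSV   header ``time_s,<muscle...>``, one row per sample
events CSV      header ``cycle_index,start_sample,end_sample``; 0-based,
                half-open ``[start, end)``
matrix CSV      one labeled column per muscle, one row per cycle point;
                provenance in a ``<name>.provenance.json`` sidecar
decomposition   ``<base>_H.csv`` (cycle points x k), ``<base>_W.csv``
                (k x muscles, labeled columns), ``<base>_meta.json``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import EMGRecording, GaitCycleMatrix
from .extract import SynergyDecomposition
from .simulate import GroundTruthSynergyModel

__all__ = [
    "write_recording_csv", "read_recording_csv",
    "write_events_csv", "read_events_csv",
    "write_matrix_csv", "read_matrix_csv",
    "write_decomposition", "read_decomposition",
    "write_ground_truth_json", "read_ground_truth_json",
]


def write_recording_csv(path: str | Path, rec: EMGRecording) -> None:
    t = np.arange(rec.n_samples) / rec.sampling_rate
    df = pd.DataFrame(rec.samples, columns=list(rec.channel_labels))
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False, float_format="%.9g")


def read_recording_csv(path: str | Path) -> EMGRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing 'time_s' column")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    fs = 1.0 / np.median(np.diff(t))
    channels = [c for c in df.columns if c != "time_s"]
    return EMGRecording(df[channels].to_numpy(float), float(fs), tuple(channels))


def write_events_csv(path: str | Path, events: Sequence[tuple[int, int]]) -> None:
    df = pd.DataFrame(
        [(i, s, e) for i, (s, e) in enumerate(events)],
        columns=["cycle_index", "start_sample", "end_sample"],
    )
    df.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> tuple[tuple[int, int], ...]:
    df = pd.read_csv(path)
    needed = {"cycle_index", "start_sample", "end_sample"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    df = df.sort_values("cycle_index")
    return tuple(
        (int(r.start_sample), int(r.end_sample)) for r in df.itertuples()
    )


def write_matrix_csv(path: str | Path, mat: GaitCycleMatrix) -> None:
    path = Path(path)
    pd.DataFrame(mat.values, columns=list(mat.channel_labels)).to_csv(
        path, index=False, float_format="%.9g"
    )
    if mat.provenance:
        sidecar = path.with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(dict(mat.provenance), indent=1,
                                      default=str))


def read_matrix_csv(path: str | Path) -> GaitCycleMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    prov = {}
    sidecar = path.with_suffix(".provenance.json")
    if sidecar.exists():
        prov = json.loads(sidecar.read_text())
    return GaitCycleMatrix(df.to_numpy(float), tuple(df.columns), prov)


def write_decomposition(
    out_dir: str | Path,
    dec: SynergyDecomposition,
    base: str,
    muscles: Sequence[str],
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        dec.H, columns=[f"synergy_{j + 1}" for j in range(dec.k)]
    ).to_csv(out_dir / f"{base}_H.csv", index=False, float_format="%.9g")
    pd.DataFrame(dec.W, columns=list(muscles)).to_csv(
        out_dir / f"{base}_W.csv", index=False, float_format="%.9g"
    )
    meta = {
        "k": dec.k,
        "frobenius_loss": dec.frobenius_loss,
        "vaf_per_muscle": {m: float(v) for m, v in zip(muscles, dec.vaf_muscle)},
        "vaf_global": dec.vaf_total,
        "seed_used": dec.seed_used,
        "n_iterations": dec.n_iterations,
    }
    (out_dir / f"{base}_meta.json").write_text(json.dumps(meta, indent=1))


def read_decomposition(out_dir: str | Path, base: str) -> SynergyDecomposition:
    out_dir = Path(out_dir)
    H = pd.read_csv(out_dir / f"{base}_H.csv").to_numpy(float)
    W = pd.read_csv(out_dir / f"{base}_W.csv").to_numpy(float)
    meta = json.loads((out_dir / f"{base}_meta.json").read_text())
    return SynergyDecomposition(
        H=H, W=W, k=int(meta["k"]),
        frobenius_loss=float(meta["frobenius_loss"]),
        vaf_muscle=np.array(list(meta["vaf_per_muscle"].values())),
        vaf_total=float(meta["vaf_global"]),
        seed_used=int(meta["seed_used"]),
        n_iterations=int(meta["n_iterations"]),
    )


def write_ground_truth_json(
    path: str | Path, model: GroundTruthSynergyModel
) -> None:
    payload = {
        "k_true": model.k_true,
        "W_true": model.W_true.tolist(),
        "burst_centers": list(model.burst_centers),
        "burst_widths": list(model.burst_widths),
        "noise_sigma": model.noise_sigma,
        "seed": model.seed,
        "channel_labels": list(model.channel_labels),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path: str | Path) -> GroundTruthSynergyModel:
    d = json.loads(Path(path).read_text())
    return GroundTruthSynergyModel(
        k_true=int(d["k_true"]),
        W_true=np.array(d["W_true"]),
        burst_centers=tuple(d["burst_centers"]),
        burst_widths=tuple(d["burst_widths"]),
        noise_sigma=float(d["noise_sigma"]),
        seed=int(d["seed"]),
        channel_labels=tuple(d["channel_labels"]),
    )
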