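"""Plain-text file formats: traces, dataset manifests, matrices, models.

* Trace: two-column delimited text (delay_ps, amplitude), one file per scan.
* Dataset manifest: JSON mapping sample ids to class labels, scan files and
  reference files, plus geometry, seed and a config echo.
* Spectra matrix: CSV with columns sample_id, label, then one column per
  frequency variable (header = frequency in THz); JSON sidecar with band,
  variable count, feature type, geometry and provenance.
* PLS model: JSON of all arrays plus a provenance hash of the training
  matrix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import SampleGeometry, SpectraMatrix, TimeDomainTrace
from .pls import PLSModel
from .simulate import InstrumentModel, SimulatedDataset

__all__ = [
    "write_trace",
    "read_trace",
    "write_dataset",
    "read_dataset",
    "write_matrix",
    "read_matrix",
    "save_model",
    "load_model",
    "matrix_hash",
]


def write_trace(trace: TimeDomainTrace, path) -> None:
    np.savetxt(
        path,
        np.column_stack([trace.delays, trace.amplitudes]),
        fmt="%.9e",
        header="delay_ps amplitude",
    )


def read_trace(path) -> TimeDomainTrace:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (delay_ps, amplitude)")
    return TimeDomainTrace(data[:, 0], data[:, 1])


def write_dataset(dataset: SimulatedDataset, out_dir) -> Path:
    """Persist all traces plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    scan_files: Dict[str, list] = {}
    for sid, scan, trace in dataset.traces:
        rel = f"traces/{sid}_scan{scan}.txt"
        write_trace(trace, out / rel)
        scan_files.setdefault(sid, []).append(rel)
    ref_files = []
    for i, trace in enumerate(dataset.reference_traces):
        rel = f"traces/reference_{i:03d}.txt"
        write_trace(trace, out / rel)
        ref_files.append(rel)
    manifest = {
        "labels": dataset.labels,
        "scan_files": scan_files,
        "reference_files": ref_files,
        "reference_index": dataset.reference_index,
        "geometry": asdict(dataset.geometry),
        "instrument": asdict(dataset.instrument),
        "rng_seed": dataset.rng_seed,
        "scans_per_sample": dataset.scans_per_sample,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def read_dataset(manifest_path) -> SimulatedDataset:
    mpath = Path(manifest_path)
    m = json.loads(mpath.read_text())
    base = mpath.parent
    traces = []
    for sid, files in m["scan_files"].items():
        for scan, rel in enumerate(files, start=1):
            traces.append((sid, scan, read_trace(base / rel)))
    refs = [read_trace(base / rel) for rel in m["reference_files"]]
    return SimulatedDataset(
        traces=traces,
        reference_traces=refs,
        reference_index={k: int(v) for k, v in m["reference_index"].items()},
        labels={k: int(v) for k, v in m["labels"].items()},
        geometry=SampleGeometry(**m["geometry"]),
        rng_seed=int(m["rng_seed"]),
        instrument=InstrumentModel(**m["instrument"]),
        scans_per_sample=int(m["scans_per_sample"]),
    )


def matrix_hash(matrix: SpectraMatrix) -> str:
    """Stable content hash of a matrix, used as model provenance."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(matrix.X).tobytes())
    h.update(np.ascontiguousarray(matrix.y).tobytes())
    h.update(np.ascontiguousarray(matrix.variable_frequencies).tobytes())
    return h.hexdigest()[:16]


def write_matrix(
    matrix: SpectraMatrix, path, sidecar: Optional[dict] = None
) -> None:
    """CSV with frequency-labelled columns plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        matrix.X, columns=[repr(float(f)) for f in matrix.variable_frequencies]
    )
    df.insert(0, "label", matrix.y)
    df.insert(0, "sample_id", list(matrix.sample_ids))
    # %.17g keeps the round trip bit-exact, so the provenance hash survives
    df.to_csv(path, index=False, float_format="%.17g")
    meta = dict(sidecar or {})
    meta.update(
        {
            "n_samples": matrix.n_samples,
            "n_variables": matrix.n_variables,
            "band_THz": [
                float(matrix.variable_frequencies[0]),
                float(matrix.variable_frequencies[-1]),
            ],
            "hash": matrix_hash(matrix),
        }
    )
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def read_matrix(path) -> SpectraMatrix:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ValueError(f"{path}: expected sample_id,label leading columns")
    freqs = np.array([float(c) for c in df.columns[2:]])
    return SpectraMatrix(
        df.iloc[:, 2:].to_numpy(float),
        freqs,
        df["label"].to_numpy(int),
        tuple(df["sample_id"].astype(str)),
    )


def save_model(model: PLSModel, path, provenance: Optional[dict] = None) -> None:
    payload = {
        "n_components": model.n_components,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "x_scores": model.x_scores.tolist(),
        "y_scores": model.y_scores.tolist(),
        "coefficients": model.coefficients.tolist(),
        "variable_frequencies": (
            None
            if model.variable_frequencies is None
            else model.variable_frequencies.tolist()
        ),
        "rmsec": model.rmsec,
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path) -> Tuple[PLSModel, dict]:
    m = json.loads(Path(path).read_text())
    model = PLSModel(
        n_components=int(m["n_components"]),
        x_mean=np.array(m["x_mean"]),
        y_mean=float(m["y_mean"]),
        weights=np.array(m["weights"]),
        x_loadings=np.array(m["x_loadings"]),
        y_loadings=np.array(m["y_loadings"]),
        x_scores=np.array(m["x_scores"]),
        y_scores=np.array(m["y_scores"]),
        coefficients=np.array(m["coefficients"]),
        variable_frequencies=(
            None
            if m["variable_frequencies"] is None
            else np.array(m["variable_frequencies"])
        ),
        rmsec=float(m["rmsec"]),
    )
    return model, m.get("provenance", {})
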