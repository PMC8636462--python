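"""Reading and writing matrices, models and ground-truth sidecars.

Dense matrices travel as CSV/TSV with a header row of variable ids and an
optional first column of row ids; large sparse inputs may be MatrixMarket
(.mtx), densified on load.  Fitted models and generator ground truth are
stored as JSON sidecars so a pipeline run is fully reconstructible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .pca_core import ComponentModel, DataMatrix
from .synthetic import GeneratedDataset

__all__ = [
    "load_matrix",
    "save_matrix",
    "save_dataset",
    "load_truth",
    "save_model",
    "load_model",
]


def load_matrix(path) -> DataMatrix:
    """Load a data matrix from CSV, TSV or MatrixMarket."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mtx", ".mm"):
        values = scipy.io.mmread(path)
        if scipy.sparse.issparse(values):
            values = values.toarray()
        return DataMatrix(values=np.asarray(values, dtype=float))
    sep = "\t" if suffix in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    first = frame.columns[0]
    row_ids = None
    if frame[first].dtype == object:
        row_ids = frame[first].astype(str).tolist()
        frame = frame.drop(columns=[first])
    return DataMatrix(
        values=frame.to_numpy(dtype=float),
        row_ids=row_ids,
        col_ids=[str(c) for c in frame.columns],
    )


def save_matrix(X: DataMatrix, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".mtx", ".mm"):
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(X.values))
        return
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    cols = X.col_ids or [f"v{j + 1}" for j in range(X.values.shape[1])]
    frame = pd.DataFrame(X.values, columns=cols)
    if X.row_ids is not None:
        frame.insert(0, "id", X.row_ids)
    frame.to_csv(path, sep=sep, index=False)


def save_dataset(dataset: GeneratedDataset, out_dir, stem: str) -> None:
    """Write X as CSV plus a JSON sidecar with the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_matrix(dataset.X, out_dir / f"{stem}.csv")
    sidecar = {
        "regime": dataset.regime,
        "scenario": dataset.scenario,
        "vaf": dataset.vaf,
        "ps": dataset.ps,
        "seed": dataset.seed,
        "T_true": dataset.T_true.tolist(),
        "P_true": dataset.P_true.tolist(),
        "W_true": None if dataset.W_true is None else dataset.W_true.tolist(),
        "zero_mask_P": None
        if dataset.zero_mask_P is None
        else dataset.zero_mask_P.astype(int).tolist(),
        "zero_mask_W": None
        if dataset.zero_mask_W is None
        else dataset.zero_mask_W.astype(int).tolist(),
    }
    (out_dir / f"{stem}.truth.json").write_text(json.dumps(sidecar))


def load_truth(path) -> dict:
    """Load a ground-truth sidecar, converting lists back to arrays."""
    raw = json.loads(Path(path).read_text())
    for key in ("T_true", "P_true", "W_true"):
        if raw.get(key) is not None:
            raw[key] = np.asarray(raw[key], dtype=float)
    for key in ("zero_mask_P", "zero_mask_W"):
        if raw.get(key) is not None:
            raw[key] = np.asarray(raw[key], dtype=bool)
    return raw


def save_model(model: ComponentModel, path) -> None:
    payload = {
        "method": model.method,
        "n_components": model.n_components,
        "formulation": model.formulation,
        "scores": model.scores.tolist(),
        "loadings": model.loadings.tolist(),
        "weights": None if model.weights is None else model.weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> ComponentModel:
    raw = json.loads(Path(path).read_text())
    return ComponentModel(
        scores=np.asarray(raw["scores"], dtype=float),
        loadings=np.asarray(raw["loadings"], dtype=float),
        weights=None
        if raw["weights"] is None
        else np.asarray(raw["weights"], dtype=float),
        n_components=raw["n_components"],
        method=raw["method"],
        formulation=raw.get("formulation"),
    )
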