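"""Delimited-text readers and writers.

All artifacts are plain text: series tables (one series per row,
comma or tab delimited, optional leading label column in the
UCR/UEA label-first dialect), square distance matrices, feature
matrices with a YAML metadata sidecar, and NMF models as a pair of
matrices plus metadata.  Numeric round-trips use full ``repr``
precision.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence

import numpy as np
import yaml

from .embedding import DistanceMatrix, TimeSeries
from .nmf import NMFModel
from .pimage import PIGridSpec

__all__ = [
    "read_series_table",
    "write_series_table",
    "write_matrix",
    "read_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
    "save_nmf_model",
    "load_nmf_model",
]


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_series_table(path, label_col: Optional[int] = None) -> List[TimeSeries]:
    """Read one series per row from a delimited text file.

    ``label_col=0`` selects the UCR/UEA label-first dialect: the first
    column is a class label and the rest are the signal.  Delimiter
    (comma or tab) is sniffed from the first line.
    """
    series: List[TimeSeries] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        for i, line in enumerate([first] + fh.readlines()):
            line = line.strip()
            if not line:
                continue
            fields = line.split(delim)
            label = None
            if label_col is not None:
                label = fields[label_col]
                fields = fields[:label_col] + fields[label_col + 1 :]
            values = np.array([float(v) for v in fields])
            series.append(TimeSeries(values, label=label, id=f"row{i}"))
    return series


def write_series_table(series: Sequence[TimeSeries], path, delimiter: str = "\t") -> None:
    """Write one series per row; the label (if any) becomes column 0."""
    with open(path, "w") as fh:
        for ts in series:
            fields = [repr(float(v)) for v in ts.values]
            if ts.label is not None:
                fields = [str(ts.label)] + fields
            fh.write(delimiter.join(fields) + "\n")


def write_matrix(matrix, path, delimiter: str = "\t") -> None:
    """Full-precision delimited matrix (repr round-trip)."""
    arr = matrix.entries if isinstance(matrix, DistanceMatrix) else np.asarray(matrix, float)
    with open(path, "w") as fh:
        for row in np.atleast_2d(arr):
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def read_matrix(path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first)
        rows = [
            [float(v) for v in line.strip().split(delim)]
            for line in [first] + fh.readlines()
            if line.strip()
        ]
    return np.array(rows)


def write_feature_matrix(features: np.ndarray, grid: PIGridSpec, path) -> None:
    """Write PI vectors one sample per row, with a ``.meta.yaml`` sidecar
    holding the grid so vectors remain comparable across runs."""
    write_matrix(features, path)
    meta = {
        "birth_range": [float(x) for x in grid.birth_range],
        "death_range": [float(x) for x in grid.death_range],
        "resolution": [int(x) for x in grid.resolution],
        "sigma": float(grid.sigma),
        "weight_name": grid.weight_name,
        "weight_mode": grid.weight_mode,
    }
    with open(str(path) + ".meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_feature_matrix(path):
    features = read_matrix(path)
    with open(str(path) + ".meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    grid = PIGridSpec(
        birth_range=tuple(meta["birth_range"]),
        death_range=tuple(meta["death_range"]),
        resolution=tuple(meta["resolution"]),
        sigma=meta["sigma"],
        weight_name=meta["weight_name"],
        weight_mode=meta["weight_mode"],
    )
    return features, grid


def save_nmf_model(model: NMFModel, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    write_matrix(model.P, os.path.join(directory, "P.tsv"))
    write_matrix(model.Q, os.path.join(directory, "Q.tsv"))
    meta = {
        "rank": int(model.rank),
        "seed": int(model.seed),
        "n_iter": int(model.n_iter),
        "final_error": float(model.reconstruction_error),
        "error_trace": [float(e) for e in model.error_trace],
    }
    with open(os.path.join(directory, "meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def load_nmf_model(directory) -> NMFModel:
    P = read_matrix(os.path.join(directory, "P.tsv"))
    Q = read_matrix(os.path.join(directory, "Q.tsv"))
    with open(os.path.join(directory, "meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    return NMFModel(
        P=P,
        Q=Q,
        rank=meta["rank"],
        error_trace=meta["error_trace"],
        seed=meta["seed"],
        n_iter=meta["n_iter"],
    )
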