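"""Delimited-text readers/writers and plain-text model persistence.

Input matrices are CSV/TSV; microarray-style matrices with genes in rows are
transposed on request. Labels of any two-level coding are mapped onto -1/+1 by
sorted order (first level -> -1) and the mapping is logged. Models are stored
as a key-value header plus a coefficient table, with coefficients written in
round-tripping decimal (`repr`) so that reloading reproduces decision values
bit-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Dataset, LinearModel, PenaltySpec

logger = logging.getLogger("pensvm")

__all__ = [
    "map_labels",
    "read_dataset",
    "write_dataset",
    "write_model",
    "read_model",
]


def map_labels(raw) -> tuple[np.ndarray, dict]:
    """Map a two-level label vector onto -1/+1 by sorted level order."""
    raw = np.asarray(raw)
    levels = sorted(pd.unique(raw).tolist(), key=str)
    if len(levels) != 2:
        raise ValueError(f"labels must have exactly two levels, got {levels}")
    if set(levels) == {-1, 1} or set(levels) == {-1.0, 1.0}:
        mapping = {-1: -1, 1: 1}
        return raw.astype(float), mapping
    mapping = {levels[0]: -1, levels[1]: 1}
    logger.info("label mapping: %r -> -1, %r -> +1", levels[0], levels[1])
    return np.where(raw == levels[0], -1.0, 1.0), mapping


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_dataset(
    path,
    label: str = "label",
    features_in_rows: bool = False,
    delimiter: str | None = None,
    label_path=None,
) -> tuple[Dataset, dict]:
    """Read a delimited feature matrix (+ labels) into a Dataset.

    ``label`` names the label column of a samples-in-rows file; with
    ``features_in_rows`` the matrix is transposed and labels must come from
    ``label_path`` (one label per line, aligned with the matrix columns).
    Returns the dataset and the applied label mapping.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if features_in_rows:
        df = df.T
    if label_path is not None:
        raw_labels = pd.read_csv(label_path, header=None).iloc[:, 0].to_numpy()
    else:
        if label not in df.columns:
            raise ValueError(f"label column {label!r} not found in {path}")
        raw_labels = df.pop(label).to_numpy()
    try:
        X = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature values in {path}: {exc}") from exc
    if np.isnan(X).any():
        raise ValueError(f"missing feature values in {path}")
    y, mapping = map_labels(raw_labels)
    ds = Dataset(X, y, [str(c) for c in df.columns], [str(i) for i in df.index])
    ds.require_both_classes()
    return ds, mapping


def write_dataset(data: Dataset, path, delimiter: str | None = None, label: str = "label") -> None:
    """Write a Dataset as a samples-in-rows delimited file with a label column."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.DataFrame(data.X, index=data.sample_ids, columns=data.feature_ids)
    df[label] = data.y.astype(int)
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# model persistence

_MODEL_HEADER = "# pensvm linear model v1"


def write_model(model: LinearModel, path) -> None:
    """Persist a LinearModel as plain text (header + active-coefficient table)."""
    spec = model.penalty or PenaltySpec("ridge")
    lines = [
        _MODEL_HEADER,
        f"family\t{spec.family}",
        f"lambda1\t{spec.lambda1!r}",
        f"lambda2\t{spec.lambda2!r}",
        f"a\t{spec.a!r}",
        f"C\t{spec.C!r}",
        f"p\t{model.n_features}",
        f"b\t{model.b!r}",
        f"solver\t{model.meta.get('solver', 'unknown')}",
        f"converged\t{model.meta.get('converged', True)}",
        f"iterations\t{model.meta.get('iterations', 0)}",
        "coefficients\tindex\tvalue",
    ]
    for j in model.active_set:
        lines.append(f"\t{int(j)}\t{float(model.w[j])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path) -> LinearModel:
    """Load a model written by `write_model`; NaN coefficients are rejected."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _MODEL_HEADER:
        raise ValueError(f"{path}: not a pensvm model file (line 1)")
    header: dict[str, str] = {}
    coef_rows: list[tuple[int, float]] = []
    in_coefs = False
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("coefficients"):
            in_coefs = True
            continue
        parts = line.split("\t")
        if in_coefs:
            try:
                j, value = int(parts[1]), float(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed coefficient at line {lineno}") from exc
            if not np.isfinite(value):
                raise ValueError(f"{path}: non-finite coefficient at line {lineno}")
            coef_rows.append((j, value))
        else:
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed header entry at line {lineno}")
            header[parts[0]] = parts[1]
    try:
        p = int(header["p"])
        b = float(header["b"])
        spec = PenaltySpec(
            header["family"],
            lambda1=float(header["lambda1"]),
            lambda2=float(header["lambda2"]),
            a=float(header["a"]),
            C=float(header["C"]),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing header field {exc}") from exc
    if not np.isfinite(b):
        raise ValueError(f"{path}: non-finite intercept")
    w = np.zeros(p)
    for j, value in coef_rows:
        if not 0 <= j < p:
            raise ValueError(f"{path}: coefficient index {j} out of range")
        w[j] = value
    return LinearModel(
        w=w,
        b=b,
        penalty=spec,
        meta={
            "solver": header.get("solver", "unknown"),
            "converged": header.get("converged", "True") == "True",
            "iterations": int(header.get("iterations", 0)),
        },
    )
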