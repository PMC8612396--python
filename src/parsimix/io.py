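"""Reading and writing of matrices, labels, parameters and BIC tables.

Matrices travel as delimited text (CSV/TSV, one row per observation, optional
header); parameters as JSON with infinite constraint constants serialized as
the string ``"inf"``; labels as one 1-based integer per line.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import ConstraintSpec
from .params import MixtureParameters


def _sniff(path: Path, delimiter: str | None):
    with open(path) as fh:
        first = fh.readline()
    if delimiter is None:
        delimiter = "\t" if "\t" in first else ","
    tokens = [t for t in first.strip().split(delimiter) if t != ""]
    try:
        [float(t) for t in tokens]
        header = None
    except ValueError:
        header = 0
    return delimiter, header


def read_matrix(path, delimiter: str | None = None, header: str | int | None = "auto") -> np.ndarray:
    """Read a numeric data matrix from delimited text.

    The delimiter (comma or tab) and the presence of a header row are
    auto-detected unless given.  Ragged rows or non-numeric/non-finite
    entries raise a ``ValueError`` naming the offending line.
    """
    path = Path(path)
    sniff_delim, sniff_header = _sniff(path, delimiter)
    if header == "auto":
        header = sniff_header
    try:
        df = pd.read_csv(path, sep=sniff_delim, header=header)
    except pd.errors.ParserError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    try:
        X = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = df.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
        rows = np.flatnonzero(bad.to_numpy())
        raise ValueError(f"non-numeric entries in data rows {rows.tolist()} of {path}") from exc
    if not np.isfinite(X).all():
        rows = np.flatnonzero(~np.isfinite(X).all(axis=1))
        raise ValueError(f"non-finite or missing entries in data rows {rows.tolist()} of {path}")
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError(f"{path} does not hold a non-empty 2-D matrix")
    return X


def write_labels(labels, path) -> None:
    """Write one 1-based label per line."""
    labels = np.asarray(labels, dtype=int) + 1
    np.savetxt(path, labels, fmt="%d")


def read_labels(path) -> np.ndarray:
    """Read 1-based labels into a 0-based array."""
    return np.loadtxt(path, dtype=int).ravel() - 1


def params_to_json_dict(params: MixtureParameters, spec: ConstraintSpec | None = None, **extra) -> dict:
    doc = params.to_dict()
    if spec is not None:
        doc["spec"] = spec.to_dict()
    for key, value in extra.items():
        doc[key] = "inf" if isinstance(value, float) and math.isinf(value) else value
    return doc


def write_params(params: MixtureParameters, path, spec: ConstraintSpec | None = None, **extra) -> None:
    """Serialize mixture parameters (and optionally their spec) to JSON."""
    with open(path, "w") as fh:
        json.dump(params_to_json_dict(params, spec, **extra), fh, indent=1)
        fh.write("\n")


def read_params(path) -> tuple[MixtureParameters, ConstraintSpec | None, dict]:
    """Read parameters back from JSON; returns (params, spec, extras)."""
    with open(path) as fh:
        doc = json.load(fh)
    params = MixtureParameters.from_dict(doc)
    spec = ConstraintSpec.from_dict(doc["spec"]) if "spec" in doc else None
    known = {"k", "p", "weights", "means", "scatters", "decomposition", "spec"}
    extra = {k: v for k, v in doc.items() if k not in known}
    return params, spec, extra


def write_fit_result(estimator, prefix) -> list[Path]:
    """Write labels CSV and parameters JSON for a fitted mixture estimator."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    labels_path = prefix.with_name(prefix.name + "_labels.csv")
    params_path = prefix.with_name(prefix.name + "_params.json")
    write_labels(estimator.labels_, labels_path)
    write_params(
        estimator.params_,
        params_path,
        spec=estimator.spec_,
        loglik=estimator.log_likelihood_,
        mode=estimator.mode,
        converged=bool(estimator.converged_),
    )
    return [labels_path, params_path]


def write_selection_result(selector, prefix) -> list[Path]:
    """Write the BIC table, selection JSON and labels of a model search."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table_path = prefix.with_name(prefix.name + "_bic.csv")
    sel_path = prefix.with_name(prefix.name + "_selection.json")
    labels_path = prefix.with_name(prefix.name + "_labels.csv")
    table = selector.table_.copy()
    for col in ("c_det", "c_shw", "c_shb"):
        table[col] = table[col].map(lambda v: "inf" if math.isinf(v) else v)
    table.to_csv(table_path, index=False)
    with open(sel_path, "w") as fh:
        json.dump(selector.result_.to_dict(), fh, indent=1)
        fh.write("\n")
    write_labels(selector.labels_, labels_path)
    return [table_path, sel_path, labels_path]
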