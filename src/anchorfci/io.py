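"""Readers and writers: datasets + roles configs, PAG matrices, DOT export.

The graph file format is a square integer matrix in CSV with a header row
of node labels; entry [i, j] is the mark at j on the edge i-j, coded
0 = absent, 1 = circle, 2 = arrowhead, 3 = tail.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .citest import DataError, validate_column_types
from .estimators import VariableRoles, infer_column_types
from .graph import GraphError, MarkedGraph, PAG


def read_roles(path: str | Path) -> tuple[VariableRoles, dict[str, str] | None]:
    """Load a roles config (YAML or JSON): interest/anchors/covariates lists
    plus an optional ``types`` map."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise DataError(f"roles file {path} must contain a mapping")
    roles = VariableRoles.from_dict(cfg)
    types = cfg.get("types")
    return roles, dict(types) if types else None


def write_roles(
    path: str | Path, roles: VariableRoles, types: Mapping[str, str] | None = None
) -> None:
    d = roles.to_dict()
    if types:
        d["types"] = dict(types)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_dataset(
    data_path: str | Path, roles_path: str | Path
) -> tuple[pd.DataFrame, dict[str, str], VariableRoles]:
    """Read a CSV dataset and its roles config; validate columns and types.

    All columns named by the roles must exist, be completely observed, and
    match their declared coding (binary in {0,1}, multinomial integers).
    Missing values are rejected with a per-column count.
    """
    roles, types = read_roles(roles_path)
    data = pd.read_csv(data_path)
    used = list(roles.interest) + list(roles.anchors) + list(roles.covariates)
    for col in used:
        if col not in data.columns:
            raise DataError(f"column {col!r} listed in roles but absent from data")
    na = data[used].isna().sum()
    na = na[na > 0]
    if len(na):
        detail = ", ".join(f"{c}: {int(n)}" for c, n in na.items())
        raise DataError(
            f"{int(na.sum())} missing values in columns ({detail}); "
            "impute before discovery"
        )
    if types is None:
        types = infer_column_types(data, used)
    validate_column_types(data, types, used)
    return data[used], types, roles


_VALID_CODES = {0, 1, 2, 3}


def write_pag(path: str | Path, g: MarkedGraph) -> None:
    """Write the mark matrix as CSV with node labels as header."""
    df = pd.DataFrame(g.marks, columns=list(g.nodes))
    df.to_csv(path, index=False)


def read_pag(path: str | Path) -> PAG:
    """Read a mark-matrix CSV back into a PAG, validating codes and shape."""
    df = pd.read_csv(path)
    nodes = list(df.columns)
    M = df.to_numpy()
    if M.shape[0] != M.shape[1]:
        raise GraphError(f"PAG matrix must be square, got {M.shape}")
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            if M[i, j] not in _VALID_CODES:
                raise GraphError(
                    f"invalid mark code {M[i, j]!r} at row {i}, column {nodes[j]}"
                )
    if ((M == 0) != (M.T == 0)).any():
        bad = np.argwhere((M == 0) != (M.T == 0))[0]
        raise GraphError(
            f"asymmetric adjacency between {nodes[bad[0]]} and {nodes[bad[1]]}"
        )
    return PAG(nodes, M)


def write_dot(path: str | Path, g: MarkedGraph) -> None:
    Path(path).write_text(g.to_dot())


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str))
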