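"""Plain-text serialization: TSV matrices, JSON patterns/reports, edge lists.

All matrix files are tab-separated decimal text written with 17 significant
digits, so values round-trip bit-for-bit through the files.  Vectorization is
column-stacking and all indices are 0-based; multilayer variables are
flattened species-fastest (variable = species + S * patch).  Lines starting
with ``#`` are comments and carry provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .constraints import PatchNetwork
from .dynamics import TimeSeries
from .exceptions import ValidationError
from .lyap_core import ReconstructionResult, ZeroPattern

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_pattern",
    "write_pattern",
    "read_edge_list",
    "write_edge_list",
    "read_timeseries",
    "write_timeseries",
    "write_result",
]

_FMT = "%.17g"


def write_matrix(path: str | Path, matrix: np.ndarray, comment: str | None = None):
    """Write a matrix as TSV (one row per line) or JSON nested arrays by suffix."""
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    if path.suffix == ".json":
        path.write_text(json.dumps(matrix.tolist()) + "\n")
        return
    lines = []
    if comment:
        lines += [f"# {line}" for line in comment.splitlines()]
    for row in np.atleast_2d(matrix):
        lines.append("\t".join(_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a TSV or JSON matrix file written by :func:`write_matrix`."""
    path = Path(path)
    if path.suffix == ".json":
        return np.asarray(json.loads(path.read_text()), dtype=float)
    rows = [
        [float(v) for v in line.split("\t")]
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return np.asarray(rows, dtype=float)


def write_pattern(path: str | Path, pattern: ZeroPattern):
    """Serialize a zero pattern as JSON.

    The object form ``{"dimension": N, "positions": [[row, col], ...]}`` is
    written; positions are 0-based (row = affected variable, col = perturbed
    variable, column-stacking vec convention, species-fastest flattening for
    multilayer systems).
    """
    obj = {
        "dimension": pattern.dimension,
        "positions": [list(p) for p in pattern.positions],
        "indexing": "0-based",
        "vec_convention": "column-stacking",
        "flattening": "species-fastest (variable = species + S * patch)",
    }
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def read_pattern(path: str | Path, dimension: int | None = None) -> ZeroPattern:
    """Read a zero pattern from JSON.

    Accepts the object form written by :func:`write_pattern` or a bare JSON
    list of ``[row, col]`` pairs (in which case ``dimension`` is required).
    """
    obj = json.loads(Path(path).read_text())
    if isinstance(obj, dict):
        return ZeroPattern(obj["positions"], int(obj["dimension"]))
    if dimension is None:
        raise ValidationError(
            f"{path}: bare pattern list needs an explicit dimension"
        )
    return ZeroPattern(obj, dimension)


def write_edge_list(path: str | Path, net: PatchNetwork, comment: str | None = None):
    """Write an undirected network as one '``u v``' pair per line (0-based)."""
    lines = []
    if comment:
        lines += [f"# {line}" for line in comment.splitlines()]
    lines.append(f"# nodes: {net.n_nodes}")
    lines += [f"{u} {v}" for u, v in net.edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path, n_nodes: int | None = None) -> PatchNetwork:
    """Read an edge-list network file; ``# nodes:`` comments set the size."""
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.lower().startswith("# nodes:") and n_nodes is None:
                n_nodes = int(line.split(":", 1)[1])
            continue
        u, v = line.split()
        edges.append((int(u), int(v)))
    if n_nodes is None:
        n_nodes = 1 + max((max(e) for e in edges), default=0)
    return PatchNetwork(n_nodes, edges)


def write_timeseries(path: str | Path, ts: TimeSeries):
    """Write a series as TSV with a header line and ``#`` provenance comments."""
    lines = [f"# {json.dumps(ts.meta, default=str)}"] if ts.meta else []
    lines.append("\t".join(["time", *ts.labels]))
    for t, row in zip(ts.times, ts.values):
        lines.append("\t".join([_FMT % t, *(_FMT % v for v in row)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a series file written by :func:`write_timeseries`."""
    meta: dict = {}
    header: list[str] | None = None
    times, rows = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("{") and not meta:
                meta = json.loads(stripped)
            continue
        if header is None:
            header = line.split("\t")
            if header[0] != "time":
                raise ValidationError(f"{path}: first column must be 'time'")
            continue
        vals = [float(v) for v in line.split("\t")]
        times.append(vals[0])
        rows.append(vals[1:])
    if header is None or not rows:
        raise ValidationError(f"{path}: no data rows")
    return TimeSeries(
        np.asarray(times), np.asarray(rows), tuple(header[1:]), meta
    )


def write_result(path: str | Path, result: ReconstructionResult):
    """Serialize a reconstruction report as JSON."""
    Path(path).write_text(json.dumps(result.to_dict(), indent=1) + "\n")
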