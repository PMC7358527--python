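"""Table schemas, validated CSV/TSV reading, Newick export, JSON sidecars.

CSV with a header row is the canonical table dialect (TSV via ``sep``).
Each table kind declares required columns and which of them are counts
(numeric and non-negative); validation errors name the offending column or
row.  Months are treated as ordered categorical labels, never parsed as
dates.  Every CLI output directory carries a JSON sidecar recording the
seed and a hash of the run configuration so stochastic stages are
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .fingerprint import Dendrogram

__all__ = [
    "SchemaError",
    "TableParseError",
    "TABLE_SCHEMAS",
    "read_table",
    "write_table",
    "newick_string",
    "write_newick",
    "write_sidecar",
]


class SchemaError(ValueError):
    """A table does not match its declared kind's schema."""


class TableParseError(ValueError):
    """A table cell could not be validated; the message names the row."""


#: required columns and, among them, the non-negative numeric "count" columns
TABLE_SCHEMAS: dict[str, dict[str, tuple[str, ...]]] = {
    "enumeration": {
        "required": ("sample_id", "treatment", "month", "plot",
                     "viral_abundance", "bacterial_abundance"),
        "counts": ("viral_abundance", "bacterial_abundance"),
    },
    "induction": {
        "required": ("sample_id", "treatment", "month", "plot",
                     "v_control", "v_mitc", "b_control", "b_mitc"),
        "counts": ("v_control", "v_mitc", "b_control", "b_mitc"),
    },
    "peaks": {
        "required": ("sample_id", "replicate", "size", "height"),
        "counts": ("size", "height"),
    },
    "bands": {
        "required": ("label", "position"),
        "counts": ("position",),
    },
    "edaphics": {
        "required": ("sample_id", "treatment", "month", "plot",
                     "moisture", "organic_c", "total_n", "cn_ratio",
                     "phosphorus", "ph"),
        "counts": (),
    },
}


def read_table(path: str | Path, kind: str, sep: str = ",") -> pd.DataFrame:
    """Read and validate a study table of the given kind.

    Coerces count columns to float, rejecting non-numeric or negative
    entries with the (1-based, header-exclusive) row number.
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; choose from {sorted(TABLE_SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    schema = TABLE_SCHEMAS[kind]
    for column in schema["required"]:
        if column not in table.columns:
            raise SchemaError(f"{path.name}: missing required column {column!r}")
    for column in schema["counts"]:
        values = pd.to_numeric(table[column], errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise TableParseError(
                f"{path.name}: non-numeric {column!r} at row {row}: "
                f"{table[column].iloc[row - 1]!r}"
            )
        negative = values < 0
        if negative.any():
            row = int(negative.idxmax()) + 1
            raise TableParseError(
                f"{path.name}: negative count in {column!r} at row {row}: "
                f"{values.iloc[row - 1]!r}"
            )
        table[column] = values.astype(float)
    # remaining numeric payloads (plot ids, edaphic measurements)
    for column in table.columns:
        if column not in schema["counts"]:
            converted = pd.to_numeric(table[column], errors="coerce")
            if not converted.isna().any():
                table[column] = converted
    return table


def write_table(table: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Newick


def _quote_label(label: str) -> str:
    if label and all(ch.isalnum() or ch in "_.-" for ch in label):
        return label
    return "'" + label.replace("'", "''") + "'"


def newick_string(tree: "Dendrogram") -> str:
    """Standard Newick with branch lengths for an ultrametric dendrogram.

    Branch length = parent merge height minus child height (leaves sit at
    height zero), so re-reading reproduces the cophenetic heights.
    """
    from .fingerprint import DendrogramNode

    root = tree.root
    if root is None:  # pragma: no cover - Dendrogram forbids this
        raise ValueError("cannot serialize an empty tree")

    def fmt(node: DendrogramNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{_quote_label(node.label)}:{length:.17g}"
        left, right = node.children
        inner = f"({fmt(left, node.height)},{fmt(right, node.height)})"
        return f"{inner}:{length:.17g}"

    if root.is_leaf:
        return f"{_quote_label(root.label)}:0;"
    left, right = root.children
    return f"({fmt(left, root.height)},{fmt(right, root.height)});"


def write_newick(tree: "Dendrogram", path: str | Path) -> None:
    """Write a dendrogram to a Newick file (with trailing newline)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# reproducibility sidecar


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_sidecar(out_dir: str | Path, seed: int | None, config: dict) -> None:
    """Record seed and configuration hash next to a stage's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    (out_dir / "run_info.json").write_text(
        json.dumps(payload, sort_keys=True, indent=2, default=str) + "\n"
    )


def dump_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, plain floats)."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, default=default) + "\n")
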