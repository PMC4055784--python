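"""Readers and writers for every tabular and network format the pipeline
touches.

All tables are tab-separated UTF-8 with a header row (compound names contain
commas, so CSV is avoided throughout).  Readers validate against a
:class:`TableSchema` and fail with messages naming the offending column or
row.  Networks are exported as GraphML via :mod:`networkx` so they load in
standard viewers (Cytoscape, Gephi).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd


class SchemaError(ValueError):
    """A table failed validation against its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Declarative description of one tabular dialect.

    ``required`` maps column name -> pandas dtype string (``"str"``,
    ``"float"``, ``"int"``, ``"bool"``); ``optional`` columns are typed when
    present and ignored when absent.
    """

    name: str
    required: Mapping[str, str]
    optional: Mapping[str, str] = field(default_factory=dict)


_DTYPE_CASTS = {
    "str": lambda s: s.astype("string").astype(object),
    "float": lambda s: pd.to_numeric(s, errors="raise").astype(float),
    "int": lambda s: pd.to_numeric(s, errors="raise").astype(int),
    "bool": lambda s: s.map(_parse_bool),
}


def _parse_bool(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


# Schemas for the pipeline's tabular dialects.
PLANT_CATALOG = TableSchema(
    "plant_catalog",
    required={"plant_id": "str", "plant_name": "str", "edible": "bool",
              "compound_id": "str"},
)
COMPOUND_TABLE = TableSchema(
    "compound_table",
    required={"compound_id": "str", "inchikey": "str", "mw": "float",
              "tpsa": "float", "slogp": "float", "fingerprint": "str"},
    optional={"smiles": "str", "group": "str"},
)
BIOACTIVITY_TABLE = TableSchema(
    "bioactivity_table",
    required={"compound_inchikey": "str", "protein_id": "str",
              "organism": "str", "type": "str", "value": "float"},
)
PPI_TABLE = TableSchema(
    "ppi_table",
    required={"protein_a": "str", "protein_b": "str", "score": "float"},
    optional={"organism": "str"},
)
EXPRESSION_TABLE = TableSchema(
    "expression_table",
    required={"protein_id": "str", "positive": "bool"},
)
REACTION_TABLE = TableSchema(
    "reaction_table",
    required={"reaction_id": "str", "metabolite_id": "str", "role": "str",
              "enzyme_id": "str", "pathway": "str"},
)
SEED_TABLE = TableSchema(
    "seed_table",
    required={"protein_id": "str", "category": "str"},
)
INTERACTION_TABLE = TableSchema(
    "interaction_table",
    required={"plant_id": "str", "compound_id": "str", "protein_id": "str",
              "route": "str", "probability": "float"},
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a TSV file against ``schema``.

    Returns a typed DataFrame whose index is the 1-based data row number
    (for error messages downstream).  Raises :class:`SchemaError` naming the
    missing column or malformed cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{schema.name}: file {path} is empty") from None
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema.name}: file {path} is missing required column(s) "
            + ", ".join(repr(c) for c in missing)
        )
    df.index = pd.RangeIndex(1, len(df) + 1, name="row")
    for col, dtype in {**schema.required, **schema.optional}.items():
        if col not in df.columns:
            continue
        try:
            df[col] = _DTYPE_CASTS[dtype](df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{schema.name}: column {col!r} of {path} has a malformed "
                f"value ({exc})"
            ) from None
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as TSV (no index), creating parent directories."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
    return path


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def write_graphml(
    nodes: Iterable[tuple[str, Mapping[str, Any]]],
    edges: Iterable[tuple[str, str, Mapping[str, Any]]],
    path: str | Path,
) -> Path:
    """Write an undirected attributed graph as GraphML.

    ``nodes`` are ``(id, attrs)`` pairs, ``edges`` are ``(a, b, attrs)``
    triples.  Duplicate node ids are an error (silent merging would corrupt
    node attributes).
    """
    graph = nx.Graph()
    seen: set[str] = set()
    for node_id, attrs in nodes:
        if node_id in seen:
            raise ValueError(f"duplicate node id {node_id!r}")
        seen.add(node_id)
        graph.add_node(node_id, **dict(attrs))
    for a, b, attrs in edges:
        graph.add_edge(a, b, **dict(attrs))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, path)
    return path


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def encode_fingerprint(bits: Iterable[int]) -> str:
    """Serialize a fingerprint as a comma-joined list of set bit positions."""
    return ",".join(str(b) for b in sorted(set(int(b) for b in bits)))


def decode_fingerprint(text: str) -> frozenset[int]:
    """Parse the on-bit serialization produced by :func:`encode_fingerprint`."""
    text = text.strip()
    if not text:
        return frozenset()
    return frozenset(int(tok) for tok in text.split(","))


def read_seed_lists(paths: Sequence[str | Path] | Mapping[str, str | Path]
                    ) -> dict[str, set[str]]:
    """Read one-id-per-line seed files; category taken from the mapping key
    or the file stem."""
    if isinstance(paths, Mapping):
        items = [(str(k), Path(v)) for k, v in paths.items()]
    else:
        items = [(Path(p).stem, Path(p)) for p in paths]
    out: dict[str, set[str]] = {}
    for category, p in items:
        ids = {line.strip() for line in Path(p).read_text().splitlines()
               if line.strip()}
        out[category] = ids
    return out
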