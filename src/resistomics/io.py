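"""Readers and writers for the plain-text formats the pipeline touches.

Formats: GMT gene-set files (regulons, pathway memberships), TSV tables
with typed column schemas (DEG tables, survival cohorts, result tables),
edge-list + node-type TSVs for pathway topology, and the metabolite
abundance matrix (first column sample id, second group label, remaining
columns metabolite abundances).

Identifier matching throughout the package is exact, case-sensitive
string equality after whitespace trimming; identifiers that fail to map
are dropped, counted and logged rather than fuzzy-matched.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed content in an input file."""


class SchemaError(ValueError):
    """A table is missing required columns."""


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into an ordered mapping of set name -> member set.

    Each line must carry at least three tab-separated fields
    (name, description, members...).  Duplicate members collapse; input
    order of set names is preserved.  An empty file yields an empty
    mapping with a logged warning.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields (name, description, members...), got {len(fields)}"
                )
            name = fields[0].strip()
            members = {m.strip() for m in fields[2:] if m.strip()}
            if name in sets:
                logger.warning("%s: duplicate set name %r; keeping last", path, name)
            sets[name] = members
    if not sets:
        logger.warning("%s: empty GMT file, returning empty mapping", path)
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path,
              description: str = "na") -> None:
    """Write gene sets as GMT, members sorted for deterministic output."""
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Typed TSV tables
# ---------------------------------------------------------------------------

#: column -> dtype contracts for the pipeline's standard tables
DEG_SCHEMA: dict[str, str] = {
    "gene": "str", "log2fc": "float", "pvalue": "float", "padj": "float",
}
SURVIVAL_SCHEMA: dict[str, str] = {
    "subject": "str", "time": "float", "event": "int", "expression": "float",
}


def read_table(path: str | Path, schema: Mapping[str, str],
               sep: str = "\t") -> pd.DataFrame:
    """Read a delimited table and enforce a column contract.

    Required columns missing from the header raise :class:`SchemaError`
    naming them.  Rows whose values cannot be coerced to the declared
    type are rejected with their row indices logged.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    bad_rows: set[int] = set()
    out: dict[str, pd.Series] = {}
    for col, kind in schema.items():
        raw = df[col].astype(str).str.strip()
        if kind == "str":
            out[col] = raw
            continue
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw != "") & (raw.str.lower() != "nan")
        bad_rows.update(df.index[bad].tolist())
        out[col] = coerced  # cast to final dtype after bad rows are dropped
    result = pd.DataFrame(out)
    if bad_rows:
        logger.warning(
            "%s: rejected %d row(s) failing type coercion (indices %s)",
            path, len(bad_rows), sorted(bad_rows)[:20],
        )
        result = result.drop(index=sorted(bad_rows)).reset_index(drop=True)
    for col, kind in schema.items():
        if kind == "int":
            result[col] = result[col].astype(int)
        elif kind == "float":
            result[col] = result[col].astype(float)
    # carry through any extra columns untyped
    for col in df.columns:
        if col not in result.columns:
            result[col] = df[col].drop(index=sorted(bad_rows), errors="ignore").reset_index(drop=True)
    return result


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with a stable float format (deterministic bytes)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Pathway topology files
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (source, target) TSV; a header row is optional."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            if lineno == 1 and fields[0].lower() in ("source", "from", "node1"):
                continue
            edges.append((fields[0], fields[1]))
    return edges


def read_node_types(path: str | Path) -> dict[str, str]:
    """Read a (node, type) TSV; type must be 'gene' or 'metabolite'."""
    types: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            if lineno == 1 and fields[1].lower() in ("type", "kind"):
                continue
            node, kind = fields[0], fields[1]
            if kind not in ("gene", "metabolite"):
                raise ParseError(
                    f"{path}: line {lineno}: node type must be "
                    f"'gene' or 'metabolite', got {kind!r}"
                )
            types[node] = kind
    return types


# ---------------------------------------------------------------------------
# Metabolite matrix
# ---------------------------------------------------------------------------

def read_metabolite_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a metabolite TSV: sample id, group label, then abundances.

    Returns (values, groups): a samples x metabolites DataFrame indexed
    by sample id, and a group-label Series aligned to it.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise SchemaError(
            f"{path}: need sample, group and >= 1 metabolite column"
        )
    sample_col, group_col = df.columns[0], df.columns[1]
    values = df.drop(columns=[sample_col, group_col]).astype(float)
    values.index = df[sample_col].astype(str).str.strip()
    groups = df[group_col].astype(str).str.strip()
    groups.index = values.index
    return values, groups


def write_metabolite_table(values: pd.DataFrame, groups: pd.Series,
                           path: str | Path) -> None:
    out = values.copy()
    out.insert(0, "group", groups.reindex(values.index).values)
    out.insert(0, "sample", values.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
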