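"""Tabular input/output.

All tables are tab-separated text with a one-line header.  Long tables carry
one value per row; wide profile matrices carry one entity per row and one
column per native fraction.  Missing values are serialized as *empty fields*
— never ``0`` and never an ``NA`` string — so a zero is always a measured
zero.  Provenance comment lines starting with ``#`` are ignored on read.

Schemas
-------
peptide   protein, peptide, condition, replicate, intensity
protein   protein, condition, replicate, intensity
score     protein, score
profile   entity, kind, f1..fN            (wide; kind in {protein, bait_phosphopeptide})
localization  entity, f1..fN              (wide; per-fraction localization scores)
fragment  peptide, fragment, channel, sample, rt, area, sn
library   peptide, fragment, rel_intensity, library_rt
ppi-edge  protein_a, protein_b, evidence  (3-column reference edge list)
gmt       GMT: term <tab> description <tab> member...
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: required columns per long-table schema; value columns are parsed as floats
#: and may be missing (empty field).
SCHEMAS: dict[str, dict] = {
    "peptide": {
        "columns": ["protein", "peptide", "condition", "replicate", "intensity"],
        "value_columns": ["intensity"],
        "key": ["protein", "peptide", "condition", "replicate"],
    },
    "protein": {
        "columns": ["protein", "condition", "replicate", "intensity"],
        "value_columns": ["intensity"],
        "key": ["protein", "condition", "replicate"],
    },
    "score": {
        "columns": ["protein", "score"],
        "value_columns": ["score"],
        "key": ["protein"],
    },
    "fragment": {
        "columns": ["peptide", "fragment", "channel", "sample", "rt", "area", "sn"],
        "value_columns": ["rt", "area", "sn"],
        "key": ["peptide", "fragment", "channel", "sample"],
    },
    "library": {
        "columns": ["peptide", "fragment", "rel_intensity", "library_rt"],
        "value_columns": ["rel_intensity", "library_rt"],
        "key": ["peptide", "fragment"],
    },
    "ppi-edge": {
        "columns": ["protein_a", "protein_b", "evidence"],
        "value_columns": ["evidence"],
        "key": ["protein_a", "protein_b"],
    },
}

#: value columns that may legitimately be negative (log-scale or signed data)
_SIGNED_COLUMNS = {"rt", "library_rt"}


def fraction_columns(n: int) -> list[str]:
    return [f"f{i}" for i in range(1, n + 1)]


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read a long TSV and validate it against a named schema.

    Returns a typed :class:`pandas.DataFrame`; missing values are ``NaN``.
    Raises :class:`SchemaError` naming the first missing column and
    :class:`ValidationError` (with a row index) on negative intensities.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return validate_table(df, schema_name, source=str(path))


def validate_table(df: pd.DataFrame, schema_name: str, source: str = "<memory>") -> pd.DataFrame:
    spec = SCHEMAS[schema_name]
    for col in spec["columns"]:
        if col not in df.columns:
            raise SchemaError(f"{source}: schema {schema_name!r} requires column {col!r}")
    df = df[spec["columns"]].copy()
    for col in spec["value_columns"]:
        raw = df[col]
        if raw.dtype == object:
            raw = raw.replace("", np.nan)
        df[col] = pd.to_numeric(raw, errors="raise")
        if col not in _SIGNED_COLUMNS:
            bad = df.index[df[col] < 0]
            if len(bad):
                raise ValidationError(
                    f"{source}: negative value in column {col!r} at row {int(bad[0])}"
                )
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    dup = df.duplicated(subset=spec["key"])
    if dup.any():
        raise ValidationError(
            f"{source}: duplicate key {tuple(df.loc[dup.idxmax(), spec['key']])} "
            f"for schema {schema_name!r}"
        )
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a table as TSV; NaN becomes an empty field; optional ``#`` header."""
    buf = _io.StringIO()
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False, na_rep="")
    Path(path).write_text(buf.getvalue())


def read_profile_matrix(path: str | Path, n_fractions: int = 64,
                        with_kind: bool = True) -> pd.DataFrame:
    """Read a wide entity x fraction matrix (``entity`` [, ``kind``], f1..fN)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = ["entity"] + (["kind"] if with_kind else []) + fraction_columns(n_fractions)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: profile matrix requires column {col!r}")
    df = df[required].copy()
    for col in fraction_columns(n_fractions):
        df[col] = pd.to_numeric(df[col].replace("", np.nan), errors="raise")
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValidationError(f"{path}: negative intensity in {col} at row {int(bad[0])}")
    return df


def read_ppi_edges(path: str | Path) -> set[frozenset]:
    """Read a 3-column (protein_a, protein_b, evidence) reference edge list."""
    df = validate_table(
        pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False),
        "ppi-edge", source=str(path),
    )
    edges = set()
    for a, b in zip(df["protein_a"], df["protein_b"]):
        if a == b:
            raise ValidationError(f"{path}: self-edge {a!r}")
        edges.add(frozenset((a, b)))
    return edges


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT annotation file: term <tab> description <tab> members..."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"{path}: GMT line needs term, description, >=1 member")
        terms[parts[0]] = set(parts[2:])
    return terms


def write_gmt(terms: dict[str, set[str]], path: str | Path) -> None:
    lines = [f"{t}\t-\t" + "\t".join(sorted(m)) for t, m in terms.items()]
    Path(path).write_text("\n".join(lines) + "\n")
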