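"""Readers and writers for the delimited-text interfaces.

All three pipeline inputs are long-format TSV/CSV tables:

* strain metadata — ``strain_id``, ``treatment``, ``fraction`` (+ optional
  taxonomy columns, carried through untouched);
* resource assays — ``strain_id``, ``resource_id``, ``replicate``, ``od600``;
* biofilm assays — ``strain_a``, ``strain_b`` (empty for monocultures),
  ``bio_rep``, ``tech_rep``, ``a590``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

METADATA_COLUMNS = ("strain_id", "treatment", "fraction")
RESOURCE_COLUMNS = ("strain_id", "resource_id", "replicate", "od600")
BIOFILM_COLUMNS = ("strain_a", "strain_b", "bio_rep", "tech_rep", "a590")


def _read_table(path, required, name: str) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={c: str for c in
                                           ("strain_id", "resource_id",
                                            "strain_a", "strain_b",
                                            "treatment", "fraction")
                                           if c in required})
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{name} table {path} missing columns: {sorted(missing)}")
    return df


def read_strain_metadata(path) -> pd.DataFrame:
    df = _read_table(path, METADATA_COLUMNS, "strain metadata")
    if df["strain_id"].duplicated().any():
        dupes = df.loc[df["strain_id"].duplicated(), "strain_id"].tolist()
        raise SchemaError(f"duplicate strain ids in metadata: {dupes[:5]}")
    return df


def read_resource_assays(path) -> pd.DataFrame:
    df = _read_table(path, RESOURCE_COLUMNS, "resource assay")
    df["od600"] = pd.to_numeric(df["od600"])
    return df


def read_biofilm_assays(path) -> pd.DataFrame:
    df = _read_table(path, BIOFILM_COLUMNS, "biofilm assay")
    df["a590"] = pd.to_numeric(df["a590"])
    df["strain_b"] = df["strain_b"].fillna("")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
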