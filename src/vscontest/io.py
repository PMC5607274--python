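"""CSV dialects for every table the pipeline reads or writes.

All tables are UTF-8 comma-separated files with a header row.  Writers
serialize reals at 12 significant digits so write-read round trips are
lossless for downstream verdicts; identifiers and integers round-trip
bit-exactly.  Readers validate required columns and report the file and
the missing column by name.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError

_SCHEMAS = {
    "compounds": ["compound_id"],
    "annotations": ["compound_id", "target_id", "measure", "value"],
    "proposals": ["group", "rank", "compound_id"],
    "plates": ["plate_id", "well_id", "role", "compound_id", "inhibition_pct"],
    "dose_response": ["compound_id", "concentration_uM", "replicate",
                      "inhibition_pct"],
    "panel": ["compound_id", "kinase_group", "inhibition_pct"],
}

_FLOAT_FORMAT = "%.12g"


def _validate(df: pd.DataFrame, kind: str, path) -> pd.DataFrame:
    required = _SCHEMAS[kind]
    for col in required:
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    if kind == "compounds" and df["compound_id"].duplicated().any():
        dups = df.loc[df["compound_id"].duplicated(), "compound_id"].unique()
        raise InputError(f"{path}: duplicate compound ids {sorted(dups)[:5]}")
    if kind == "proposals":
        if df.duplicated(subset=["group", "rank"]).any():
            raise InputError(f"{path}: duplicate (group, rank) pairs")
        if df.duplicated(subset=["group", "compound_id"]).any():
            raise InputError(f"{path}: duplicate compound ids within a group")
    return df


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate one of the documented CSV dialects."""
    if kind not in _SCHEMAS:
        raise InputError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, dtype={"compound_id": str}, keep_default_na=False,
                     na_values=[""])
    if "compound_id" in df.columns:
        df["compound_id"] = df["compound_id"].fillna("").astype(str)
    return _validate(df, kind, path)


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> None:
    """Write a table in the canonical dialect (12-significant-digit reals)."""
    if kind is not None and kind in _SCHEMAS:
        _validate(df, kind, path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_compounds(path) -> pd.DataFrame:
    return read_table(path, "compounds")


def read_annotations(path) -> pd.DataFrame:
    return read_table(path, "annotations")


def read_proposals(path) -> pd.DataFrame:
    return read_table(path, "proposals")


def read_plates(path) -> pd.DataFrame:
    return read_table(path, "plates")


def read_dose_response(path) -> pd.DataFrame:
    return read_table(path, "dose_response")


def read_sdf(path) -> pd.DataFrame:
    """Read an SDF into a compound table with SMILES populated.

    Molecule names (title line or ``_Name``) become compound ids;
    unnamed molecules get sequential ``MOL<i>`` ids.
    """
    from rdkit import Chem

    rows = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        rows.append((name or f"MOL{i}", Chem.MolToSmiles(mol)))
    df = pd.DataFrame(rows, columns=["compound_id", "smiles"])
    return _validate(df, "compounds", path)
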