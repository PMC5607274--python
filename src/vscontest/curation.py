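"""Library preparation: remove known inhibitors and promiscuous binders.

Two filters run over an activity-annotation table before a screening
campaign: (1) compounds with any reported activity against the target
kinase family below the potency thresholds (known inhibitors) and
(2) drug-like compounds active against more than four distinct proteins
(promiscuous binders).  Both sets are removed from the library and a
conservation ledger records the arithmetic.

All activity comparisons are strict, exactly as the criteria are
usually stated: IC50 < 10 uM, Ki < 10 uM, Kd < 10 uM, inhibition > 30%.
Experimental conditions attached to annotations are deliberately
ignored.  Values are normalized to uM internally (nM/uM/mM accepted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

_POTENCY_MEASURES = ("ic50", "ki", "kd")
_UNIT_TO_UM = {"nm": 1e-3, "um": 1.0, "µm": 1.0, "μm": 1.0, "mm": 1e3}


@dataclass(frozen=True)
class CurationThresholds:
    """Activity and promiscuity cutoffs for library curation."""

    ic50_max: float = 10.0      # uM, strict <
    ki_max: float = 10.0        # uM, strict <
    kd_max: float = 10.0        # uM, strict <
    inhibition_min: float = 30.0  # %, strict >
    promiscuity_min_targets: int = 5  # "more than four": >= 5 distinct targets

    def __post_init__(self):
        for name in ("ic50_max", "ki_max", "kd_max", "inhibition_min"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.promiscuity_min_targets < 2:
            raise ConfigurationError("promiscuity_min_targets must be >= 2")


@dataclass
class CurationLedger:
    """Conservation record of a curation pass."""

    initial_count: int
    known_inhibitors_in_library: int
    promiscuous_druglike_in_library: int
    removed_total: int
    final_count: int
    flagged_ids: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "initial_count": self.initial_count,
            "known_inhibitors_in_library": self.known_inhibitors_in_library,
            "promiscuous_druglike_in_library": self.promiscuous_druglike_in_library,
            "removed_total": self.removed_total,
            "final_count": self.final_count,
        }


def _normalize(annotations: pd.DataFrame) -> pd.DataFrame:
    """Lower-case measures, convert potency values to uM; validate."""
    required = {"compound_id", "target_id", "measure", "value"}
    missing = required - set(annotations.columns)
    if missing:
        raise InputError(f"annotation table lacks columns {sorted(missing)}")
    df = annotations.copy()
    df["measure"] = df["measure"].astype(str).str.lower()
    known = set(_POTENCY_MEASURES) | {"inhibition"}
    bad = ~df["measure"].isin(known)
    if bad.any():
        rows = df.index[bad].tolist()
        raise InputError(
            f"unknown measure type(s) {sorted(df.loc[bad, 'measure'].unique())} "
            f"in rows {rows}"
        )
    if (df["value"] < 0).any():
        raise InputError("annotation values must be non-negative")
    if "unit" in df.columns:
        unit = df["unit"].astype(str).str.lower().str.strip()
        is_potency = df["measure"].isin(_POTENCY_MEASURES)
        factor = unit.map(_UNIT_TO_UM)
        bad_unit = is_potency & factor.isna()
        if bad_unit.any():
            raise InputError(
                f"unrecognized potency units {sorted(unit[bad_unit].unique())}"
            )
        df.loc[is_potency, "value"] = df.loc[is_potency, "value"] * factor[is_potency]
    return df


def _passes_activity(df: pd.DataFrame, thresholds: CurationThresholds) -> pd.Series:
    """Boolean mask: annotation row meets any of the activity criteria."""
    limits = {"ic50": thresholds.ic50_max, "ki": thresholds.ki_max,
              "kd": thresholds.kd_max}
    mask = pd.Series(False, index=df.index)
    for m, lim in limits.items():
        mask |= (df["measure"] == m) & (df["value"] < lim)
    mask |= (df["measure"] == "inhibition") & (df["value"] > thresholds.inhibition_min)
    return mask


def flag_known_inhibitors(annotations: pd.DataFrame,
                          thresholds: CurationThresholds = CurationThresholds(),
                          target_set=None) -> set:
    """Compound ids with any qualifying activity against the target set.

    ``target_set`` restricts which ``target_id`` values count (default:
    every target in the table, i.e. the caller pre-filtered to the
    kinase family of interest).
    """
    df = _normalize(annotations)
    if target_set is not None:
        df = df[df["target_id"].isin(set(target_set))]
    hits = df[_passes_activity(df, thresholds)]
    return set(hits["compound_id"].unique())


def flag_promiscuous(annotations: pd.DataFrame,
                     thresholds: CurationThresholds = CurationThresholds(),
                     druglike=None) -> set:
    """Drug-like compounds active on >= ``promiscuity_min_targets`` targets.

    ``druglike`` maps compound id -> bool (mapping, Series or callable);
    ``None`` treats every compound as drug-like.
    """
    df = _normalize(annotations)
    active = df[_passes_activity(df, thresholds)]
    counts = active.groupby("compound_id")["target_id"].nunique()
    prom = set(counts.index[counts >= thresholds.promiscuity_min_targets])
    if druglike is None:
        return prom
    if callable(druglike):
        return {c for c in prom if druglike(c)}
    return {c for c in prom if bool(druglike.get(c, False))
            } if hasattr(druglike, "get") else {c for c in prom if bool(druglike[c])}


def lipinski_druglike(smiles: str) -> bool:
    """Rule-of-five check (MW <= 500, logP <= 5, HBD <= 5, HBA <= 10)."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES {smiles!r}")
    return (Descriptors.MolWt(mol) <= 500 and Crippen.MolLogP(mol) <= 5
            and Lipinski.NumHDonors(mol) <= 5 and Lipinski.NumHAcceptors(mol) <= 10)


def curate_library(library: pd.DataFrame, known_inhibitors: set,
                   promiscuous: set):
    """Remove flagged compounds present in the library; keep the ledger.

    Flag sets may contain ids absent from the library (annotated
    compounds that were never stocked); only in-library ids are removed
    and counted.  Ordering of surviving records is preserved.
    Returns ``(curated_library, CurationLedger)``.
    """
    if "compound_id" not in library.columns:
        raise InputError("library table lacks column 'compound_id'")
    ids = library["compound_id"]
    in_lib = set(ids)
    known_in = set(known_inhibitors) & in_lib
    prom_in = set(promiscuous) & in_lib
    removed = known_in | prom_in
    curated = library[~ids.isin(removed)].reset_index(drop=True)
    ledger = CurationLedger(
        initial_count=len(library),
        known_inhibitors_in_library=len(known_in),
        promiscuous_druglike_in_library=len(prom_in),
        removed_total=len(removed),
        final_count=len(curated),
        flagged_ids={"known_inhibitors": sorted(known_in),
                     "promiscuous": sorted(prom_in)},
    )
    assert ledger.final_count + ledger.removed_total == ledger.initial_count
    return curated, ledger
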