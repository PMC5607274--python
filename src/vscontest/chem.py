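"""Fingerprint analyses: novelty, diversity, selectivity and PAINS.

Two fingerprint backends coexist.  The *abstract* backend works on any
binary bit vector (e.g. the simulated 166-bit fingerprints), so every
analysis here runs without chemical structures.  The *structure*
backend computes MACCS keys from SMILES via RDKit and additionally
enables PAINS substructure screening.

Novelty of a hit is its maximum Tanimoto similarity to any known
inhibitor; diversity is visualized by PCA of the fingerprint matrix;
selectivity is summarized by k-means clustering of compounds crossed
with per-kinase-group hit rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import InputError

#: Src-family kinase groups used for the selectivity matrix
KINASE_GROUPS = {
    "Group1": ("Src", "Fyn", "Yes", "Fgr"),
    "Group2": ("Blk", "Hck", "Lck", "Lyn"),
    "Group3": ("Frk", "Srm", "Brk"),
}


def _as_bits(fp) -> np.ndarray:
    a = np.asarray(fp)
    if a.dtype.kind in "US":  # '0101...' strings
        a = np.frombuffer(str(fp).encode(), dtype=np.uint8) - ord("0")
    return a.astype(bool)


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two bit vectors.

    Defined as 0.0 when both vectors are all-zero.
    """
    a, b = _as_bits(a), _as_bits(b)
    if a.shape != b.shape:
        raise InputError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return int(np.sum(a & b)) / union


def max_similarity(fp, known: dict) -> tuple[float, str]:
    """Max Tanimoto of ``fp`` to a ``{known_id: fingerprint}`` set.

    Returns ``(score, nearest_id)``; ties break lexicographically on id.
    """
    if not known:
        raise InputError("known-inhibitor set is empty")
    best_score, best_id = -1.0, None
    for kid in sorted(known):
        s = tanimoto(fp, known[kid])
        if s > best_score:
            best_score, best_id = s, kid
    return best_score, best_id


def novelty_table(compounds: pd.DataFrame, known: dict) -> pd.DataFrame:
    """Max similarity of each compound to the known-inhibitor set.

    ``compounds`` needs ``compound_id`` and ``fingerprint`` columns.
    """
    rows = []
    for _, r in compounds.iterrows():
        score, nearest = max_similarity(r["fingerprint"], known)
        rows.append((r["compound_id"], score, nearest))
    return pd.DataFrame(rows, columns=["compound_id", "max_similarity",
                                       "nearest_known"])


def pca_diversity(fps, n_components: int = 2):
    """Mean-centered PCA of a fingerprint matrix (rows = compounds).

    No standardization is applied, the usual practice for binary MACCS
    matrices.  Component signs are fixed by making each component's
    largest-magnitude loading positive, so coordinates are fully
    deterministic.  Returns ``(coordinates, explained_pct)``.
    """
    X = np.vstack([_as_bits(f).astype(float) for f in fps])
    if X.shape[0] < 2:
        raise InputError("need at least 2 compounds for PCA")
    if np.all(X.std(axis=0) == 0):
        raise InputError("fingerprint matrix is constant; no variance to analyse")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    flip = np.sign(pca.components_[
        np.arange(n_components),
        np.argmax(np.abs(pca.components_), axis=1),
    ])
    flip[flip == 0] = 1.0
    coords = coords * flip
    return coords, pca.explained_variance_ratio_ * 100.0


def kmeans_selectivity(compounds: pd.DataFrame, inhibition: pd.DataFrame,
                       k: int = 3, hit_threshold: float = 50.0,
                       seed: int = 0):
    """Cluster compounds on fingerprints; cross with kinase-group hit rates.

    ``inhibition`` rows are (``compound_id``, ``kinase_group``,
    ``inhibition_pct``); sparse coverage is allowed.  Hit rate of a
    (cluster, kinase group) cell = #(inhibition >= hit_threshold) /
    #measured.  k-means uses k-means++ with 10 restarts at a fixed seed;
    cluster labels are reassigned in decreasing-size order.  Returns
    ``(matrix, assignments)``.
    """
    if k > len(compounds):
        raise InputError(f"k={k} exceeds number of compounds {len(compounds)}")
    X = np.vstack([_as_bits(f).astype(float)
                   for f in compounds["fingerprint"]])
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    order = pd.Series(raw).value_counts().index.to_list()  # decreasing size
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[r] for r in raw])
    assignments = pd.DataFrame({
        "compound_id": compounds["compound_id"].to_numpy(),
        "cluster": labels,
    })
    merged = inhibition.merge(assignments, on="compound_id", how="inner")
    groups = sorted(inhibition["kinase_group"].unique())
    matrix = pd.DataFrame(0.0, index=range(k), columns=groups)
    for (cl, grp), sub in merged.groupby(["cluster", "kinase_group"]):
        measured = len(sub)
        hits = int((sub["inhibition_pct"] >= hit_threshold).sum())
        matrix.loc[cl, grp] = hits / measured if measured else np.nan
    matrix.index.name = "cluster"
    return matrix, assignments


# ---------------------------------------------------------------------------
# structure backend (RDKit)

def maccs_fingerprint(smiles: str) -> np.ndarray:
    """166-bit MACCS keys for a SMILES string (RDKit bit 0 dropped)."""
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES {smiles!r}")
    bv = MACCSkeys.GenMACCSKeys(mol)
    return np.array([bv.GetBit(i) for i in range(1, 167)], dtype=bool)


def pains_screen(compounds: pd.DataFrame) -> pd.DataFrame:
    """Screen SMILES against the PAINS A/B/C substructure catalogs.

    ``compounds`` needs ``compound_id`` and ``smiles``.  Returns one row
    per compound with the matched filter families (empty string when
    clean); unparseable SMILES are flagged not-evaluable.
    """
    from rdkit import Chem
    from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

    params = FilterCatalogParams()
    for cat in ("PAINS_A", "PAINS_B", "PAINS_C"):
        params.AddCatalog(getattr(FilterCatalogParams.FilterCatalogs, cat))
    catalog = FilterCatalog(params)
    rows = []
    for _, r in compounds.iterrows():
        mol = Chem.MolFromSmiles(r["smiles"])
        if mol is None:
            rows.append((r["compound_id"], False, "", "", False))
            continue
        entries = list(catalog.GetMatches(mol))
        families = sorted({e.GetProp("FilterSet") for e in entries})
        patterns = sorted({e.GetDescription() for e in entries})
        rows.append((r["compound_id"], True, ";".join(families),
                     ";".join(patterns), bool(entries)))
    return pd.DataFrame(rows, columns=["compound_id", "evaluable",
                                       "matched_filters", "matched_patterns",
                                       "flagged"])
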