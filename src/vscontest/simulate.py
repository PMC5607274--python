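"""Synthetic contest data with controlled ground truth.

Every input the screening pipeline consumes can be generated here: a
clustered compound library with activity annotations, ranked per-group
proposal lists with latent hit enrichment, 384-well plates with additive
plate effects and replicate noise, and four-parameter-logistic
dose-response tables.  All generators are deterministic functions of
``SimulationConfig.seed``; each stage draws from its own seed stream so
outputs do not depend on call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .doseresponse import four_pl
from .errors import ConfigurationError, GenerationError, InputError

SRC_FAMILY_KINASES = (
    "Src", "Fyn", "Yes", "Fgr", "Blk", "Hck", "Lck", "Lyn", "Frk", "Srm", "Brk",
)

# seed-stream offsets, one per generator stage
_STREAM_LIBRARY = 1
_STREAM_PROPOSALS = 2
_STREAM_PLATES = 3


@dataclass
class SimulationConfig:
    """Parameters of the simulated screening contest.

    Percentages are on the 0-100 scale, concentrations in uM.  The
    defaults reflect an 11-group contest in which each group proposes a
    ranked list of 400 compounds and its top 181 are assayed; one group
    has a strongly enriched hit rate (4%) against a background of 0.5%.
    """

    seed: int = 0
    n_library: int = 20_000
    n_clusters: int = 10
    n_groups: int = 11
    n_proposed_per_group: int = 400
    n_selected_per_group: int = 181
    group_hit_rates: tuple[float, ...] | None = None
    plate_effect_sd: float = 2.0
    replicate_sd: float = 5.0
    inactive_mean: float = 0.0
    active_inhibition_range: tuple[float, float] = (50.0, 100.0)
    fingerprint_length: int = 166
    # library composition
    active_frac: float = 0.01
    known_inhibitor_frac: float = 0.002
    promiscuous_frac: float = 0.002
    cluster_flip_prob: float = 0.05
    # rank enrichment of actives: placement weight ~ exp(-decay * (rank-1))
    enrichment_decay: float = 0.03
    # plate geometry
    plate_size: int = 384
    compounds_per_plate: int = 80
    replicates_per_compound: int = 4
    n_pos_controls: int = 32
    n_neg_controls: int = 32

    def __post_init__(self) -> None:
        if self.group_hit_rates is None:
            self.group_hit_rates = tuple([0.04] + [0.005] * (self.n_groups - 1))
        self.group_hit_rates = tuple(float(r) for r in self.group_hit_rates)
        for name in (
            "n_library", "n_clusters", "n_groups", "n_proposed_per_group",
            "n_selected_per_group", "fingerprint_length", "plate_size",
            "compounds_per_plate", "replicates_per_compound",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("plate_effect_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("active_frac", "known_inhibitor_frac", "promiscuous_frac",
                     "cluster_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1], got {v!r}")
        if len(self.group_hit_rates) != self.n_groups:
            raise ConfigurationError(
                f"group_hit_rates must have n_groups={self.n_groups} entries, "
                f"got {len(self.group_hit_rates)}"
            )
        if any(not 0.0 <= r <= 1.0 for r in self.group_hit_rates):
            raise ConfigurationError("group_hit_rates entries must lie in [0, 1]")
        if self.n_selected_per_group > self.n_proposed_per_group:
            raise ConfigurationError(
                "n_selected_per_group must not exceed n_proposed_per_group"
            )
        if self.n_pos_controls < 0 or self.n_neg_controls < 0:
            raise ConfigurationError("control well counts must be non-negative")
        wells_needed = (self.compounds_per_plate * self.replicates_per_compound
                        + self.n_pos_controls + self.n_neg_controls)
        if wells_needed != self.plate_size:
            raise ConfigurationError(
                f"plate layout inconsistent: {self.compounds_per_plate} compounds x "
                f"{self.replicates_per_compound} wells + {self.n_pos_controls}+"
                f"{self.n_neg_controls} controls != plate_size {self.plate_size}"
            )
        lo, hi = self.active_inhibition_range
        if lo > hi:
            raise ConfigurationError("active_inhibition_range must be (low, high)")

    def replace(self, **kwargs) -> "SimulationConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SimulationConfig(**current)


@dataclass
class TrueState:
    """Latent ground truth behind a simulated contest.

    ``active`` is a boolean Series indexed by compound id; ``ic50_uM``
    holds the latent IC50 for actives only; ``true_inhibition`` the
    latent mean % inhibition every well of that compound reports before
    plate effect and noise.  ``plate_effects`` is filled in by
    :func:`gen_plate_data`.
    """

    active: pd.Series
    ic50_uM: pd.Series
    true_inhibition: pd.Series
    plate_effects: dict = field(default_factory=dict)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def fingerprint_to_array(bits: str) -> np.ndarray:
    """Decode a '0101...' fingerprint string to a boolean vector."""
    return np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0") > 0


def gen_library(config: SimulationConfig):
    """Generate the compound library, its activity annotations and ground truth.

    Returns ``(library, annotations, true_state)``.  Fingerprints are
    binary vectors derived from ``n_clusters`` random prototypes with
    per-bit flip noise, so cluster structure is recoverable.  A small
    fraction of compounds carries annotations marking them as known
    Src-family inhibitors or as promiscuous drug-like binders, to
    exercise the curation filters downstream.
    """
    rng = _rng(config, _STREAM_LIBRARY)
    n = config.n_library
    ids = np.array([f"C{i:07d}" for i in range(n)])
    clusters = rng.integers(0, config.n_clusters, size=n)
    prototypes = rng.random((config.n_clusters, config.fingerprint_length)) < 0.3
    bits = prototypes[clusters]
    flips = rng.random(bits.shape) < config.cluster_flip_prob
    bits = bits ^ flips
    fp_strings = ["".join("1" if b else "0" for b in row) for row in bits]

    active = rng.random(n) < config.active_frac
    lo, hi = config.active_inhibition_range
    true_inh = np.full(n, float(config.inactive_mean))
    true_inh[active] = rng.uniform(lo, hi, size=int(active.sum()))
    # latent potency of actives: log-uniform 0.1-5 uM, comfortably under the
    # 10 uM hit criterion so the configured hit rates carry through the cascade
    ic50 = 10.0 ** rng.uniform(-1.0, math.log10(5.0), size=int(active.sum()))

    library = pd.DataFrame({
        "compound_id": ids,
        "cluster": clusters,
        "drug_like": True,
        "fingerprint": fp_strings,
    })
    true_state = TrueState(
        active=pd.Series(active, index=ids),
        ic50_uM=pd.Series(ic50, index=ids[active]),
        true_inhibition=pd.Series(true_inh, index=ids),
    )
    annotations = _gen_annotations(rng, config, ids, active)
    return library, annotations, true_state


def _gen_annotations(rng, config, ids, active):
    """Annotation rows marking known inhibitors and promiscuous binders."""
    rows = []
    n_known = round(config.known_inhibitor_frac * config.n_library)
    n_prom = round(config.promiscuous_frac * config.n_library)
    chosen = rng.choice(len(ids), size=min(n_known + n_prom, len(ids)), replace=False)
    known, prom = chosen[:n_known], chosen[n_known:]
    measures = ("IC50", "Ki", "Kd", "inhibition")
    for i in known:
        target = SRC_FAMILY_KINASES[rng.integers(len(SRC_FAMILY_KINASES))]
        m = measures[rng.integers(4)]
        if m == "inhibition":
            rows.append((ids[i], target, m, float(rng.uniform(35, 95)), "%"))
        else:
            rows.append((ids[i], target, m, float(10 ** rng.uniform(-2, 0.9)), "uM"))
    for i in prom:
        n_targets = int(rng.integers(5, 9))
        for t in range(n_targets):
            rows.append((ids[i], f"OffTarget{t:02d}", "IC50",
                         float(10 ** rng.uniform(-2, 0.9)), "uM"))
    # decoys: annotated but above every activity threshold, must never be flagged
    n_decoy = max(1, n_known // 2)
    decoys = rng.choice(len(ids), size=min(n_decoy, len(ids)), replace=False)
    for i in decoys:
        target = SRC_FAMILY_KINASES[rng.integers(len(SRC_FAMILY_KINASES))]
        rows.append((ids[i], target, "IC50", float(rng.uniform(20, 500)), "uM"))
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "measure",
                                       "value", "unit"])


def gen_group_proposals(library: pd.DataFrame, true_state: TrueState,
                        config: SimulationConfig) -> pd.DataFrame:
    """Ranked proposal lists, one per group.

    For each group the number of actives among its top
    ``n_selected_per_group`` ranks is Binomial(n_selected, rate), so the
    realized hit fraction is unbiased for the configured rate; actives
    are biased toward high (small-number) ranks with geometric decay.
    Overlap between groups is allowed; within a group compounds are
    distinct.
    """
    rng = _rng(config, _STREAM_PROPOSALS)
    active_ids = true_state.active.index[true_state.active].to_numpy()
    inactive_ids = true_state.active.index[~true_state.active].to_numpy()
    n_sel, n_prop = config.n_selected_per_group, config.n_proposed_per_group
    frames = []
    for g, rate in enumerate(config.group_hit_rates, start=1):
        n_act = int(rng.binomial(n_sel, rate))
        if n_act > len(active_ids):
            raise GenerationError(
                f"group G{g}: {n_act} actives requested but only "
                f"{len(active_ids)} exist in the library"
            )
        acts = rng.choice(active_ids, size=n_act, replace=False)
        ranks = np.arange(1, n_sel + 1)
        w = np.exp(-config.enrichment_decay * (ranks - 1))
        act_ranks = rng.choice(ranks, size=n_act, replace=False, p=w / w.sum())
        compounds = np.empty(n_prop, dtype=object)
        compounds[act_ranks - 1] = acts
        n_inact = n_prop - n_act
        fill = rng.choice(inactive_ids, size=n_inact, replace=False)
        compounds[[i for i in range(n_prop) if compounds[i] is None]] = fill
        frames.append(pd.DataFrame({
            "group": f"G{g}",
            "rank": np.arange(1, n_prop + 1),
            "compound_id": compounds.astype(str),
        }))
    return pd.concat(frames, ignore_index=True)


_ROWS = "ABCDEFGHIJKLMNOP"


def _well_ids(plate_size: int) -> list[str]:
    n_cols = plate_size // len(_ROWS)
    return [f"{r}{c:02d}" for r in _ROWS for c in range(1, n_cols + 1)]


def gen_plate_data(selected: pd.DataFrame, true_state: TrueState,
                   config: SimulationConfig,
                   plate_prefix: str = "P") -> pd.DataFrame:
    """Lay selected compounds out on 384-well plates and measure them.

    ``selected`` needs columns ``compound_id`` and ``group``.  Each
    compound occupies ``replicates_per_compound`` wells; remaining wells
    are split between positive (mean 100%) and negative (mean 0%)
    controls.  Compound-to-plate assignment round-robins over proposing
    groups so no plate is dominated by one group, then well positions are
    shuffled within each plate.  Measured inhibition = latent mean +
    shared plate effect N(0, plate_effect_sd^2) + well noise
    N(0, replicate_sd^2).  Plate effects are recorded in
    ``true_state.plate_effects``.
    """
    if selected.empty:
        raise InputError("selected compound set is empty")
    rng = _rng(config, _STREAM_PLATES)
    # round-robin over groups to stratify plates
    queues = [list(sub.compound_id) for _, sub in selected.groupby("group", sort=True)]
    order: list[str] = []
    while queues:
        for q in queues:
            if q:
                order.append(q.pop(0))
        queues = [q for q in queues if q]

    per_plate = config.compounds_per_plate
    n_rep = config.replicates_per_compound
    wells = _well_ids(config.plate_size)
    rows = []
    n_plates = math.ceil(len(order) / per_plate)
    for p in range(n_plates):
        plate_id = f"{plate_prefix}{p + 1:03d}"
        chunk = order[p * per_plate:(p + 1) * per_plate]
        effect = float(rng.normal(0.0, config.plate_effect_sd))
        true_state.plate_effects[plate_id] = effect
        n_ctrl = config.plate_size - n_rep * len(chunk)
        n_pos = n_ctrl // 2 + n_ctrl % 2
        n_neg = n_ctrl // 2
        positions = rng.permutation(wells)
        idx = 0
        for cid in rng.permutation(chunk):
            mu = float(true_state.true_inhibition[cid]) + effect
            for _ in range(n_rep):
                rows.append((plate_id, positions[idx], "compound", cid,
                             mu + rng.normal(0.0, config.replicate_sd)))
                idx += 1
        for role, mean, count in (("pos_ctrl", 100.0, n_pos), ("neg_ctrl", 0.0, n_neg)):
            for _ in range(count):
                rows.append((plate_id, positions[idx], role, "",
                             mean + effect + rng.normal(0.0, config.replicate_sd)))
                idx += 1
    return pd.DataFrame(rows, columns=["plate_id", "well_id", "role",
                                       "compound_id", "inhibition_pct"])


def gen_dose_response(ic50: float, top: float = 100.0, bottom: float = 0.0,
                      hill: float = 1.0, concentrations=None,
                      noise_sd: float = 0.0, seed: int = 0,
                      n_replicates: int = 3) -> pd.DataFrame:
    """Simulate a dose-response table from a 4PL curve plus Gaussian noise."""
    if concentrations is None:
        concentrations = [0.01, 0.1, 1.0, 10.0, 100.0]
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0):
        raise InputError("concentrations must be strictly positive")
    if ic50 <= 0:
        raise InputError("ic50 must be strictly positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in concentrations:
        mu = four_pl(c, bottom, top, hill, ic50)
        for r in range(1, n_replicates + 1):
            rows.append((c, r, mu + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["concentration_uM", "replicate",
                                       "inhibition_pct"])
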