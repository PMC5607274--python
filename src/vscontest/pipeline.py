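"""End-to-end synthetic contest: simulate, curate, screen, fit, evaluate.

Mirrors the screening cascade of a multi-group compound-proposal
contest: each group submits a ranked list; the top compounds of each
list (skipping any not available in the curated library, extending down
the ranks until the quota is met) are assayed in quadruplicate on
384-well plates; plate-wise triage and a fixed-threshold re-assay
narrow the field; survivors get dose-response curves and an IC50-based
hit call; finally groups are compared by exact binomial tests against
the pooled hit rate and by rank-enrichment curves, and hits are
analysed for novelty and diversity.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, io
from .config import PipelineConfig
from .curation import (CurationThresholds, curate_library,
                       flag_known_inhibitors, flag_promiscuous)
from .doseresponse import FourPLModel, call_hits
from .errors import ConfigurationError
from .evaluate import ContestOutcome, enrichment_curve, evaluate_groups, \
    truncation_analysis
from .plates import first_screen, second_screen, summarize_replicates
from .simulate import (SRC_FAMILY_KINASES, TrueState, gen_dose_response,
                       gen_group_proposals, gen_library, gen_plate_data)

logger = logging.getLogger(__name__)

# seed offset separating the re-assay plate stream from the first screen
_REASSAY_SEED_OFFSET = 1_000_003


def select_for_assay(proposals: pd.DataFrame, available: set,
                     quota: int) -> pd.DataFrame:
    """Walk each group's ranked list, skip unavailable compounds, stop at quota.

    A compound proposed by several groups is selected once (it will be
    assayed once) but remains on every proposer's assayed list for
    evaluation.  Returns the per-group assayed lists with columns
    ``group``, ``rank``, ``compound_id``.
    """
    frames = []
    for g, sub in proposals.groupby("group", sort=True):
        sub = sub.sort_values("rank")
        keep = sub[sub["compound_id"].isin(available)].head(quota)
        if len(keep) < quota:
            raise ConfigurationError(
                f"group {g}: only {len(keep)} available compounds for a "
                f"quota of {quota}"
            )
        frames.append(keep)
    return pd.concat(frames, ignore_index=True)


def _dose_response_tables(compound_ids, true_state: TrueState, params, seed):
    """Simulated dose-response tables for the IC50 stage.

    Actives follow a rising 4PL curve at their latent IC50; inactives
    produce a flat near-zero response that should fail the DRR check.
    """
    tables = {}
    for i, cid in enumerate(sorted(compound_ids)):
        if bool(true_state.active.get(cid, False)):
            ic50 = float(true_state.ic50_uM[cid])
            top, bottom = 100.0, 0.0
        else:
            ic50, top, bottom = 1e6, 100.0, 0.0
        tables[cid] = gen_dose_response(
            ic50=ic50, top=top, bottom=bottom, hill=-1.0,
            concentrations=params.concentrations_uM,
            noise_sd=params.noise_sd, seed=(seed * 100_003 + i) % (2**31),
            n_replicates=params.n_replicates,
        )
    return tables


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full synthetic contest; return the report bundle.

    When ``out_dir`` is given every intermediate table, the resolved
    config and a JSON report of stage counts are written there.
    """
    sim = config.simulation
    report: dict = {"stage_counts": {}}
    counts = report["stage_counts"]

    library, annotations, truth = gen_library(sim)
    counts["library"] = len(library)

    thresholds = CurationThresholds(
        ic50_max=config.curation.ic50_max, ki_max=config.curation.ki_max,
        kd_max=config.curation.kd_max,
        inhibition_min=config.curation.inhibition_min,
        promiscuity_min_targets=config.curation.promiscuity_min_targets,
    )
    known = flag_known_inhibitors(annotations, thresholds,
                                  target_set=SRC_FAMILY_KINASES)
    druglike = dict(zip(library["compound_id"], library["drug_like"]))
    promiscuous = flag_promiscuous(annotations, thresholds, druglike=druglike)
    curated, ledger = curate_library(library, known, promiscuous)
    counts["curated_library"] = ledger.final_count
    report["curation_ledger"] = ledger.as_dict()

    curated_ids = set(curated["compound_id"])
    truth_curated = TrueState(
        active=truth.active[truth.active.index.isin(curated_ids)],
        ic50_uM=truth.ic50_uM[truth.ic50_uM.index.isin(curated_ids)],
        true_inhibition=truth.true_inhibition[
            truth.true_inhibition.index.isin(curated_ids)],
    )
    proposals = gen_group_proposals(curated, truth_curated, sim)
    counts["proposed_distinct"] = proposals["compound_id"].nunique()

    assayed_lists = select_for_assay(proposals, curated_ids,
                                     sim.n_selected_per_group)
    # re-rank each group's assayed list 1..quota for evaluation
    assayed_lists = assayed_lists.copy()
    assayed_lists["rank"] = assayed_lists.groupby("group")["rank"].rank(
        method="first").astype(int)
    distinct = assayed_lists.drop_duplicates("compound_id")[
        ["compound_id", "group"]]
    counts["assayed"] = len(distinct)

    plates1 = gen_plate_data(distinct, truth_curated, sim, plate_prefix="P")
    summaries1 = summarize_replicates(plates1)
    verdicts1, plate_stats = first_screen(
        summaries1, abs_threshold=config.screening.abs_threshold,
        k_sd=config.screening.k_sd)
    passed1 = verdicts1.loc[verdicts1["passed"], "compound_id"].tolist()
    counts["first_screen_pass"] = len(passed1)

    if passed1:
        reassay = distinct[distinct["compound_id"].isin(passed1)]
        sim2 = sim.replace(seed=(sim.seed + _REASSAY_SEED_OFFSET) % (2**31))
        plates2 = gen_plate_data(reassay, truth_curated, sim2, plate_prefix="R")
        summaries2 = summarize_replicates(plates2)
        verdicts2 = second_screen(summaries2,
                                  threshold=config.screening.second_threshold)
        passed2 = verdicts2.loc[verdicts2["passed"], "compound_id"].tolist()
    else:
        plates2 = pd.DataFrame(columns=plates1.columns)
        verdicts2 = pd.DataFrame(columns=["compound_id", "passed"])
        passed2 = []
    counts["second_screen_pass"] = len(passed2)

    dr_tables = _dose_response_tables(passed2, truth_curated,
                                      config.dose_response, sim.seed)
    fits = {cid: FourPLModel(tbl).fit() for cid, tbl in dr_tables.items()}
    hit_table = call_hits(fits, hit_threshold=config.dose_response.hit_threshold_uM,
                          min_span=config.dose_response.min_span,
                          trend_alpha=config.dose_response.trend_alpha)
    hits = set(hit_table.loc[hit_table["hit"], "compound_id"])
    counts["hits"] = len(hits)

    outcome = ContestOutcome(
        groups={g: sub[["rank", "compound_id"]].reset_index(drop=True)
                for g, sub in assayed_lists.groupby("group")},
        hits=hits,
    )
    evaluation = evaluate_groups(outcome, alpha=config.evaluation.alpha)
    curves = {
        g: enrichment_curve(df, hits & set(df["compound_id"]), p0=outcome.p0)
        for g, df in outcome.groups.items()
    }
    truncated = truncation_analysis(outcome, config.evaluation.truncation_depth,
                                    alpha=config.evaluation.alpha)
    report["pooled_hit_rate"] = outcome.p0
    report["evaluation"] = evaluation.to_dict(orient="records")
    report["truncated_evaluation"] = truncated.to_dict(orient="records")

    # chem analysis on the assayed set: novelty vs the flagged known
    # inhibitors, PCA diversity of the assayed compounds
    fp_map = dict(zip(library["compound_id"], library["fingerprint"]))
    known_in_lib = {cid: fp_map[cid] for cid in sorted(known) if cid in fp_map}
    if hits and known_in_lib:
        hit_df = pd.DataFrame({"compound_id": sorted(hits)})
        hit_df["fingerprint"] = hit_df["compound_id"].map(fp_map)
        novelty = chem.novelty_table(hit_df, known_in_lib)
    else:
        novelty = pd.DataFrame(columns=["compound_id", "max_similarity",
                                        "nearest_known"])
    assayed_fps = distinct["compound_id"].map(fp_map)
    coords, explained = chem.pca_diversity(assayed_fps.tolist(),
                                           n_components=config.chem.n_components)
    report["pca_explained_pct"] = [float(v) for v in explained]
    report["novelty"] = novelty.to_dict(orient="records")

    # nesting check of the cascade
    assert (counts["assayed"] >= counts["first_screen_pass"]
            >= counts["second_screen_pass"] >= counts["hits"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "resolved_config.yaml")
        io.write_table(library, out / "library.csv")
        io.write_table(annotations, out / "annotations.csv")
        io.write_table(proposals, out / "proposals.csv", "proposals")
        io.write_table(plates1, out / "plates_first_screen.csv", "plates")
        io.write_table(verdicts1, out / "first_screen_verdicts.csv")
        io.write_table(plates2, out / "plates_second_screen.csv")
        io.write_table(verdicts2, out / "second_screen_verdicts.csv")
        io.write_table(hit_table, out / "hit_calls.csv")
        io.write_table(evaluation, out / "group_evaluation.csv")
        io.write_table(truncated, out / "group_evaluation_truncated.csv")
        io.write_table(novelty, out / "novelty.csv")
        curve_frames = []
        for g, c in curves.items():
            c = c.copy()
            c.insert(0, "group", g)
            curve_frames.append(c)
        io.write_table(pd.concat(curve_frames, ignore_index=True),
                       out / "enrichment_curves.csv")
        pca_df = pd.DataFrame(coords, columns=[f"PC{i+1}"
                                               for i in range(coords.shape[1])])
        pca_df.insert(0, "compound_id", distinct["compound_id"].to_numpy())
        io.write_table(pca_df, out / "pca_coordinates.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    for stage, n in counts.items():
        logger.info("stage %-20s %d records", stage, n)
    report["hit_ids"] = sorted(hits)
    report["outcome"] = outcome
    report["hit_table"] = hit_table
    report["enrichment_curves"] = curves
    return report
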