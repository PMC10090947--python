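"""End-to-end pipeline: chain the stages on simulated or user-supplied tables.

The stage order mirrors the experimental design: simulate (or load) ->
AP-MS quantification -> kinetic clustering -> co-migration modules ->
module evaluation -> mutant integration -> targeted PRM panel.  Every output
table carries a provenance header (package version, seed, config hash) and a
fixed seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import apms, comigration, integration, kinetics, module_eval, prm, simulate
from .config import PipelineConfig
from .errors import StageError
from .io import fraction_columns, write_table

log = logging.getLogger(__name__)

#: default gel calibration: (fraction, kDa), decreasing mass down the gel
DEFAULT_CALIBRATION = [(5, 1236.0), (15, 720.0), (25, 480.0), (35, 242.0),
                       (45, 146.0), (55, 66.0), (62, 20.0)]

TREATMENTS = ["vanadate_2", "vanadate_20", "okadaic_60", "okadaic_150"]


def _provenance(config: PipelineConfig) -> list[str]:
    return [f"phoscomplex v{__version__}", f"seed={config.seed}",
            f"config_sha={config.hash()}"]


def default_apms_design(truth: simulate.ComplexTruth, seed: int) -> simulate.ApmsDesign:
    """Treatment design over the planted interactome: per-module kinetic effects."""
    rng = np.random.default_rng(seed)
    proteins = sorted({p for m in truth.modules for p in m.members})
    background = [f"BG{i:03d}" for i in range(1, 16)]
    log2fc: dict[str, dict[str, float]] = {c: {} for c in TREATMENTS}
    for m in truth.modules:
        effect = float(rng.choice([-2.0, 0.0, 2.0]))
        treated = list(rng.choice(TREATMENTS, size=2, replace=False))
        for cond in treated:
            for p in m.members:
                log2fc[cond][p] = effect
    return simulate.ApmsDesign(
        conditions=["untreated"] + TREATMENTS, replicates=3, reference="untreated",
        true_interactors=proteins, background=background, log2fc=log2fc,
        missingness=0.05, bait_id=truth.bait_id,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on seeded synthetic data and write the run directory.

    Returns a dict with the in-memory stage outputs; raises
    :class:`StageError` naming the first failing stage.
    """
    config.validate()
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    results: dict = {}
    log_lines: list[str] = []
    stage = "simulate"
    try:
        truth = simulate.default_complex_truth(seed=config.seed, bait_id=config.bait_id,
                                               fraction_count=config.fraction_count)
        profiles, localization, labels = simulate.simulate_bnpage(truth, seed=config.seed)
        design = default_apms_design(truth, config.seed)
        peptides, scores, apms_truth = simulate.simulate_apms(design, seed=config.seed + 1)
        write_table(profiles, outdir / "profiles.tsv", header)
        write_table(localization, outdir / "localization.tsv", header)
        write_table(labels, outdir / "bnpage_truth.tsv", header)
        write_table(peptides, outdir / "peptides.tsv", header)
        write_table(scores, outdir / "scores.tsv", header)
        results["truth"] = truth
        log_lines.append(f"simulate: {len(profiles)} profiles, {len(peptides)} peptide rows")

        stage = "apms"
        prot = apms.protein_table(peptides, config.apms.top_n_peptides)
        prot = apms.normalize_to_bait(
            apms.impute_missing(prot, config.apms, seed=config.seed + 2), config.bait_id)
        interactors = apms.filter_interactors(scores, config.apms.saint_threshold)
        prot_f = prot[prot["protein"].isin(interactors | {config.bait_id})]
        diffs = {cond: apms.differential(prot_f, cond, design.reference, config.apms)
                 for cond in TREATMENTS}
        for cond, d in diffs.items():
            write_table(d, outdir / f"differential_{cond}.tsv", header)
        results["interactors"], results["differential"] = interactors, diffs
        log_lines.append(f"apms: {len(interactors)} interactors pass "
                         f"score > {config.apms.saint_threshold}")

        stage = "kinetics"
        profiles_fc = kinetics.kinetic_profiles(
            prot_f[prot_f["protein"] != config.bait_id], TREATMENTS, design.reference)
        clustering = kinetics.fuzzy_cmeans(profiles_fc, config.kinetics,
                                           seed=config.seed + 3)
        write_table(clustering.membership.reset_index(),
                    outdir / "kinetic_membership.tsv", header)
        results["kinetics"] = clustering
        log_lines.append(f"kinetics: {clustering.membership.shape[0]} profiles, "
                         f"c={config.kinetics.n_clusters}")

        stage = "comigrate"
        irt = np.ones(config.fraction_count)
        prepped = comigration.preprocess_profiles(
            profiles, irt, config.bait_id, config.peaks, localization,
            config.fraction_count)
        traces = []
        for p in prepped:
            traces.extend(comigration.split_profile(
                p, comigration.detect_peaks(p, config.peaks), config.peaks))
        clustered = comigration.cluster_modules(traces, config.bait_id, config.clustering)
        modules = comigration.assemble_modules(clustered, DEFAULT_CALIBRATION)
        write_table(comigration.module_report(modules), outdir / "modules.tsv", header)
        results["modules"], results["clustered"] = modules, clustered
        log_lines.append(f"comigrate: {len(traces)} traces -> {len(modules)} modules "
                         f"(k={clustered.chosen_k})")

        stage = "evaluate"
        universe = sorted({p for m in truth.modules for p in m.members})
        reference = {frozenset(pair) for m in truth.modules
                     for pair in __import__("itertools").combinations(sorted(m.members), 2)}
        evaluation = module_eval.recall_vs_background(
            modules, reference, set(universe), config.bait_id, seed=config.seed + 4)
        eval_df = pd.DataFrame(
            [{"module": k, "recall": v} for k, v in evaluation.module_recalls.items()]
        )
        eval_df["background_recall"] = evaluation.background_recall
        eval_df["shapiro_p"] = evaluation.shapiro_p
        eval_df["comparison_p"] = evaluation.comparison_p
        write_table(eval_df, outdir / "module_eval.tsv", header)
        results["evaluation"] = evaluation
        log_lines.append(f"evaluate: comparison p={evaluation.comparison_p:.3g}")

        stage = "integrate"
        mutant_results = _simulated_mutant_panel(truth, config, seed=config.seed + 5)
        matrix = integration.association_matrix(modules, mutant_results,
                                                config.integration)
        write_table(matrix, outdir / "associations.tsv", header)
        results["associations"] = matrix
        log_lines.append(f"integrate: {len(matrix)} co-migration associations")

        stage = "prm"
        peptide_ids = [f"{p}_pep1" for p in universe[:10]]
        assay = simulate.PrmAssay(peptides=peptide_ids)
        fragments, library, prm_truth = simulate.simulate_prm(
            assay, {p: 100.0 for p in peptide_ids}, seed=config.seed + 6)
        quant = prm.quantify_panel(fragments, library, assay.gradient_length, config.prm)
        write_table(quant, outdir / "prm_quant.tsv", header)
        results["prm"] = quant
        accepted_true = quant.merge(prm_truth, on=["peptide", "sample"])
        rate = accepted_true.loc[~accepted_true["is_decoy"], "accepted"].mean()
        log_lines.append(f"prm: true-peak acceptance {rate:.2f}")
    except Exception as exc:
        (outdir / "run.log").write_text("\n".join(log_lines + [f"FAILED at {stage}: {exc}"]))
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return results


def _simulated_mutant_panel(truth: simulate.ComplexTruth, config: PipelineConfig,
                            seed: int) -> dict[str, pd.DataFrame]:
    """AP-MS differential tables for one alanine mutant per planted phosphosite.

    A mutant suppresses the members of every module its site is attached to
    (planted log2FC = -2), the synthetic analogue of phosphorylation-dependent
    binding.
    """
    mutant_results: dict[str, pd.DataFrame] = {}
    sites = sorted({s for m in truth.modules for s in m.phosphosites})
    proteins = sorted({p for m in truth.modules for p in m.members})
    for i, site in enumerate(sites):
        mutant = f"{site}A"
        suppressed = {p for m in truth.modules if site in m.phosphosites
                      for p in m.members}
        design = simulate.ApmsDesign(
            conditions=["wt", mutant], replicates=3, reference="wt",
            true_interactors=proteins, background=[],
            log2fc={mutant: {p: -2.0 for p in suppressed}},
            bait_id=truth.bait_id,
        )
        peptides, _, _ = simulate.simulate_apms(design, seed=seed + i)
        prot = apms.normalize_to_bait(apms.protein_table(peptides), truth.bait_id)
        mutant_results[site] = apms.differential(prot, mutant, "wt", config.apms)
    return mutant_results
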