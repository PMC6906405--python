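"""End-to-end orchestration of the seed-network exome association workflow.

Stages, in order: load the background interactome and expand the seed genes
to their first-neighbour network; restrict the discovery panel's variants to
member genes plus flanking windows; single-variant logistic association with
PC covariates and genomic-inflation QC; threshold-scan candidate selection;
replication association (age added to covariates) with Bonferroni
correction; PRS variant selection, scoring of the replication panel with
discovery log-OR weights and the PRS association test; prediction-model
evaluation (variant and PRS models, trained on discovery, tested on
replication); and the degree-binned permutation test of the candidate
subnetwork's topology.  Every stage's counts, thresholds and seeds land in a
machine-readable run report.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .annotation import filter_variants_to_geneset, load_genes
from .association import (
    AnalysisConfig,
    association_table,
    bonferroni_threshold,
    genomic_lambda,
    logistic_sva,
    select_candidate_threshold,
    select_prs_variants,
)
from .interactome import expand_seed_network, load_interactome, load_seed_list
from .prediction import evaluate_classifier, fit_prs_model, fit_variant_model
from .prs import PrsModel, compute_prs, prs_report
from .simulate import GenotypePanel
from .topology_null import null_topology_distribution

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Per-stage bookkeeping of one pipeline run."""

    version: str = __version__
    seeds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _subset_panel(panel: GenotypePanel, kept_keys) -> GenotypePanel:
    keep = [j for j, k in enumerate(panel.variants) if k in set(kept_keys)]
    return GenotypePanel(
        samples=panel.samples,
        variants=[panel.variants[j] for j in keep],
        dosages=panel.dosages[:, keep],
        phenotype=panel.phenotype,
        covariates=panel.covariates,
        truth=panel.truth,
    )


def _analysis_config(cfg: dict) -> AnalysisConfig:
    kwargs = {}
    section = cfg.get("analysis", {})
    for f in ("candidate_thresholds", "selection_min_variants", "bonferroni_alpha",
              "flank", "n_pcs", "prs_maf_tolerance", "n_permutations", "n_bins"):
        if f in section:
            v = section[f]
            kwargs[f] = tuple(v) if f == "candidate_thresholds" else v
    return AnalysisConfig(**kwargs)


def run_pipeline(config_path, out_dir=None) -> RunReport:
    """Execute the workflow described by a YAML config file.

    The config names the input files (interactome edge list, seed list, gene
    BED, discovery/replication VCF + phenotype TSV), the analysis thresholds,
    declared LD blocks and exclusion list, and per-stage seeds.  A missing
    replication panel skips the replication-dependent stages with a warning;
    the discovery and network stages still run.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    out = Path(out_dir or cfg.get("out_dir", config_path.parent / "netseed_out"))
    out.mkdir(parents=True, exist_ok=True)
    base = config_path.parent

    def _p(rel):
        p = Path(rel)
        return p if p.is_absolute() else base / p

    report = RunReport()
    config = _analysis_config(cfg)
    master_seed = int(cfg.get("seed", 0))
    report.seeds["master"] = master_seed
    inputs = cfg["inputs"]

    # --- network expansion ---------------------------------------------
    interactome = load_interactome(_p(inputs["interactome"]))
    seeds = load_seed_list(_p(inputs["seeds"]))
    net = expand_seed_network(interactome, seeds)
    report.counts["interactome_nodes"] = interactome.number_of_nodes()
    report.counts["interactome_edges"] = interactome.number_of_edges()
    report.counts["seed_genes"] = len(net.seeds)
    report.counts["seed_network_members"] = len(net.members)
    io.write_id_list(net.members, out / "seed_network_members.txt")
    report.artifacts["seed_network_members"] = str(out / "seed_network_members.txt")

    # --- variant filtering ----------------------------------------------
    genes = load_genes(_p(inputs["genes_bed"]))
    gene_of_variant: dict = {}
    discovery = io.read_panel(_p(inputs["discovery"]["vcf"]),
                              _p(inputs["discovery"]["phenotypes"]))
    report.counts["discovery_variants_in"] = len(discovery.variants)
    kept, assignment = filter_variants_to_geneset(
        discovery.variants, genes, net.members, flank=config.flank)
    gene_of_variant.update({k: ";".join(v) for k, v in assignment.items()})
    discovery = _subset_panel(discovery, kept)
    report.counts["discovery_variants_kept"] = len(discovery.variants)
    report.thresholds["flank_bp"] = config.flank

    # --- discovery SVA ---------------------------------------------------
    disc_res = logistic_sva(discovery, config)
    disc_tab = association_table(disc_res, gene_of_variant)
    disc_tab.to_csv(out / "sva_discovery.tsv", sep="\t", index=False)
    report.artifacts["sva_discovery"] = str(out / "sva_discovery.tsv")
    valid_p = {r.key: r.p_value for r in disc_res if r.ok and np.isfinite(r.p_value)}
    report.metrics["lambda_discovery"] = genomic_lambda(valid_p.values())
    report.counts["discovery_variants_tested"] = len(valid_p)

    # --- candidate selection --------------------------------------------
    threshold, candidates = select_candidate_threshold(valid_p, config)
    report.thresholds["candidate_p"] = threshold
    report.counts["candidates"] = len(candidates)
    report.thresholds["bonferroni_replication"] = bonferroni_threshold(
        config.bonferroni_alpha, max(len(candidates), 1))

    # --- replication -----------------------------------------------------
    repl_cfg = inputs.get("replication")
    repl_res = []
    if repl_cfg is None:
        report.warnings.append("no replication panel: replication, PRS and "
                               "prediction stages skipped")
    else:
        replication = io.read_panel(_p(repl_cfg["vcf"]), _p(repl_cfg["phenotypes"]))
        replication = _subset_panel(replication, candidates)
        report.counts["replication_candidates_present"] = len(replication.variants)
        repl_res = logistic_sva(replication, config, extra_covariates=("age",))
        repl_tab = association_table(repl_res, gene_of_variant)
        repl_tab.to_csv(out / "sva_replication.tsv", sep="\t", index=False)
        report.artifacts["sva_replication"] = str(out / "sva_replication.tsv")
        bonf = report.thresholds["bonferroni_replication"]
        report.counts["replication_significant"] = int(sum(
            1 for r in repl_res if r.ok and np.isfinite(r.p_value) and r.p_value < bonf))

        # --- PRS ---------------------------------------------------------
        disc_by_key = {r.key: r for r in disc_res}
        label_to_key = {r.key.label(): r.key for r in disc_res}
        ld_blocks = []
        for block in cfg.get("ld_blocks", []):
            members = [label_to_key[m] for m in block["members"] if m in label_to_key]
            entry = {"members": members}
            rep = block.get("representative")
            if rep is not None and rep in label_to_key:
                entry["representative"] = label_to_key[rep]
            ld_blocks.append(entry)
        exclusions = [label_to_key[x] for x in cfg.get("exclusions", [])
                      if x in label_to_key]
        prs_keys = select_prs_variants(
            [disc_by_key[k] for k in candidates if k in disc_by_key],
            repl_res, ld_blocks=ld_blocks, exclusions=exclusions,
            config=config, p_cutoff=threshold)
        report.counts["prs_variants"] = len(prs_keys)
        if prs_keys:
            model = PrsModel.from_odds_ratios(
                prs_keys, [disc_by_key[k].or_estimate for k in prs_keys])
            rep_prs = prs_report(replication, model, n_pcs=config.n_pcs)
            rep_prs.association.to_csv(out / "prs_association.tsv", sep="\t")
            report.artifacts["prs_association"] = str(out / "prs_association.tsv")
            report.metrics["prs_mean"] = rep_prs.mean
            report.metrics["prs_range"] = [rep_prs.min, rep_prs.max]
            report.metrics["prs_upper_quartile_case_fraction"] = \
                rep_prs.upper_quartile_case_fraction
            report.metrics["prs_upper_quartile_control_fraction"] = \
                rep_prs.upper_quartile_control_fraction
            if "PRS" in rep_prs.association.index:
                row = rep_prs.association.loc["PRS"]
                report.metrics["prs_or"] = float(row["OR"])
                report.metrics["prs_p"] = float(row["P"])
                report.metrics["prs_ci"] = [float(row["2.5%"]), float(row["97.5%"])]

            # --- prediction ---------------------------------------------
            rf_seed = int(cfg.get("prediction", {}).get("seed", master_seed))
            report.seeds["variant_model"] = rf_seed
            tr = _subset_panel(discovery, prs_keys)
            te = _subset_panel(replication, prs_keys)
            clf, importances = fit_variant_model(
                tr.dosages, tr.phenotype,
                feature_names=[k.label() for k in tr.variants], rng=rf_seed)
            var_eval = evaluate_classifier(clf, te.dosages, te.phenotype)
            var_eval.importances = importances
            tr_scores, _ = compute_prs(tr, model)
            prs_clf = fit_prs_model(tr_scores, tr.phenotype)
            prs_eval = evaluate_classifier(prs_clf, rep_prs.scores.reshape(-1, 1),
                                           te.phenotype)
            report.metrics["prediction"] = {
                name: {
                    "accuracy": e.accuracy, "specificity": e.specificity,
                    "sensitivity": e.sensitivity,
                    "balanced_accuracy": e.balanced_accuracy,
                    "auc": e.auc, "auc_ci": list(e.auc_ci),
                    "importances": e.importances,
                    "confusion": asdict(e.confusion),
                }
                for name, e in (("variant_model", var_eval), ("prs_model", prs_eval))
            }
        else:
            report.warnings.append("no variants survived PRS selection")

    # --- network topology test ------------------------------------------
    net_cfg = cfg.get("network_test", {})
    if net_cfg.get("enabled", True):
        if "subset" in net_cfg:
            subset = set(load_seed_list(_p(net_cfg["subset"])))
        else:
            candidate_genes = {
                g for k in candidates for g in gene_of_variant.get(k, "").split(";") if g
            }
            subset = (set(seeds) | candidate_genes) & set(interactome.nodes)
        perm_seed = int(net_cfg.get("seed", master_seed))
        report.seeds["network_test"] = perm_seed
        res = null_topology_distribution(
            interactome, subset,
            n_permutations=int(net_cfg.get("n_permutations", config.n_permutations)),
            n_bins=int(net_cfg.get("n_bins", config.n_bins)),
            rng=perm_seed)
        report.metrics["topology"] = {
            "subset_size": len(subset),
            "lcc_size": res.observed.lcc_size,
            "apl": res.observed.apl,
            "acc": res.observed.acc,
            "p_apl_lower": res.p_apl_lower,
            "p_acc_upper": res.p_acc_upper,
            "n_permutations": res.n_permutations,
            "n_degenerate": res.n_degenerate,
        }
        io.write_json(report.metrics["topology"], out / "topology_test.json")
        report.artifacts["topology_test"] = str(out / "topology_test.json")

    io.write_json(report.to_dict(), out / "run_report.json")
    report.artifacts["run_report"] = str(out / "run_report.json")
    return report
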