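"""Assemble a complete synthetic study bundle for the end-to-end workflow.

The bundle emulates the shape of a PPI-targeted exome study at desk scale: a
background interactome with a planted dense seed module, a gene map whose
gene identifiers are interactome node names (so variant filtering and
candidate-gene mapping are exercised for real), and a discovery plus a
replication case-control cohort sharing the same variant panel.  A handful
of risk variants with odds ratios in the range the single-variant screen can
detect are planted inside seed-network member genes; the rest of the panel
is null.  Cohort sizes default to the discovery 439/855 and replication
60/8214 design of a small national exome study.  All files are written in
the pipeline's input formats together with a ready-to-run YAML config and a
truth sidecar.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import yaml

from . import io
from .annotation import write_genes_bed
from .interactome import expand_seed_network
from .simulate import (
    CohortSimSpec,
    InteractomeSimSpec,
    VariantSimSpec,
    simulate_cohort,
    simulate_gene_map,
    simulate_interactome,
)

logger = logging.getLogger(__name__)

# planted per-allele effects: a strong GBA-like signal, a block of
# moderate-effect variants, and a protective one, spanning the odds-ratio
# range a screen of this size can flag
_CAUSAL_PLAN = [
    (2.2, 0.05), (2.0, 0.06), (1.9, 0.08), (1.8, 0.10), (1.7, 0.12),
    (1.64, 0.12), (1.6, 0.15), (1.75, 0.09), (1.85, 0.07), (2.1, 0.05),
    (1.9, 0.10), (0.55, 0.12),
]


@dataclasses.dataclass
class StudyBundle:
    """Paths and ground truth of one generated study."""

    dir: Path
    config_path: Path
    truth: dict


def build_study_bundle(
    out_dir,
    seed: int = 0,
    n_nodes: int = 1000,
    module_size: int = 20,
    module_extra_edge_prob: float = 0.3,
    n_member_genes: int = 50,
    n_other_genes: int = 30,
    n_null_variants: int = 188,
    n_cases: int = 439,
    n_controls: int = 855,
    n_repl_cases: int = 60,
    n_repl_controls: int = 8214,
    admixture_fraction: float = 0.3,
    fst: float = 0.01,
    n_permutations: int = 2000,
) -> StudyBundle:
    """Generate interactome, gene map, two cohorts and a pipeline config.

    Null variants are scattered over member-gene bodies, flanks, other genes
    and intergenic space; causal variants sit inside seed-module gene bodies
    so that the candidate genes overlap the planted module and the topology
    stage sees a coherent subnetwork.  Two of the planted moderate-effect
    variants are declared as one LD block in the config and one null variant
    that happens to reach the candidate list can be named on the exclusion
    list by the caller; by default the exclusion list is empty.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # --- interactome -----------------------------------------------------
    ispec = InteractomeSimSpec(
        n_nodes=n_nodes, attachment_edges=2, seed_module_size=module_size,
        seed_module_extra_edge_prob=module_extra_edge_prob,
        rng_seed=int(rng.integers(2**31)))
    graph, seeds = simulate_interactome(ispec)
    net = expand_seed_network(graph, seeds)
    io.write_edge_list(graph, out / "edges.tsv")
    io.write_id_list(seeds, out / "seeds.txt")

    # --- gene map: gene ids are interactome nodes ------------------------
    members = sorted(net.members)
    non_members = sorted(set(graph.nodes) - net.members)
    member_genes = [members[i] for i in
                    rng.choice(len(members), size=min(n_member_genes, len(members)),
                               replace=False)]
    # module genes must be among the mapped genes so causal hits land there
    for m in seeds:
        if m not in member_genes:
            member_genes.append(m)
    other_genes = [non_members[i] for i in
                   rng.choice(len(non_members), size=min(n_other_genes, len(non_members)),
                              replace=False)]
    gene_names = sorted(member_genes) + sorted(other_genes)
    intervals, _ = simulate_gene_map(
        n_genes=len(gene_names), gene_length=10_000, spacing=50_000,
        rng_seed=int(rng.integers(2**31)))
    genes = [dataclasses.replace(g, gene_id=nm) for g, nm in zip(intervals, gene_names)]
    write_genes_bed(genes, out / "genes.bed")
    by_name = {g.gene_id: g for g in genes}

    # --- variant panel ---------------------------------------------------
    used_pos: set[int] = set()

    def _pos_in(lo: int, hi: int) -> int:
        while True:
            p = int(rng.integers(lo, hi + 1))
            if p not in used_pos:
                used_pos.add(p)
                return p

    variants: list[VariantSimSpec] = []
    causal_genes = [g for g in sorted(seeds) if g in by_name]
    for k, (o, maf) in enumerate(_CAUSAL_PLAN):
        g = by_name[causal_genes[k % len(causal_genes)]]
        variants.append(VariantSimSpec(
            maf=maf, odds_ratio=o, gene_id=g.gene_id,
            position=_pos_in(g.start, g.end), fst=fst))

    flank = 20_000
    chrom_end = max(g.end for g in genes) + flank + 50_000
    placements = ("member_body", "member_flank", "other_body", "intergenic")
    for k in range(n_null_variants):
        target = placements[k % len(placements)]
        if target == "member_body":
            g = by_name[member_genes[int(rng.integers(len(member_genes)))]]
            pos = _pos_in(g.start, g.end)
        elif target == "member_flank":
            g = by_name[member_genes[int(rng.integers(len(member_genes)))]]
            side = rng.random() < 0.5
            pos = _pos_in(max(1, g.start - flank), g.start - 1) if side \
                else _pos_in(g.end + 1, g.end + flank)
        elif target == "other_body":
            g = by_name[other_genes[int(rng.integers(len(other_genes)))]]
            pos = _pos_in(g.start, g.end)
        else:
            g = None
            while True:
                pos = int(rng.integers(1, chrom_end))
                near = any(x.start - flank <= pos <= x.end + flank for x in genes)
                if not near and pos not in used_pos:
                    used_pos.add(pos)
                    break
        variants.append(VariantSimSpec(
            maf=float(rng.uniform(0.02, 0.45)), odds_ratio=1.0,
            gene_id=g.gene_id if g else "", position=pos, fst=fst))

    variants_t = tuple(variants)

    # --- cohorts ---------------------------------------------------------
    disc = simulate_cohort(CohortSimSpec(
        n_cases=n_cases, n_controls=n_controls, variants=variants_t,
        baseline_prevalence=0.01, admixture_fraction=admixture_fraction,
        rng_seed=int(rng.integers(2**31))))
    repl = simulate_cohort(CohortSimSpec(
        n_cases=n_repl_cases, n_controls=n_repl_controls, variants=variants_t,
        baseline_prevalence=0.01, admixture_fraction=admixture_fraction,
        rng_seed=int(rng.integers(2**31))))
    io.write_vcf(disc, out / "discovery.vcf")
    io.write_phenotypes(disc, out / "discovery_phenotypes.tsv")
    io.write_vcf(repl, out / "replication.vcf")
    io.write_phenotypes(repl, out / "replication_phenotypes.tsv")

    # two moderate-effect variants declared as an LD block (declared, not
    # simulated: the panel itself carries no linkage)
    block_labels = [f"var{i + 1}" for i in (4, 5)]
    config = {
        "seed": int(seed),
        "inputs": {
            "interactome": "edges.tsv",
            "seeds": "seeds.txt",
            "genes_bed": "genes.bed",
            "discovery": {"vcf": "discovery.vcf",
                          "phenotypes": "discovery_phenotypes.tsv"},
            "replication": {"vcf": "replication.vcf",
                            "phenotypes": "replication_phenotypes.tsv"},
        },
        "analysis": {"flank": flank, "n_pcs": 10,
                     "n_permutations": int(n_permutations), "n_bins": 30},
        "ld_blocks": [{"members": block_labels, "representative": block_labels[1]}],
        "exclusions": [],
        "network_test": {"enabled": True, "n_permutations": int(n_permutations),
                         "n_bins": 30, "seed": int(seed)},
    }
    config_path = out / "run.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))

    truth = {
        "seed": int(seed),
        "interactome": dataclasses.asdict(ispec),
        "module": seeds,
        "n_seed_network_members": len(net.members),
        "causal": [dataclasses.asdict(v) for v in variants_t
                   if v.odds_ratio != 1.0],
        "n_variants": len(variants_t),
        "cohorts": {"discovery": [n_cases, n_controls],
                    "replication": [n_repl_cases, n_repl_controls]},
    }
    io.write_json(truth, out / "truth.json")
    return StudyBundle(dir=out, config_path=config_path, truth=truth)
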