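"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as multi-sample VCF v4.2 (diploid unphased GT), phenotypes
and covariates as TSV (``sample_id``, ``status`` coded 1=control/2=case,
``age``, ``sex``, ``PC1``..``PC10``), interactomes as two-column edge lists,
genes as BED.  Reading VCF goes through cyvcf2; writing produces plain
VCFv4.2 text.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .annotation import VariantKey
from .simulate import GenotypePanel

logger = logging.getLogger(__name__)

N_PC_COLUMNS = 10


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel's genotypes as an uncompressed multi-sample VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({v.chromosome for v in panel.variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        idx = sorted(range(len(panel.variants)),
                     key=lambda j: (panel.variants[j].chromosome, panel.variants[j].position))
        for j in idx:
            v = panel.variants[j]
            gts = []
            for d in panel.dosages[:, j]:
                if np.isnan(d):
                    gts.append("./.")
                else:
                    d = int(d)
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
            fh.write(f"{v.chromosome}\t{v.position}\t{v.id or '.'}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf_dosages(path) -> tuple[list[str], list[VariantKey], np.ndarray]:
    """Read sample ids, variant keys and an alt-allele dosage matrix from VCF."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    keys: list[VariantKey] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        keys.append(VariantKey(str(rec.CHROM), int(rec.POS), rec.REF,
                               ",".join(rec.ALT) if rec.ALT else alt,
                               rec.ID))
        gt = np.asarray(rec.genotypes, dtype=float)[:, :2]
        dos = (gt > 0).sum(axis=1).astype(float)  # any non-reference allele copy
        dos[(gt < 0).any(axis=1)] = np.nan
        cols.append(dos)
    vcf.close()
    dosages = np.column_stack(cols) if cols else np.zeros((len(samples), 0))
    return samples, keys, dosages


# ---------------------------------------------------------------------------
# phenotype / covariates
# ---------------------------------------------------------------------------

def write_phenotypes(panel: GenotypePanel, path) -> None:
    """Phenotype/covariate TSV; PC columns zero-padded out to PC10."""
    df = pd.DataFrame({
        "sample_id": panel.samples,
        "status": np.where(panel.phenotype == 1, 2, 1),
        "age": panel.covariates["age"].to_numpy(),
        "sex": panel.covariates["sex"].to_numpy().astype(int),
    })
    for k in range(1, N_PC_COLUMNS + 1):
        col = f"PC{k}"
        df[col] = panel.covariates[col].to_numpy() if col in panel.covariates else 0.0
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_panel(vcf_path, phenotype_path) -> GenotypePanel:
    """Assemble a GenotypePanel from a VCF and a phenotype/covariate TSV."""
    samples, keys, dosages = read_vcf_dosages(vcf_path)
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
    pheno = pheno.set_index("sample_id")
    missing = [s for s in samples if s not in pheno.index]
    if missing:
        raise ValueError(f"{len(missing)} VCF sample(s) absent from phenotype table, "
                         f"e.g. {missing[:3]}")
    pheno = pheno.loc[samples]
    status = pheno["status"].to_numpy()
    if not set(np.unique(status)) <= {1, 2}:
        raise ValueError("status must be coded 1 (control) / 2 (case)")
    cov_cols = [c for c in pheno.columns if c in ("age", "sex") or c.startswith("PC")]
    cov = pheno[cov_cols].copy()
    # drop all-zero PC padding so fits see only informative components
    for c in [c for c in cov.columns if c.startswith("PC")]:
        if np.allclose(cov[c], 0.0):
            cov = cov.drop(columns=c)
    return GenotypePanel(
        samples=samples,
        variants=keys,
        dosages=dosages,
        phenotype=(status == 2).astype(int),
        covariates=cov,
    )


# ---------------------------------------------------------------------------
# graphs, seeds, misc
# ---------------------------------------------------------------------------

def write_edge_list(graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted((min(e), max(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def write_id_list(ids, path) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(f"{i}\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    return str(o)
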