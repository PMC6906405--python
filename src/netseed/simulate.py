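"""Synthetic interactomes, gene maps and stratified case-control cohorts.

The generators produce desk-scale inputs with the statistical structure the
downstream analysis assumes:

* ``simulate_interactome`` — a preferential-attachment background graph
  (heavy-tailed degrees, like real interactomes) with a planted dense seed
  module, so the topology permutation test has a realisable alternative.
* ``simulate_cohort`` — a case-control genotype panel under an additive
  log-odds disease model with optional two-subpopulation stratification via
  Balding–Nichols allele-frequency drift, plus principal components as
  ancestry covariates.
* ``simulate_gene_map`` — non-overlapping genes on one synthetic chromosome
  with variants placed in gene bodies, flanks or intergenic space, and the
  ground-truth category recorded for filter testing.

All generators are bit-reproducible for a fixed ``rng_seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .annotation import GeneInterval, VariantKey

logger = logging.getLogger(__name__)

_REJECTION_CAP = 10_000_000  # max individuals drawn while filling case/control quotas
_PREVALENCE_POOL = 20_000    # genotype pool size for solving the model intercept


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractomeSimSpec:
    """Background interactome with a planted dense seed module.

    ``attachment_edges`` is the number of edges each new node attaches with
    during preferential-attachment growth; ``seed_module_extra_edge_prob``
    is the Bernoulli probability of adding each missing edge inside the
    planted module on top of the background.
    """

    n_nodes: int
    attachment_edges: int = 2
    seed_module_size: int = 0
    seed_module_extra_edge_prob: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.seed_module_size > self.n_nodes:
            raise ValueError("seed_module_size exceeds n_nodes")
        if not 0.0 <= self.seed_module_extra_edge_prob <= 1.0:
            raise ValueError("seed_module_extra_edge_prob must be in [0, 1]")


@dataclass(frozen=True)
class VariantSimSpec:
    """One simulated biallelic variant: frequency, per-allele effect, location.

    ``odds_ratio`` is the multiplicative per-allele effect on disease odds;
    ``fst`` the Balding–Nichols differentiation between the two
    subpopulations (0 = no stratification at this site).
    """

    maf: float
    odds_ratio: float = 1.0
    gene_id: str = ""
    position: int = 1
    fst: float = 0.0
    chromosome: str = "1"

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if self.position < 1:
            raise ValueError("position must be 1-based")


@dataclass(frozen=True)
class CohortSimSpec:
    """A case-control cohort drawn from a two-subpopulation mixture."""

    n_cases: int
    n_controls: int
    variants: tuple[VariantSimSpec, ...]
    baseline_prevalence: float = 0.1
    admixture_fraction: float = 0.0
    age_range: tuple[float, float] = (40.0, 80.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be positive")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if not 0.0 <= self.admixture_fraction <= 1.0:
            raise ValueError("admixture_fraction must be in [0, 1]")
        pos = [(v.chromosome, v.position) for v in self.variants]
        if len(pos) != len(set(pos)):
            raise ValueError("variant positions must be unique per chromosome")
        object.__setattr__(self, "variants", tuple(self.variants))


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix with phenotype and covariates.

    ``dosages`` holds 0/1/2 allele counts as float with NaN for missing;
    ``phenotype`` is 1 for cases, 0 for controls; ``covariates`` carries
    ``age``, ``sex`` and however many principal components the dosage matrix
    supports (up to 10), as columns ``PC1``...
    """

    samples: list[str]
    variants: list[VariantKey]
    dosages: np.ndarray
    phenotype: np.ndarray
    covariates: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError("dosage matrix shape inconsistent with labels")
        if len(self.phenotype) != n or len(self.covariates) != n:
            raise ValueError("phenotype/covariate length inconsistent")
        if np.isnan(self.phenotype.astype(float)).any():
            raise ValueError("phenotype must be non-missing")

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.phenotype == 0))

    def pc_columns(self) -> list[str]:
        return [c for c in self.covariates.columns if c.startswith("PC")]

    def variant_index(self, key: VariantKey) -> int:
        try:
            return self.variants.index(key)
        except ValueError:
            raise KeyError(f"variant {key} not in panel") from None


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def simulate_interactome(spec: InteractomeSimSpec) -> tuple[nx.Graph, list[str]]:
    """Preferential-attachment background with a planted dense module.

    Returns the graph (node ids ``G0001``...) and the planted module's node
    list as the seed genes.  With ``attachment_edges=1`` the background is a
    random tree; ``seed_module_extra_edge_prob=1`` forces the module to be a
    clique.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if spec.n_nodes == 1:
        g = nx.Graph()
        g.add_node(0)
    else:
        m = min(spec.attachment_edges, spec.n_nodes - 1)
        g = nx.barabasi_albert_graph(spec.n_nodes, m, seed=int(rng.integers(2**31)))
    width = max(4, len(str(spec.n_nodes)))
    mapping = {i: f"G{i + 1:0{width}d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)

    module = sorted(
        mapping[i] for i in rng.choice(spec.n_nodes, size=spec.seed_module_size, replace=False)
    )
    for i, a in enumerate(module):
        for b in module[i + 1:]:
            if not g.has_edge(a, b) and rng.random() < spec.seed_module_extra_edge_prob:
                g.add_edge(a, b)
    return g, module


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _subpop_frequencies(spec: CohortSimSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-variant allele frequencies in the two subpopulations (2 x m).

    Balding–Nichols drift: each subpopulation frequency is drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral MAF p at the variant's
    fst F; fst = 0 short-circuits to the shared MAF.
    """
    freqs = np.empty((2, len(spec.variants)))
    for j, v in enumerate(spec.variants):
        if v.fst == 0.0:
            freqs[:, j] = v.maf
        else:
            a = v.maf * (1 - v.fst) / v.fst
            b = (1 - v.maf) * (1 - v.fst) / v.fst
            freqs[:, j] = np.clip(rng.beta(a, b, size=2), 1e-6, 1 - 1e-6)
    return freqs


def _solve_intercept(spec: CohortSimSpec, freqs: np.ndarray, rng: np.random.Generator) -> float:
    """Intercept of the additive logistic disease model.

    Solved so that mean disease probability over a Monte Carlo genotype pool
    matches ``baseline_prevalence``.
    """
    betas = np.log([v.odds_ratio for v in spec.variants]) if spec.variants else np.empty(0)
    pool_sub = (rng.random(_PREVALENCE_POOL) < spec.admixture_fraction).astype(int)
    if len(spec.variants):
        pool = rng.binomial(2, freqs[pool_sub, :])
        lin = pool @ betas
    else:
        lin = np.zeros(_PREVALENCE_POOL)

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + lin))) - spec.baseline_prevalence

    try:
        return brentq(gap, -40.0, 40.0, xtol=1e-10)
    except ValueError as exc:
        raise RuntimeError(
            "could not reach baseline prevalence "
            f"{spec.baseline_prevalence} with the requested odds ratios/MAFs: {exc}"
        ) from exc


def _attach_pcs(dosages: np.ndarray, max_pcs: int = 10) -> np.ndarray:
    """Top principal components of the mean-imputed centred dosage matrix."""
    x = dosages.astype(float).copy()
    col_mean = np.nanmean(x, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(x))
    x[nan_rows, nan_cols] = col_mean[nan_cols]
    x -= x.mean(axis=0)
    if x.size == 0:
        return np.zeros((x.shape[0], 0))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    keep = min(max_pcs, int(np.sum(s > 1e-9)))
    return u[:, :keep] * s[:keep]


def simulate_cohort(spec: CohortSimSpec) -> GenotypePanel:
    """Draw a case-control panel under the additive logistic disease model.

    Individuals are drawn from the two-subpopulation mixture; genotypes are
    binomial in the subpopulation allele frequency; disease status follows
    logit(P) = b0 + sum_j ln(OR_j) * dosage_j with b0 solved so the
    population prevalence matches ``baseline_prevalence``.  Sampling
    continues (rejection sampling) until exactly ``n_cases`` and
    ``n_controls`` are banked.  Ages are uniform over ``age_range``; sex is
    Bernoulli(0.5); the top-10 PCs of the centred dosage matrix are attached.
    """
    rng = np.random.default_rng(spec.rng_seed)
    freqs = _subpop_frequencies(spec, rng)
    b0 = _solve_intercept(spec, freqs, rng)
    betas = np.log([v.odds_ratio for v in spec.variants]) if spec.variants else np.empty(0)

    m = len(spec.variants)
    need_cases, need_controls = spec.n_cases, spec.n_controls
    case_rows, control_rows = [], []
    case_sub, control_sub = [], []
    drawn = 0
    batch = max(1024, 4 * (spec.n_cases + spec.n_controls))
    while need_cases > 0 or need_controls > 0:
        if drawn >= _REJECTION_CAP:
            raise RuntimeError(
                f"rejection-sampling cap of {_REJECTION_CAP:,} draws reached with "
                f"{need_cases} cases / {need_controls} controls still missing "
                f"(prevalence {spec.baseline_prevalence}, intercept {b0:.3f})"
            )
        sub = (rng.random(batch) < spec.admixture_fraction).astype(int)
        geno = rng.binomial(2, freqs[sub, :]) if m else np.zeros((batch, 0), dtype=int)
        p = expit(b0 + (geno @ betas if m else 0.0))
        status = rng.random(batch) < p
        drawn += batch
        for rows, subs, mask, need in (
            (case_rows, case_sub, status, need_cases),
            (control_rows, control_sub, ~status, need_controls),
        ):
            idx = np.where(mask)[0][:need]
            rows.extend(geno[idx])
            subs.extend(sub[idx])
        need_cases = spec.n_cases - len(case_rows)
        need_controls = spec.n_controls - len(control_rows)

    dosages = np.asarray(case_rows + control_rows, dtype=float).reshape(-1, m)
    phenotype = np.concatenate(
        [np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]
    )
    n = spec.n_cases + spec.n_controls
    order = rng.permutation(n)  # shuffle so sample order carries no label signal
    dosages, phenotype = dosages[order], phenotype[order]
    subpop = np.asarray(case_sub + control_sub)[order]

    samples = [f"S{i + 1:06d}" for i in range(n)]
    pcs = _attach_pcs(dosages)
    cov = pd.DataFrame(
        {
            "age": rng.uniform(*spec.age_range, size=n),
            "sex": rng.integers(0, 2, size=n),
        },
        index=samples,
    )
    for k in range(pcs.shape[1]):
        cov[f"PC{k + 1}"] = pcs[:, k]

    variants = [
        VariantKey(
            chromosome=v.chromosome,
            position=v.position,
            ref="A",
            alt="G",
            id=f"var{j + 1}",
        )
        for j, v in enumerate(spec.variants)
    ]
    truth = {
        "intercept": b0,
        "subpop": subpop,
        "subpop_freqs": freqs,
        "odds_ratios": [v.odds_ratio for v in spec.variants],
        "spec": spec,
    }
    return GenotypePanel(
        samples=samples,
        variants=variants,
        dosages=dosages,
        phenotype=phenotype,
        covariates=cov,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# gene map
# ---------------------------------------------------------------------------

def simulate_gene_map(
    n_genes: int,
    gene_length: int = 10_000,
    spacing: int = 50_000,
    n_variants: int = 0,
    flank: int = 20_000,
    rng_seed: int = 0,
    chromosome: str = "1",
) -> tuple[list[GeneInterval], pd.DataFrame]:
    """Non-overlapping genes on one chromosome plus labelled variant placements.

    Genes are laid head-to-tail with ``spacing`` bp between them.  Each
    variant is placed uniformly in a gene body, in a flank (within ``flank``
    bp of a gene end, including the exact boundary), or outside both, with
    roughly equal probability, and the realised category — recomputed against
    all genes — recorded in the returned frame (columns ``id``, ``chromosome``,
    ``position``, ``category``).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(rng_seed)
    genes = []
    pos = 1 + flank + spacing  # leave room for the first gene's upstream flank
    for i in range(n_genes):
        genes.append(
            GeneInterval(
                gene_id=f"GENE{i + 1:04d}",
                chromosome=chromosome,
                start=pos,
                end=pos + gene_length - 1,
                strand="+",
            )
        )
        pos += gene_length + spacing

    def categorize(p: int) -> str:
        in_body = any(g.start <= p <= g.end for g in genes)
        if in_body:
            return "body"
        in_flank = any(g.start - flank <= p <= g.end + flank for g in genes)
        return "flank" if in_flank else "outside"

    chrom_end = pos + flank + spacing
    records = []
    used: set[int] = set()
    for k in range(n_variants):
        target = ("body", "flank", "outside")[int(rng.integers(3))]
        if n_genes == 0:
            target = "outside"
        for _ in range(1000):
            g = genes[int(rng.integers(n_genes))] if n_genes else None
            if target == "body":
                p = int(rng.integers(g.start, g.end + 1))
            elif target == "flank":
                if rng.random() < 0.5:
                    p = int(rng.integers(max(1, g.start - flank), g.start))
                else:
                    p = int(rng.integers(g.end + 1, g.end + flank + 1))
            else:
                p = int(rng.integers(1, chrom_end))
            if p not in used and categorize(p) == target:
                break
        used.add(p)
        records.append(
            {"id": f"v{k + 1:04d}", "chromosome": chromosome, "position": p,
             "category": categorize(p)}
        )
    placements = pd.DataFrame(records, columns=["id", "chromosome", "position", "category"])
    return genes, placements
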