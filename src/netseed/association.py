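"""Single-variant logistic association with ancestry covariates.

Per variant, case/control status is regressed on allele dosage with the top
principal components (and optionally age) as covariates; the per-allele odds
ratio is ``exp`` of the dosage coefficient and the p-value comes from the
Wald test on that coefficient (a likelihood-ratio test is available behind a
flag).  Companion routines cover allele counting by status, the crude 2x2
odds ratio, genomic-inflation QC (median-chi-square lambda), the
threshold-scan candidate selection rule, Bonferroni correction, and the
polygenic-score variant selection rule (p cutoff, exclusion list, LD-block
representatives, discovery/replication frequency concordance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .annotation import VariantKey
from .simulate import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the association workflow.

    ``candidate_thresholds`` is scanned from the smallest upwards: the
    selected threshold is the lowest one yielding at least
    ``selection_min_variants`` hits (strict ``p < t``), which keeps the false
    positive rate low while guaranteeing enough candidates to carry forward.
    """

    candidate_thresholds: tuple[float, ...] = (0.05, 0.01, 0.005, 0.001, 0.0005, 0.00005)
    selection_min_variants: int = 11
    bonferroni_alpha: float = 0.05
    flank: int = 20_000
    n_pcs: int = 10
    prs_maf_tolerance: float = 0.5
    n_permutations: int = 10_000
    n_bins: int = 30

    def __post_init__(self) -> None:
        t = tuple(sorted(self.candidate_thresholds, reverse=True))
        if len(set(t)) != len(t):
            raise ValueError("candidate thresholds must be distinct")
        self.candidate_thresholds = t
        for p in t + (self.bonferroni_alpha,):
            if not 0.0 < p < 1.0:
                raise ValueError("probabilities must lie in (0, 1)")


@dataclass
class VariantAssociation:
    """One row of the single-variant association table.

    ``c_a``/``c_u`` are allele-1 counts among cases/controls over non-missing
    genotypes, ``f_a``/``f_u`` the corresponding frequencies (denominator
    2 x non-missing group size).  ``or_estimate``/``p_value`` are NaN when the
    fit did not converge or the variant was skipped (see ``status``).
    """

    key: VariantKey
    or_estimate: float
    p_value: float
    c_a: int
    c_u: int
    f_a: float
    f_u: float
    n_eff: int
    beta: float = float("nan")
    se: float = float("nan")
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


# ---------------------------------------------------------------------------
# allele counting
# ---------------------------------------------------------------------------

def allele_stats(
    panel: GenotypePanel, variant: VariantKey | int
) -> tuple[int, int, float, float]:
    """Allele-1 counts and frequencies by case/control status.

    Counts run over non-missing genotypes only; frequencies divide by twice
    the non-missing group size.  With every genotype missing in a group the
    frequency is NaN.
    """
    j = variant if isinstance(variant, (int, np.integer)) else panel.variant_index(variant)
    dos = panel.dosages[:, j]
    case = panel.phenotype == 1
    c_a, f_a = _count_group(dos[case])
    c_u, f_u = _count_group(dos[~case])
    return c_a, c_u, f_a, f_u


def _count_group(dos: np.ndarray) -> tuple[int, float]:
    ok = ~np.isnan(dos)
    n = int(ok.sum())
    c = int(np.nansum(dos[ok]))
    if n == 0:
        logger.warning("all genotypes missing in one status group")
        return c, float("nan")
    return c, c / (2 * n)


def crude_odds_ratio(
    c_a: int, n_case_alleles: int, c_u: int, n_control_alleles: int
) -> tuple[float, bool]:
    """Unadjusted 2x2 allele odds ratio.

    (c_a / (N_a - c_a)) / (c_u / (N_u - c_u)); when any cell is zero the
    Haldane–Anscombe +0.5 correction is applied to all four cells and the
    returned flag is True.  A zero margin leaves the OR undefined (NaN).
    """
    if min(c_a, c_u) < 0 or c_a > n_case_alleles or c_u > n_control_alleles:
        raise ValueError("counts must satisfy 0 <= c <= margin")
    if n_case_alleles == 0 or n_control_alleles == 0:
        logger.warning("zero margin: odds ratio undefined")
        return float("nan"), True
    cells = [c_a, n_case_alleles - c_a, c_u, n_control_alleles - c_u]
    corrected = 0 in cells
    if corrected:
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    return (a / b) / (c / d), corrected


# ---------------------------------------------------------------------------
# logistic SVA
# ---------------------------------------------------------------------------

def _covariate_frame(panel: GenotypePanel, n_pcs: int, extra: Sequence[str]) -> pd.DataFrame:
    pcs = panel.pc_columns()[:n_pcs]
    cols = list(pcs) + [c for c in extra if c in panel.covariates.columns]
    missing = [c for c in extra if c not in panel.covariates.columns]
    if missing:
        raise ValueError(f"covariate(s) not in panel: {missing}")
    return panel.covariates[cols].reset_index(drop=True)


def _independent_columns(x: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns.

    Earlier columns take precedence, so ordering the design as
    (const, dosage, covariates) protects the term of interest when a
    covariate is collinear with it (e.g. PCs computed from a near-degenerate
    dosage matrix).
    """
    basis: list[np.ndarray] = []
    keep: list[int] = []
    for j in range(x.shape[1]):
        v = x[:, j].astype(float)
        r = v.copy()
        for q in basis:
            r -= q * (q @ r)
        nrm = np.linalg.norm(r)
        if nrm > tol * max(np.linalg.norm(v), 1.0):
            basis.append(r / nrm)
            keep.append(j)
    return keep


def logistic_sva(
    panel: GenotypePanel,
    config: AnalysisConfig | None = None,
    extra_covariates: Sequence[str] = (),
    use_lrt: bool = False,
) -> list[VariantAssociation]:
    """Per-variant logistic regression of status on dosage plus covariates.

    Missing genotypes are excluded per variant (complete-case); monomorphic
    variants are skipped with ``status='monomorphic'``; non-convergence or
    separation is flagged, never silently dropped.  Covariate columns that
    are constant within a variant's complete cases are dropped from that fit.
    """
    config = config or AnalysisConfig()
    if panel.n_cases < 2 or panel.n_controls < 2:
        raise ValueError("need at least two cases and two controls")
    cov = _covariate_frame(panel, config.n_pcs, extra_covariates)
    y_all = panel.phenotype.astype(float)

    results: list[VariantAssociation] = []
    for j, key in enumerate(panel.variants):
        dos = panel.dosages[:, j]
        ok = ~np.isnan(dos)
        c_a, c_u, f_a, f_u = allele_stats(panel, j)
        base = dict(key=key, c_a=c_a, c_u=c_u, f_a=f_a, f_u=f_u, n_eff=int(ok.sum()))
        d, y = dos[ok], y_all[ok]
        if d.size == 0 or np.all(d == d[0]):
            results.append(VariantAssociation(
                or_estimate=float("nan"), p_value=float("nan"),
                status="monomorphic", **base))
            continue
        if len(np.unique(y)) < 2:
            raise ValueError("phenotype constant among complete cases")
        x = np.column_stack([d, cov.values[ok]])
        keep = [0] + [k for k in range(1, x.shape[1]) if np.ptp(x[:, k]) > 0]
        x = sm.add_constant(x[:, keep], has_constant="add")
        indep = _independent_columns(x)
        if 1 not in indep:  # dosage absorbed by the intercept: cannot test
            results.append(VariantAssociation(
                or_estimate=float("nan"), p_value=float("nan"),
                status="monomorphic", **base))
            continue
        if len(indep) < x.shape[1]:
            logger.debug("variant %s: dropped %d collinear covariate column(s)",
                         key.label(), x.shape[1] - len(indep))
            x = x[:, indep]
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            beta, se = fit.params[1], fit.bse[1]
            if use_lrt:
                x0 = np.delete(x, 1, axis=1)
                fit0 = sm.Logit(y, x0).fit(disp=0, maxiter=200)
                p = float(chi2.sf(2 * (fit.llf - fit0.llf), df=1))
            else:
                p = float(fit.pvalues[1])
            status = "ok"
            if not fit.mle_retvals.get("converged", True) or not np.isfinite(se) or se > 100:
                status = "non_converged"
            results.append(VariantAssociation(
                or_estimate=float(np.exp(beta)), p_value=p,
                beta=float(beta), se=float(se), status=status, **base))
        except Exception as exc:  # separation / singularities
            logger.warning("variant %s: fit failed (%s)", key.label(), exc)
            results.append(VariantAssociation(
                or_estimate=float("nan"), p_value=float("nan"),
                status="fit_failed", **base))
    return results


# ---------------------------------------------------------------------------
# QC and selection
# ---------------------------------------------------------------------------

def genomic_lambda(p_values: Iterable[float]) -> float:
    """Genomic inflation factor: median observed chi-square over its null median.

    Each p-value is transformed to the 1-df chi-square quantile it would
    correspond to under the null; lambda is the median of those divided by
    the exact chi-square(1) median (computed, not the rounded 0.456).
    """
    p = np.asarray([x for x in p_values if np.isfinite(x)], dtype=float)
    if p.size == 0:
        raise ValueError("no valid p-values")
    observed = chi2.isf(p, df=1)
    return float(np.median(observed) / chi2.ppf(0.5, df=1))


def select_candidate_threshold(
    p_values: Mapping[VariantKey, float] | Sequence[float],
    config: AnalysisConfig | None = None,
) -> tuple[float, list]:
    """Lowest listed threshold that yields enough candidates.

    Scans the configured thresholds from the smallest up and returns the
    first with at least ``selection_min_variants`` p-values strictly below
    it, plus the passing variants; if none qualifies the largest threshold
    is returned with a warning.
    """
    config = config or AnalysisConfig()
    if isinstance(p_values, Mapping):
        items = list(p_values.items())
    else:
        items = list(enumerate(p_values))
    for t in sorted(config.candidate_thresholds):
        selected = [k for k, p in items if np.isfinite(p) and p < t]
        if len(selected) >= config.selection_min_variants:
            return t, selected
    t = max(config.candidate_thresholds)
    selected = [k for k, p in items if np.isfinite(p) and p < t]
    logger.warning(
        "no threshold yielded %d variants; falling back to %g with %d",
        config.selection_min_variants, t, len(selected))
    return t, selected


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance cutoff alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def select_prs_variants(
    discovery: Sequence[VariantAssociation],
    replication: Sequence[VariantAssociation],
    ld_blocks: Sequence[Mapping] | Sequence = (),
    exclusions: Iterable[VariantKey] = (),
    config: AnalysisConfig | None = None,
    p_cutoff: float | None = None,
) -> list[VariantKey]:
    """Variants entering the polygenic risk score.

    Keep discovery hits with ``p < cutoff``; drop the explicit exclusion list
    (e.g. variants that failed orthogonal validation); drop variants whose
    case-group allele frequency moves by more than ``prs_maf_tolerance``
    (relative to the discovery frequency) between discovery and replication;
    within each declared LD block keep exactly one representative — the
    configured one if given, else the smallest discovery p.

    ``ld_blocks`` entries are either iterables of keys or mappings with
    ``members`` and optional ``representative``.
    """
    config = config or AnalysisConfig()
    cutoff = p_cutoff if p_cutoff is not None else min(config.candidate_thresholds)
    disc = {r.key: r for r in discovery}
    repl = {r.key: r for r in replication}
    excluded = set(exclusions)

    kept: list[VariantKey] = []
    for key, r in disc.items():
        if not (np.isfinite(r.p_value) and r.p_value < cutoff):
            continue
        if key in excluded:
            logger.info("%s removed: on exclusion list", key.label())
            continue
        rr = repl.get(key)
        if rr is None:
            logger.info("%s removed: absent from replication", key.label())
            continue
        if r.f_a > 0:
            rel_diff = abs(r.f_a - rr.f_a) / r.f_a
        else:
            rel_diff = 0.0 if rr.f_a == 0 else float("inf")
        if not rel_diff <= config.prs_maf_tolerance:
            logger.info("%s removed: case-frequency rel. diff %.3f > %.3f",
                        key.label(), rel_diff, config.prs_maf_tolerance)
            continue
        kept.append(key)

    for block in ld_blocks:
        if isinstance(block, Mapping):
            members = set(block["members"])
            rep = block.get("representative")
        else:
            members, rep = set(block), None
        if rep is not None and rep not in members:
            raise ValueError(f"LD representative {rep} not in its block")
        in_block = [k for k in kept if k in members]
        if not in_block:
            continue
        if rep is not None:
            if rep not in in_block:
                logger.warning("LD representative %s filtered out earlier; "
                               "using smallest discovery p instead", rep)
                rep = min(in_block, key=lambda k: disc[k].p_value)
        else:
            rep = min(in_block, key=lambda k: disc[k].p_value)
        kept = [k for k in kept if k not in members or k == rep]
    return kept


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def association_table(
    results: Sequence[VariantAssociation],
    gene_of: Mapping[VariantKey, str] | None = None,
) -> pd.DataFrame:
    """Results as a frame with the conventional column layout."""
    gene_of = gene_of or {}
    rows = []
    for r in results:
        rows.append({
            "GENE": gene_of.get(r.key, ""),
            "SNP": r.key.label(),
            "CHR": r.key.chromosome,
            "BP": r.key.position,
            "A1": r.key.alt,
            "OR": r.or_estimate,
            "P": r.p_value,
            "C_A": r.c_a,
            "C_U": r.c_u,
            "F_A": r.f_a,
            "F_U": r.f_u,
            "STATUS": r.status,
        })
    return pd.DataFrame(rows)
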