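"""Log-odds-weighted polygenic risk score and its replication test.

The score of a sample is the sum over selected variants of allele dosage
times the natural log of the variant's discovery-set odds ratio:
``PRS_i = sum_j dosage_ij * ln(OR_j)``.  With all ORs >= 1 the score is
non-negative, zero for a carrier of no risk alleles, and at most
``2 * sum_j ln(OR_j)``.  Association of the score with disease in an
independent panel is tested by logistic regression with age, sex and
principal components as covariates; per-term p-values are reported with
Benjamini–Hochberg and Bonferroni adjustments across the model terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .annotation import VariantKey
from .simulate import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrsModel:
    """Selected variants and their ln(OR) weights.

    ``source`` records which dataset the odds ratios were estimated in
    (weights are trained on discovery and applied in replication).
    """

    variants: tuple[VariantKey, ...]
    weights: tuple[float, ...]
    source: str = "discovery"

    def __post_init__(self) -> None:
        if len(self.variants) != len(self.weights):
            raise ValueError("one weight per variant required")
        if not all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @classmethod
    def from_odds_ratios(cls, variants, odds_ratios, source="discovery") -> "PrsModel":
        return cls(tuple(variants), tuple(float(np.log(o)) for o in odds_ratios), source)


@dataclass
class PrsReport:
    """Score summary plus the replication association table."""

    scores: np.ndarray
    mean: float
    min: float
    max: float
    upper_quartile_case_fraction: float
    upper_quartile_control_fraction: float
    association: pd.DataFrame = field(default_factory=pd.DataFrame)
    missingness_flags: np.ndarray | None = None
    degenerate: bool = False


def compute_prs(panel: GenotypePanel, model: PrsModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample weighted allele-dosage sum.

    Missing dosages contribute zero (conservative; scores stay comparable)
    and the affected samples are flagged in the returned boolean vector.
    Raises if a model variant is absent from the panel.
    """
    idx = [panel.variant_index(v) for v in model.variants]
    dos = panel.dosages[:, idx]
    miss = np.isnan(dos)
    scores = np.where(miss, 0.0, dos) @ np.asarray(model.weights)
    return scores, miss.any(axis=1)


def prs_quartile_summary(
    scores: np.ndarray, phenotype: np.ndarray
) -> tuple[float, float, bool]:
    """Fraction of each status group strictly above the combined 75th percentile.

    The cut is the 75th percentile of the pooled score distribution; samples
    exactly at the cut count as below it.  Constant scores are degenerate:
    both fractions are zero and the flag is set.
    """
    scores = np.asarray(scores, dtype=float)
    phenotype = np.asarray(phenotype)
    if scores.size < 4:
        raise ValueError("need at least four samples for quartiles")
    if np.ptp(scores) == 0:
        logger.warning("constant PRS: quartile summary degenerate")
        return 0.0, 0.0, True
    cut = float(np.percentile(scores, 75))
    top = scores > cut
    case = phenotype == 1
    f_case = float(top[case].mean()) if case.any() else float("nan")
    f_ctrl = float(top[~case].mean()) if (~case).any() else float("nan")
    return f_case, f_ctrl, False


def prs_association(
    panel: GenotypePanel,
    scores: np.ndarray,
    covariates: tuple[str, ...] = ("age", "sex"),
    n_pcs: int = 10,
) -> pd.DataFrame:
    """Logistic regression of status on PRS plus covariates.

    Returns one row per model term (including the intercept) with columns
    ``P``, ``FDR`` (Benjamini–Hochberg), ``Bonf``, ``OR``, ``2.5%``,
    ``97.5%``, ``Estimate``, ``std.error``, ``Statistic``; the multiplicity
    adjustments run across all fitted terms.  A constant score is a
    degenerate design and raises.
    """
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("PRS constant across samples: coefficient undefined")
    y = panel.phenotype.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must include both classes")
    cols = {"PRS": scores}
    for c in covariates:
        if c in panel.covariates.columns:
            cols[c.upper()] = panel.covariates[c].to_numpy(dtype=float)
    for c in panel.pc_columns()[:n_pcs]:
        cols[c] = panel.covariates[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    X = X.loc[:, (X.max() - X.min()) > 0]  # drop constant covariates
    X.insert(0, "(Intercept)", 1.0)
    # PCs of a small dosage panel can span the score exactly; drop collinear
    # covariate columns, intercept and PRS taking precedence
    from .association import _independent_columns

    indep = _independent_columns(X.to_numpy())
    if len(indep) < X.shape[1]:
        dropped = [c for j, c in enumerate(X.columns) if j not in indep]
        logger.info("dropped collinear covariate column(s): %s", dropped)
        X = X.iloc[:, indep]
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", True):
        logger.warning("PRS association fit did not converge")
    est = fit.params
    se = fit.bse
    z = est / se
    p = fit.pvalues
    ci = fit.conf_int()
    fdr = multipletests(p.values, method="fdr_bh")[1]
    bonf = np.minimum(p.values * len(p), 1.0)
    out = pd.DataFrame({
        "P": p.values,
        "FDR": fdr,
        "Bonf": bonf,
        "OR": np.exp(est.values),
        "2.5%": np.exp(ci[0].values),
        "97.5%": np.exp(ci[1].values),
        "Estimate": est.values,
        "std.error": se.values,
        "Statistic": z.values,
    }, index=est.index)
    return out


def prs_report(
    panel: GenotypePanel,
    model: PrsModel,
    covariates: tuple[str, ...] = ("age", "sex"),
    n_pcs: int = 10,
    with_association: bool = True,
) -> PrsReport:
    """Score a panel, summarise, and (optionally) run the association test."""
    scores, miss = compute_prs(panel, model)
    f_case, f_ctrl, degenerate = prs_quartile_summary(scores, panel.phenotype)
    assoc = pd.DataFrame()
    if with_association and not degenerate:
        assoc = prs_association(panel, scores, covariates=covariates, n_pcs=n_pcs)
    return PrsReport(
        scores=scores,
        mean=float(scores.mean()),
        min=float(scores.min()),
        max=float(scores.max()),
        upper_quartile_case_fraction=f_case,
        upper_quartile_control_fraction=f_ctrl,
        association=assoc,
        missingness_flags=miss,
        degenerate=degenerate,
    )
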