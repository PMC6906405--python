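# Methods

This note documents the models implemented in `netseed`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Seed-network expansion and variant filtering

The background interactome is an undirected simple graph over opaque
identifiers; self-loops are dropped on load and duplicate edges collapsed.
The analysis gene set is the seed list plus all first neighbours. Seeds
absent from the interactome (e.g. mitochondrially encoded proteins, which
often lack PPI records) are retained as isolated members so seed counts
stay auditable. No interaction-confidence filtering is applied; the
association test downstream is the evidence filter.

Variants are kept iff their position lies in `[start − f, end + f]` of at
least one member gene, with flank `f = 20,000` bp applied symmetrically on
both sides regardless of strand and with **inclusive** boundaries (a
variant exactly 20 kbp from a gene end is kept). Gene (BED) boundaries are
used rather than transcript models. Cohort intersection normalises
chromosome labels (`chr` prefix stripped) and splits multi-allelic records
into biallelic keys; allele strand flips are not reconciled — cohorts are
assumed to share a reference strand.

## Single-variant association

Per variant, case/control status is regressed on allele dosage by maximum
likelihood logistic regression with the top-10 principal components of the
mean-imputed, centred dosage matrix as ancestry covariates (age added in
replication panels). The per-allele odds ratio is `exp(β)` and the p-value
is the Wald test on the dosage coefficient; a likelihood-ratio alternative
sits behind `use_lrt=True`. Missing genotypes are handled complete-case per
variant — this convention is what makes reported allele frequencies
reproducible from counts and non-missing group sizes. Monomorphic variants
are skipped with a reason; separation and non-convergence are flagged, not
dropped, and no Firth-type penalisation is applied (an explicit extension
point).

Two numerical details: covariate columns that are constant within a
variant's complete cases are removed from that fit, and the design is
reduced to a linearly independent column set by a greedy Gram–Schmidt pass
ordered (intercept, dosage, covariates). The second rule exists because at
desk scale the PCs are computed from the same small dosage matrix being
tested: with very few variants the PC span contains the dosages exactly,
and without the reduction every fit would be singular. The same reduction
protects the PRS term in the score's replication regression.

Genomic inflation is `λ = median(χ²_obs) / median(χ²₁)` with the observed
χ² obtained by quantile-transforming the p-values and the reference median
computed from the χ²₁ quantile function, not the rounded 0.455/0.456
constant (so `λ = 1` exactly when every p = 0.5). At a few hundred tested
variants the median itself carries substantial sampling noise (sd of λ
≈ 0.1 at 500 variants, ≈ 0.2 at 100), so single-panel λ values at desk
scale scatter widely around 1 even under perfect calibration; calibration
claims in the tests therefore average over replicates or use large
uniform-p samples.

## Candidate selection and multiple testing

The threshold scan walks the configured cutoffs (default 0.05 … 5×10⁻⁵)
from the smallest upward and returns the first with at least
`selection_min_variants` (default 11) p-values strictly below it — the
"lowest threshold with enough candidates" rule keeps the false-positive
rate low while guaranteeing material for the score; if none qualifies the
largest cutoff is returned with a warning. Replication uses the Bonferroni
cutoff `α/m` over the candidates actually carried forward.

## Polygenic risk score

`PRS_i = Σ_j g_ij · ln(OR_j)` with natural-log weights taken from the
discovery fit and applied unchanged in replication. Missing dosages
contribute zero and flag the sample (deterministic and conservative; mean
imputation would make scores depend on the panel). Score selection applies,
in order: discovery p-cutoff; an explicit exclusion list (for variants that
failed orthogonal validation); a frequency-concordance screen; one
representative per declared LD block (the configured one, else the
smallest discovery p). LD blocks are *declared* in the config — the package
does not estimate linkage.

The concordance screen quantifies "similar allele frequency between
datasets" as `|f_disc − f_repl| / f_disc ≤ 0.5` on case-group frequencies,
with the discovery frequency as the reference denominator. The asymmetric
denominator is deliberate: discovery is the dataset the weight was
estimated in, and the screen asks whether that estimate is transportable.
On the reference candidate table this rule keeps exactly the
strong-concordance variants and drops every zero-replication-count and
discordant one; a symmetric mean denominator would admit one discordant
variant that the asymmetric rule correctly rejects.

The replication association fits
`status ~ PRS + age + sex + PC₁…₁₀` and reports every model term
(intercept included) with Benjamini–Hochberg and Bonferroni adjustments
across all fitted terms — the adjustment family is the model's coefficient
list, which is what makes the adjusted columns reconstructible from the raw
p-values and the term count. The upper-quartile summary cuts at the 75th
percentile of the **combined** score distribution (samples exactly at the
cut count as below); a control-only cut would be an alternative reading and
is not implemented.

## Prediction models

The variant model is a random forest on allele dosages (500 trees,
unlimited depth, fixed seed) and the PRS model a univariate logistic
classifier; both use inverse-class-frequency ("balanced") weighting.
Without it, a classifier trained on a 1:137 case:control panel degenerates
to the majority class and every threshold metric is vacuous; with it the
models operate in the regime where a material fraction of controls is
called positive — the regime the reference confusion matrix exhibits.
Feature importances are normalised mean decrease in Gini impurity and sum
to one whenever any split occurred. AUC is the Mann–Whitney statistic with
ties counted ½, and its 95% CI uses DeLong's structural-component variance
estimator (implemented here; no installed package exposes it), clipped to
[0, 1].

## Subnetwork topology null model

APL is the mean shortest-path distance over unordered node pairs of the
largest connected component; ACC the mean local clustering coefficient
over LCC nodes with degree-<2 nodes contributing 0. Equal-sized LCC ties
break to the component containing the lexicographically smallest node, and
binning ties break by identifier, so all graph statistics are
deterministic.

The null preserves degree structure by ranking all background nodes by
(degree, identifier) and cutting them into `n_bins = 30` contiguous
rank-blocks (the first `n mod 30` bins take the extra node); each
permutation replaces the subset nodes of a bin with a uniform
without-replacement sample of that bin's members (self-maps allowed). The
per-bin multiset of the subset is preserved exactly — an assertable
invariant, tested. One-sided Monte Carlo p-values use the add-one estimator
`p = (1 + #extreme) / (1 + N)` with ties counted extreme, so `p > 0`
always; tails are fixed to APL-lower and ACC-upper (the "small-world"
alternative) but configurable. Permuted subsets whose LCC has fewer than 3
nodes are excluded from the APL null (APL on < 2 reachable pairs is
uninformative) and counted so the effective N is transparent; they remain
in the ACC null.

A known behaviour of the ACC-on-LCC convention at desk scale: a fragmented
null draw whose LCC happens to be a single triangle scores ACC = 1, which
fattens the null's upper tail. Consequently only dense, clique-like planted
modules are reliably detected in 500–1000-node backgrounds
(`analysis/04_topology_power.py` traces the power curve: ~0% power at 30%
excess density, ~90% at clique density). Detection of diffuse modules needs
either larger backgrounds or an all-subset-nodes ACC variant, neither of
which is the reference convention implemented here.

## Synthetic data

`simulate_interactome` grows a Barabási–Albert background (heavy-tailed
degrees, like real interactomes; `attachment_edges = 2` gives mean degree
≈ 4, the right order for experimentally detected PPI networks at desk
scale) and plants a module by Bernoulli edge fill-in among a random node
subset — the module is returned as the seed list, making the topology
test's alternative hypothesis realisable.

`simulate_cohort` draws individuals from a two-subpopulation mixture;
subpopulation allele frequencies follow Balding–Nichols drift
`Beta(p(1−F)/F, (1−p)(1−F)/F)` around the ancestral MAF (F = 0
short-circuits to the shared MAF). Disease follows the additive log-odds
model `logit P = β₀ + Σ_j ln(OR_j)·g_j` — the same model family the SVA
fits, so effect recovery is well defined — with β₀ solved by root-finding
on a 20,000-draw Monte Carlo genotype pool so the population prevalence
matches the target. Cases and controls are banked by rejection sampling
(cap 10⁷ draws, then a convergence error with diagnostics). Ages are
uniform on 40–80 years (adult sampling ages of a population cohort), sex
Bernoulli(½), and the top-10 dosage PCs are attached as covariates. Panels
with fewer informative dosage dimensions carry min(10, rank) PCs; the TSV
writer zero-pads to PC10 for schema stability and the reader drops the
padding.

The reference study bundle (`netseed.study.build_study_bundle`) uses the
small-cohort design the workflow targets: discovery 439 cases / 855
controls, replication 60 / 8214, a 1000-node interactome with a 20-gene
module at 30% excess density expanding to ~90 member genes, and 200
variants — 12 planted effects spanning OR 0.55–2.2 at MAF 0.05–0.15
(the range of the reference candidate table) inside module genes, 188 null
variants spread over member bodies, flanks, non-member genes and
intergenic space — with mild stratification (F_ST = 0.01, 30% admixture)
and 1% prevalence. Not emulated: linkage disequilibrium (blocks are
declared, not simulated), realistic site-frequency spectra, genotype
missingness patterns, case/control age–sex matching, and sequencing-depth
artefacts. Passing tests therefore demonstrate the statistical machinery
under the stated generative model, not robustness to those real-data
features.

## Problem sizes in tests and scripts

The test suite and acceptance script scale the experiments to desk size as
the package's own reference conditions: null calibration at 500 variants ×
1000 samples; effect recovery over 20–50 replicates at n = 4000; topology
power over 10–20 replicates at N = 1000 permutations; the study pipeline at
the cohort sizes above with N = 2000 permutations. The full N = 10,000
permutation default remains the production setting of the CLI.

## Known limitations

* Wald p-values degrade for very rare variants (the zero-count replication
  rows of the reference table are exactly the regime where the fit is
  flagged rather than trusted).
* No Firth penalisation; separation is reported, not repaired.
* The topology test's power at desk scale is limited to dense modules (see
  above); the printed significance of any particular real-database
  subnetwork depends on that database snapshot and is not reproducible
  from this package alone.
* `λ` at a few hundred variants is a noisy QC indicator, not a test
  statistic.
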