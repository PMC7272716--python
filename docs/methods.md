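# Methods

This note documents the statistical model behind each stage of `lncnet`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions for degenerate inputs.

## Differential expression (`diffexp`)

Per gene, expression is compared between two groups of log2 intensities with
the equal-variance two-sample Student's *t*-test (df = n₁ + n₂ − 2); Welch's
variant is available via flag but is not the default because with n = 3 per
group the pooled-variance test is the conventional microarray choice and the
per-gene variance estimates are too unstable to justify separate variances.
The effect size is the signed linear fold change: log2FC is the difference of
group means; FC = 2^log2FC when ≥ 1, otherwise −2^(−log2FC), so |FC| ≥ 1
always and a 4-fold loss is written −4. A gene is UP when FC ≥ 2 and
p < 0.05, DOWN when FC ≤ −2 and p < 0.05, otherwise NS. Both thresholds are
parameters. Benjamini–Hochberg adjusted p-values are computed (via
statsmodels) and reported but do not gate the call: with three replicates
per group the raw-p + fold-change rule is the screen's operating point, and
the FDR column exists for auditability. Zero-variance conventions: equal
means → t = 0, p = 1; unequal means with zero variance → p = 0 and an
infinite statistic of the sign of the difference.

No moderated (limma-style) variance shrinkage is attempted; that is a
deliberate non-goal — the pipeline reproduces a plain t-test screen.

## Over-representation analysis (`enrichment`)

Terms are scored with the upper-tail hypergeometric probability
P(X ≥ k | N, K, n) where N is the universe (all genes on the annotation
table — the microarray background convention, not the genome), K the term
size after intersection with the universe, n the study size and k the
overlap. A conservative EASE-style variant (scoring k − 1) is available by
flag. Significance defaults to raw p < 0.05. The GO/KEGG "overlap"
selection is interpreted at the gene level: a DE-mRNA is kept when it is a
member of at least one significant GO term and at least one significant
KEGG pathway. A term-level interpretation (intersecting term lists) was
rejected because it does not produce a gene list at all, and the selection
must feed genes to the network stage. No GO DAG propagation is performed.

## Coexpression network and hubs (`coexpression`)

Pearson r is computed between every candidate lncRNA and mRNA across all
samples of both groups pooled. Pooling is an assumption (within-group
correlation at n = 3 would be essentially noise); it also explains the
near-unity |r| values that a real two-group separation produces, which is
why the working threshold can sit at |r| ≥ 0.99. The threshold applies to
the absolute value and is inclusive by default (both configurable); the sign
is kept as an edge attribute and exported as pos/neg interaction types in
SIF. Genes with zero variance are skipped with a warning rather than
failing the whole build. The network is strictly bipartite by default; an
optional flag adds mRNA–mRNA edges for exploring intercorrelated partner
sets. Degree centrality is the raw incident-edge count; hubs are lncRNAs
with degree ≥ 6, ordered by degree descending with the gene id as a
deterministic tiebreak. No soft thresholding, topological overlap or
correlation p-values are computed: with six samples a correlation p-value
is meaningless and the screen is defined by the hard cutoff.

## Pathway network (`pathways`)

Fig-style tripartite links are pure membership: each hub's partner mRNAs are
joined to every pathway gene set containing them (so the link count is the
sum of membership counts over partners). Separately, per-hub pathway
significance treats the hub's partner set as the study list and scores each
pathway hypergeometrically, BH-adjusted, significant at FDR < 0.05. Both
views are provided because membership answers "which pathways could this hub
touch" while enrichment answers "which pathways are over-represented among
its partners"; the universe for the latter is the array-wide gene list.

## Survival analysis (`survival`)

Cleaning removes records with expression exactly 0 and records with
follow-up under 30 days; the two rules are counted independently (a record
failing both is dropped once, counted twice) and the drop report is carried
into the result for auditability. The high/low split is at the median of
the post-cleaning expression values, high meaning strictly above; the
quantile is a parameter because the split rule of the original analysis
software is not recoverable. The Kaplan–Meier estimator is the standard
product limit; censored records shrink the risk set without a step. The
log-rank test is the Mantel–Haenszel form: at each pooled event time the
observed events in the high group are compared with their conditional
expectation, variances are hypergeometric (tie-aware for d > 1), and
χ² = (O − E)²/V on 1 df. The hazard ratio is the O/E ratio estimator
(O_h/E_h)/(O_l/E_l) rather than a Cox fit — no partial-likelihood machinery
is in scope — with the usual caveat that O/E is biased toward the null for
hazard ratios far from 1 (observed empirically: a generating HR of 3 with
complete follow-up is estimated around 2.4). A cohort with no events
reports χ² = 0, p = 1 and an undefined (NaN) HR. Subgroup analyses filter
on covariate values (e.g. ER = 1) before cleaning and refuse subgroups with
fewer than 10 analyzable records.

## Clinical statistics (`clinstats`)

The 2×2 association test is the Pearson χ² without continuity correction —
this exactly reproduces the printed statistics of the bundled 20-patient
validation tables (ER 4.848, HER2 5.488, PR 1.818, age 0.606, TNM 3.810,
Ki-67 3.778); Yates correction is a flag. One printed row (lymph-node
metastasis, 3.333) is not consistent with its own printed counts under
either variant and is deliberately not matched. ROC AUC is the rank-sum
form P(case > control) + ½P(tie). 2^−ΔΔCq relative quantification follows
the standard housekeeping-gene/calibrator algebra, multiplicative in ΔΔCq
shifts. The paired t-test shares the zero-variance conventions of the
two-sample test.

## ceRNA assembly (`cerna`)

The module never contacts an interaction database: it filters user-supplied
(or simulated) score tables. Boundary handling follows the stated rules
exactly — strict inequalities for correlation > 0.9 and binding > 0.04,
inclusive for context++ ≤ −0.2. Triplets chain a hub→miRNA link with a
miRNA→mRNA link, and by default the mRNA must also be a coexpression
partner of the hub, keeping the sponge hypothesis anchored to the
expression evidence (a flag disables the restriction). Output is sorted by
(miRNA, mRNA), so assembly is invariant to input row order. The bundled
worked-example tables carry synthetic scores: only the candidate names and
the thresholds are published, so the per-edge scores and the miRNA→mRNA
edge assignment are constructed placeholders that satisfy the thresholds,
and only node counts are treated as checkable facts.

## Synthetic data (`simulate`)

The expression generator emulates a 3-vs-3 two-group design: gene baselines
are Normal(baseline_mean = 8, baseline_sd = 2) on the log2 scale with
Normal(0, noise_sd = 0.25) residuals — values chosen as a plain
representation of normalized log2 microarray intensities, since the
original normalization convention is not recoverable. Planted DE genes add
±log2|FC| to the case group, so the mean realized log2 difference equals
the planted effect by construction. Hub modules are generated analytically:
the partner is an affine transform of the hub profile with slope
log2FC_partner/log2FC_hub plus Gaussian noise of variance
slope²·σ_h²·(1/r² − 1), where σ_h² = (Δ/2)² + noise_sd² is the population
variance of the hub profile under a balanced group shift Δ; the population
correlation then equals the target r exactly, a negative partner fold
change yields a negative correlation, and target r = 1 with zero noise
gives sample r = 1 identically.

The survival generator draws expression log-normally, assigns the planted
hazard ratio to the above-median half (so a later median split recovers the
generating groups), and draws exponential event times. Censoring is an
independent exponential whose rate is scaled per record to
h·c/(1 − c), making the censoring probability exactly c for every record by
the competing-exponentials identity. Records with expression forced to 0
and follow-up times resampled below 30 days are injected into disjoint
random subsets with exact counts, so the cleaning filters have known ground
truth. An optional per-covariate hazard-ratio override plants subgroup
effects (e.g. ER-positive-only risk). Gene-set and interaction generators
plant, respectively, a term equal to a supplied gene list and score rows
drawn from passing/failing ranges around the ceRNA thresholds.

What the simulators do **not** emulate: probe-level microarray physics
(background, saturation), batch effects, correlated null genes,
non-proportional hazards, informative censoring, or realistic miRNA score
distributions. Passing tests on these simulations therefore demonstrate
correctness of the statistical machinery under its stated model, not
robustness to real-data artefacts.

## Problem sizes and determinism

The test and acceptance workloads use deliberately compact problem sizes —
hundreds of genes, cohorts of 30–1000, 100-seed hub-recovery sweeps, 2000
null log-rank simulations — which are sufficient for the Monte-Carlo
tolerances asserted (e.g. type-I error within 0.05 ± 0.015, O/E recovery of
a planted HR = 2 within 15%). All randomness flows through explicit
`numpy.random.default_rng` seeds; a fixed seed and configuration reproduce
outputs byte-identically.

## Known limitations

* Dataset-scale published counts (thousands of DE transcripts, the
  855-edge full network, specific pathway p-values, TCGA cohort sizes and
  survival p-values) depend on the original data snapshots and annotation
  versions and are intentionally out of scope; the bundled worked-example
  tables are the reproducible surface.
* The O/E hazard ratio is a screen statistic, not an efficient estimator;
  users needing adjusted or efficient HR estimates should fit a Cox model
  elsewhere.
* Enrichment ignores GO topology and treats terms independently.
* With n = 3 per group, all per-gene inference is fragile by nature; the
  package reproduces the screen's rules, it does not endorse them as
  optimal statistics.
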