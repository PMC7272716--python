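# lncnet

**lncRNA–mRNA coexpression network analysis of chemoresistance.**

`lncnet` is a tested, reusable re-implementation of the integrative screen
used to nominate regulatory long non-coding RNAs (lncRNAs) from a two-group
expression comparison — the canonical setting being doxorubicin-resistant
(MCF-7/ADR) versus sensitive (MCF-7) breast-cancer cells profiled on an
lncRNA microarray at n = 3 replicates per group, followed by clinical
validation. It is aimed at computational biologists who want the whole chain
as auditable library code rather than a string of web tools.

## The pipeline

1. **Differential expression** (`lncnet.diffexp`) — per-gene equal-variance
   Student's *t* on log2 intensities plus a signed linear fold change
   (log2FC = mean(case) − mean(control); FC = 2^log2FC, reported as
   −2^(−log2FC) for down-regulation). A gene is called UP/DOWN when
   |FC| ≥ 2 **and** p < 0.05; BH FDR is reported alongside.
2. **Enrichment + overlap selection** (`lncnet.enrichment`) — upper-tail
   hypergeometric over-representation P(X ≥ k) of the DE-mRNAs in GO and
   KEGG collections; the mRNAs belonging to ≥ 1 significant term in *both*
   analyses move forward.
3. **Coexpression network** (`lncnet.coexpression`) — Pearson *r* between
   every lncRNA and selected mRNA across all samples pooled; edges at
   |r| ≥ 0.99; hub lncRNAs are nodes with degree ≥ 6.
4. **Pathway network** (`lncnet.pathways`) — tripartite
   lncRNA–mRNA–pathway links by gene-set membership, with per-hub
   hypergeometric pathway significance (FDR < 0.05).
5. **Survival stratification** (`lncnet.survival`) — cohort cleaning
   (drop expression = 0 and follow-up < 30 days), median split into
   high/low expression, Kaplan–Meier curves, Mantel–Haenszel log-rank
   χ² and the O/E hazard ratio (O_high/E_high)/(O_low/E_low), plus
   covariate subgroup analyses (ER+, HER2+, chemoresistant).
6. **Clinical statistics** (`lncnet.clinstats`) — Pearson χ² (no continuity
   correction) on 2×2 clinicopathological tables, rank-based ROC AUC,
   2^−ΔΔCq relative quantification, paired *t*-test.
7. **ceRNA network** (`lncnet.cerna`) — lncRNA–miRNA–mRNA triplets from
   scored interaction tables: correlation > 0.9, binding > 0.04,
   context++ ≤ −0.2, with the mRNA side restricted to the hub's
   coexpression partners.

`lncnet.simulate` generates every input with known ground truth (planted
fold changes, hub modules at an analytically controlled target correlation,
exponential survival cohorts with planted hazard ratios, gene sets and
interaction tables with planted enriched/passing subsets), and
`lncnet.datasets` bundles the published worked-example tables (the six-hub
edge list, the 20-patient 2×2 clinical tables, and the ceRNA candidate set).

## Worked example

```python
from lncnet import coexpression, datasets, cerna
from lncnet.clinstats import chi_square_2x2

net = coexpression.CoexpressionNetwork.from_edge_list(datasets.hub_edge_table())
deg = coexpression.degree_centrality(net)
hubs = coexpression.select_hubs(net, min_degree=6)
print("edges:", net.n_edges)
print("hubs :", ", ".join(f"{h} (deg {deg[h]})" for h in hubs))

res = chi_square_2x2(9, 3, 2, 6)          # ER status vs high/low expression
print(f"ER chi2 = {res.chi2:.3f}, p = {res.p:.3f}")

t1, t2 = datasets.cerna_example_tables()
_, summary = cerna.assemble_cerna(
    datasets.CERNA_HUB, t1, t2, hub_partners=net.partners_of(datasets.CERNA_HUB)
)
print("ceRNA:", summary)
```

prints

```
edges: 71
hubs : ENST00000422749 (deg 18), NONHSAT057283 (deg 18), ENST00000456355 (deg 14), ENST00000455354 (deg 8), NONHSAT097797 (deg 7), ENST00000594783 (deg 6)
ER chi2 = 4.848, p = 0.028
ceRNA: {'n_mirnas': 5, 'n_mrnas': 6, 'n_triplets': 9}
```

i.e. the published edge list contains 71 lncRNA–mRNA pairs; the degree ≥ 6
filter recovers exactly the six candidate lncRNAs with their printed degrees
(lnc-TRDMT1-5 = ENST00000456355 at degree 14); high expression of the top
hub associates with ER positivity (χ² = 4.848, p < 0.05); and the sponge
network around it has five miRNA and six mRNA nodes.

A thin CLI mirrors the library (`lncnet simulate-expression`,
`lncnet diffexp`, `lncnet coexpress`, `lncnet survival`, `lncnet chi2`,
`lncnet cerna`); for instance `lncnet chi2 9 3 2 6` prints
`chi2=4.848  df=1  p=0.02767`.

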