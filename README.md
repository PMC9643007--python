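# netpert

Individual-specific **gene interaction-perturbation** subtyping for bulk
expression cohorts.

Molecular subtypes are usually derived from snapshot expression profiles,
which drift with time, platform and condition. Gene-pair *rank relations*
inside a biological network are far more stable: in normal tissue the
relative ordering of two interacting genes' expression is strongly
conserved, while tumors perturb it broadly. `netpert` implements a
rank-based pipeline that exploits this: it turns a genes × samples
expression matrix and a background interaction network into an edge-level
perturbation matrix against a normal-tissue benchmark, discovers subtypes
by consensus clustering with PAC model selection, trains centroid and
reduced-panel classifiers so new cohorts can be assigned, and validates
subtype-specific signals with a sample-set enrichment statistic. It is
aimed at computational biologists studying tumor heterogeneity (the design
case is colorectal cancer) who want network-level, platform-robust
subtypes, and it ships a first-class synthetic-cohort generator with ground
truth for every stage.

## The model

For sample *s*, genes shared between the expression matrix and the network
are ranked within the sample (ascending, ties averaged), giving
*R<sub>g</sub>(s)*. For each network edge (a, b) in canonical orientation
the **delta rank** is

&nbsp;&nbsp;&nbsp;&nbsp;*d<sub>ab</sub>(s) = R<sub>a</sub>(s) − R<sub>b</sub>(s)*.

The **benchmark vector** *b<sub>ab</sub>* is the delta rank of the average
normal profile (gene-pair relations are conserved in normal tissue, so one
reference vector suffices; a rank-space average of the normals' delta ranks
is available as an alternative convention). The **interaction
perturbation** is

&nbsp;&nbsp;&nbsp;&nbsp;*p<sub>ab</sub>(s) = d<sub>ab</sub>(s) − b<sub>ab</sub>*,

an edges × samples matrix that is invariant under any strictly increasing
transform of each sample's expression. Downstream:

* **edge selection** — edges that separate tumor from normal (combined
  location + scale test, BH-adjusted) and stay variable within tumors;
* **subtyping** — consensus k-means over subsampled runs; the cluster
  number minimises the proportion of ambiguous clustering,
  PAC = CDF(u₂) − CDF(u₁) of the consensus entries; silhouette widths on
  1 − consensus define a representative core set;
* **classifiers** — a SAM screen, a nearest-shrunken-centroid (PAM) model
  with cross-validated shrinkage, a diagonal quadratic discriminant (DQDA)
  rule δ<sub>k</sub>(x) = −Σ<sub>i</sub>[(x<sub>i</sub>−μ<sub>ik</sub>)²/(2σ²<sub>ik</sub>) + ½log σ²<sub>ik</sub>] + log π<sub>k</sub>,
  and a correlation-to-centroid mode for cross-platform assignment; plus a
  reduced-panel chain (paired DE → bootstrap logistic → LASSO 1-SE →
  random forest) for qPCR-sized panels;
* **SSEA** — per-sample integrated pathway scores (mean over positively
  correlated genes minus mean over negatively correlated genes) feed a
  GSEA-style running sum over the *ranked sample list*, testing whether a
  subtype's samples concentrate at high ranks.

## Worked example

```python
from netpert import (
    SimConfig, simulate_cohort, build_perturbation, differential_edge_test,
    tumor_variability, select_representative_network, sweep_k, select_k,
    silhouette_core, degree_distribution_fit,
)

cohort = simulate_cohort(SimConfig(n_genes=500, edges_per_subtype=10, n_subtypes=4,
                                   n_tumors=120, n_normals=30, seed=0))
fit = degree_distribution_fit(cohort.net)
print(f"background network: {cohort.net.n_nodes} genes, "
      f"{cohort.net.n_edges} interactions, scale-free r = {fit.r:.3f}")

pert = build_perturbation(cohort.expr, cohort.phenotype, cohort.net)
stats = differential_edge_test(pert, cohort.phenotype)
var = tumor_variability(pert, cohort.phenotype)
sel = select_representative_network(stats, var, cohort.net)
print(f"representative network: {sel.n_genes} genes, {sel.n_edges} interactions")

X = pert.values.loc[sel.selected_edge_ids, cohort.tumor_samples].T
runs = sweep_k(X, range(2, 7), seed=0, n_reps=100)
for r in runs:
    print(f"  K={r.k}: PAC={r.pac:.3f}")
k = select_k(runs)
core = silhouette_core(next(r for r in runs if r.k == k))
print(f"selected K={k}; core set {core.core_count}/{len(cohort.tumor_samples)} samples")
```

prints

```
background network: 500 genes, 996 interactions, scale-free r = -0.925
representative network: 156 genes, 160 interactions
  K=2: PAC=0.519
  K=3: PAC=0.109
  K=4: PAC=0.000
  K=5: PAC=0.116
  K=6: PAC=0.212
selected K=4; core set 120/120 samples
```

The generator planted 4 subtypes; PAC is exactly 0 at K = 4 (every
subsampled k-means run co-clusters the same samples) and rises on either
side, so K = 4 is selected, and all 120 tumors sit in the silhouette-positive
core. The estimator-style interface
(`PerturbationTransformer`, `RepresentativeEdgeSelector`,
`ConsensusClustering`, `ShrunkenCentroidClassifier`, `DqdaClassifier`,
`MiniClassifierPipeline`) composes with scikit-learn; the functions above
are thin wrappers around it.

A CLI mirrors the pipeline stage by stage:

```bash
netpert simulate -o run1 --seed 1
netpert perturb  -o run1
netpert select   -o run1
netpert cluster  -o run1
netpert classify -o run1
netpert run config.yaml --stages simulate,perturb,select,cluster
```

Each stage writes plain-text artifacts plus a `manifest.json` with seeds,
input hashes and shape counts; identical config + seed reproduces identical
outputs.

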