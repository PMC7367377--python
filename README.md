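# ssnmark

Sample-specific network biomarkers for tumor expression cohorts.

Bulk co-expression networks describe a cohort; they say nothing about the
one patient in front of you. The sample-specific network (SSN) approach
turns a cohort-level correlation network into a per-sample object: add one
sample to a reference cohort of normal tissue, recompute every edge's
Pearson correlation, and keep the edges that one sample significantly
perturbs. `ssnmark` implements the full SSN biomarker pipeline for
tumor/normal studies — originally developed for colon adenocarcinoma
(COAD) cohorts of TCGA scale — together with a synthetic-cohort generator
so every stage is testable without any data download.

## The method

**Per-sample networks.** For background edge $(i,j)$ with Pearson
correlation $PCC_n$ over the $n$ reference (normal) samples, adding a
single query sample gives $PCC_{n+1}$ and

$$\Delta PCC = PCC_{n+1} - PCC_n, \qquad
  z = \frac{\Delta PCC}{(1 - PCC_n^2)/(n-1)},$$

with $z$ referred to a standard-normal null (two-sided). Edges with
$p < \alpha$ form the sample's SSN.

**Functional network.** Edges appearing in the SSN of *any* normal sample
are subtracted from every tumor SSN; an edge recurring in strictly more
than 90% of the tumor-specific SSNs joins the cancer *functional network*.
Its nodes are the functional genes; nodes of degree $> 3$ are the core
functional genes.

**Downstream biomarker analyses** on the functional genes/edges:

- *Enrichment*: upper-tail hypergeometric test
  $p = 1-\sum_{i=0}^{k-1}\binom{A}{i}\binom{N-A}{n-i}/\binom{N}{n}$
  of the $n$ functional genes against known cancer gene sets of size $A$
  in an $N$-gene universe, overall and for degree-ranked subsets.
- *Diagnosis*: Gaussian-kernel SVM tumor/normal classification with
  normal-cohort-sized tumor subgroups, stratified 5-fold CV, pooled
  ROC/AUC; hierarchical clustering on $1-$Pearson distance.
- *Subtyping*: Monti consensus clustering (resampled Ward clustering on
  $1-$Pearson distance), unique per-subtype top-100 up/down DEG signatures
  from one-vs-rest Welch $t$-tests, Fisher-exact subtype-feature
  association, multi-group log-rank survival comparison.
- *Prognosis*: every functional gene (expression) and edge (per-patient
  $\Delta PCC$) median-split and tested by Kaplan-Meier/log-rank plus
  univariate and confounder-adjusted multivariate Cox; markers with
  $p<0.05$ in both Cox models pass. LASSO-Cox with cross-validated
  deviance picks the most informative panel.

## Worked example

The `analysis/` scripts run the whole pipeline on a synthetic cohort
(200 genes, 40 normals, 100 tumors; 20 planted dysregulated edges carried
by 95% of tumors; 6 expression subtypes; survival driven by three planted
genes):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_build_functional_network.py
python analysis/06_prognostic_screen.py
```

prints (abridged):

```
background network: 147 edges (20 planted, carried by 95% of tumors)
functional network: 20 edges over 40 genes
planted-edge recovery 100%, 0 false edges
...
5 prognostic genes and 3 prognostic edges pass both Cox tests at p < 0.05
planted hazard genes recovered: ['g0013', 'g0025', 'g0032']
```

The functional network recovers exactly the 20 planted edges, and the
prognostic screen finds all three genes whose expression was wired into
the simulated hazard. Stages 03–05 and 07 add enrichment (the planted gene
set dominates at $p=4.9\times10^{-43}$), diagnostic classification
(pooled AUC 1.0 on the separable cohort), consensus subtyping (ARI 1.0
against the generating labels) and LASSO-Cox selection (all three hazard
genes selected, joint $p=4.3\times10^{-17}$).

A `ssnmark` command-line interface exposes the same stages for file-based
use (`ssnmark simulate`, `ssnmark build-ssn`, `ssnmark enrich`,
`ssnmark classify`, `ssnmark subtype`, `ssnmark survival-screen`).

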