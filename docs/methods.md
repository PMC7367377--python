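# Methods

## The SSN statistic

An SSN asks how much one added sample perturbs each edge of a reference
correlation network. For an edge with reference Pearson correlation
$PCC_n$ over $n$ reference samples and perturbed correlation $PCC_{n+1}$
after appending the query sample,

$$z = \frac{PCC_{n+1} - PCC_n}{(1 - PCC_n^2)/(n-1)},$$

referred to a two-sided standard-normal null. The denominator is the
scale of the perturbation a single extra observation can induce in a
correlation estimated from $n$ samples; the statistic is the canonical
form of the published SSN method and is isolated behind
`ssn_core.ssn_statistic` so an alternative null could be swapped in.

Two numerical caveats are measured rather than assumed:

- **Central calibration is good, deep tails are heavy.** Under the null
  (query drawn from the reference population, $n=40$) the empirical
  retention rate at nominal $\alpha=0.05$ is $\approx 0.068$, inside the
  $[0.03, 0.08]$ band the tests enforce. Deeper tails are anti-conservative:
  a nominal $10^{-3}$ cutoff really passes $\approx 5.7\times10^{-3}$ of
  null queries, and nominal $10^{-5}$ passes $\approx 7\times10^{-4}$. The
  influence of one Gaussian point on a correlation is a product-normal
  quantity, heavier-tailed than the Gaussian reference.
- **Degenerate edges.** Edges with a constant endpoint or $|PCC_n|=1$
  have an undefined statistic; they are excluded from testing and counted
  (`ReferenceNetwork.n_degenerate`).

Boundary conventions, all strict per the thresholds' "more than"
phrasing: the interaction-score filter keeps score $>$ threshold; the
expression filter removes genes whose zero fraction strictly exceeds 50%;
the functional network keeps edges with tumor-SSN frequency strictly
above the threshold (denominator: all tumor samples, empty SSNs
included); core genes have degree strictly above the threshold. Median
splits send ties to the low group. The default per-edge $\alpha$ is 0.05
with no multiple-testing correction; both are configurable, and the
prognostic screen exposes an optional Benjamini–Hochberg column without
using it in the pass rule.

## Why the functional-network stage needs a strict per-edge alpha

Tumor-specific SSNs are formed by deleting every edge that appears in the
SSN of *any* normal sample. With $m$ normal samples and per-edge
false-positive rate $r$, an edge survives that union with probability
$(1-r)^m$: at $\alpha=0.05$ and $m=40$ this is $0.95^{40}\approx 0.13$,
so the subtraction rule erases almost everything regardless of how
strongly tumors perturb an edge — an intrinsic property of the union
rule, not an implementation artifact. The planted-edge recovery
experiment therefore runs the pipeline at per-edge $\alpha=10^{-5}$
(measured true null rate $\approx 7\times10^{-4}$, giving
$(1-r)^{40}\approx 0.97$ survival), which is the strictness the
subtraction rule demands at this cohort size. The analysis drivers use
the same setting.

## The synthetic cohort generator

`synthetic_data` emulates the statistical structure the pipeline assumes,
not RNA-seq noise in detail.

**Reference model.** One latent factor per background edge: gene $g$ is a
loading-weighted sum of its incident edge factors plus unique noise, unit
variance, then shifted by +10 and clipped at zero to give nonnegative
expression units (the shift leaves every Pearson correlation untouched;
clipping is negligible at 10 SD). Target edge correlation is
$\rho_{\mathrm{ref}}$ (default 0.7). Exact $\rho$ on every edge of an
arbitrary graph is impossible — positive semidefiniteness caps $\rho$ at
$1/\lambda_{\max}$ of the adjacency — so loadings are attenuated on genes
with $\rho\cdot\mathrm{degree}>1$ and the target is exact elsewhere;
`on_infeasible="error"` raises instead. Planted edges are laid out as a
matching over reserved degree-1 genes, so they always carry exact
$\rho_{\mathrm{ref}}$; a consequence is that the default cohort's
functional network has maximum degree 1 and the degree-threshold
machinery is exercised by constructed fixtures rather than by the
flagship cohort. An optional `zero_fraction` zeroes entries to exercise
the expression filter.

**Tumor perturbation.** In a fraction $f$ (default 0.95) of tumors each
planted edge is rewired to correlation $\rho_{\mathrm{ref}}-\delta$
(default $\delta=1.4$, a sign flip) and its endpoints receive an
antagonistic mean shift ($+s$ SD on one gene, $-s$ SD on the other;
default $s=3$). The shift matters: a pre-freeze power analysis showed
pure decorrelation caps single-sample detection power near 0.8, because
a perturbed sample drawn near the origin cannot move a correlation;
coordinated up/down dysregulation of the two partners is both the
realistic tumor signature and what makes per-tumor detection power
$\approx 0.99$. $\delta=0$ disables the whole perturbation, shift
included, so tumors and normals are exchangeable. The recovery
experiments use the strong regime $s=4$.

**Subtypes.** Tumors are assigned uniformly to 6 subtypes; each subtype
gets 10 disjoint marker genes, half shifted $+3$ SD and half $-3$ SD
within the subtype (real subtypes carry both up- and down-regulated
signatures; one-directional markers would collide across one-vs-rest
tests and be erased by the uniqueness filter).

**Survival.** Exponential proportional hazards:
$\log h_i = \log h_0 + \sum_g \beta_g z_{g,i}$ over standardized hazard-gene
expression, baseline $h_0 = 10^{-3}$/day. Censoring is exponential with
its rate solved by bisection so the expected censored fraction matches
`censoring_rate` (default 0.5). Confounder columns are categorical draws
independent of survival; `confound_stage=True` instead couples pathologic
stage to both the hazard (log-HR 0.8 per stage step) and the first hazard
gene's expression tertile — the classic confounding triangle used to test
that multivariate adjustment removes a spurious univariate association.

**Gene sets and mutations.** Sets are built with controlled overlap
against the planted genes so the hypergeometric p-values are predictable
by enumeration; mutations are per-sample Bernoulli draws with
subtype-specific hotspot rates (default: 4 genes at rate 0.8 in one
subtype vs 0.05 elsewhere, a hypermutated-subtype pattern).

All generators are deterministic given `SimulationConfig.seed`, each
drawing from its own fixed stream so they may be called in any order.

## Downstream analysis choices

- **Classifier:** RBF-kernel SVM, `gamma="scale"`, unit cost, per-fold
  feature standardization; stratified folds (with 40-odd normals,
  unstratified folds could lose a class). The tumor-subgroup balancing
  uses round-robin assignment of a shuffled ordering, giving sizes within
  one of each other. Pooled AUC concatenates held-out decision scores
  across subgroups; per-subgroup AUCs are reported alongside since a
  single aggregation convention is not canonical.
- **Consensus clustering:** Monti resampling (80% sample subsets, Ward
  linkage on $1-$Pearson, default 1000 iterations; the desk-scale
  experiments use 200–500). Consensus = co-clustered / co-sampled;
  never-co-sampled pairs are NaN in the matrix and treated as
  no-evidence (distance 1) in the final average-linkage clustering of
  $1-$consensus. $k$ is a parameter, default 6; no automatic $k$
  selection.
- **DEG signatures:** Welch one-vs-rest $t$-tests (a pooled-variance flag
  exists); per-subtype top-$n$ up and down lists by ascending $p$, then
  genes picked by more than one subtype are dropped from all lists.
- **Survival:** log-rank and Cox fits via lifelines; Cox markers enter as
  the median-split high/low indicator by default (`binary=False` for the
  standardized continuous value). Multivariate models are complete-case,
  dummy-coded against each categorical confounder's modal level, numeric
  confounders standardized. The per-patient value of an edge marker is
  the signed $\Delta PCC$ from that patient's SSN, 0 when the edge is
  absent. LASSO-Cox uses the scikit-survival Coxnet path with 10-fold
  cross-validated held-out Breslow partial-likelihood deviance (computed
  directly; the library's own CV scorer is concordance-based) and an
  unpenalized lifelines refit of the selection for the joint
  likelihood-ratio p.

## Problem sizes

The test suite and acceptance script run on 200-gene cohorts with 40
normals and 100 tumors (300 for Cox recovery), ~150 background edges, 200
consensus iterations, and 100-replicate calibration loops — sizes chosen
so every property that matters (calibration bands, recovery rates,
parameter recovery) is measurable with comfortable margins while the
whole suite completes in about a minute.

## What passing tests do and do not show

The generator's Gaussian latent-factor structure means the pipeline is
validated under exactly the correlation model the SSN statistic assumes.
Passing tests demonstrate correctness of the machinery and its operating
characteristics under that model; they do not establish performance on
real RNA-seq data, where counts are overdispersed and library-size
dependent, correlations are not jointly Gaussian, "normal" tissue is
heterogeneous, and batch effects exist. Dataset-scale results from real
cohorts (thousand-gene functional networks, near-perfect diagnostic AUC,
specific subtype counts) require the original data and are not asserted
by this package's tests.

## Known limitations

- The z statistic's deep-tail anti-conservativeness (measured above) is
  inherited from the published statistic; a permutation-calibrated
  variant would be the principled fix and would slot in behind
  `ssn_statistic`.
- Normal samples' own SSNs are built with the full normal reference
  including the sample itself, matching the described procedure; a
  leave-one-out option exists (`build_all_ssns(..., leave_one_out=True)`)
  but is off by default.
- The exact-correlation constraint limits planted edges to a matching;
  hub-structured planted signal (and hence nontrivial core-gene sets in
  the flagship cohort) would require attenuated targets.
- No partial-correlation or mutual-information edge statistics; no
  batch correction; no competing-risks or time-dependent survival
  models.
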