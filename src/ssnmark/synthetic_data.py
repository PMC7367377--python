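"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a tumor/normal expression study over a known
interaction network:

* reference (normal) samples are drawn from a latent-factor Gaussian in
  which each background edge shares one latent factor, giving Pearson
  correlation ``rho_ref`` on network edges and ~0 off-network;
* tumor samples follow the reference model except on a planted subset of
  edges: in a fraction ``planted_frequency`` of tumors the edge's coupling
  is rewired to correlation ``rho_ref - delta`` and its endpoints receive
  an antagonistic mean shift (one up, one down) — the co-expression-breaking
  dysregulation the per-sample network stage is designed to detect;
* tumors carry a mean-shift subtype structure with subtype-specific genes;
* survival times follow an exponential proportional-hazards model driven by
  chosen hazard genes, with exponential censoring tuned to a target rate;
* gene sets with controlled overlap and subtype-biased mutation tables
  complete the inputs.

Everything is deterministic given ``SimulationConfig.seed``; each generator
draws from its own fixed random stream so generators can be called in any
order or in isolation.

Exact edge correlation on every edge of an arbitrary graph is impossible
(positive semidefiniteness caps rho at 1/lambda_max of the adjacency), so
loadings are attenuated on high-degree genes; the target is exact whenever
``rho_ref * degree <= 1``. Planted edges are laid out as a matching over
reserved genes so they always carry the exact target correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .io_formats import (
    NORMAL,
    TUMOR,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    ScoredEdgeList,
)

# fixed per-generator random streams
_STREAM_MODEL, _STREAM_REF, _STREAM_TUMOR, _STREAM_SURV, _STREAM_SETS, _STREAM_MUT = range(6)

_STAGES = ("stage i", "stage ii", "stage iii", "stage iv")
_RACES = ("white", "black or african american", "asian", "other")
_MS_LEVELS = ("mss", "msi-l", "msi-h")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the desk-scale cohort used throughout the test suite:
    200 genes, 40 normals, 100 tumors, edge correlation 0.7, 20 planted
    edges rewired by a sign flip (delta 1.4) with a +/-3 SD antagonistic
    endpoint shift in 95% of tumors, 6 mean-shift subtypes at 3 SD, and
    3 hazard genes at |log HR| ~ 1.
    """

    n_genes: int = 200
    n_normal: int = 40
    n_tumor: int = 100
    background_density: float = 0.01
    background_edges: list[tuple[int, int]] | None = None  # explicit, by gene index
    rho_ref: float = 0.7
    n_planted_edges: int = 20
    delta: float = 1.4  # target correlation change on planted edges
    perturb_shift: float = 3.0  # antagonistic endpoint mean shift, SD units
    planted_frequency: float = 0.95
    n_subtypes: int = 6
    subtype_effect: float = 3.0  # mean shift of subtype genes, SD units
    n_subtype_genes: int = 10  # per subtype
    hazard_genes: dict[str, float] = field(
        default_factory=lambda: {"g0001": 1.0, "g0003": -1.0, "g0005": 0.7}
    )
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_rate: float = 0.5
    confound_stage: bool = False  # couple stage to hazard and to the first hazard gene
    expression_offset: float = 10.0  # shift applied so values are nonnegative
    zero_fraction: float = 0.0  # entries zeroed to exercise the expression filter
    edge_score: int = 700  # score attached to exported background edges
    on_infeasible: str = "attenuate"  # or "error"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.planted_frequency <= 1:
            raise ValidationError("planted_frequency must be in (0, 1]")
        if self.n_normal < 3:
            raise ValidationError("need at least 3 normal samples")
        if not -1 < self.rho_ref < 1:
            raise ValidationError("rho_ref must be in (-1, 1)")
        if not 0 <= self.zero_fraction < 1:
            raise ValidationError("zero_fraction must be in [0, 1)")
        if not 0 <= self.censoring_rate <= 1:
            raise ValidationError("censoring_rate must be in [0, 1]")
        if self.on_infeasible not in ("attenuate", "error"):
            raise ValidationError("on_infeasible must be 'attenuate' or 'error'")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % 2**31, stream])

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]


@dataclass
class ReferenceModel:
    """Latent-factor model shared by normal and tumor generation."""

    gene_ids: list[str]
    edges: list[tuple[int, int]]  # all background edges (gene indices)
    planted: list[tuple[int, int]]  # subset laid out as a matching
    loadings: np.ndarray  # (E, 2) factor loading of each endpoint
    noise_sd: np.ndarray  # (G,) unique-noise SD, chosen so Var(x_g) = 1

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        g = self.gene_ids
        return {tuple(sorted((g[i], g[j]))) for i, j in self.planted}

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n samples (columns) from the reference distribution, genes x n."""
        G, E = len(self.gene_ids), len(self.edges)
        x = self.noise_sd[:, None] * rng.standard_normal((G, n))
        factors = rng.standard_normal((E, n))
        for e, (i, j) in enumerate(self.edges):
            x[i] += self.loadings[e, 0] * factors[e]
            x[j] += self.loadings[e, 1] * factors[e]
        return x


def make_reference_model(config: SimulationConfig) -> ReferenceModel:
    """Lay out the background graph and solve the factor loadings.

    Planted edges form a matching over reserved genes (endpoints touch no
    other edge), so their correlation is exactly ``rho_ref``; remaining
    background edges are sampled uniformly among the other genes at
    ``background_density``. Loadings on genes with ``rho_ref * degree > 1``
    are attenuated to keep unit variance (or an error is raised when
    ``on_infeasible="error"``).
    """
    rng = config.rng(_STREAM_MODEL)
    G = config.n_genes
    if config.background_edges is not None:
        edges = [tuple(sorted(e)) for e in config.background_edges]
        planted = edges[: config.n_planted_edges]
    else:
        n_planted = config.n_planted_edges
        if 2 * n_planted > G:
            raise GenerationError("not enough genes to reserve planted-edge endpoints")
        perm = rng.permutation(G)
        reserved = perm[: 2 * n_planted]
        planted = [tuple(sorted((reserved[2 * t], reserved[2 * t + 1]))) for t in range(n_planted)]
        rest = np.sort(perm[2 * n_planted:])
        n_rest = len(rest)
        n_bg = int(round(config.background_density * n_rest * (n_rest - 1) / 2))
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n_bg:
            i, j = rng.integers(0, n_rest, size=2)
            if i != j:
                a, b = rest[min(i, j)], rest[max(i, j)]
                chosen.add((int(a), int(b)))
        edges = planted + sorted(chosen)
    planted = [tuple(map(int, e)) for e in planted]
    edges = [tuple(map(int, e)) for e in edges]

    degree = np.zeros(G)
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1
    rho = abs(config.rho_ref)
    infeasible = degree * rho > 1 + 1e-12
    if infeasible.any() and config.on_infeasible == "error":
        worst = int(np.argmax(degree))
        raise GenerationError(
            f"correlation {config.rho_ref} infeasible: gene index {worst} has degree "
            f"{int(degree[worst])} (> 1/rho = {1 / rho:.2f}); lower the density or rho_ref"
        )
    with np.errstate(divide="ignore"):
        scale = np.minimum(1.0, 1.0 / np.sqrt(np.where(degree > 0, rho * degree, 1.0)))
    sign = math.copysign(1.0, config.rho_ref)
    loadings = np.zeros((len(edges), 2))
    for e, (i, j) in enumerate(edges):
        loadings[e, 0] = math.sqrt(rho) * scale[i]
        loadings[e, 1] = sign * math.sqrt(rho) * scale[j]
    var_factor = np.zeros(G)
    for e, (i, j) in enumerate(edges):
        var_factor[i] += loadings[e, 0] ** 2
        var_factor[j] += loadings[e, 1] ** 2
    noise_sd = np.sqrt(np.clip(1.0 - var_factor, 0.0, None))
    return ReferenceModel(
        gene_ids=config.gene_ids, edges=edges, planted=planted,
        loadings=loadings, noise_sd=noise_sd,
    )


def _finalize_expression(config: SimulationConfig, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shift latent values to nonnegative expression units; optionally zero
    a random fraction of entries (dropout-style) to exercise the filter."""
    values = np.clip(x + config.expression_offset, 0.0, None)
    if config.zero_fraction > 0:
        mask = rng.random(values.shape) < config.zero_fraction
        values = np.where(mask, 0.0, values)
    return values


def generate_reference_expression(
    config: SimulationConfig, model: ReferenceModel | None = None
) -> ExpressionMatrix:
    """Normal-sample expression matrix drawn from the reference model."""
    if model is None:
        model = make_reference_model(config)
    rng = config.rng(_STREAM_REF)
    x = model.draw(config.n_normal, rng)
    values = _finalize_expression(config, x, rng)
    ids = [f"N{i:03d}" for i in range(config.n_normal)]
    df = pd.DataFrame(values, index=model.gene_ids, columns=ids)
    return ExpressionMatrix(df, pd.Series(NORMAL, index=ids))


@dataclass
class TumorTruth:
    """Ground truth attached to a generated tumor cohort."""

    subtype: pd.Series  # sample -> subtype label "c1".."cK"
    subtype_genes: dict[str, list[str]]
    carriers: dict[tuple[str, str], set[str]]  # planted edge -> carrier samples
    subtype_genes_up: dict[str, list[str]] = None
    subtype_genes_down: dict[str, list[str]] = None


def generate_tumor_samples(
    config: SimulationConfig, model: ReferenceModel
) -> tuple[ExpressionMatrix, TumorTruth]:
    """Tumor cohort: reference model plus planted-edge perturbation and
    subtype mean shifts.

    ``delta`` is the master perturbation switch — with ``delta == 0`` no
    edge is rewired and no endpoint shift is applied, so tumor and normal
    samples are exchangeable (up to the subtype structure, which is also
    disabled when ``subtype_effect == 0``).
    """
    rng = config.rng(_STREAM_TUMOR)
    n = config.n_tumor
    ids = [f"T{i:03d}" for i in range(n)]
    x = model.draw(n, rng)

    # subtype structure: equal-probability assignment, disjoint marker genes;
    # half of each subtype's markers shift up, half down (real subtypes carry
    # both up- and down-regulated signature genes)
    labels = np.array([f"c{k + 1}" for k in rng.integers(0, config.n_subtypes, size=n)])
    planted_idx = {i for e in model.planted for i in e}
    pool = [i for i in range(config.n_genes) if i not in planted_idx]
    rng.shuffle(pool)
    subtype_genes: dict[str, list[str]] = {}
    subtype_genes_up: dict[str, list[str]] = {}
    subtype_genes_down: dict[str, list[str]] = {}
    cursor = 0
    for k in range(config.n_subtypes):
        take = pool[cursor: cursor + config.n_subtype_genes]
        cursor += config.n_subtype_genes
        name = f"c{k + 1}"
        half = len(take) // 2
        subtype_genes[name] = [model.gene_ids[i] for i in take]
        subtype_genes_up[name] = [model.gene_ids[i] for i in take[:half]]
        subtype_genes_down[name] = [model.gene_ids[i] for i in take[half:]]
        if config.subtype_effect != 0:
            members = labels == name
            for gi in take[:half]:
                x[gi, members] += config.subtype_effect
            for gi in take[half:]:
                x[gi, members] -= config.subtype_effect

    # planted-edge perturbation in a fraction of tumors
    carriers: dict[tuple[str, str], set[str]] = {}
    if config.delta != 0 and model.planted:
        n_carry = int(round(config.planted_frequency * n))
        if n_carry < 1:
            import warnings

            warnings.warn("planted_frequency * n_tumor < 1: no tumor carries the perturbation")
        rho_pert = float(np.clip(config.rho_ref - config.delta, -1.0, 1.0))
        a = math.sqrt(abs(rho_pert))
        s = math.copysign(1.0, rho_pert) if rho_pert != 0 else 0.0
        b = math.sqrt(1.0 - abs(rho_pert))
        for i, j in model.planted:
            carry = rng.choice(n, size=n_carry, replace=False)
            pair = tuple(sorted((model.gene_ids[i], model.gene_ids[j])))
            carriers[pair] = {ids[c] for c in carry}
            h = rng.standard_normal(n_carry)
            x[i, carry] = a * h + b * rng.standard_normal(n_carry) + config.perturb_shift
            x[j, carry] = s * a * h + b * rng.standard_normal(n_carry) - config.perturb_shift
    else:
        for i, j in model.planted:
            pair = tuple(sorted((model.gene_ids[i], model.gene_ids[j])))
            carriers[pair] = set()

    values = _finalize_expression(config, x, rng)
    df = pd.DataFrame(values, index=model.gene_ids, columns=ids)
    expr = ExpressionMatrix(df, pd.Series(TUMOR, index=ids))
    truth = TumorTruth(
        subtype=pd.Series(labels, index=ids), subtype_genes=subtype_genes, carriers=carriers,
        subtype_genes_up=subtype_genes_up, subtype_genes_down=subtype_genes_down,
    )
    return expr, truth


def _solve_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate mu with mean P(C < T) = target, where
    T_i ~ Exp(hazards_i): P(censored | i) = mu / (hazards_i + mu)."""
    if target <= 0:
        return 0.0
    lo, hi = 1e-12, float(hazards.max()) * 1e6
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if np.mean(mid / (hazards + mid)) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def generate_survival(config: SimulationConfig, tumor_expr: ExpressionMatrix) -> ClinicalTable:
    """Clinical table with exponential proportional-hazards survival.

    log hazard = log(baseline) + sum_g beta_g * z_g where z_g is the
    standardized expression of hazard gene g across tumors. Censoring is
    exponential with rate solved so the expected censored fraction matches
    ``censoring_rate``. Confounder columns are categorical draws independent
    of survival unless ``confound_stage`` couples pathologic stage both to
    the hazard and to the first hazard gene's expression ranking.
    """
    rng = config.rng(_STREAM_SURV)
    missing = [g for g in config.hazard_genes if g not in tumor_expr.values.index]
    if missing:
        raise ValidationError(f"hazard genes absent from tumor expression: {missing}")
    if all(b == 0 for b in config.hazard_genes.values()) and config.censoring_rate >= 1:
        raise GenerationError("all beta = 0 with censoring_rate = 1 yields no usable events")

    ids = tumor_expr.sample_ids
    n = len(ids)
    lp = np.zeros(n)
    for g, beta in config.hazard_genes.items():
        v = tumor_expr.values.loc[g].to_numpy(dtype=float)
        sd = v.std()
        if sd > 0:
            lp += beta * (v - v.mean()) / sd

    stage = rng.choice(_STAGES, size=n, p=(0.2, 0.35, 0.3, 0.15))
    if config.confound_stage and config.hazard_genes:
        # stage follows the first hazard gene's expression tertile and
        # contributes its own hazard — the classic confounding triangle
        first = next(iter(config.hazard_genes))
        v = tumor_expr.values.loc[first].to_numpy(dtype=float)
        tert = np.searchsorted(np.quantile(v, [1 / 3, 2 / 3]), v)
        stage = np.array(_STAGES)[np.minimum(tert + 1, 3)]
        stage_code = {s: i for i, s in enumerate(_STAGES)}
        lp = lp + 0.8 * np.array([stage_code[s] for s in stage])

    hazards = config.baseline_hazard * np.exp(lp)
    times = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        mu = _solve_censoring_rate(hazards, config.censoring_rate)
        ctimes = rng.exponential(1.0 / mu, size=n)
        event = (times <= ctimes).astype(int)
        obs = np.minimum(times, ctimes)
    else:
        event = np.ones(n, dtype=int)
        obs = times

    df = pd.DataFrame(
        {
            "survival_time": np.round(obs, 1),
            "event": event,
            "sex": rng.choice(["female", "male"], size=n),
            "pathologic_stage": stage,
            "retrospective_indicator": rng.choice(["yes", "no"], size=n, p=(0.7, 0.3)),
            "race": rng.choice(_RACES, size=n, p=(0.7, 0.15, 0.1, 0.05)),
            "year_of_diagnosis": rng.integers(1998, 2014, size=n),
            "age_at_diagnosis": np.round(np.clip(rng.normal(68, 10, size=n), 30, 95)),
            "microsatellite_status": rng.choice(_MS_LEVELS, size=n, p=(0.7, 0.15, 0.15)),
        },
        index=pd.Index(ids, name="patient_id"),
    )
    return ClinicalTable(df)


def generate_gene_sets(
    config: SimulationConfig,
    planted_genes: list[str],
    set_sizes: tuple[int, ...] = (40, 25, 25, 25, 25),
    overlaps: tuple[int, ...] | None = None,
) -> GeneSetCollection:
    """Gene sets with controlled overlap against the planted genes.

    The first set is the planted genes padded to its requested size; the
    rest draw ``overlaps[i]`` genes from the planted set and the remainder
    from outside it. Universe is the simulated gene panel.
    """
    rng = config.rng(_STREAM_SETS)
    universe = config.gene_ids
    planted = [g for g in planted_genes if g in set(universe)]
    if len(planted) != len(planted_genes):
        raise ValidationError("planted_genes must lie inside the simulated gene universe")
    others = [g for g in universe if g not in set(planted)]
    if overlaps is None:
        overlaps = (min(len(planted), set_sizes[0]),) + tuple(
            max(1, len(planted) // (i + 2)) for i in range(len(set_sizes) - 1)
        )
    sets: dict[str, set[str]] = {}
    for idx, (size, k) in enumerate(zip(set_sizes, overlaps)):
        if k > size:
            raise ValidationError(f"requested overlap {k} exceeds set size {size}")
        if k > len(planted) or size - k > len(others):
            raise ValidationError("not enough genes to build the requested set")
        members = set(rng.choice(planted, size=k, replace=False)) | set(
            rng.choice(others, size=size - k, replace=False)
        )
        sets[f"set_{idx}" if idx else "planted_set"] = members
    return GeneSetCollection(sets, universe_size=len(universe))


def generate_mutations(
    config: SimulationConfig,
    subtypes: pd.Series,
    hotspot_genes: dict[str, str] | None = None,
    base_rate: float = 0.05,
    hotspot_rate: float = 0.8,
    n_mut_genes: int = 12,
) -> MutationTable:
    """Bernoulli per-sample mutation table with subtype-specific hotspots.

    ``hotspot_genes`` maps gene id -> subtype label with elevated rate
    (default: the last ``4`` simulated genes hotspotted in subtype c3,
    emulating a hypermutated subtype).
    """
    if not 0 <= base_rate <= 1 or not 0 <= hotspot_rate <= 1:
        raise ValidationError("mutation rates must lie in [0, 1]")
    rng = config.rng(_STREAM_MUT)
    genes = config.gene_ids[-n_mut_genes:]
    if hotspot_genes is None:
        hotspot_genes = {g: "c3" for g in genes[-4:]}
    rows = []
    for g in genes:
        for sid, sub in subtypes.items():
            rate = hotspot_rate if hotspot_genes.get(g) == sub else base_rate
            if rate > 0 and rng.random() < rate:
                rows.append((g, sid, "Missense_Mutation", "SNP"))
    df = pd.DataFrame(
        rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification", "Variant_Type"]
    )
    return MutationTable(df)


@dataclass
class SimulatedDataset:
    """Everything one pipeline run needs, plus the generating truth."""

    config: SimulationConfig
    model: ReferenceModel
    expression: ExpressionMatrix  # normals + tumors combined
    truth: TumorTruth
    clinical: ClinicalTable
    gene_sets: GeneSetCollection
    mutations: MutationTable

    @property
    def edge_list(self) -> ScoredEdgeList:
        g = self.model.gene_ids
        return ScoredEdgeList(
            {tuple(sorted((g[i], g[j]))): self.config.edge_score for i, j in self.model.edges}
        )

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        return self.model.planted_pairs


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete cohort (expression, clinical, sets, mutations)."""
    model = make_reference_model(config)
    normals = generate_reference_expression(config, model)
    tumors, truth = generate_tumor_samples(config, model)
    combined = ExpressionMatrix(
        pd.concat([normals.values, tumors.values], axis=1),
        pd.concat([normals.sample_class, tumors.sample_class]),
    )
    clinical = generate_survival(config, tumors)
    planted_genes = sorted({g for pair in model.planted_pairs for g in pair})
    gene_sets = generate_gene_sets(config, planted_genes)
    mutations = generate_mutations(config, truth.subtype)
    return SimulatedDataset(
        config=config, model=model, expression=combined, truth=truth,
        clinical=clinical, gene_sets=gene_sets, mutations=mutations,
    )
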