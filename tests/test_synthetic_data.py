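import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssnmark import GenerationError, SimulationConfig, ValidationError, simulate_dataset
from ssnmark.survival_biomarkers import cox_univariate, logrank_test, median_split
from ssnmark.synthetic_data import (
    generate_gene_sets,
    generate_mutations,
    generate_reference_expression,
    generate_survival,
    generate_tumor_samples,
    make_reference_model,
)
from ssnmark.enrichment import enrich_collection


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a = simulate_dataset(SimulationConfig(seed=7))
        b = simulate_dataset(SimulationConfig(seed=7))
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(a.clinical.data, b.clinical.data)
        pd.testing.assert_frame_equal(a.mutations.data, b.mutations.data)
        assert a.gene_sets.sets == b.gene_sets.sets
        assert a.planted_pairs == b.planted_pairs

    def test_different_seed_differs(self):
        a = simulate_dataset(SimulationConfig(seed=7))
        b = simulate_dataset(SimulationConfig(seed=8))
        assert not a.expression.values.equals(b.expression.values)


class TestReferenceExpression:
    def test_planted_edges_hit_target_correlation(self):
        cfg = SimulationConfig(seed=3, n_normal=200, rho_ref=0.7)
        model = make_reference_model(cfg)
        expr = generate_reference_expression(cfg, model)
        hits = 0
        for a, b in model.planted_pairs:
            r = np.corrcoef(expr.values.loc[a], expr.values.loc[b])[0, 1]
            hits += abs(r - 0.7) <= 0.1
        assert hits / len(model.planted_pairs) >= 0.95

    def test_zero_correlation_matches_fisher_null_spread(self):
        # with rho_ref = 0, atanh(pcc) on edges is ~N(0, 1/sqrt(n-3))
        cfg = SimulationConfig(seed=3, n_normal=200, rho_ref=0.0)
        model = make_reference_model(cfg)
        expr = generate_reference_expression(cfg, model)
        zs = []
        for i, j in model.edges:
            r = np.corrcoef(expr.values.iloc[i], expr.values.iloc[j])[0, 1]
            zs.append(np.arctanh(r) * np.sqrt(cfg.n_normal - 3))
        assert abs(np.mean(zs)) < 0.3
        assert 0.7 < np.std(zs) < 1.3

    def test_off_network_pairs_uncorrelated(self):
        cfg = SimulationConfig(seed=3, n_normal=200)
        model = make_reference_model(cfg)
        expr = generate_reference_expression(cfg, model)
        edge_set = {tuple(sorted(e)) for e in model.edges}
        rng = np.random.default_rng(0)
        rs = []
        while len(rs) < 50:
            i, j = rng.integers(0, cfg.n_genes, 2)
            if i != j and tuple(sorted((int(i), int(j)))) not in edge_set:
                rs.append(np.corrcoef(expr.values.iloc[i], expr.values.iloc[j])[0, 1])
        assert np.quantile(np.abs(rs), 0.95) < 0.25

    def test_infeasible_structure_raises_with_error_policy(self):
        cfg = SimulationConfig(seed=0, n_genes=30, background_density=0.5,
                               n_planted_edges=2, rho_ref=0.7, on_infeasible="error")
        with pytest.raises(GenerationError, match="infeasible"):
            make_reference_model(cfg)

    def test_values_nonnegative_and_zero_fraction(self):
        cfg = SimulationConfig(seed=4, zero_fraction=0.3)
        expr = generate_reference_expression(cfg)
        v = expr.values.to_numpy()
        assert (v >= 0).all()
        assert 0.25 < (v == 0).mean() < 0.35


class TestTumorSamples:
    def test_delta_zero_tumors_exchangeable_with_normals(self):
        cfg = SimulationConfig(seed=5, delta=0.0, subtype_effect=0.0,
                               n_normal=60, n_tumor=60)
        model = make_reference_model(cfg)
        normals = generate_reference_expression(cfg, model)
        tumors, _ = generate_tumor_samples(cfg, model)
        _, p = stats.ttest_ind(tumors.values.to_numpy(), normals.values.to_numpy(),
                               axis=1, equal_var=False)
        assert (p >= 0.01).mean() >= 0.95

    def test_full_frequency_marks_every_tumor_a_carrier(self):
        cfg = SimulationConfig(seed=5, planted_frequency=1.0)
        model = make_reference_model(cfg)
        tumors, truth = generate_tumor_samples(cfg, model)
        for carriers in truth.carriers.values():
            assert carriers == set(tumors.sample_ids)

    def test_carriers_decorrelate_planted_edges(self):
        cfg = SimulationConfig(seed=5, planted_frequency=1.0, n_tumor=200)
        model = make_reference_model(cfg)
        tumors, _ = generate_tumor_samples(cfg, model)
        # rho_ref - delta = 0.7 - 1.4 = -0.7 on every planted edge
        rs = [np.corrcoef(tumors.values.loc[a], tumors.values.loc[b])[0, 1]
              for a, b in model.planted_pairs]
        assert np.mean(rs) < -0.5

    def test_subtype_genes_shift_both_directions(self):
        cfg = SimulationConfig(seed=5)
        model = make_reference_model(cfg)
        tumors, truth = generate_tumor_samples(cfg, model)
        sub = truth.subtype
        for name in ("c1", "c4"):
            members = sub.index[sub == name]
            rest = sub.index[sub != name]
            for g in truth.subtype_genes_up[name]:
                assert tumors.values.loc[g, members].mean() > tumors.values.loc[g, rest].mean() + 1
            for g in truth.subtype_genes_down[name]:
                assert tumors.values.loc[g, members].mean() < tumors.values.loc[g, rest].mean() - 1


class TestSurvival:
    def test_no_censoring_means_all_events(self):
        cfg = SimulationConfig(seed=6, censoring_rate=0.0)
        model = make_reference_model(cfg)
        tumors, _ = generate_tumor_samples(cfg, model)
        clin = generate_survival(cfg, tumors)
        assert (clin.data["event"] == 1).all()

    def test_censoring_rate_approximately_hit(self):
        cfg = SimulationConfig(seed=6, censoring_rate=0.5, n_tumor=400)
        model = make_reference_model(cfg)
        tumors, _ = generate_tumor_samples(cfg, model)
        clin = generate_survival(cfg, tumors)
        assert 0.4 < (clin.data["event"] == 0).mean() < 0.6

    def test_positive_beta_gives_hazard_ratio_above_one(self):
        cfg = SimulationConfig(seed=6, n_tumor=300, hazard_genes={"g0010": 1.0})
        model = make_reference_model(cfg)
        tumors, _ = generate_tumor_samples(cfg, model)
        clin = generate_survival(cfg, tumors)
        res = cox_univariate(tumors.values.loc["g0010"], clin)
        assert res.hr > 1 and res.p < 0.01

    def test_null_beta_logrank_type_one_error_calibrated(self):
        # markers without effect should reject at roughly the nominal rate
        rejections = 0
        n_reps = 100
        for rep in range(n_reps):
            cfg = SimulationConfig(seed=1000 + rep, n_tumor=60, n_genes=30,
                                   n_planted_edges=5, n_subtypes=2,
                                   hazard_genes={}, censoring_rate=0.3)
            model = make_reference_model(cfg)
            tumors, _ = generate_tumor_samples(cfg, model)
            clin = generate_survival(cfg, tumors)
            split = median_split(tumors.values.loc["g0000"], "g0000")
            _, p = logrank_test(clin.data["survival_time"], clin.data["event"],
                                split.groups)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_reps <= 0.12

    def test_degenerate_config_rejected(self):
        cfg = SimulationConfig(seed=6, hazard_genes={"g0001": 0.0}, censoring_rate=1.0)
        model = make_reference_model(cfg)
        tumors, _ = generate_tumor_samples(cfg, model)
        with pytest.raises(GenerationError):
            generate_survival(cfg, tumors)


class TestGeneSets:
    def test_planted_set_has_minimal_enrichment_p(self):
        cfg = SimulationConfig(seed=8)
        model = make_reference_model(cfg)
        planted_genes = sorted({g for pair in model.planted_pairs for g in pair})
        coll = generate_gene_sets(cfg, planted_genes)
        results = {r.set_name: r for r in enrich_collection(set(planted_genes), coll)}
        best = min(results.values(), key=lambda r: r.p_value)
        assert best.set_name == "planted_set"
        assert results["planted_set"].p_value < 1e-10

    def test_zero_overlap_yields_p_one(self):
        cfg = SimulationConfig(seed=8)
        coll = generate_gene_sets(cfg, ["g0000", "g0001"],
                                  set_sizes=(5,), overlaps=(0,))
        res = enrich_collection({"g0000", "g0001"}, coll)
        assert res[0].p_value == 1.0

    def test_requested_overlap_exceeding_size_rejected(self):
        cfg = SimulationConfig(seed=8)
        with pytest.raises(ValidationError, match="overlap"):
            generate_gene_sets(cfg, ["g0000"], set_sizes=(3,), overlaps=(5,))


class TestMutations:
    def test_hotspot_rate_dominates_in_target_subtype(self):
        cfg = SimulationConfig(seed=9, n_tumor=200)
        model = make_reference_model(cfg)
        _, truth = generate_tumor_samples(cfg, model)
        mut = generate_mutations(cfg, truth.subtype)
        hot = cfg.gene_ids[-1]  # hotspotted in c3 by default
        carriers = set(mut.data.loc[mut.data["Hugo_Symbol"] == hot, "Tumor_Sample_Barcode"])
        in_c3 = truth.subtype.index[truth.subtype == "c3"]
        out_c3 = truth.subtype.index[truth.subtype != "c3"]
        rate_in = np.mean([s in carriers for s in in_c3])
        rate_out = np.mean([s in carriers for s in out_c3])
        assert rate_in > 0.6 and rate_out < 0.2

    def test_zero_rates_give_empty_table(self):
        cfg = SimulationConfig(seed=9)
        model = make_reference_model(cfg)
        _, truth = generate_tumor_samples(cfg, model)
        mut = generate_mutations(cfg, truth.subtype, base_rate=0.0, hotspot_rate=0.0)
        assert len(mut) == 0

    def test_invalid_rate_rejected(self):
        cfg = SimulationConfig(seed=9)
        model = make_reference_model(cfg)
        _, truth = generate_tumor_samples(cfg, model)
        with pytest.raises(ValidationError):
            generate_mutations(cfg, truth.subtype, base_rate=1.5)


@pytest.mark.parametrize("field, value", [
    ("planted_frequency", 0.0),
    ("n_normal", 2),
    ("rho_ref", 1.0),
    ("zero_fraction", 1.0),
    ("censoring_rate", 1.5),
    ("on_infeasible", "ignore"),
])
def test_invalid_config_rejected(field, value):
    with pytest.raises(ValidationError):
        SimulationConfig(**{field: value})
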