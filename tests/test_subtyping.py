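import numpy as np
import pandas as pd
import pytest
from math import comb
from sklearn.metrics import adjusted_rand_score

from ssnmark import AnalysisError, ValidationError
from ssnmark.io_formats import ClinicalTable, ExpressionMatrix, MutationTable
from ssnmark.io_formats import CLINICAL_COLUMNS
from ssnmark.subtyping import (
    consensus_cluster,
    representative_degs,
    subtype_feature_association,
    subtype_proportions,
    subtype_survival,
)
from ssnmark.survival_biomarkers import logrank_test


def _blob_expr(sizes, sep=6.0, n_genes=12, seed=0):
    # each blob gets its own per-gene center pattern: correlation distance is
    # invariant to a constant offset, so a shared shift would be invisible
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for b, size in enumerate(sizes):
        center = rng.normal(0, sep, n_genes)
        blocks.append(center[:, None] + rng.normal(0, 1, (n_genes, size)))
        labels += [b] * size
    ids = [f"s{i}" for i in range(sum(sizes))]
    df = pd.DataFrame(np.hstack(blocks) + 20, columns=ids,
                      index=[f"g{i}" for i in range(n_genes)])
    return ExpressionMatrix(df, pd.Series("tumor", index=ids)), pd.Series(labels, index=ids)


def _clinical(ids, times, events, ms=None):
    n = len(ids)
    df = pd.DataFrame({
        "survival_time": times, "event": events,
        "sex": ["male"] * n, "pathologic_stage": ["stage ii"] * n,
        "retrospective_indicator": ["yes"] * n, "race": ["white"] * n,
        "year_of_diagnosis": [2005] * n, "age_at_diagnosis": [65] * n,
        "microsatellite_status": ms if ms is not None else ["mss"] * n,
    }, index=pd.Index(ids, name="patient_id"))
    return ClinicalTable(df)


class TestConsensusClustering:
    def test_two_blobs_give_block_consensus(self):
        expr, truth = _blob_expr([10, 10])
        res = consensus_cluster(expr, k=2, iterations=60, seed=0)
        assert adjusted_rand_score(truth, res.assignments) == 1.0
        same = truth.to_numpy()[:, None] == truth.to_numpy()[None, :]
        cons = res.consensus.to_numpy()
        assert np.nanmin(cons[same]) > 0.95
        assert np.nanmax(cons[~same]) < 0.05

    def test_deterministic_under_seed(self):
        expr, _ = _blob_expr([8, 8, 8], sep=3.0)
        a = consensus_cluster(expr, k=3, iterations=40, seed=5)
        b = consensus_cluster(expr, k=3, iterations=40, seed=5)
        pd.testing.assert_frame_equal(a.consensus, b.consensus)
        assert (a.assignments == b.assignments).all()

    def test_consensus_matches_bruteforce_tally_of_iteration_log(self):
        expr, _ = _blob_expr([7, 7], sep=2.0)
        res = consensus_cluster(expr, k=2, iterations=30, seed=1, keep_log=True)
        m = len(expr.sample_ids)
        together = np.zeros((m, m))
        sampled = np.zeros((m, m))
        for idx, labels in res.iteration_log:
            for a_pos, a in enumerate(idx):
                for b_pos, b in enumerate(idx):
                    sampled[a, b] += 1
                    together[a, b] += labels[a_pos] == labels[b_pos]
        expected = np.where(sampled > 0, together / np.maximum(sampled, 1), np.nan)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(res.consensus.to_numpy(), expected, atol=1e-12)

    def test_consensus_matrix_invariants(self):
        expr, _ = _blob_expr([6, 6, 6], sep=1.0)
        res = consensus_cluster(expr, k=3, iterations=50, seed=2)
        cons = res.consensus.to_numpy()
        np.testing.assert_allclose(cons, cons.T, atol=1e-12)
        assert np.nanmin(cons) >= 0 and np.nanmax(cons) <= 1

    def test_subsample_smaller_than_k_rejected(self):
        expr, _ = _blob_expr([3, 3])
        with pytest.raises(ValidationError):
            consensus_cluster(expr, k=5, iterations=5, subsample_fraction=0.5)


class TestRepresentativeDegs:
    @staticmethod
    def _three_subtype_markers(seed=4):
        # each subtype has its own strong up and down marker gene, as in real
        # subtype structure; remaining genes carry no signal
        expr, truth = _blob_expr([10, 10, 10], sep=0.0, seed=seed)
        values = expr.values.copy()
        for s, (up_g, down_g) in enumerate([("g0", "g1"), ("g2", "g3"), ("g4", "g5")]):
            members = truth.index[truth == s]
            values.loc[up_g, members] += 5.0
            values.loc[down_g, members] -= 5.0
        return ExpressionMatrix(values, expr.sample_class), truth

    def test_dominant_shifted_gene_ranks_first(self):
        expr, truth = self._three_subtype_markers()
        sig = representative_degs(expr, truth, top_n=1)
        assert sig.up[0]["gene"].iloc[0] == "g0"
        assert sig.down[0]["gene"].iloc[0] == "g1"
        assert sig.up[2]["gene"].iloc[0] == "g4"

    def test_identically_distributed_gene_not_selected(self):
        expr, truth = self._three_subtype_markers(seed=5)
        sig = representative_degs(expr, truth, top_n=1)
        flat = {f"g{i}" for i in range(6, 12)}  # no planted signal
        selected = sig.genes(0) | sig.genes(1) | sig.genes(2)
        assert not selected & flat

    def test_gene_topping_two_subtypes_dropped_from_both(self):
        expr, truth = _blob_expr([8, 8, 8], sep=0.0, seed=5)
        values = expr.values.copy()
        # g2 up in subtype 0 and down in subtype 1 -> picked by both, then dropped
        values.loc["g2", truth.index[truth == 0]] += 6.0
        values.loc["g2", truth.index[truth == 1]] -= 6.0
        expr = ExpressionMatrix(values, expr.sample_class)
        sig = representative_degs(expr, truth, top_n=2)
        assert "g2" in sig.dropped_shared
        for s in (0, 1, 2):
            assert "g2" not in sig.genes(s)

    def test_planted_signatures_recovered_with_high_precision(self, strong_dataset):
        ds = strong_dataset
        tumors = ds.expression.subset_samples(ds.expression.samples_of_class("tumor"))
        per_direction = len(ds.truth.subtype_genes_up["c1"])
        sig = representative_degs(tumors, ds.truth.subtype, top_n=per_direction)
        selected, planted = set(), set()
        for s in sorted(ds.truth.subtype.unique()):
            selected |= sig.genes(s)
            planted |= set(ds.truth.subtype_genes[s])
        assert len(selected & planted) / len(selected) >= 0.9

    def test_tiny_subtype_rejected(self):
        expr, truth = _blob_expr([10, 1])
        with pytest.raises(AnalysisError):
            representative_degs(expr, truth, top_n=3)


class TestFeatureAssociation:
    def test_planted_mutation_flagged_for_its_subtype(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(120)]
        assign = pd.Series(rng.choice(["c1", "c2", "c3"], size=120), index=ids)
        rows = []
        for s in ids:
            rate = 0.8 if assign[s] == "c1" else 0.05
            if rng.random() < rate:
                rows.append(("MUTG", s, "Missense_Mutation", "SNP"))
        mut = MutationTable(pd.DataFrame(
            rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                           "Variant_Classification", "Variant_Type"]))
        out = subtype_feature_association(assign, mutations=mut)
        hit = out[(out["feature"] == "mut:MUTG") & (out["level"] == "mutated")
                  & (out["subtype"] == "c1")]
        assert hit["p"].iloc[0] < 0.01 and hit["direction"].iloc[0] == "enriched"

    def test_perfect_two_by_two_matches_exact_fisher(self):
        ids = [f"s{i}" for i in range(20)]
        assign = pd.Series(["c1"] * 10 + ["c2"] * 10, index=ids)
        clin = _clinical(ids, [100] * 20, [1] * 20,
                         ms=["msi-h"] * 10 + ["mss"] * 10)
        out = subtype_feature_association(assign, clinical=clin)
        row = out[(out["feature"] == "microsatellite_status")
                  & (out["level"] == "msi-h") & (out["subtype"] == "c1")]
        assert row["p"].iloc[0] == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_single_level_feature_skipped(self):
        ids = [f"s{i}" for i in range(10)]
        assign = pd.Series(["c1"] * 5 + ["c2"] * 5, index=ids)
        clin = _clinical(ids, [100] * 10, [1] * 10)  # sex is all male
        out = subtype_feature_association(assign, clinical=clin)
        assert "sex" not in set(out["feature"])

    def test_independent_feature_flags_at_nominal_rate(self):
        rng = np.random.default_rng(7)
        false_hits, total = 0, 0
        for rep in range(40):
            ids = [f"s{i}" for i in range(60)]
            assign = pd.Series(rng.choice(["c1", "c2"], size=60), index=ids)
            clin = _clinical(ids, [100] * 60, [1] * 60,
                             ms=list(rng.choice(["mss", "msi-h"], size=60)))
            out = subtype_feature_association(assign, clinical=clin)
            ms = out[out["feature"] == "microsatellite_status"]
            false_hits += int((ms["p"] < 0.05).any())
            total += 1
        # 4 correlated tests per replicate; family-wise false flags stay modest
        assert false_hits / total < 0.35


class TestSubtypeSurvival:
    def test_elevated_hazard_subtype_detected(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(120)]
        assign = pd.Series(["c1"] * 40 + ["c2"] * 40 + ["c3"] * 40, index=ids)
        hazard = np.where(assign == "c2", 5.0, 1.0)
        times = rng.exponential(1000.0 / hazard)
        clin = _clinical(ids, np.round(times, 1), [1] * 120)
        chi2, p, km = subtype_survival(assign, clin)
        assert p < 0.01
        assert set(km) == {"c1", "c2", "c3"}
        for frame in km.values():
            surv = frame["survival"].to_numpy()
            assert (np.diff(surv) <= 1e-12).all()  # KM is a nonincreasing step fn

    def test_two_group_case_equals_pairwise_logrank(self):
        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(40)]
        assign = pd.Series(["c1"] * 20 + ["c2"] * 20, index=ids)
        times = np.round(rng.exponential(500, size=40), 1)
        events = rng.integers(0, 2, size=40)
        events[0] = 1
        clin = _clinical(ids, times, events)
        chi2_multi, p_multi, _ = subtype_survival(assign, clin)
        chi2_two, p_two = logrank_test(clin.data["survival_time"],
                                       clin.data["event"], assign)
        assert chi2_multi == pytest.approx(chi2_two, abs=1e-10)
        assert p_multi == pytest.approx(p_two, abs=1e-10)

    def test_no_events_rejected(self):
        ids = ["a", "b", "c", "d"]
        assign = pd.Series(["c1", "c1", "c2", "c2"], index=ids)
        clin = _clinical(ids, [10, 20, 30, 40], [0, 0, 0, 0])
        with pytest.raises(AnalysisError):
            subtype_survival(assign, clin)


class TestProportions:
    def test_percentages_match_printed_arithmetic(self):
        counts = {"c1": 38, "c2": 138, "c3": 99, "c4": 85, "c5": 38, "c6": 56}
        ids = []
        labels = []
        for name, n in counts.items():
            ids += [f"{name}_{i}" for i in range(n)]
            labels += [name] * n
        table = subtype_proportions(pd.Series(labels, index=ids))
        expected = {"c1": 8.37, "c2": 30.40, "c3": 21.81, "c4": 18.72,
                    "c5": 8.37, "c6": 12.33}
        for row in table.itertuples():
            assert row.percent == pytest.approx(expected[row.subtype], abs=0.005)
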