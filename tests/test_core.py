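"""TPP correlation, stage assignment and cascade construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from trcascade.core import (
    StageAssignment,
    TemplatePeakPattern,
    TrcParameters,
    assign_stages,
    build_cascade,
    build_tpp_library,
    build_trc,
    classify_interactions,
    collapse_replicates,
    correlate_to_tpp,
    tpp_correlation_matrix,
)
from trcascade.network import RegulatoryNetwork

from conftest import make_dataset


class TestTppLibrary:
    def test_one_pattern_per_timepoint(self):
        lib = build_tpp_library(4)
        assert len(lib) == 4
        assert lib[1].vector.tolist() == [0, 100, 0, 0]

    def test_two_timepoints(self):
        lib = build_tpp_library(2)
        assert [p.vector.tolist() for p in lib] == [[100, 0], [0, 100]]

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            build_tpp_library(1)

    def test_pattern_is_one_hot_at_peak_level(self):
        for tpp in build_tpp_library(6):
            v = tpp.vector
            assert np.count_nonzero(v) == 1 and v[tpp.stage] == 100


class TestCorrelation:
    def test_identical_shape_gives_one(self):
        tpp = TemplatePeakPattern(1, 4)
        assert correlate_to_tpp([0, 100, 0, 0], tpp) == pytest.approx(1.0)

    def test_constant_profile_undefined(self):
        tpp = TemplatePeakPattern(1, 4)
        assert np.isnan(correlate_to_tpp([5, 5, 5, 5], tpp))

    def test_against_direct_pearson(self):
        # direct Pearson computation is the oracle for the closed form
        x = np.array([1.0, 9.0, 2.0, 0.0])
        tpp = TemplatePeakPattern(1, 4)
        expected = pearsonr(x, tpp.vector).statistic
        # (9 - 3) / (sqrt(12.5) * sqrt(3)) = 0.97980
        assert expected == pytest.approx(0.9797959, abs=1e-6)
        assert correlate_to_tpp(x, tpp) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            correlate_to_tpp([1, 2, 3], TemplatePeakPattern(1, 4))

    @settings(derandomize=True, max_examples=200)
    @given(
        t=st.integers(3, 8),
        seed=st.integers(0, 10_000),
    )
    def test_closed_form_matches_pearson_everywhere(self, t, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, size=t)
        if np.ptp(x) == 0:
            return
        for s, tpp in enumerate(build_tpp_library(t)):
            direct = pearsonr(x, tpp.vector).statistic
            assert correlate_to_tpp(x, tpp) == pytest.approx(direct, abs=1e-10)

    @settings(derandomize=True, max_examples=100)
    @given(t=st.integers(3, 8), seed=st.integers(0, 10_000))
    def test_conservation_of_squared_correlations(self, t, seed):
        # sum over stages of r^2 equals T/(T-1) for every non-flat profile
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 50, size=t)
        rs = [correlate_to_tpp(x, tpp) for tpp in build_tpp_library(t)]
        assert np.sum(np.square(rs)) == pytest.approx(t / (t - 1), abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.01, 50),
        b=st.floats(0, 100),
    )
    def test_invariant_to_positive_affine_transform(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 100, size=5)
        tpp = TemplatePeakPattern(2, 5)
        assert correlate_to_tpp(a * x + b, tpp) == pytest.approx(
            correlate_to_tpp(x, tpp), abs=1e-9
        )

    def test_matrix_form_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.uniform(0, 10, size=(6, 5)))
        collapsed = collapse_replicates(ds)
        mat = tpp_correlation_matrix(collapsed)
        for g in collapsed.index:
            for s, tpp in enumerate(build_tpp_library(5)):
                assert mat.loc[g, s] == pytest.approx(
                    correlate_to_tpp(collapsed.loc[g].to_numpy(), tpp), abs=1e-12
                )


class TestCollapse:
    def test_replicate_mean(self):
        ds = make_dataset(
            [[2, 4, 6, 8]], times=[0, 0, 1, 1], reps=[0, 1, 0, 1],
            samples=["a", "b", "c", "d"],
        )
        assert ds.collapse().loc["G0"].tolist() == [3.0, 7.0]

    def test_single_replicate_identity(self, small_dataset):
        assert np.array_equal(
            small_dataset.collapse().to_numpy(), small_dataset.values.to_numpy()
        )


class TestParameters:
    @pytest.mark.parametrize(
        "kwargs", [dict(minE=-1), dict(minC=1.5), dict(minC=-2), dict(maxS=0)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrcParameters(**kwargs)


class TestAssignStages:
    def test_gene_at_exactly_min_e_excluded(self):
        # the expression floor is strict: a maximum equal to minE fails
        ds = make_dataset([[0, 4, 0, 0], [0, 4.01, 0, 0]], genes=["AT", "ABOVE"])
        asg = assign_stages(ds, {"AT", "ABOVE"}, TrcParameters(minE=4))
        assert asg.genes() == ["ABOVE"]

    def test_one_hot_regulators_each_get_own_stage(self):
        ds = make_dataset(np.eye(3) * 50, genes=["R0", "R1", "R2"],
                          samples=["T0", "T1", "T2"])
        asg = assign_stages(ds, {"R0", "R1", "R2"}, TrcParameters(minE=1))
        assert asg.stage_of() == {"R0": 0, "R1": 1, "R2": 2}
        assert all(r == pytest.approx(1.0) for _, col in asg.stages
                   for _, r in col)

    def test_max_s_keeps_top_correlated(self):
        # 15 candidates at one stage; brute-force ranking picks the top 10
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 10, size=(15, 4))  # baselines vary, so r varies
        values[:, 1] = 50 + 50 * rng.random(15)
        genes = [f"R{i:02d}" for i in range(15)]
        ds = make_dataset(values, genes=genes)
        params = TrcParameters(minE=1, minC=0.6, maxS=10)
        asg = assign_stages(ds, set(genes), params)
        rs = {
            g: correlate_to_tpp(values[i], TemplatePeakPattern(1, 4))
            for i, g in enumerate(genes)
        }
        expected = sorted(genes, key=lambda g: (-rs[g], g))[:10]
        assert asg.genes(1) == expected
        assert asg.genes() == expected  # nothing leaks to other stages

    def test_gene_joins_only_its_best_stage(self):
        # a profile above minC for two TPPs lands in the better one only
        ds = make_dataset([[90, 100, 0, 0, 0, 0]], genes=["R"])
        asg = assign_stages(ds, {"R"}, TrcParameters(minE=1, minC=0.0))
        assert asg.stage_of() == {"R": 1}

    def test_non_regulators_ineligible(self):
        ds = make_dataset([[0, 50, 0, 0], [0, 60, 0, 0]], genes=["TF", "GENE"])
        asg = assign_stages(ds, {"TF"}, TrcParameters(minE=1))
        assert asg.genes() == ["TF"]

    def test_flat_profiles_silently_excluded(self):
        ds = make_dataset([[7, 7, 7, 7], [0, 50, 0, 0]], genes=["FLAT", "PK"])
        asg = assign_stages(ds, {"FLAT", "PK"}, TrcParameters(minE=1))
        assert asg.genes() == ["PK"]

    def test_empty_regulator_universe_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="regulator universe"):
            assign_stages(small_dataset, set(), TrcParameters())

    def test_columns_sorted_descending(self, noisy_fixture):
        ds, net, _, _ = noisy_fixture
        asg = assign_stages(ds, net.regulators, TrcParameters())
        for _, col in asg.stages:
            rs = [r for _, r in col]
            assert rs == sorted(rs, reverse=True)
            assert all(r >= 0.6 for r in rs)


class TestBuildCascade:
    def _assignment(self, cols):
        return StageAssignment.from_dict(
            {s: [(g, 1.0) for g in genes] for s, genes in cols.items()},
            n_timepoints=max(cols) + 1,
        )

    def test_empty_network_gives_columns_without_edges(self):
        asg = self._assignment({0: ["A"], 1: ["B"]})
        cascade = build_cascade(asg, RegulatoryNetwork())
        assert cascade.n_nodes == 2 and cascade.edges == frozenset()

    def test_cross_edge_between_consecutive_stages(self):
        asg = self._assignment({0: ["A"], 1: ["B"]})
        net = RegulatoryNetwork.from_edge_list([("A", "B")])
        cascade = build_cascade(asg, net)
        assert cascade.edges == frozenset({("A", 0, "B", 1, "cross")})

    def test_no_edge_skipping_a_nonempty_stage(self):
        asg = self._assignment({0: ["A"], 1: ["B"], 2: ["C"]})
        net = RegulatoryNetwork.from_edge_list([("A", "C")])
        cascade = build_cascade(asg, net)
        assert cascade.edges == frozenset()

    def test_empty_stage_bridged(self):
        # stage 1 has no regulators: stage 0 links straight to stage 2
        asg = self._assignment({0: ["A"], 2: ["C"]})
        net = RegulatoryNetwork.from_edge_list([("A", "C")])
        cascade = build_cascade(asg, net)
        assert cascade.edges == frozenset({("A", 0, "C", 2, "cross")})

    def test_within_edges_and_metrics(self):
        asg = self._assignment({0: ["A", "B"]})
        net = RegulatoryNetwork.from_edge_list([("A", "B"), ("B", "A"), ("A", "X")])
        cascade = build_cascade(asg, net)
        assert cascade.edges == frozenset(
            {("A", 0, "B", 0, "within"), ("B", 0, "A", 0, "within")}
        )
        metrics = cascade.node_metrics()
        assert metrics.loc["A", "indegree"] == 1
        assert metrics.loc["A", "outdegree"] == 1


class TestClassifyInteractions:
    def test_reciprocal_within_pair(self):
        asg = StageAssignment.from_dict(
            {0: [("X", 1.0), ("Y", 0.9)]}, n_timepoints=2
        )
        net = RegulatoryNetwork.from_edge_list([("X", "Y"), ("Y", "X")])
        edge_table, _ = classify_interactions(build_cascade(asg, net))
        assert set(edge_table["pattern"]) == {"reciprocal"}

    def test_next_stage_fan_counts(self):
        asg = StageAssignment.from_dict(
            {0: [("X", 1.0)], 1: [(g, 0.9) for g in "ABC"]}, n_timepoints=2
        )
        net = RegulatoryNetwork.from_edge_list([("X", g) for g in "ABC"])
        _, node_table = classify_interactions(build_cascade(asg, net))
        row = node_table.set_index("gene").loc["X"]
        assert row["next_stage_fan"] == 3 and row["same_stage_fan"] == 0
        assert node_table.iloc[0]["gene"] in set("ABC") or \
            node_table.iloc[0]["next_stage_fan"] == 3

    def test_edgeless_cascade_empty_labeling(self):
        asg = StageAssignment.from_dict({0: [("X", 1.0)]}, n_timepoints=2)
        edge_table, node_table = classify_interactions(
            build_cascade(asg, RegulatoryNetwork())
        )
        assert edge_table.empty
        assert node_table["same_stage_fan"].tolist() == [0]


class TestDeterminism:
    def test_identical_inputs_identical_cascades(self, noisy_fixture):
        ds, net, _, _ = noisy_fixture
        c1, a1 = build_trc(ds, net, TrcParameters())
        c2, a2 = build_trc(ds, net, TrcParameters())
        assert c1 == c2 and a1 == a2
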