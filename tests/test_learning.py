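import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ctd.learning import (
    LearnConfig,
    ProfileMatrix,
    assemble_design,
    glasso_edge_path_scores,
    learn_gmrf,
    make_surrogates,
    prune_network,
    select_features,
    select_perturbation_set,
    zscore_profiles,
    _precision_to_graph,
)
from ctd.simulate import FixtureSpec, generate_profiles, random_sparse_precision
from conftest import make_graph


def profile(values, features=None, samples=None, labels=None, scale="raw"):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return ProfileMatrix(
        features or tuple(f"f{i}" for i in range(p)),
        samples or tuple(f"s{i}" for i in range(n)),
        values,
        labels or tuple("disease" for _ in range(n)),
        scale,
    )


class TestZScore:
    def test_reference_mean_maps_to_zero(self):
        ref = profile([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]])
        obs = profile([[2.0], [20.0]])
        z = zscore_profiles(obs, ref)
        np.testing.assert_allclose(z.values, 0.0, atol=1e-12)

    def test_hand_arithmetic(self):
        # reference {1,2,3} has sd 1 (ddof 1); observation 4 -> z = 2
        ref = profile([[1.0, 2.0, 3.0]])
        obs = profile([[4.0]])
        z = zscore_profiles(obs, ref)
        assert z.values[0, 0] == pytest.approx(2.0)
        assert z.scale == "zscore"

    def test_self_zscore_is_standardized(self):
        rng = np.random.default_rng(0)
        ref = profile(rng.normal(5, 3, size=(4, 200)))
        z = zscore_profiles(ref, ref)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_zero_variance_feature_dropped_with_warning(self):
        ref = profile([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        obs = profile([[5.0], [2.0]])
        with pytest.warns(UserWarning, match="zero reference variance"):
            z = zscore_profiles(obs, ref)
        assert z.feature_names == ("f1",)

    def test_features_absent_from_reference_dropped(self):
        ref = profile([[1.0, 2.0, 3.0]], features=("f1",))
        obs = profile([[9.0], [2.0]], features=("f0", "f1"))
        z = zscore_profiles(obs, ref)
        assert z.feature_names == ("f1",)


class TestSurrogates:
    def test_zero_surrogates(self):
        src = profile([[1.0, 2.0]])
        surr = make_surrogates(src, 0, rng_seed=0)
        assert surr.n_samples == 0

    def test_noise_is_standard_normal(self):
        src = profile(np.zeros((100, 1)))
        surr = make_surrogates(src, 100, rng_seed=1)
        diffs = surr.values  # source is zero, so surrogate == noise
        assert abs(diffs.mean()) < 0.03
        assert abs(diffs.std() - 1.0) < 0.03

    def test_seeded_determinism_and_cycling(self):
        src = profile([[1.0, 100.0]], labels=("disease", "disease"))
        a = make_surrogates(src, 5, rng_seed=3)
        b = make_surrogates(src, 5, rng_seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        # cycling: surrogates 0,2,4 come from sample 0; 1,3 from sample 1
        assert np.all(np.abs(a.values[0, [0, 2, 4]] - 1.0) < 6)
        assert np.all(np.abs(a.values[0, [1, 3]] - 100.0) < 6)
        assert set(a.class_labels) == {"surrogate_disease"}

    def test_empty_source_rejected(self):
        src = profile(np.zeros((2, 0)), samples=(), labels=())
        with pytest.raises(ValueError):
            make_surrogates(src, 3, rng_seed=0)


class TestAssembleDesign:
    def test_halving_rule_arithmetic(self):
        # 9 disease + 68 control reals at rank 136: 68 per side,
        # so 59 disease surrogates and no control surrogates
        rng = np.random.default_rng(0)
        disease = profile(rng.normal(size=(5, 9)), labels=tuple(["disease"] * 9))
        control = profile(rng.normal(size=(5, 68)), labels=tuple(["control"] * 68))
        design = assemble_design(disease, control, LearnConfig(target_rank=136))
        labels = list(design.class_labels)
        assert labels.count("disease") == 9
        assert labels.count("surrogate_disease") == 59
        assert labels.count("control") == 68
        assert labels.count("surrogate_control") == 0
        assert design.n_samples == 136

    def test_exact_rank_needs_no_surrogates(self):
        rng = np.random.default_rng(1)
        disease = profile(rng.normal(size=(4, 3)), labels=tuple(["disease"] * 3))
        control = profile(rng.normal(size=(4, 3)), labels=tuple(["control"] * 3))
        design = assemble_design(disease, control, LearnConfig(target_rank=6))
        assert sorted(set(design.class_labels)) == ["control", "disease"]

    def test_non_discriminative_uses_disease_side_only(self):
        rng = np.random.default_rng(2)
        disease = profile(rng.normal(size=(4, 9)), labels=tuple(["disease"] * 9))
        control = profile(rng.normal(size=(4, 5)), labels=tuple(["control"] * 5))
        design = assemble_design(
            disease, control, LearnConfig(target_rank=20, discriminative=False)
        )
        assert design.n_samples == 20
        assert "control" not in design.class_labels
        assert "surrogate_control" not in design.class_labels

    def test_infeasible_rank_rejected(self):
        rng = np.random.default_rng(3)
        disease = profile(rng.normal(size=(4, 9)), labels=tuple(["disease"] * 9))
        control = profile(rng.normal(size=(4, 5)), labels=tuple(["control"] * 5))
        with pytest.raises(ValueError, match="real samples"):
            assemble_design(disease, control, LearnConfig(target_rank=10))


class TestLearnGmrf:
    def test_independent_features_give_edgeless_graph(self):
        rng = np.random.default_rng(0)
        design = profile(rng.standard_normal((5, 400)))
        net = learn_gmrf(design, LearnConfig())
        assert net.edges() == []

    def test_partial_correlation_formula(self):
        # Theta = [[2,-1],[-1,2]] -> rho = -(-1)/sqrt(2*2) = 0.5
        g = _precision_to_graph(np.array([[2.0, -1.0], [-1.0, 2.0]]), ("a", "b"))
        assert g.adjacency[0, 1] == pytest.approx(0.5)
        assert g.adjacency[0, 0] == 0.0

    def test_partial_correlations_bounded(self):
        prof = generate_profiles(
            FixtureSpec(n_features=12, n_disease=80, n_control=80,
                        substrates=("f000", "f001"), products=("f002", "f003"),
                        rng_seed=5)
        )
        net = learn_gmrf(prof, LearnConfig())
        assert np.max(np.abs(net.adjacency)) <= 1 + 1e-9
        assert net.weight_convention == "signed"

    def test_support_recovery_auc_from_path(self):
        theta = random_sparse_precision(30, density=0.1, rng_seed=0)
        cov = np.linalg.inv(theta)
        rng = np.random.default_rng(100)
        X = rng.multivariate_normal(np.zeros(30), cov, size=200)
        design = profile(X.T)
        scores = glasso_edge_path_scores(design, LearnConfig())
        iu = np.triu_indices(30, 1)
        auc = roc_auc_score((theta[iu] != 0).astype(int), scores[iu])
        assert auc > 0.8


class TestPruneNetwork:
    def test_edgeless_control_changes_nothing(self):
        dis = make_graph(["a", "b", "c"], [("a", "b", 0.5), ("b", "c", 0.3)], "signed")
        ctrl = make_graph(["a", "b", "c"], [], "signed")
        out = prune_network(dis, ctrl)
        np.testing.assert_array_equal(out.adjacency, dis.adjacency)

    def test_identical_control_empties_graph(self):
        dis = make_graph(["a", "b", "c"], [("a", "b", 0.5), ("b", "c", 0.3)], "signed")
        out = prune_network(dis, dis)
        assert out.edges() == []

    def test_set_subtraction_rule(self):
        dis = make_graph(["a", "b", "c"], [("a", "b", 0.5), ("b", "c", 0.3)], "signed")
        ctrl = make_graph(["a", "b", "c"], [("b", "c", 0.9)], "signed")
        out = prune_network(dis, ctrl)
        assert [(u, v) for u, v, _ in out.edges()] == [("a", "b")]

    def test_idempotent(self):
        dis = make_graph(["a", "b", "c"], [("a", "b", 0.5), ("b", "c", 0.3)], "signed")
        ctrl = make_graph(["a", "b", "c"], [("b", "c", 0.9)], "signed")
        once = prune_network(dis, ctrl)
        twice = prune_network(once, ctrl)
        np.testing.assert_array_equal(once.adjacency, twice.adjacency)

    def test_weight_subtraction_variant(self):
        dis = make_graph(["a", "b"], [("a", "b", 0.5)], "signed")
        ctrl = make_graph(["a", "b"], [("a", "b", 0.2)], "signed")
        out = prune_network(dis, ctrl, subtract_weights=True)
        assert out.adjacency[0, 1] == pytest.approx(0.3)


class TestPerturbationSelection:
    def test_threshold_rule(self):
        z = {"m1": 2.5, "m2": -2.4, "m3": 1.9}
        s = select_perturbation_set(z, mode="threshold", z_cut=2.0)
        assert s.members == {"m1", "m2"}

    def test_topk_by_magnitude(self):
        s = select_perturbation_set({"m1": 0.5, "m2": -3.0}, mode="topk", k=1)
        assert s.members == {"m2"}

    def test_zero_cut_keeps_all_nonzero(self):
        z = {"m1": 0.1, "m2": -0.2, "m3": 0.0}
        s = select_perturbation_set(z, mode="threshold", z_cut=0.0)
        assert s.members == {"m1", "m2"}

    def test_graph_intersection_and_empty_warning(self):
        g = make_graph(["m1", "m2"], [("m1", "m2", 1.0)])
        s = select_perturbation_set({"m9": 5.0}, z_cut=2.0, graph=g)
        assert s is None  # warning path: nothing intersects the graph


class TestSelectFeatures:
    def test_single_patient_returns_its_subset(self):
        assert set(select_features([("a", "b")])) == {"a", "b"}

    def test_boundary_frequency_inclusive(self):
        res = select_features([("a", "b"), ("a",), ("c", "b"), ("c",)], 0.5)
        assert set(res) == {"a", "b", "c"}

    def test_full_frequency_is_intersection(self):
        res = select_features([("a", "b"), ("a", "c")], 1.0)
        assert res == ["a"]

    def test_sorted_by_frequency_then_name(self):
        res = select_features([("b", "a"), ("b",), ("a", "b"), ("z",)], 0.25)
        assert res == ["b", "a", "z"]
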