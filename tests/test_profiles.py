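"""Subsystem profiles, cosine similarity, clustering, embedding, group comparison."""
import numpy as np
import pytest

from gemflux.model import FluxDistribution, Reaction
from gemflux.profiles import (
    SubsystemProfile,
    cluster_profiles,
    compare_groups,
    cosine_similarity,
    embed_profiles,
    subsystem_profile,
)
from gemflux.solvers import SampleEnsemble

from conftest import build_model


@pytest.fixture
def two_subsystem_model():
    return build_model(
        [
            Reaction("A1", {"A": 1}, 0, 10, subsystem="alpha"),
            Reaction("A2", {"A": -1, "B": 1}, 0, 10, subsystem="alpha"),
            Reaction("B1", {"B": -1}, 0, 10, subsystem="beta"),
        ],
        ["A", "B"],
        {"B1": 1.0},
    )


class TestSubsystemProfile:
    def test_sums_and_normalizes(self, two_subsystem_model):
        flux = FluxDistribution({"A1": 3.0, "A2": 4.0, "B1": 7.0}, 7.0, "optimal")
        prof = subsystem_profile(flux, two_subsystem_model)
        assert prof.values == pytest.approx({"alpha": 0.5, "beta": 0.5})

    def test_single_subsystem_is_one(self):
        model = build_model([Reaction("R", {"A": 1}, 0, 10, subsystem="solo")], ["A"], {})
        prof = subsystem_profile(FluxDistribution({"R": 2.0}, 0, "optimal"), model)
        assert prof.values == {"solo": 1.0}

    def test_scale_invariance(self, two_subsystem_model):
        f1 = FluxDistribution({"A1": 1.0, "A2": 2.0, "B1": 3.0}, 0, "optimal")
        f2 = FluxDistribution({"A1": 5.0, "A2": 10.0, "B1": 15.0}, 0, "optimal")
        p1 = subsystem_profile(f1, two_subsystem_model)
        p2 = subsystem_profile(f2, two_subsystem_model)
        assert p1.values == pytest.approx(p2.values)

    def test_all_zero_flux_rejected(self, two_subsystem_model):
        with pytest.raises(ValueError):
            subsystem_profile(FluxDistribution({"A1": 0.0}, 0, "optimal"), two_subsystem_model)

    def test_unannotated_pool_into_other(self):
        model = build_model([Reaction("R", {"A": 1}, 0, 10)], ["A"], {})
        prof = subsystem_profile(FluxDistribution({"R": 1.0}, 0, "optimal"), model)
        assert prof.values == {"other": 1.0}


class TestCosineSimilarity:
    def test_identical_vectors(self):
        sim = cosine_similarity(np.array([[1.0, 2.0], [1.0, 2.0]]), ["a", "b"])
        assert sim.matrix[0, 1] == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        sim = cosine_similarity(np.array([[1.0, 0.0], [0.0, 1.0]]), ["a", "b"])
        assert sim.matrix[0, 1] == pytest.approx(0.0)

    def test_scale_invariance(self):
        sim = cosine_similarity(np.array([[1.0, 1.0], [2.0, 2.0]]), ["a", "b"])
        assert sim.matrix[0, 1] == pytest.approx(1.0)

    def test_zero_vector_named(self):
        with pytest.raises(ValueError, match="zed"):
            cosine_similarity(np.array([[1.0, 0.0], [0.0, 0.0]]), ["a", "zed"])

    def test_matrix_invariants(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 1, (6, 4))
        sim = cosine_similarity(X)
        assert np.allclose(sim.matrix, sim.matrix.T, atol=1e-12)
        assert np.allclose(np.diag(sim.matrix), 1.0)
        assert (sim.matrix >= -1 - 1e-12).all() and (sim.matrix <= 1 + 1e-12).all()


class TestClustering:
    def test_identical_pair_co_clusters(self):
        profiles = [
            SubsystemProfile("a", {"x": 0.5, "y": 0.5}),
            SubsystemProfile("b", {"x": 0.5, "y": 0.5}),
            SubsystemProfile("c", {"x": 1.0}),
        ]
        res = cluster_profiles(profiles, k=2)
        labels = dict(zip(res.labels, res.flat))
        assert labels["a"] == labels["b"] != labels["c"]

    def test_all_identical_single_cluster(self):
        profiles = [SubsystemProfile(str(i), {"x": 1.0}) for i in range(4)]
        res = cluster_profiles(profiles, k=1)
        assert len(set(res.flat)) == 1

    def test_fewer_than_two_profiles_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles([SubsystemProfile("a", {"x": 1.0})])


class TestEmbedding:
    def test_collinear_profiles_have_flat_second_axis(self):
        profiles = [SubsystemProfile(str(i), {"x": 0.2 + 0.2 * i, "y": 0.8 - 0.2 * i})
                    for i in range(3)]
        coords = embed_profiles(profiles, method="pca", seed=0)
        assert np.abs(coords[:, 1]).max() < 1e-8

    def test_duplicate_profiles_duplicate_coordinates(self):
        profiles = [
            SubsystemProfile("a", {"x": 0.3, "y": 0.7}),
            SubsystemProfile("b", {"x": 0.3, "y": 0.7}),
            SubsystemProfile("c", {"x": 0.9, "y": 0.1}),
        ]
        coords = embed_profiles(profiles, method="pca", seed=0)
        assert np.allclose(coords[0], coords[1])

    def test_umap_or_fallback_finite(self):
        rng = np.random.default_rng(0)
        profiles = [SubsystemProfile(str(i), {"x": v, "y": 1 - v})
                    for i, v in enumerate(rng.uniform(0, 1, 8))]
        coords = embed_profiles(profiles, method="umap", seed=0)
        assert coords.shape == (8, 2) and np.isfinite(coords).all()


def _ensemble(values_by_rxn, seed=0):
    rids = list(values_by_rxn)
    samples = np.column_stack([values_by_rxn[r] for r in rids])
    return SampleEnsemble(samples=samples, reaction_ids=rids, seed=seed)


class TestCompareGroups:
    def test_identical_ensembles(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 1, 200)
        a = _ensemble({"R1": vals})
        b = _ensemble({"R1": vals.copy()})
        df = compare_groups({"g1": a, "g2": b})
        row = df.iloc[0]
        assert row["median_diff_g2"] == pytest.approx(0.0)
        assert row["overlap_g2"] == pytest.approx(1.0)

    def test_location_shift_detected(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 1, 500)
        df = compare_groups({"ref": _ensemble({"R1": vals}), "hi": _ensemble({"R1": vals + 2})})
        assert df.iloc[0]["median_diff_hi"] == pytest.approx(2.0, abs=0.05)
        assert df.iloc[0]["overlap_hi"] < 0.6

    def test_absent_reaction_is_structural_zero(self):
        rng = np.random.default_rng(2)
        a = _ensemble({"R1": rng.normal(3, 1, 100), "R2": rng.normal(1, 1, 100)})
        b = _ensemble({"R1": rng.normal(3, 1, 100)})
        df = compare_groups({"g1": a, "g2": b}, reactions=["R1", "R2"])
        row = df[df.reaction_id == "R2"].iloc[0]
        assert row["absent_g2"] and row["median_g2"] == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"g": _ensemble({"R1": np.ones(10)})})

    def test_no_p_values_reported(self):
        df = compare_groups(
            {"a": _ensemble({"R1": np.arange(50.0)}), "b": _ensemble({"R1": np.arange(50.0)})}
        )
        assert not any("pvalue" in c or "p_value" in c for c in df.columns)
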