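"""Toy network ground truth and the cohort/respirometry generators."""
import numpy as np
import pytest

from gemflux.solvers import fba
from gemflux.synthetic import (
    ATP_PER_GLUCOSE_AEROBIC,
    ATP_PER_GLUCOSE_ANAEROBIC,
    SyntheticCohortConfig,
    make_random_network,
    make_toy_model,
    simulate_expression,
    simulate_respirometry,
    toy_down_genes,
)


class TestToyModel:
    def test_deterministic_construction(self):
        a, b = make_toy_model(), make_toy_model()
        assert a.reaction_ids == b.reaction_ids
        assert [r.stoichiometry for r in a.reactions] == [r.stoichiometry for r in b.reactions]

    def test_structure(self, toy_model):
        assert set(toy_model.compartments) == {"e", "c", "m"}
        subsystems = {r.subsystem for r in toy_model.reactions}
        for required in ("glycolysis", "tca", "oxphos", "fatty_acid_oxidation",
                        "exchange", "transport", "atp_demand"):
            assert required in subsystems
        assert 40 <= len(toy_model.reactions) <= 55
        assert 50 <= len(toy_model.genes) <= 70
        assert toy_model.objective == {"ATPM": 1.0}

    def test_aerobic_yield_exceeds_anaerobic(self, toy_model):
        for r in toy_model.reactions:
            if r.is_exchange and r.lower_bound < 0:
                r.lower_bound = 0.0
        toy_model.get_reaction("EX_glc").lower_bound = -1.0
        anaerobic = fba(toy_model).objective_value
        toy_model.get_reaction("EX_o2").lower_bound = -1000.0
        aerobic = fba(toy_model).objective_value
        assert anaerobic == pytest.approx(ATP_PER_GLUCOSE_ANAEROBIC)
        assert aerobic == pytest.approx(ATP_PER_GLUCOSE_AEROBIC)
        assert aerobic > anaerobic

    def test_complex_i_knockout_leaves_reduced_aerobic_yield(self, toy_model):
        for r in toy_model.reactions:
            if r.is_exchange and r.lower_bound < 0:
                r.lower_bound = 0.0
        toy_model.get_reaction("EX_glc").lower_bound = -1.0
        toy_model.get_reaction("EX_o2").lower_bound = -1000.0
        ci = toy_model.get_reaction("CI")
        ci.lower_bound = ci.upper_bound = 0.0
        reduced = fba(toy_model)
        assert reduced.status == "optimal"
        assert ATP_PER_GLUCOSE_ANAEROBIC < reduced.objective_value < ATP_PER_GLUCOSE_AEROBIC


class TestSimulateExpression:
    def test_down_gene_fold_recovered_in_tpm(self, toy_model):
        """Disease/control TPM ratio of down-regulated genes tracks the fold."""
        ratios, null_ratios = [], []
        for seed in range(1, 6):
            cfg = SyntheticCohortConfig(seed=seed)
            expr, truth = simulate_expression(toy_model, cfg)
            down = sorted(toy_down_genes(toy_model, cfg.down_subsystems))
            frame = expr.to_frame()
            ctrl = frame[[s for s in expr.sample_ids if s.startswith("control")]].mean(axis=1)
            dis = frame[[s for s in expr.sample_ids if s.startswith("disease")]].mean(axis=1)
            ratios.append((dis[down] / ctrl[down]).median())
            other = [g for g in expr.gene_ids
                     if g not in down and truth.gene_state[("control", g)]["on"]]
            null_ratios.append((dis[other] / ctrl[other]).median())
        assert np.mean(ratios) == pytest.approx(0.25, rel=0.2)
        assert np.mean(null_ratios) == pytest.approx(1.0, rel=0.2)

    def test_poisson_limit_of_dispersion(self, toy_model):
        """At vanishing dispersion and fixed library size, counts are Poisson."""
        cfg = SyntheticCohortConfig(seed=3, nb_dispersion=1e-12, n_per_group=10,
                                    library_size_range=(300_000, 300_001))
        expr, _ = simulate_expression(toy_model, cfg)
        cols = [i for i, s in enumerate(expr.sample_ids) if s.startswith("control")]
        counts = expr.counts[:, cols]
        means = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        keep = means > 50
        assert np.median(var[keep] / means[keep]) == pytest.approx(1.0, abs=0.35)

    def test_reproducible_given_seed(self, toy_model):
        cfg = SyntheticCohortConfig(seed=9)
        a, _ = simulate_expression(toy_model, cfg)
        b, _ = simulate_expression(toy_model, cfg)
        assert np.array_equal(a.counts, b.counts)

    def test_ground_truth_folds_match_config(self, toy_model):
        cfg = SyntheticCohortConfig(seed=1)
        _, truth = simulate_expression(toy_model, cfg)
        down = toy_down_genes(toy_model, cfg.down_subsystems)
        g = next(iter(down))
        assert truth.gene_state[("disease", g)]["fold"] == cfg.disease_fold
        assert truth.gene_state[("treated", g)]["fold"] == cfg.treated_fold
        assert truth.expected_direction[("disease", "oxphos")] == "down"
        assert truth.expected_direction[("disease", "tca")] == "unchanged"

    def test_invalid_folds_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(disease_fold=0.8, treated_fold=0.5)


class TestSimulateRespirometry:
    def test_noise_free_ordering(self):
        cfg = SyntheticCohortConfig(seed=0, respirometry_noise_sd=0.0)
        by_group = {
            m.group: m.oxygen_flux
            for m in simulate_respirometry(cfg)
            if m.state == "oxphos"
        }
        assert by_group["disease"] < by_group["treated"] < by_group["control"]

    def test_reproducible(self):
        cfg = SyntheticCohortConfig(seed=4)
        a = simulate_respirometry(cfg)
        b = simulate_respirometry(cfg)
        assert [(m.group, m.state, m.oxygen_flux) for m in a] == [
            (m.group, m.state, m.oxygen_flux) for m in b
        ]

    def test_null_configuration_equalizes_groups(self):
        cfg = SyntheticCohortConfig(seed=0, disease_fold=1.0, treated_fold=1.0,
                                    respirometry_noise_sd=0.0)
        values = {m.group: m.oxygen_flux for m in simulate_respirometry(cfg) if m.state == "oxphos"}
        assert len(set(values.values())) == 1


class TestRandomNetworks:
    def test_deterministic(self):
        a = make_random_network(7)
        b = make_random_network(7)
        assert a.reaction_ids == b.reaction_ids
        assert [r.stoichiometry for r in a.reactions] == [r.stoichiometry for r in b.reactions]

    def test_size_bounds(self):
        for seed in range(20):
            model = make_random_network(seed)
            assert len(model.reactions) <= 14
            model.validate()
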