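"""Reaction classification, flux-consistency pruning, core-preserving extraction, tasks."""
import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from gemflux.expression import GeneDiscretization, MixtureParams
from gemflux.extraction import (
    ExtractionConfig,
    InconsistentCoreError,
    TaskDefinition,
    build_context_model,
    check_tasks,
    classify_reactions,
    fastcc_consistent,
    fastcore_extract,
    load_tasks,
)
from gemflux.model import Reaction, stoichiometric_matrix
from gemflux.synthetic import SyntheticCohortConfig, make_random_network, simulate_expression

from conftest import build_model


def make_disc(categories):
    return GeneDiscretization(
        sample_id="s",
        category=dict(categories),
        score={g: float(c) for g, c in categories.items()},
        mixture_params=MixtureParams(0, 5, 1, 1, 0.5, 0.5),
    )


class TestClassify:
    def test_or_rule_promotes_to_core(self, toy_model):
        disc = make_disc({g: 0 for g in toy_model.genes} | {"gSlc2a1": 1})
        sets = classify_reactions(toy_model, disc)
        assert "GLCt" in sets.core

    def test_all_unexpressed_and_rule_is_inactive(self, toy_model):
        disc = make_disc({g: -1 for g in toy_model.genes})
        sets = classify_reactions(toy_model, disc)
        assert "PDH" in sets.inactive

    def test_no_gpr_defaults_to_noncore(self, toy_model):
        disc = make_disc({g: 1 for g in toy_model.genes})
        sets = classify_reactions(toy_model, disc)
        assert "ATPM" in sets.noncore
        assert "EX_glc" in sets.noncore

    def test_partition_is_exact(self, toy_model):
        disc = make_disc({g: [1, 0, -1][i % 3] for i, g in enumerate(toy_model.genes)})
        sets = classify_reactions(toy_model, disc)
        all_ids = set(toy_model.reaction_ids)
        assert sets.core | sets.noncore | sets.inactive == all_ids
        assert not (sets.core & sets.noncore or sets.core & sets.inactive
                    or sets.noncore & sets.inactive)


def fva_consistency_oracle(model, eps=1e-4):
    """Per-reaction brute force: max (and min, if reversible) of v_i >= eps."""
    S = stoichiometric_matrix(model)
    lb, ub = model.bounds_arrays()
    m, n = S.shape
    bounds = list(zip(lb, ub))
    consistent = set()
    for j, rid in enumerate(model.reaction_ids):
        e = np.zeros(n)
        e[j] = 1.0
        hi = linprog(-e, A_eq=S, b_eq=np.zeros(m), bounds=bounds, method="highs")
        if hi.status == 0 and hi.x[j] >= eps * (1 - 1e-6):
            consistent.add(rid)
            continue
        if lb[j] < 0:
            lo = linprog(e, A_eq=S, b_eq=np.zeros(m), bounds=bounds, method="highs")
            if lo.status == 0 and lo.x[j] <= -eps * (1 - 1e-6):
                consistent.add(rid)
    return consistent


class TestFastcc:
    def test_chain_fully_consistent(self, chain_model):
        assert fastcc_consistent(chain_model) == set(chain_model.reaction_ids)

    def test_orphan_reaction_excluded(self, chain_model):
        chain_model.metabolites += [
            type(chain_model.metabolites[0])("C", "C", "c"),
            type(chain_model.metabolites[0])("D", "D", "c"),
        ]
        chain_model.reactions.append(Reaction("ORPH", {"C": -1, "D": 1}, 0, 10))
        consistent = fastcc_consistent(chain_model)
        assert "ORPH" not in consistent
        assert consistent == {"EX_a", "R1", "EX_b"}

    def test_toy_network_fully_consistent(self, toy_model):
        assert fastcc_consistent(toy_model) == set(toy_model.reaction_ids)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_fva_oracle_on_random_networks(self, seed):
        model = make_random_network(seed)
        assert fastcc_consistent(model) == fva_consistency_oracle(model)


def brute_force_minimum_added(model, core, eps=1e-4, max_extra=8):
    """Exhaustive search for the smallest consistent superset of the core."""
    noncore = [r for r in model.reaction_ids if r not in core]
    if len(noncore) > max_extra:
        raise ValueError("instance too large for exhaustive search")
    for k in range(len(noncore) + 1):
        for combo in itertools.combinations(noncore, k):
            sub = model.subnetwork(set(core) | set(combo))
            ok = fva_consistency_oracle(sub, eps)
            if set(core) <= ok and ok == set(sub.reaction_ids):
                return k
    return None


class TestFastcore:
    def test_core_pulls_in_needed_support(self, chain_model):
        ctx = fastcore_extract({"R1"}, chain_model)
        assert ctx.kept_reactions == {"EX_a", "R1", "EX_b"}

    def test_full_core_adds_nothing(self, toy_model):
        core = fastcc_consistent(toy_model)
        ctx = fastcore_extract(core, toy_model)
        assert ctx.kept_reactions == core

    def test_empty_core_empty_model(self, toy_model):
        ctx = fastcore_extract(set(), toy_model)
        assert ctx.kept_reactions == set()
        assert len(ctx.model.reactions) == 0

    def test_unsupportable_core_raises_with_name(self, chain_model):
        chain_model.metabolites += [
            type(chain_model.metabolites[0])("C", "C", "c"),
            type(chain_model.metabolites[0])("D", "D", "c"),
        ]
        chain_model.reactions.append(Reaction("ORPH", {"C": -1, "D": 1}, 0, 10))
        with pytest.raises(InconsistentCoreError, match="ORPH"):
            fastcore_extract({"ORPH"}, chain_model)

    def test_output_flux_consistent_and_contains_core(self, toy_model):
        rng = np.random.default_rng(0)
        consistent = sorted(fastcc_consistent(toy_model))
        for _ in range(5):
            core = set(rng.choice(consistent, size=6, replace=False))
            ctx = fastcore_extract(core, toy_model)
            assert core <= ctx.kept_reactions
            assert fastcc_consistent(ctx.model) == ctx.kept_reactions

    def test_deterministic(self, toy_model):
        core = {"ATPS", "PFK", "CK"}
        a = fastcore_extract(core, toy_model)
        b = fastcore_extract(core, toy_model)
        assert a.kept_reactions == b.kept_reactions

    @pytest.mark.parametrize("seed", range(6))
    def test_added_count_matches_exhaustive_minimum(self, seed):
        model = make_random_network(seed, n_extra=4)
        consistent = fastcc_consistent(model)
        pruned = model.subnetwork(consistent)
        rng = np.random.default_rng(seed + 1000)
        ids = sorted(consistent)
        core = set(rng.choice(ids, size=min(3, len(ids)), replace=False))
        ctx = fastcore_extract(core, pruned)
        minimum = brute_force_minimum_added(pruned, core)
        assert len(ctx.kept_reactions - core) == minimum


@pytest.fixture(scope="module")
def cohort():
    from gemflux.synthetic import make_toy_model

    model = make_toy_model()
    expr, truth = simulate_expression(model, SyntheticCohortConfig(seed=2))
    return model, expr, truth


class TestBuildContextModel:

    def test_control_sample_retains_energy_subsystems(self, cohort):
        model, expr, _ = cohort
        ctx = build_context_model(model, expr, "control_1")
        subsystems = {r.subsystem for r in ctx.model.reactions}
        assert "oxphos" in subsystems and "glycolysis" in subsystems

    def test_disease_sample_loses_or_shrinks_oxphos(self, cohort):
        model, expr, _ = cohort
        ctrl = build_context_model(model, expr, "control_1")
        dis = build_context_model(model, expr, "disease_1")
        n_ox = lambda ctx: sum(r.subsystem == "oxphos" for r in ctx.model.reactions)
        assert n_ox(dis) <= n_ox(ctrl)

    def test_all_genes_on_keeps_every_expressed_reaction(self, cohort):
        """Uniform high expression: the fit falls back to quantile thresholds,
        every gene is expressed, and the extraction keeps the whole core."""
        model, expr, _ = cohort
        import numpy as np

        from gemflux.expression import ExpressionMatrix

        n = len(expr.gene_ids)
        flat = ExpressionMatrix(expr.gene_ids, ["s"], np.full((n, 1), 1e6 / n))
        ctx = build_context_model(model, flat, "s")
        with_gpr = {r.id for r in model.reactions if r.gpr is not None}
        assert with_gpr <= ctx.kept_reactions
        assert fastcc_consistent(ctx.model) == ctx.kept_reactions


class TestTasks:
    def test_packaged_tasks_all_feasible_on_toy(self, toy_model):
        from pathlib import Path

        import gemflux

        tasks = load_tasks(Path(gemflux.__file__).parent / "data" / "brain_tasks.yaml")
        results = check_tasks(toy_model, tasks)
        assert all(r.feasible for r in results), [r.task_id for r in results if not r.feasible]

    def test_atp_synthase_knockout_breaks_aerobic_task(self, toy_model):
        for rid in ("ATPS", "PYK"):  # no oxidative and no substrate-level phosphorylation
            r = toy_model.get_reaction(rid)
            r.lower_bound = r.upper_bound = 0.0
        task = TaskDefinition(
            id="atp_aerobic",
            allowed_inputs={"glc_e": 1, "o2_e": 100, "adp_c": 1000},
            required_outputs={"atp_c": 2},
        )
        (res,) = check_tasks(toy_model, [task])
        assert not res.feasible

    def test_unknown_metabolite_reported_unsupported(self, toy_model):
        task = TaskDefinition(
            id="impossible", allowed_inputs={"glc_e": 1}, required_outputs={"glycogen_c": 1}
        )
        (res,) = check_tasks(toy_model, [task])
        assert not res.feasible and "unsupported" in res.reason

    def test_model_unmodified_by_task_check(self, toy_model):
        before = [(r.lower_bound, r.upper_bound) for r in toy_model.reactions]
        task = TaskDefinition(id="t", allowed_inputs={"glc_e": 1}, required_outputs={"lac_e": 1})
        check_tasks(toy_model, [task])
        after = [(r.lower_bound, r.upper_bound) for r in toy_model.reactions]
        assert before == after

    def test_task_requires_outputs(self):
        with pytest.raises(ValueError):
            TaskDefinition(id="empty", allowed_inputs={}, required_outputs={})
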