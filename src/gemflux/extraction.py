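"""Context-specific model extraction.

Pipeline: gene categories are mapped to reactions through GPR rules
(core / noncore / inactive), inactive reactions are removed, the
flux-inconsistent remainder is pruned, and a minimal flux-consistent
subnetwork containing every core reaction is extracted with the
FASTCORE-style pair of LPs:

* support LP (LP-7) — maximize the number of not-yet-supported core
  reactions that reach flux >= epsilon simultaneously, via auxiliary
  variables z_i <= v_i, 0 <= z_i <= epsilon;
* sparsity LP (LP-10) — holding the currently supported core reactions
  at >= epsilon, minimize the L1 norm of fluxes through the noncore
  penalty set (an LP surrogate for adding as few noncore reactions as
  possible).

Reversible core reactions that cannot be supported forward are retried
with flipped sign.  Functionality of extracted models is checked with
metabolic tasks: can the network produce stated outputs from stated
inputs with all exchanges closed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .expression import ExpressionMatrix, GeneDiscretization, discretize_genes, fit_expression_mixture
from .gpr import evaluate_discrete
from .model import MetabolicModel, stoichiometric_matrix

logger = logging.getLogger(__name__)


@dataclass
class CoreSets:
    """Partition of a model's reactions by expression evidence."""

    core: Set[str]
    noncore: Set[str]
    inactive: Set[str]


@dataclass
class ExtractionConfig:
    epsilon: float = 1e-4  # minimum |v| for a reaction to count as active
    scaling_factor: float = 1.0  # weight on the L1 penalty in the sparsity LP
    max_iterations: int = 100

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class ContextModel:
    model: MetabolicModel
    kept_reactions: Set[str]
    removed_reactions: Set[str]
    provenance: Dict[str, object] = field(default_factory=dict)


class InconsistentCoreError(ValueError):
    """A core reaction cannot carry flux in the flux-consistent model."""

    def __init__(self, reactions: Sequence[str]):
        self.reactions = sorted(reactions)
        super().__init__(f"core reactions unsupportable: {', '.join(self.reactions)}")


# ---- reaction classification ----------------------------------------------

def classify_reactions(model: MetabolicModel, disc: GeneDiscretization) -> CoreSets:
    """Map gene categories to reactions through the GPR rules.

    Rule value +1 -> core, 0 -> noncore, -1 -> inactive; reactions
    without a GPR carry no evidence and default to noncore.
    """
    core, noncore, inactive = set(), set(), set()
    for r in model.reactions:
        if r.gpr is None:
            noncore.add(r.id)
            continue
        value = evaluate_discrete(r.gpr, disc.category, default_missing=0)
        (core if value > 0 else inactive if value < 0 else noncore).add(r.id)
    return CoreSets(core=core, noncore=noncore, inactive=inactive)


# ---- flux-consistency (FASTCC-style) --------------------------------------

def _lp7(S, lb, ub, J: Sequence[int], signs: Optional[np.ndarray] = None, eps: float = 1e-4):
    """Support LP: maximize the number of reactions in J reaching flux eps.

    Variables [v, z]; maximize sum z, with 0 <= z_j <= eps and
    z_j <= s_j * v_j for the requested sign s_j (default +1).
    """
    m, n = S.shape
    k = len(J)
    if signs is None:
        signs = np.ones(k)
    A_eq = sparse.hstack([S, sparse.csc_matrix((m, k))], format="csc")
    rows, cols, data = [], [], []
    for r, (j, s) in enumerate(zip(J, signs)):
        rows += [r, r]
        cols += [n + r, j]
        data += [1.0, -float(s)]
    A_ub = sparse.csc_matrix((data, (rows, cols)), shape=(k, n + k))
    bounds = list(zip(lb, ub)) + [(0.0, eps)] * k
    cost = np.concatenate([np.zeros(n), -np.ones(k)])
    res = linprog(cost, A_ub=A_ub, b_ub=np.zeros(k), A_eq=A_eq,
                  b_eq=np.zeros(m), bounds=bounds, method="highs")
    if res.status != 0:
        return None
    return res.x[:n]


def fastcc_consistent(model: MetabolicModel, config: Optional[ExtractionConfig] = None) -> Set[str]:
    """Maximal set of reactions that can each carry |v| >= epsilon.

    Batched support LPs certify most reactions at once; anything left
    uncertified is settled by a targeted max/min LP, so the result
    coincides with the per-reaction flux-variability definition.
    """
    config = config or ExtractionConfig()
    eps = config.epsilon
    S = stoichiometric_matrix(model)
    m, n = S.shape
    if n == 0:
        return set()
    lb, ub = model.bounds_arrays()
    sup_tol = eps * (1.0 - 1e-6)

    consistent = np.zeros(n, dtype=bool)
    # batched passes: all reactions forward, then uncertified (both signs)
    # until no new certificates appear
    v = _lp7(S, lb, ub, list(range(n)), eps=eps)
    if v is None:
        raise RuntimeError("base model admits no steady state")
    consistent |= np.abs(v) >= sup_tol
    for _ in range(4):
        left = [j for j in range(n) if not consistent[j]]
        if not left:
            break
        before = consistent.sum()
        v = _lp7(S, lb, ub, left, eps=eps)
        if v is not None:
            consistent |= np.abs(v) >= sup_tol
        rev_left = [j for j in range(n) if not consistent[j] and lb[j] < 0]
        if rev_left:
            v = _lp7(S, lb, ub, rev_left, signs=-np.ones(len(rev_left)), eps=eps)
            if v is not None:
                consistent |= np.abs(v) >= sup_tol
        if consistent.sum() == before:
            break
    # targeted certificates for the remainder
    bounds = list(zip(lb, ub))
    e = np.zeros(n)
    for j in range(n):
        if consistent[j]:
            continue
        e[:] = 0
        e[j] = 1.0
        hi = linprog(-e, A_eq=S, b_eq=np.zeros(m), bounds=bounds, method="highs")
        if hi.status == 0:
            consistent |= np.abs(hi.x) >= sup_tol
        if consistent[j] or lb[j] >= 0:
            continue
        lo = linprog(e, A_eq=S, b_eq=np.zeros(m), bounds=bounds, method="highs")
        if lo.status == 0:
            consistent |= np.abs(lo.x) >= sup_tol
    rids = model.reaction_ids
    return {rids[j] for j in range(n) if consistent[j]}


def _removal_structurally_safe(rxn_by_id, trial: Set[str], removed) -> bool:
    """Cheap pre-filter: removing a reaction cannot leave any of its
    metabolites with consumers but no producer (or vice versa)."""
    for met in removed.stoichiometry:
        producers = consumers = 0
        for rid in trial:
            r = rxn_by_id[rid]
            coef = r.stoichiometry.get(met)
            if coef is None:
                continue
            rev = r.reversible
            if coef > 0 or rev:
                producers += 1
            if coef < 0 or rev:
                consumers += 1
        if (producers == 0) != (consumers == 0):
            return False
    return True


# ---- FASTCORE-style extraction --------------------------------------------

def _lp10(S, lb, ub, K: Sequence[int], signs: Dict[int, float], P: Sequence[int],
          eps: float, weight: float = 1.0, support_scale: float = 1e4):
    """Sparsity LP: min sum_{i in P} |v_i| s.t. supported core carries flux.

    The core constraint is scaled well above epsilon (``support_scale``)
    so the whole supporting pathway clears the support threshold even
    through unequal stoichiometric ratios; if the scaled problem is
    infeasible (tight bounds), the scale backs off geometrically.
    """
    m, n = S.shape
    p = len(P)
    A_eq = sparse.hstack([S, sparse.csc_matrix((m, p))], format="csc")
    rows, cols, data = [], [], []
    for r, j in enumerate(P):  # v_j - t_r <= 0 and -v_j - t_r <= 0
        rows += [2 * r, 2 * r, 2 * r + 1, 2 * r + 1]
        cols += [j, n + r, j, n + r]
        data += [1.0, -1.0, -1.0, -1.0]
    A_ub = sparse.csc_matrix((data, (rows, cols)), shape=(2 * p, n + p))
    big = float(max(np.abs(lb).max(initial=0.0), np.abs(ub).max(initial=0.0), 1.0))
    cost = np.concatenate([np.zeros(n), weight * np.ones(p)])
    scale = support_scale
    while scale >= 1.0:
        vb = [list(b) for b in zip(lb, ub)]
        for j in K:  # force supported core reactions to carry flux
            if signs.get(j, 1.0) >= 0:
                vb[j][0] = max(vb[j][0], eps * 0.99 * scale)
            else:
                vb[j][1] = min(vb[j][1], -eps * 0.99 * scale)
        bounds = [tuple(b) for b in vb] + [(0.0, big)] * p
        res = linprog(cost, A_ub=A_ub, b_ub=np.zeros(2 * p), A_eq=A_eq,
                      b_eq=np.zeros(m), bounds=bounds, method="highs")
        if res.status == 0:
            return res.x[:n]
        scale /= 100.0
    return None


def _lp10_weighted(S, lb, ub, K, signs, P, eps, weights):
    """Variant of the sparsity LP with per-reaction L1 weights."""
    m, n = S.shape
    p = len(P)
    A_eq = sparse.hstack([S, sparse.csc_matrix((m, p))], format="csc")
    rows, cols, data = [], [], []
    for r, j in enumerate(P):
        rows += [2 * r, 2 * r, 2 * r + 1, 2 * r + 1]
        cols += [j, n + r, j, n + r]
        data += [1.0, -1.0, -1.0, -1.0]
    A_ub = sparse.csc_matrix((data, (rows, cols)), shape=(2 * p, n + p))
    big = float(max(np.abs(lb).max(initial=0.0), np.abs(ub).max(initial=0.0), 1.0))
    scale = 1e4
    while scale >= 1.0:
        vb = [list(b) for b in zip(lb, ub)]
        for j in K:
            if signs.get(j, 1.0) >= 0:
                vb[j][0] = max(vb[j][0], eps * 0.99 * scale)
            else:
                vb[j][1] = min(vb[j][1], -eps * 0.99 * scale)
        bounds = [tuple(b) for b in vb] + [(0.0, big)] * p
        cost = np.concatenate([np.zeros(n), np.array([weights[j] for j in P])])
        res = linprog(cost, A_ub=A_ub, b_ub=np.zeros(2 * p), A_eq=A_eq,
                      b_eq=np.zeros(m), bounds=bounds, method="highs")
        if res.status == 0:
            return res.x[:n]
        scale /= 100.0
    return None


def fastcore_extract(
    core: Iterable[str],
    model: MetabolicModel,
    config: Optional[ExtractionConfig] = None,
) -> ContextModel:
    """Minimal flux-consistent subnetwork containing every core reaction.

    ``model`` must already be flux-consistent (inactive reactions removed
    and :func:`fastcc_consistent` applied) and ``core`` a subset of its
    reactions; otherwise :class:`InconsistentCoreError` is raised for
    the unsupportable core reactions.
    """
    config = config or ExtractionConfig()
    eps = config.epsilon
    sup_tol = eps * 0.9
    rids = model.reaction_ids
    ridx = model.reaction_index()
    core_ids = set(core)
    unknown = core_ids - set(rids)
    if unknown:
        raise ValueError(f"core reactions not in model: {sorted(unknown)}")
    if not core_ids:
        return ContextModel(
            model=model.subnetwork([], model_id=f"{model.id}_ctx"),
            kept_reactions=set(),
            removed_reactions=set(rids),
            provenance={"core_size": 0, "added": 0},
        )

    S = stoichiometric_matrix(model)
    lb, ub = model.bounds_arrays()
    n = S.shape[1]
    C = sorted(ridx[r] for r in core_ids)
    irrev = lb >= 0
    P_all = [j for j in range(n) if rids[j] not in core_ids]

    A: Set[int] = set()
    signs: Dict[int, float] = {}

    def find_sparse_mode(J: List[int], flip: Dict[int, float]) -> Set[int]:
        sg = np.array([flip.get(j, 1.0) for j in J])
        v7 = _lp7(S, lb, ub, J, signs=sg, eps=eps)
        if v7 is None:
            return set()
        K = [j for j, s in zip(J, sg) if s * v7[j] >= sup_tol]
        if not K:
            return set()
        for j, s in zip(J, sg):
            if j in K:
                signs[j] = s
        v10 = _lp10(S, lb, ub, K, signs, [j for j in P_all if j not in A], eps,
                    weight=config.scaling_factor)
        if v10 is None:
            return set()
        return {j for j in range(n) if abs(v10[j]) >= sup_tol}

    flip: Dict[int, float] = {}
    J = [j for j in C if irrev[j]]
    if J:
        A |= find_sparse_mode(J, flip)
        missing = [j for j in J if j not in A]
        if missing:
            raise InconsistentCoreError([rids[j] for j in missing])
    J = [j for j in C if j not in A]
    flipped = False
    singleton = False
    iterations = 0
    while J:
        iterations += 1
        if iterations > config.max_iterations * max(1, len(C)):
            raise InconsistentCoreError([rids[j] for j in J])
        target = [J[0]] if singleton else J
        new = find_sparse_mode(target, flip)
        if new & set(J):
            A |= new
            J = [j for j in J if j not in A]
            flipped = False
            continue
        A |= new
        if flipped:
            flipped = False
            if singleton:
                raise InconsistentCoreError([rids[J[0]]])
            singleton = True
        else:
            rev_targets = [j for j in target if not irrev[j]]
            if not rev_targets:
                if singleton or all(irrev[j] for j in target):
                    raise InconsistentCoreError([rids[j] for j in target])
                singleton = True
                continue
            for j in rev_targets:
                flip[j] = -flip.get(j, 1.0)
            flipped = True

    # global polish: iteratively re-weighted L1 over the full core (signs
    # fixed by the main loop) concentrates flux on few noncore reactions,
    # escaping supports the plain L1 surrogate picks sub-optimally
    base_signs = {j: signs.get(j, 1.0) for j in C}
    sign_variants = [dict(base_signs)]
    for j in C:  # reversible core reactions may support a sparser flipped mode
        if not irrev[j]:
            flipped_signs = dict(base_signs)
            flipped_signs[j] = -flipped_signs[j]
            sign_variants.append(flipped_signs)
    best = set(A)
    for core_signs in sign_variants:
        weights = {j: 1.0 for j in P_all}
        for _ in range(3):
            v = _lp10_weighted(S, lb, ub, C, core_signs, P_all, eps, weights)
            if v is None:
                break
            support = {j for j in range(n) if abs(v[j]) >= eps * 0.9} | set(C)
            if len(support) < len(best):
                best = support
            weights = {j: 1.0 / (abs(v[j]) + eps) for j in P_all}
    if len(best) < len(A):
        A = best

    kept = {rids[j] for j in sorted(A)}
    # greedy redundancy elimination: the L1 surrogate can pick a slightly
    # larger support than necessary; drop added reactions (fixed order)
    # whenever the subnetwork stays flux-consistent with the core intact
    rxn_by_id = {r.id: r for r in model.reactions}
    for rid in sorted(kept - core_ids):
        trial = kept - {rid}
        if not trial:
            continue
        if not _removal_structurally_safe(rxn_by_id, trial, rxn_by_id[rid]):
            continue
        sub_try = model.subnetwork(trial)
        if fastcc_consistent(sub_try, config) == trial:
            kept = trial
    removed = set(rids) - kept
    sub = model.subnetwork(kept, model_id=f"{model.id}_ctx")
    return ContextModel(
        model=sub,
        kept_reactions=kept,
        removed_reactions=removed,
        provenance={
            "core_size": len(core_ids),
            "added": len(kept - core_ids),
            "epsilon": eps,
        },
    )


# ---- end-to-end builder ----------------------------------------------------

def build_context_model(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    sample_id: str,
    config: Optional[ExtractionConfig] = None,
    z_margin: float = 1.0,
    pooled_fit: bool = False,
    seed: int = 0,
) -> ContextModel:
    """Discretize -> classify -> drop inactive -> prune -> extract.

    With ``pooled_fit`` the mixture is fitted on all samples' values
    jointly instead of per sample.  Core reactions that the pruning step
    reveals to be blocked are demoted (with a log message) rather than
    failing the build, since unexpressed neighbours can legitimately cut
    an expressed reaction off from the network.
    """
    config = config or ExtractionConfig()
    log2_vals = (
        np.log2(expr.tpm + 1.0).ravel() if pooled_fit else np.log2(expr.sample_column(sample_id) + 1.0)
    )
    params = fit_expression_mixture(log2_vals, seed=seed)
    disc = discretize_genes(expr, sample_id, params, z_margin=z_margin)
    sets = classify_reactions(model, disc)
    active = model.subnetwork(sets.core | sets.noncore, model_id=f"{model.id}_{sample_id}")
    consistent = fastcc_consistent(active, config)
    pruned = active.subnetwork(consistent, model_id=active.id)
    core = sets.core & consistent
    dropped_core = sets.core - consistent
    if dropped_core:
        logger.info("%s: %d core reactions blocked after pruning", sample_id, len(dropped_core))
    ctx = fastcore_extract(core, pruned, config)
    n_genes = {g for r in ctx.model.reactions if r.gpr is not None for g in r.gpr.genes()}
    ctx.provenance.update(
        {
            "sample_id": sample_id,
            "z_margin": z_margin,
            "pooled_fit": pooled_fit,
            "n_core": len(sets.core),
            "n_noncore": len(sets.noncore),
            "n_inactive": len(sets.inactive),
            "n_expressed_genes": sum(1 for c in disc.category.values() if c == 1),
            "n_unexpressed_genes": sum(1 for c in disc.category.values() if c == -1),
            "n_reactions": len(ctx.model.reactions),
            "n_metabolites": len(ctx.model.metabolites),
            "n_active_genes": len(n_genes),
        }
    )
    # carry the parent objective so downstream FBA works on the context model
    if not ctx.model.objective:
        ctx.model.objective = {
            k: v for k, v in model.objective.items() if k in ctx.kept_reactions
        }
    return ctx


# ---- metabolic tasks -------------------------------------------------------

@dataclass
class TaskDefinition:
    """A feasibility probe: produce the outputs from the inputs alone."""

    id: str
    allowed_inputs: Dict[str, float]  # metabolite -> max uptake
    required_outputs: Dict[str, float]  # metabolite -> min production
    description: str = ""

    def __post_init__(self):
        if not self.required_outputs:
            raise ValueError(f"task {self.id!r} has no required outputs")


@dataclass
class TaskResult:
    task_id: str
    feasible: bool
    reason: str = ""


def load_tasks(path) -> List[TaskDefinition]:
    """Read task definitions from a YAML/JSON list."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    return [
        TaskDefinition(
            id=t["id"],
            allowed_inputs={str(k): float(v) for k, v in (t.get("inputs") or {}).items()},
            required_outputs={str(k): float(v) for k, v in (t.get("outputs") or {}).items()},
            description=t.get("description", ""),
        )
        for t in doc
    ]


def check_tasks(model: MetabolicModel, tasks: Sequence[TaskDefinition]) -> List[TaskResult]:
    """LP feasibility of each task with all exchanges closed.

    Allowed inputs re-open the metabolite's exchange reaction for uptake
    at the stated maximum — but never beyond the model's own uptake
    capacity, so a respirometry-capped oxygen exchange stays capped.
    Metabolites without an exchange (e.g. internal redox carriers) get a
    temporary injection column instead.  Required outputs analogously
    become demands at the stated minima.  The model is not modified.
    Tasks naming metabolites absent from the model are reported
    infeasible with reason "unsupported".
    """
    S = stoichiometric_matrix(model)
    m, n = S.shape
    orig_lb, orig_ub = model.bounds_arrays()
    midx = model.metabolite_index()
    # map boundary metabolite -> (column, stoichiometric sign)
    exchange_of: Dict[str, Tuple[int, float]] = {}
    for j, r in enumerate(model.reactions):
        if r.is_exchange and len(r.stoichiometry) == 1:
            (mid, coef), = r.stoichiometry.items()
            exchange_of.setdefault(mid, (j, float(coef)))
    results: List[TaskResult] = []
    big = 1e6
    for task in tasks:
        missing = [mid for mid in list(task.allowed_inputs) + list(task.required_outputs) if mid not in midx]
        if missing:
            results.append(TaskResult(task.id, False, f"unsupported: {', '.join(sorted(set(missing)))}"))
            continue
        lb = orig_lb.copy()
        ub = orig_ub.copy()
        for j, r in enumerate(model.reactions):
            if r.is_exchange:
                lb[j] = 0.0
                ub[j] = 0.0
        cols, col_bounds = [], []
        feasible_setup = True
        for mid, cap in task.allowed_inputs.items():
            if mid in exchange_of:
                j, coef = exchange_of[mid]
                # uptake direction: flux of sign -coef produces the metabolite
                capacity = max(0.0, -orig_lb[j]) if coef < 0 else max(0.0, orig_ub[j])
                allowed = min(float(cap), capacity)
                if coef < 0:
                    lb[j] = -allowed
                else:
                    ub[j] = allowed
            else:
                cols.append(sparse.csc_matrix(([1.0], ([midx[mid]], [0])), shape=(m, 1)))
                col_bounds.append((0.0, float(cap)))
        for mid, minimum in task.required_outputs.items():
            cols.append(sparse.csc_matrix(([-1.0], ([midx[mid]], [0])), shape=(m, 1)))
            col_bounds.append((float(minimum), big))
        A = sparse.hstack([S] + cols, format="csc") if cols else S
        bounds = list(zip(lb, ub)) + col_bounds
        res = linprog(
            np.zeros(A.shape[1]), A_eq=A, b_eq=np.zeros(m), bounds=bounds, method="highs"
        )
        ok = feasible_setup and res.status == 0
        results.append(TaskResult(task.id, ok, "" if ok else "infeasible"))
    return results
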