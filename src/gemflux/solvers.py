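"""Linear-programming machinery for steady-state flux analysis.

All solvers operate on the polytope {v : S v = 0, lb <= v <= ub} and are
backed by scipy's HiGHS interface:

* :func:`fba` — maximize the linear objective c.v (flux balance analysis).
* :func:`pfba` — fix the objective at a fraction of its optimum and
  minimize total absolute flux, making the reported distribution
  canonical at degenerate optima (parsimonious FBA).
* :func:`fva` — per-reaction flux minima/maxima at a stated fraction of
  the optimum (flux variability analysis).
* :func:`sample_fluxes` — hit-and-run sampling of the polytope in
  null-space coordinates, warm-started from FVA extreme solutions.

Numerical conventions: solver feasibility/optimality tolerances are the
HiGHS defaults (~1e-9/1e-7); equality comparisons downstream use 1e-6.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import FluxDistribution, MetabolicModel, stoichiometric_matrix

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}

FEAS_TOL = 1e-9
EQ_TOL = 1e-6


def _solve(c, A_eq=None, b_eq=None, A_ub=None, b_ub=None, bounds=None, method="highs"):
    return linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method=method
    )


def _objective_vector(model: MetabolicModel, objective: Optional[Dict[str, float]]) -> np.ndarray:
    obj = objective if objective is not None else model.objective
    c = np.zeros(len(model.reactions))
    ridx = model.reaction_index()
    for rid, w in obj.items():
        c[ridx[rid]] = float(w)
    return c


def fba(
    model: MetabolicModel,
    objective: Optional[Dict[str, float]] = None,
    method: str = "highs",
) -> FluxDistribution:
    """Maximize c.v subject to S v = 0 and bounds.

    Infeasibility/unboundedness is reported in ``status``, not raised.
    """
    S = stoichiometric_matrix(model)
    lb, ub = model.bounds_arrays()
    c = _objective_vector(model, objective)
    res = _solve(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method=method)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=float("nan"), status=status)
    return FluxDistribution(
        fluxes=dict(zip(model.reaction_ids, res.x)),
        objective_value=float(c @ res.x),
        status="optimal",
    )


def pfba(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    objective: Optional[Dict[str, float]] = None,
    method: str = "highs",
) -> FluxDistribution:
    """Parsimonious FBA: minimal total |v| at >= fraction of the FBA optimum.

    Stage 1 computes the optimum; stage 2 adds auxiliary variables t >= |v|
    and minimizes sum(t) subject to c.v >= fraction * optimum.
    """
    stage1 = fba(model, objective=objective, method=method)
    if stage1.status != "optimal":
        return stage1
    S = stoichiometric_matrix(model)
    m, n = S.shape
    lb, ub = model.bounds_arrays()
    c = _objective_vector(model, objective)
    # variables [v, t]; t_i >= |v_i|
    A_eq = sparse.hstack([S, sparse.csc_matrix((m, n))], format="csc")
    eye = sparse.identity(n, format="csc")
    A_ub = sparse.vstack(
        [
            sparse.hstack([eye, -eye]),   # v - t <= 0
            sparse.hstack([-eye, -eye]),  # -v - t <= 0
            sparse.csc_matrix(np.concatenate([-c, np.zeros(n)])[None, :]),
        ],
        format="csc",
    )
    b_ub = np.concatenate([np.zeros(2 * n), [-fraction_of_optimum * stage1.objective_value]])
    big = float(np.abs(np.concatenate([lb, ub])).max() or 1.0)
    bounds = list(zip(lb, ub)) + [(0.0, big)] * n
    cost = np.concatenate([np.zeros(n), np.ones(n)])
    res = _solve(cost, A_eq=A_eq, b_eq=np.zeros(m), A_ub=A_ub, b_ub=b_ub, bounds=bounds, method=method)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=float("nan"), status="infeasible")
    v = res.x[:n]
    return FluxDistribution(
        fluxes=dict(zip(model.reaction_ids, v)),
        objective_value=float(c @ v),
        status="optimal",
    )


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a stated fraction of the optimum."""

    minimum: Dict[str, float]
    maximum: Dict[str, float]
    fraction: float

    def range(self, rid: str):
        return self.minimum[rid], self.maximum[rid]

    def to_frame(self):
        import pandas as pd

        rids = list(self.minimum)
        return pd.DataFrame(
            {
                "reaction_id": rids,
                "minimum": [self.minimum[r] for r in rids],
                "maximum": [self.maximum[r] for r in rids],
            }
        )


def fva(
    model: MetabolicModel,
    reactions: Optional[Iterable[str]] = None,
    fraction_of_optimum: float = 1.0,
    objective: Optional[Dict[str, float]] = None,
    method: str = "highs",
    _return_solutions: bool = False,
):
    """Min and max flux per reaction subject to c.v >= fraction * optimum."""
    S = stoichiometric_matrix(model)
    m, n = S.shape
    lb, ub = model.bounds_arrays()
    bounds = list(zip(lb, ub))
    c = _objective_vector(model, objective)
    A_ub = b_ub = None
    if fraction_of_optimum > 0 and np.any(c):
        stage1 = fba(model, objective=objective, method=method)
        if stage1.status != "optimal":
            raise RuntimeError(f"FVA requires an optimal base solution, got {stage1.status}")
        A_ub = sparse.csc_matrix(-c[None, :])
        b_ub = np.array([-fraction_of_optimum * stage1.objective_value])
    ridx = model.reaction_index()
    targets = list(reactions) if reactions is not None else model.reaction_ids
    vmin: Dict[str, float] = {}
    vmax: Dict[str, float] = {}
    solutions: List[np.ndarray] = []
    e = np.zeros(n)
    for rid in targets:
        j = ridx[rid]
        e[:] = 0
        e[j] = 1.0
        hi = _solve(-e, A_eq=S, b_eq=np.zeros(m), A_ub=A_ub, b_ub=b_ub, bounds=bounds, method=method)
        lo = _solve(e, A_eq=S, b_eq=np.zeros(m), A_ub=A_ub, b_ub=b_ub, bounds=bounds, method=method)
        if hi.status != 0 or lo.status != 0:
            raise RuntimeError(f"FVA subproblem for {rid} did not solve (status {hi.status}/{lo.status})")
        vmax[rid] = float(hi.x[j])
        vmin[rid] = float(lo.x[j])
        if vmin[rid] > vmax[rid]:  # numerical inversion only
            vmin[rid] = vmax[rid] = 0.5 * (vmin[rid] + vmax[rid])
        if _return_solutions:
            solutions.append(hi.x.copy())
            solutions.append(lo.x.copy())
    result = FVAResult(minimum=vmin, maximum=vmax, fraction=fraction_of_optimum)
    if _return_solutions:
        return result, solutions
    return result


@dataclass
class SampleEnsemble:
    """Steady-state flux samples: rows satisfy S v = 0 and the bounds."""

    samples: np.ndarray  # n_samples x n_reactions
    reaction_ids: List[str]
    seed: int
    method: str = "hit_and_run"
    thinning: int = 100

    def column(self, rid: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rid)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.samples, columns=self.reaction_ids)


def sample_fluxes(
    model: MetabolicModel,
    n_samples: int,
    seed: int,
    thinning: int = 100,
    method: str = "hit_and_run",
) -> SampleEnsemble:
    """Hit-and-run sampling of the steady-state polytope.

    Directions are drawn in the null space of S so every iterate keeps
    S v = 0; the chain is warm-started from the average of FVA extreme
    solutions (a relative-interior point).  ``method='achr'`` draws
    directions through the running sample center instead of isotropically.
    Reproducible for a fixed seed.
    """
    if method not in ("hit_and_run", "achr"):
        raise ValueError(f"unknown sampling method {method!r}")
    S = stoichiometric_matrix(model)
    lb, ub = model.bounds_arrays()
    n = S.shape[1]
    check = fba(model, objective={})
    if check.status != "optimal":
        raise RuntimeError("cannot sample: the flux polytope is empty")

    # warm-up: FVA extreme solutions (capped) give a relative-interior start
    max_warm = min(n, 20)
    _, extremes = fva(model, reactions=model.reaction_ids[:max_warm], fraction_of_optimum=0.0, _return_solutions=True)
    v0 = np.mean(extremes, axis=0)

    from scipy.linalg import null_space

    N = null_space(S.toarray())
    if N.size == 0:  # fully determined: the polytope is a single point
        samples = np.tile(v0, (n_samples, 1))
        return SampleEnsemble(samples=samples, reaction_ids=model.reaction_ids, seed=seed,
                              method=method, thinning=thinning)
    k = N.shape[1]
    rng = np.random.default_rng(int(seed))
    v = v0.copy()
    samples = np.empty((n_samples, n))
    center = v0.copy()
    n_recorded = 0
    step = 0
    margin = 1e-12
    while n_recorded < n_samples:
        step += 1
        if method == "achr" and n_recorded > 1:
            ref = samples[rng.integers(0, n_recorded)]
            d = ref - center
            d = N @ (N.T @ d)  # project into the null space
        else:
            d = N @ rng.standard_normal(k)
        norm = np.linalg.norm(d)
        t = 0.0
        if norm >= 1e-12:
            d /= norm
            with np.errstate(divide="ignore", invalid="ignore"):
                t_lo = (lb - v) / d
                t_hi = (ub - v) / d
            pos = d > 1e-11
            neg = d < -1e-11
            t_min = max(
                np.max(t_lo[pos], initial=-np.inf), np.max(t_hi[neg], initial=-np.inf)
            )
            t_max = min(
                np.min(t_hi[pos], initial=np.inf), np.min(t_lo[neg], initial=np.inf)
            )
            # a degenerate segment (box-fixed point) counts as a zero-step so
            # the chain always advances toward its sample quota
            if np.isfinite(t_min) and np.isfinite(t_max) and t_max - t_min >= margin:
                t = rng.uniform(t_min, t_max)
        v = v + t * d if t != 0.0 else v
        # counter drift: re-project into the affine space and clip to bounds
        if step % 512 == 0:
            v = v0 + N @ (N.T @ (v - v0))
        np.clip(v, lb, ub, out=v)
        if step % thinning == 0:
            samples[n_recorded] = v
            if method == "achr":
                center = (center * (n_recorded + 1) + v) / (n_recorded + 2)
            n_recorded += 1
    return SampleEnsemble(
        samples=samples,
        reaction_ids=model.reaction_ids,
        seed=int(seed),
        method=method,
        thinning=thinning,
    )


def verify_ensemble(model: MetabolicModel, ensemble: SampleEnsemble,
                    sv_tol: float = 1e-6, bound_tol: float = 1e-9) -> None:
    """Raise if any sample violates S v = 0 (sv_tol) or the bounds (bound_tol)."""
    S = stoichiometric_matrix(model)
    lb, ub = model.bounds_arrays()
    resid = np.abs(S @ ensemble.samples.T).max() if ensemble.samples.size else 0.0
    if resid > sv_tol:
        raise AssertionError(f"steady-state residual {resid:.2e} exceeds {sv_tol:.0e}")
    if ensemble.samples.size:
        lo_viol = (lb[None, :] - ensemble.samples).max()
        hi_viol = (ensemble.samples - ub[None, :]).max()
        if max(lo_viol, hi_viol) > bound_tol:
            raise AssertionError("sampled fluxes violate bounds")
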