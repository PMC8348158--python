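"""Expression- and respirometry-derived flux bounds.

E-Flux maps continuous gene expression onto reaction capacity: each
reaction's score (its GPR evaluated over expression levels, isozymes
summing) is divided by the model's maximum score and scaled by v_max to
give a new upper bound; reversible reactions get the mirrored lower
bound.  Reactions without expression evidence are untouched, so absence
of a GPR never closes transport or spontaneous reactions.

Measured oxygen consumption (high-resolution respirometry, pmol O2 s^-1
mg protein^-1) caps the oxygen exchange uptake through a single
configurable unit-conversion scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from .gpr import evaluate_continuous
from .model import MetabolicModel

RESPIROMETRY_STATES = ("routine", "oxphos", "max_ox", "atp_link", "max_u", "rox")


@dataclass
class BoundedModel:
    """A model with bound overrides plus a log of what was changed."""

    model: MetabolicModel
    normalization_max: float
    applied_constraints: List[Tuple[str, Tuple[float, float], Tuple[float, float]]] = field(
        default_factory=list
    )

    def constraint_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"reaction_id": rid, "old_lb": old[0], "old_ub": old[1],
                 "new_lb": new[0], "new_ub": new[1]}
                for rid, old, new in self.applied_constraints
            ]
        )


@dataclass
class RespirometryMeasurement:
    group: str
    state: str  # one of RESPIROMETRY_STATES
    oxygen_flux: float  # pmol O2 / s / mg protein, ROX-corrected

    def __post_init__(self):
        if self.state not in RESPIROMETRY_STATES:
            raise ValueError(f"unknown respirometry state {self.state!r}")
        if self.oxygen_flux < 0:
            raise ValueError("oxygen flux must be non-negative after ROX correction")


def reaction_scores(
    model: MetabolicModel,
    levels: Mapping[str, float],
    or_mode: str = "sum",
) -> Dict[str, float]:
    """Continuous GPR evaluation per reaction (no-GPR reactions omitted)."""
    scores: Dict[str, float] = {}
    for r in model.reactions:
        if r.gpr is not None:
            scores[r.id] = evaluate_continuous(r.gpr, levels, or_mode=or_mode)
    return scores


def eflux_bounds(
    model: MetabolicModel,
    reaction_scores: Mapping[str, float],
    v_max: float = 1000.0,
) -> BoundedModel:
    """Cap bounds of scored reactions at v_max * score / max(score).

    Scale-invariant in the scores; a zero score closes the reaction;
    unscored reactions keep their bounds.  New bounds never exceed the
    original magnitudes.
    """
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    bad = [r for r, s in reaction_scores.items() if s < 0]
    if bad:
        raise ValueError(f"negative reaction scores: {sorted(bad)}")
    max_score = max(reaction_scores.values(), default=0.0)
    if max_score <= 0:
        raise ValueError("all reaction scores are zero; cannot normalize")
    bounded = model.copy()
    log: List[Tuple[str, Tuple[float, float], Tuple[float, float]]] = []
    for r in bounded.reactions:
        if r.id not in reaction_scores:
            continue
        cap = v_max * reaction_scores[r.id] / max_score
        old = (r.lower_bound, r.upper_bound)
        new_ub = min(r.upper_bound, cap)
        new_lb = max(r.lower_bound, -cap) if r.lower_bound < 0 else max(r.lower_bound, 0.0)
        if new_ub < new_lb:  # can only happen for forced-flux reactions
            new_lb = new_ub
        r.lower_bound, r.upper_bound = new_lb, new_ub
        log.append((r.id, old, (new_lb, new_ub)))
    return BoundedModel(model=bounded, normalization_max=max_score, applied_constraints=log)


def apply_respirometry(
    model: MetabolicModel,
    measurement: RespirometryMeasurement,
    scale: float,
    oxygen_exchange_id: str = "EX_o2",
) -> BoundedModel:
    """Cap oxygen uptake at scale * measured flux.

    Uptake is the negative direction of the oxygen exchange; the cap is
    only ever a tightening, and other bounds are untouched.
    """
    bounded = model.copy()
    try:
        rxn = bounded.get_reaction(oxygen_exchange_id)
    except KeyError:
        raise ValueError(f"model has no oxygen exchange reaction {oxygen_exchange_id!r}")
    old = (rxn.lower_bound, rxn.upper_bound)
    cap = scale * measurement.oxygen_flux
    rxn.lower_bound = max(rxn.lower_bound, -cap)
    if rxn.upper_bound < rxn.lower_bound:
        rxn.upper_bound = rxn.lower_bound
    return BoundedModel(
        model=bounded,
        normalization_max=float("nan"),
        applied_constraints=[(oxygen_exchange_id, old, (rxn.lower_bound, rxn.upper_bound))],
    )


def read_respirometry_tsv(path, sep: str = "\t") -> List[RespirometryMeasurement]:
    df = pd.read_csv(path, sep=sep)
    return [
        RespirometryMeasurement(
            group=str(row["group"]), state=str(row["state"]), oxygen_flux=float(row["oxygen_flux"])
        )
        for _, row in df.iterrows()
    ]
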