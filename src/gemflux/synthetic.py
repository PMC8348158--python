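"""Synthetic study data with known ground truth.

Three generators stand in for the study inputs so the whole pipeline is
testable offline:

* :func:`make_toy_model` — a hand-designed brain-energetics network
  (~48 reactions, 3 compartments) with glycolysis, TCA cycle, OXPHOS
  (separate complex-I, complex-II, glycerol-3-phosphate shuttle and ATP
  synthase), fatty-acid beta-oxidation, glutamate anaplerosis and a
  phosphocreatine buffer.  Proton/redox bookkeeping is chosen so ATP
  yields are auditable integers: 32 ATP per glucose aerobically, 2
  anaerobically, 106 per palmitate-like fatty acid, 10 per glutamate.
* :func:`simulate_expression` — negative-binomial RNA-seq counts for a
  three-group design (control / disease / treated, n per group), with
  disease down-regulation concentrated in configurable subsystems and
  partial restoration in the treated group.
* :func:`simulate_respirometry` — matching noisy oxygen-flux
  measurements ordered disease < treated < control.

Baseline log2 abundances are right-skewed for expressed genes and
left-skewed for silent ones, mimicking the heavy upper tail and
zero-inflated floor of real RNA-seq and keeping both populations inside
the mixture-derived discretization thresholds.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .constraints import RespirometryMeasurement
from .expression import ExpressionMatrix, tpm_from_counts
from .model import MetabolicModel, Metabolite, Reaction

# designed integer yields, fixed by the network's construction
ATP_PER_GLUCOSE_AEROBIC = 32
ATP_PER_GLUCOSE_ANAEROBIC = 2
ATP_PER_FATTY_ACID = 106
ATP_PER_GLUTAMATE = 10
O2_PER_GLUCOSE = 6


@dataclass
class SyntheticCohortConfig:
    n_per_group: int = 3
    groups: Tuple[str, str, str] = ("control", "disease", "treated")
    down_subsystems: Tuple[str, ...] = ("oxphos", "glycolysis", "fatty_acid_oxidation")
    disease_fold: float = 0.25
    treated_fold: float = 0.6
    nb_dispersion: float = 0.005
    library_size_range: Tuple[int, int] = (700_000, 1_000_000)
    seed: int = 0
    # background (non-model) genes pad the expression distribution so the
    # two-Gaussian fit sees a realistic bimodal transcriptome
    n_background_on: int = 300
    n_background_off: int = 200
    on_log2_floor: float = 3.0
    on_log2_scale: float = 1.0
    off_log2_ceiling: float = -6.0
    off_log2_scale: float = 1.0
    respirometry_base: float = 100.0  # pmol O2 / s / mg protein
    respirometry_noise_sd: float = 4.0

    def __post_init__(self):
        if not (0 < self.disease_fold <= self.treated_fold <= 1):
            raise ValueError("require 0 < disease_fold <= treated_fold <= 1")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


@dataclass
class GroundTruth:
    """Generator ground truth used as the oracle for recovery tests."""

    gene_state: Dict[Tuple[str, str], Dict[str, object]]  # (group, gene) -> {on, fold}
    expected_direction: Dict[Tuple[str, str], str]  # (group, subsystem) -> down|up|unchanged

    def on_genes(self, group: str) -> Set[str]:
        return {g for (grp, g), st in self.gene_state.items() if grp == group and st["on"]}

    def off_genes(self, group: str) -> Set[str]:
        return {g for (grp, g), st in self.gene_state.items() if grp == group and not st["on"]}


def _rxn(rid, stoich, lb=0.0, ub=1000.0, gpr=None, subsystem=None, name=""):
    return Reaction(
        id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
        gpr_text=gpr, subsystem=subsystem, name=name or rid,
    )


def make_toy_model() -> MetabolicModel:
    """Deterministic brain-energetics toy network.

    Proton stoichiometry (complex I pumps 4 H+, the lumped complex
    III+IV 6 H+ per quinol, ATP synthase uses 4 H+ per ATP) gives the
    textbook 32 ATP per glucose with the malate-aspartate shuttle.  The
    glycerol-3-phosphate shuttle bypasses complex I, so knocking out
    complex I leaves aerobic ATP production feasible at reduced yield
    through complex II and the shuttle.
    """
    compartments = {"e": "extracellular", "c": "cytosol", "m": "mitochondrion"}
    mets = []
    for mid, comp in [
        ("glc_e", "e"), ("o2_e", "e"), ("lac_e", "e"), ("fa_e", "e"), ("glu_e", "e"),
        ("pcr_e", "e"), ("cr_e", "e"), ("co2_e", "e"), ("h2o_e", "e"), ("nh4_e", "e"),
        ("pyr_e", "e"),
        ("glc_c", "c"), ("g3p_c", "c"), ("pg3_c", "c"), ("pyr_c", "c"), ("lac_c", "c"),
        ("nad_c", "c"), ("nadh_c", "c"), ("atp_c", "c"), ("adp_c", "c"), ("fa_c", "c"),
        ("glu_c", "c"), ("pcr_c", "c"), ("cr_c", "c"), ("co2_c", "c"), ("h2o_c", "c"),
        ("o2_c", "c"), ("nh4_c", "c"),
        ("pyr_m", "m"), ("accoa_m", "m"), ("akg_m", "m"), ("nad_m", "m"), ("nadh_m", "m"),
        ("fad_m", "m"), ("fadh2_m", "m"), ("q_m", "m"), ("qh2_m", "m"), ("h_i", "m"),
        ("atp_m", "m"), ("adp_m", "m"), ("o2_m", "m"), ("co2_m", "m"), ("h2o_m", "m"),
        ("glu_m", "m"), ("fa_m", "m"), ("facoa_m", "m"), ("nh4_m", "m"),
    ]:
        mets.append(Metabolite(id=mid, name=mid, compartment=comp))

    R = [
        # exchanges (negative flux = uptake)
        _rxn("EX_glc", {"glc_e": -1}, lb=-10, subsystem="exchange"),
        _rxn("EX_o2", {"o2_e": -1}, lb=-1000, subsystem="exchange"),
        _rxn("EX_fa", {"fa_e": -1}, lb=-2, subsystem="exchange"),
        _rxn("EX_glu", {"glu_e": -1}, lb=-2, subsystem="exchange"),
        _rxn("EX_pcr", {"pcr_e": -1}, lb=-5, subsystem="exchange"),
        _rxn("EX_lac", {"lac_e": -1}, subsystem="exchange"),
        _rxn("EX_pyr", {"pyr_e": -1}, subsystem="exchange"),
        _rxn("EX_cr", {"cr_e": -1}, subsystem="exchange"),
        _rxn("EX_co2", {"co2_e": -1}, subsystem="exchange"),
        _rxn("EX_h2o", {"h2o_e": -1}, subsystem="exchange"),
        _rxn("EX_nh4", {"nh4_e": -1}, subsystem="exchange"),
        # transport
        _rxn("GLCt", {"glc_e": -1, "glc_c": 1}, gpr="gSlc2a1 or gSlc2a3", subsystem="transport"),
        _rxn("O2t", {"o2_e": -1, "o2_c": 1}, subsystem="transport"),
        _rxn("O2tm", {"o2_c": -1, "o2_m": 1}, subsystem="transport"),
        _rxn("LACt", {"lac_c": -1, "lac_e": 1}, gpr="gSlc16a1", subsystem="transport"),
        _rxn("PYRte", {"pyr_c": -1, "pyr_e": 1}, gpr="gSlc16a7", subsystem="transport"),
        _rxn("PYRtm", {"pyr_c": -1, "pyr_m": 1}, gpr="gMpc1 and gMpc2", subsystem="transport"),
        _rxn("FAt", {"fa_e": -1, "fa_c": 1}, gpr="gCd36", subsystem="transport"),
        _rxn("FAtm", {"fa_c": -1, "fa_m": 1}, gpr="gCpt1a and gCpt2", subsystem="transport"),
        _rxn("GLUt", {"glu_e": -1, "glu_c": 1}, gpr="gSlc1a3", subsystem="transport"),
        _rxn("GLUtm", {"glu_c": -1, "glu_m": 1}, gpr="gSlc25a22", subsystem="transport"),
        _rxn("ANT", {"atp_m": -1, "adp_c": -1, "atp_c": 1, "adp_m": 1},
             gpr="gSlc25a4", subsystem="transport", name="adenine nucleotide translocase"),
        _rxn("MAS", {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1}, lb=-1000,
             gpr="gGot1 and gGot2 and gMdh1", subsystem="transport",
             name="malate-aspartate shuttle (lumped, reversible)"),
        _rxn("CO2tm", {"co2_m": -1, "co2_c": 1}, subsystem="transport"),
        _rxn("CO2t", {"co2_c": -1, "co2_e": 1}, subsystem="transport"),
        _rxn("H2Otm", {"h2o_m": -1, "h2o_c": 1}, subsystem="transport"),
        _rxn("H2Ot", {"h2o_c": -1, "h2o_e": 1}, subsystem="transport"),
        _rxn("NH4tm", {"nh4_m": -1, "nh4_c": 1}, subsystem="transport"),
        _rxn("NH4t", {"nh4_c": -1, "nh4_e": 1}, subsystem="transport"),
        _rxn("PCRt", {"pcr_e": -1, "pcr_c": 1}, gpr="gSlc6a8", subsystem="transport"),
        _rxn("CRt", {"cr_c": -1, "cr_e": 1}, gpr="gSlc6a8", subsystem="transport"),
        # glycolysis (upper lumped HK+PFK+aldolase, lower lumped PGK..PK)
        _rxn("PFK", {"glc_c": -1, "atp_c": -2, "g3p_c": 2, "adp_c": 2},
             gpr="(gHk1 or gHk2) and gPfkm and (gAldoa or gAldoc)", subsystem="glycolysis",
             name="upper glycolysis (lumped)"),
        _rxn("GAPD", {"g3p_c": -1, "nad_c": -1, "pg3_c": 1, "nadh_c": 1},
             gpr="gGapdh", subsystem="glycolysis"),
        _rxn("PYK", {"pg3_c": -1, "adp_c": -2, "pyr_c": 1, "atp_c": 2},
             gpr="gPgk1 and gPgam1 and gEno1 and (gPkm or gPklr)", subsystem="glycolysis",
             name="lower glycolysis (lumped)"),
        _rxn("LDH", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1}, lb=-1000,
             gpr="gLdha or gLdhb", subsystem="glycolysis"),
        # TCA cycle
        _rxn("PDH", {"pyr_m": -1, "nad_m": -1, "accoa_m": 1, "nadh_m": 1, "co2_m": 1},
             gpr="gPdha1 and gPdhb and gDlat", subsystem="tca"),
        _rxn("CSIDH", {"accoa_m": -1, "nad_m": -1, "akg_m": 1, "co2_m": 1, "nadh_m": 1},
             gpr="gCs and gIdh3a and gIdh3b", subsystem="tca",
             name="citrate synthase + isocitrate dehydrogenase (lumped)"),
        _rxn("AKGDM", {"akg_m": -1, "nad_m": -2, "fad_m": -1, "adp_m": -1,
                       "co2_m": 2, "nadh_m": 2, "fadh2_m": 1, "atp_m": 1},
             gpr="gOgdh and gSucla2 and gMdh2", subsystem="tca",
             name="2-oxoglutarate -> oxaloacetate (lumped)"),
        # OXPHOS: 4 H+ per NADH at CI, 6 H+ per quinol at CIII+CIV, 4 H+ per ATP
        _rxn("CI", {"nadh_m": -1, "q_m": -1, "nad_m": 1, "qh2_m": 1, "h_i": 4},
             gpr="gNdufa1 and gNdufs1 and gNdufv1 and gNdufb8", subsystem="oxphos",
             name="complex I"),
        _rxn("CII", {"fadh2_m": -1, "q_m": -1, "fad_m": 1, "qh2_m": 1},
             gpr="gSdha and gSdhb and gSdhc", subsystem="oxphos", name="complex II"),
        _rxn("G3PS", {"nadh_c": -1, "q_m": -1, "nad_c": 1, "qh2_m": 1},
             gpr="gGpd1 and gGpd2", subsystem="oxphos",
             name="glycerol-3-phosphate shuttle"),
        _rxn("CIV", {"qh2_m": -1, "o2_m": -0.5, "q_m": 1, "h2o_m": 1, "h_i": 6},
             gpr="gUqcrc1 and gUqcrfs1 and gCox4i1 and gCox5a", subsystem="oxphos",
             name="complex III+IV (lumped)"),
        _rxn("ATPS", {"adp_m": -1, "h_i": -4, "atp_m": 1},
             gpr="gAtp5a1 and gAtp5b and gAtp5o", subsystem="oxphos", name="ATP synthase"),
        # fatty-acid oxidation (palmitate-like C16: 7 beta-oxidation cycles)
        _rxn("FAA", {"fa_m": -1, "atp_m": -2, "facoa_m": 1, "adp_m": 2},
             gpr="gAcsl1", subsystem="fatty_acid_oxidation", name="fatty-acid activation"),
        _rxn("BOX", {"facoa_m": -1, "nad_m": -7, "fad_m": -7,
                     "accoa_m": 8, "nadh_m": 7, "fadh2_m": 7},
             gpr="gAcadvl and gHadha and gAcaa2", subsystem="fatty_acid_oxidation",
             name="beta-oxidation (7 cycles, lumped)"),
        # glutamate anaplerosis
        _rxn("GDH", {"glu_m": -1, "nad_m": -1, "akg_m": 1, "nadh_m": 1, "nh4_m": 1},
             gpr="gGlud1", subsystem="amino_acid", name="glutamate dehydrogenase"),
        # phosphocreatine buffer
        _rxn("CK", {"pcr_c": -1, "adp_c": -1, "cr_c": 1, "atp_c": 1},
             gpr="gCkb or gCkmt1", subsystem="creatine_metabolism", name="creatine kinase"),
        # ATP demand (objective); its ceiling sits above any attainable supply
        # so expression caps, never the demand bound, limit the optimum
        _rxn("ATPM", {"atp_c": -1, "adp_c": 1}, ub=100000, subsystem="atp_demand", name="ATP demand"),
    ]
    model = MetabolicModel(
        id="toy_brain_gem",
        metabolites=mets,
        reactions=R,
        objective={"ATPM": 1.0},
        compartments=compartments,
    )
    model.validate()
    return model


def toy_down_genes(model: MetabolicModel, down_subsystems: Sequence[str]) -> Set[str]:
    """Genes carried by reactions in the down-regulated subsystems."""
    down = set()
    for r in model.reactions:
        if r.subsystem in set(down_subsystems) and r.gpr is not None:
            down |= r.gpr.genes()
    return down


def simulate_expression(
    model: MetabolicModel,
    config: Optional[SyntheticCohortConfig] = None,
) -> Tuple[ExpressionMatrix, GroundTruth]:
    """Negative-binomial counts for the three-group design.

    Per-gene baseline abundances are drawn once; disease multiplies the
    means of genes in ``down_subsystems`` by ``disease_fold`` and the
    treated group by ``treated_fold``; silent background genes stay near
    zero everywhere.  Counts are NB with the configured dispersion and
    per-sample library sizes; ``nb_dispersion -> 0`` recovers Poisson.
    """
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(int(config.seed))
    model_genes = model.genes
    bg_on = [f"bg_on_{i:03d}" for i in range(config.n_background_on)]
    bg_off = [f"bg_off_{i:03d}" for i in range(config.n_background_off)]
    genes = model_genes + bg_on + bg_off
    on_mask = np.array([g not in set(bg_off) for g in genes])

    x = np.empty(len(genes))
    n_on = int(on_mask.sum())
    x[on_mask] = config.on_log2_floor + rng.exponential(config.on_log2_scale, n_on)
    x[~on_mask] = config.off_log2_ceiling - rng.exponential(
        config.off_log2_scale, len(genes) - n_on
    )
    abundance = np.power(2.0, x)
    lengths = {g: int(L) for g, L in zip(genes, rng.integers(500, 5001, len(genes)))}
    len_arr = np.array([lengths[g] for g in genes], dtype=float)

    down = toy_down_genes(model, config.down_subsystems)
    fold_by_group = {config.groups[0]: 1.0, config.groups[1]: config.disease_fold,
                     config.groups[2]: config.treated_fold}

    sample_ids: List[str] = []
    counts = np.zeros((len(genes), config.n_per_group * len(config.groups)))
    gene_state: Dict[Tuple[str, str], Dict[str, object]] = {}
    col = 0
    for group in config.groups:
        fold = fold_by_group[group]
        factors = np.array([fold if g in down else 1.0 for g in genes])
        for g, on, f in zip(genes, on_mask, factors):
            gene_state[(group, g)] = {"on": bool(on), "fold": float(f)}
        mean_rel = abundance * factors * len_arr
        mean_rel = mean_rel / mean_rel.sum()
        for i in range(config.n_per_group):
            sample_ids.append(f"{group}_{i + 1}")
            lib = rng.integers(*config.library_size_range)
            mu = mean_rel * lib
            if config.nb_dispersion < 1e-8:
                counts[:, col] = rng.poisson(mu)
            else:
                r = 1.0 / config.nb_dispersion
                p = r / (r + mu)
                counts[:, col] = rng.negative_binomial(r, p)
            col += 1

    expected_direction: Dict[Tuple[str, str], str] = {}
    for subsystem in sorted({r.subsystem or "other" for r in model.reactions}):
        for group in config.groups[1:]:
            if subsystem in set(config.down_subsystems) and fold_by_group[group] < 1.0:
                expected_direction[(group, subsystem)] = "down"
            else:
                expected_direction[(group, subsystem)] = "unchanged"

    expr = tpm_from_counts(counts, lengths, genes, sample_ids)
    return expr, GroundTruth(gene_state=gene_state, expected_direction=expected_direction)


def simulate_respirometry(
    config: Optional[SyntheticCohortConfig] = None,
) -> List[RespirometryMeasurement]:
    """Oxygen fluxes per group and titration state, ordered with the folds.

    The oxphos-state flux is base * group factor (control 1, disease =
    disease_fold, treated = treated_fold) plus Gaussian noise, clipped
    at zero; other titration states are fixed multiples of it.
    """
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(int(config.seed) + 101)
    state_mult = {"routine": 0.35, "oxphos": 1.0, "max_ox": 1.25,
                  "atp_link": 0.15, "max_u": 1.3, "rox": 0.02}
    factors = {config.groups[0]: 1.0, config.groups[1]: config.disease_fold,
               config.groups[2]: config.treated_fold}
    out: List[RespirometryMeasurement] = []
    for group in config.groups:
        oxphos = config.respirometry_base * factors[group]
        noise = rng.normal(0.0, config.respirometry_noise_sd)
        for state, mult in state_mult.items():
            value = max(0.0, (oxphos + noise) * mult)
            out.append(RespirometryMeasurement(group=group, state=state, oxygen_flux=value))
    return out


# ---- random toy networks for oracle tests ---------------------------------

def make_random_network(seed: int, n_extra: int = 6, p_reversible: float = 0.25,
                        p_blocked: float = 0.5) -> MetabolicModel:
    """Small random branched pathway networks (<= ~12 reactions).

    A linear backbone chain with an uptake and a secretion guarantees a
    feasible route; random branch/parallel reactions add alternatives,
    and with probability ``p_blocked`` a dead-end reaction is appended
    so flux-consistency pruning has something to remove.
    """
    rng = np.random.default_rng(int(seed))
    n_mets = int(rng.integers(3, 6))
    met_ids = [f"M{i}" for i in range(n_mets)]
    mets = [Metabolite(id=m, name=m, compartment="c") for m in met_ids]
    reactions = [
        _rxn("EX_in", {"M0": 1}, lb=0, ub=10),
        _rxn("EX_out", {met_ids[-1]: -1}, lb=0, ub=10),
    ]
    for i in range(n_mets - 1):
        lb = -10.0 if rng.random() < p_reversible else 0.0
        reactions.append(_rxn(f"B{i}", {met_ids[i]: -1, met_ids[i + 1]: 1}, lb=lb, ub=10))
    k = 0
    while len(reactions) < 2 + (n_mets - 1) + n_extra:
        i, j = rng.choice(n_mets, size=2, replace=False)
        lb = -10.0 if rng.random() < p_reversible else 0.0
        coef = float(rng.choice([1.0, 2.0]))
        reactions.append(_rxn(f"X{k}", {met_ids[i]: -1, met_ids[j]: coef}, lb=lb, ub=10))
        k += 1
    if rng.random() < p_blocked:
        mets.append(Metabolite(id="D0", name="D0", compartment="c"))
        src = met_ids[int(rng.integers(0, n_mets))]
        reactions.append(_rxn("DEAD", {src: -1, "D0": 1}, lb=0, ub=10))
    model = MetabolicModel(
        id=f"random_{seed}", metabolites=mets, reactions=reactions,
        objective={"EX_out": 1.0}, compartments={"c": "cytosol"},
    )
    model.validate()
    return model
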