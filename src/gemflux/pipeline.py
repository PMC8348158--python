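"""End-to-end workflow: simulate -> build -> analyze.

The analysis pipeline mirrors the study design: per-sample context
models are built from expression (discretize -> classify -> prune ->
extract), expression is re-applied continuously as E-Flux bound caps,
oxygen uptake is capped by the group's respirometry measurement, and
the resulting models are simulated (pFBA, FVA, flux sampling) and
compared through subsystem profiles, cosine similarity, clustering,
2-D embedding and per-reaction sampled-flux reports.

By default all exchange bounds are opened before E-Flux so that the
expression-derived caps — not arbitrary medium limits — constrain the
flux state; this is the standard way E-Flux is used and is what lets
group differences in expression propagate into flux differences.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .constraints import (
    BoundedModel,
    RespirometryMeasurement,
    apply_respirometry,
    eflux_bounds,
    reaction_scores,
    read_respirometry_tsv,
)
from .expression import ExpressionMatrix, read_counts_tsv
from .extraction import ContextModel, ExtractionConfig, build_context_model, check_tasks, load_tasks
from .model import MetabolicModel, read_model, write_model
from .profiles import (
    SubsystemProfile,
    cluster_profiles,
    compare_groups,
    cosine_similarity,
    embed_profiles,
    subsystem_profile,
)
from .solvers import fva, pfba, sample_fluxes, verify_ensemble
from .synthetic import (
    SyntheticCohortConfig,
    make_toy_model,
    simulate_expression,
    simulate_respirometry,
)

logger = logging.getLogger(__name__)

OPEN_BOUND = 1000.0


@dataclass
class RunConfig:
    """All knobs of the end-to-end workflow, recorded in provenance."""

    model_path: Optional[str] = None
    counts_path: Optional[str] = None
    lengths_path: Optional[str] = None
    respirometry_path: Optional[str] = None
    tasks_path: Optional[str] = None
    output_dir: str = "gemflux_out"
    group_assignment: Dict[str, str] = field(default_factory=dict)
    epsilon: float = 1e-4
    z_margin: float = 1.0
    or_mode: str = "sum"
    v_max: float = 1000.0
    fraction_of_optimum: float = 1.0
    n_samples: int = 500
    thinning: int = 50
    sampler: str = "hit_and_run"
    seed: int = 1
    open_exchanges: bool = True
    pooled_fit: bool = False
    respirometry_state: str = "oxphos"
    respirometry_scale: Optional[float] = None  # None -> auto-calibrated
    use_respirometry: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def group_of(sample_id: str, assignment: Mapping[str, str]) -> str:
    if sample_id in assignment:
        return assignment[sample_id]
    # synthetic convention: "<group>_<replicate>"
    return sample_id.rsplit("_", 1)[0]


# ---- simulate --------------------------------------------------------------

def run_simulate(output_dir, cohort: Optional[SyntheticCohortConfig] = None) -> Dict[str, str]:
    """Write the toy model, synthetic cohort and ground truth to disk."""
    cohort = cohort or SyntheticCohortConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = make_toy_model()
    expr, truth = simulate_expression(model, cohort)
    resp = simulate_respirometry(cohort)

    write_model(model, out / "model.json")
    write_model(model, out / "model.xml")
    counts = pd.DataFrame(expr.counts, index=expr.gene_ids, columns=expr.sample_ids).astype(int)
    counts.to_csv(out / "counts.tsv", sep="\t")
    pd.DataFrame(
        {"gene_id": expr.gene_ids, "length_bp": [expr.gene_lengths_bp[g] for g in expr.gene_ids]}
    ).to_csv(out / "lengths.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"group": r.group, "state": r.state, "oxygen_flux": r.oxygen_flux} for r in resp]
    ).to_csv(out / "respirometry.tsv", sep="\t", index=False)
    truth_doc = {
        "gene_state": {f"{g}|{gene}": st for (g, gene), st in truth.gene_state.items()},
        "expected_direction": {f"{g}|{s}": d for (g, s), d in truth.expected_direction.items()},
        "config": dataclasses.asdict(cohort),
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    import shutil

    tasks_src = Path(__file__).parent / "data" / "brain_tasks.yaml"
    shutil.copy(tasks_src, out / "tasks.yaml")
    return {name: str(out / name) for name in
            ("model.json", "model.xml", "counts.tsv", "lengths.tsv",
             "respirometry.tsv", "truth.json", "tasks.yaml")}


# ---- build -----------------------------------------------------------------

def _opened(model: MetabolicModel) -> MetabolicModel:
    opened = model.copy()
    for r in opened.reactions:
        if r.is_exchange:
            r.lower_bound = -OPEN_BOUND
            r.upper_bound = OPEN_BOUND
    return opened


def auto_respirometry_scale(model: MetabolicModel, control: RespirometryMeasurement,
                            oxygen_exchange_id: str = "EX_o2", margin: float = 1.05) -> float:
    """Unit bridge pmol/s/mg -> flux: control's cap sits just above its optimum."""
    sol = pfba(model)
    if sol.status != "optimal" or oxygen_exchange_id not in sol.fluxes:
        return 1.0
    uptake = max(0.0, -sol.fluxes[oxygen_exchange_id])
    if control.oxygen_flux <= 0 or uptake <= 0:
        return 1.0
    return margin * uptake / control.oxygen_flux


def build_sample_models(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    config: RunConfig,
    respirometry: Optional[Sequence[RespirometryMeasurement]] = None,
) -> Tuple[Dict[str, BoundedModel], pd.DataFrame]:
    """Context models per sample plus pooled per-group models.

    Returns bounded context models keyed by sample id and by
    ``group::<name>`` for the pooled group models, together with a
    component-count table (active genes/reactions/metabolites).
    """
    xcfg = ExtractionConfig(epsilon=config.epsilon)
    base = _opened(model) if config.open_exchanges else model
    resp_by_group: Dict[str, RespirometryMeasurement] = {}
    if respirometry and config.use_respirometry:
        for meas in respirometry:
            if meas.state == config.respirometry_state:
                resp_by_group[meas.group] = meas

    def contextualize(label: str, tpm_map: Dict[str, float], sample_for_disc: str,
                      expr_for_disc: ExpressionMatrix) -> Tuple[BoundedModel, Dict]:
        ctx = build_context_model(
            base, expr_for_disc, sample_for_disc, config=xcfg,
            z_margin=config.z_margin, pooled_fit=config.pooled_fit, seed=config.seed,
        )
        scores = reaction_scores(ctx.model, tpm_map, or_mode=config.or_mode)
        if scores and max(scores.values()) > 0:
            bounded = eflux_bounds(ctx.model, scores, v_max=config.v_max)
        else:  # degenerate context model without expression evidence
            logger.warning("%s: no positive reaction scores; E-Flux skipped", label)
            bounded = BoundedModel(model=ctx.model, normalization_max=0.0)
        return bounded, ctx.provenance

    results: Dict[str, BoundedModel] = {}
    stats_rows: List[Dict] = []
    for sample in expr.sample_ids:
        bounded, prov = contextualize(sample, expr.tpm_map(sample), sample, expr)
        results[sample] = bounded
        stats_rows.append({"label": sample, "group": group_of(sample, config.group_assignment),
                           "kind": "sample", **{k: v for k, v in prov.items()
                                                if isinstance(v, (int, float, bool, str))}})

    # pooled group models: mean TPM re-normalized to 1e6
    groups = sorted({group_of(s, config.group_assignment) for s in expr.sample_ids})
    for group in groups:
        cols = [i for i, s in enumerate(expr.sample_ids) if group_of(s, config.group_assignment) == group]
        mean_tpm = expr.tpm[:, cols].mean(axis=1)
        mean_tpm = mean_tpm / mean_tpm.sum() * 1_000_000.0
        pooled = ExpressionMatrix(gene_ids=expr.gene_ids, sample_ids=[group],
                                  tpm=mean_tpm[:, None])
        bounded, prov = contextualize(group, pooled.tpm_map(group), group, pooled)
        results[f"group::{group}"] = bounded
        stats_rows.append({"label": group, "group": group, "kind": "group",
                           **{k: v for k, v in prov.items()
                              if isinstance(v, (int, float, bool, str))}})

    # respirometry: calibrate the unit scale on the control group, cap everyone
    if resp_by_group:
        control_group = next(
            (g for g in ("control", groups[0]) if g in resp_by_group), None
        )
        scale = config.respirometry_scale
        if scale is None and control_group is not None and f"group::{control_group}" in results:
            scale = auto_respirometry_scale(
                results[f"group::{control_group}"].model, resp_by_group[control_group]
            )
        if scale is not None:
            for key, bounded in list(results.items()):
                label = key.split("::", 1)[-1]
                grp = label if key.startswith("group::") else group_of(label, config.group_assignment)
                if grp in resp_by_group and any(
                    r.id == "EX_o2" for r in bounded.model.reactions
                ):
                    capped = apply_respirometry(bounded.model, resp_by_group[grp], scale)
                    bounded.model = capped.model
                    bounded.applied_constraints.extend(capped.applied_constraints)
    stats = pd.DataFrame(stats_rows)
    return results, stats


def run_build(output_dir, config: RunConfig) -> Dict[str, object]:
    """Build per-sample and per-group context models and write them out."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = read_model(config.model_path)
    expr = read_counts_tsv(config.counts_path, config.lengths_path)
    respirometry = (
        read_respirometry_tsv(config.respirometry_path) if config.respirometry_path else None
    )
    models, stats = build_sample_models(model, expr, config, respirometry)
    models_dir = out / "context_models"
    models_dir.mkdir(exist_ok=True)
    for key, bounded in models.items():
        fname = key.replace("::", "_") + ".json"
        write_model(bounded.model, models_dir / fname)
    stats.to_csv(out / "model_components.tsv", sep="\t", index=False)
    return {"models": models, "stats": stats, "expr": expr, "parent": model}


# ---- analyze ---------------------------------------------------------------

def analyze_models(
    models: Mapping[str, BoundedModel],
    config: RunConfig,
) -> Dict[str, object]:
    """pFBA + profiles for sample models; sampling + comparison for groups."""
    sample_keys = [k for k in models if not k.startswith("group::")]
    group_keys = [k for k in models if k.startswith("group::")]

    profiles: List[SubsystemProfile] = []
    pfba_fluxes: Dict[str, Dict[str, float]] = {}
    for key in sample_keys + group_keys:
        bounded = models[key]
        sol = pfba(bounded.model, fraction_of_optimum=config.fraction_of_optimum)
        if sol.status != "optimal":
            logger.warning("pFBA %s on %s; profile skipped", sol.status, key)
            continue
        pfba_fluxes[key] = sol.fluxes
        label = key.split("::", 1)[-1]
        profiles.append(subsystem_profile(sol, bounded.model, label=label))

    sample_profiles = [p for p, k in zip(profiles, list(pfba_fluxes)) if not k.startswith("group::")]
    similarity = cosine_similarity(sample_profiles) if len(sample_profiles) >= 2 else None
    clusters = (
        cluster_profiles(sample_profiles, k=len({group_of(p.label, config.group_assignment) for p in sample_profiles}))
        if len(sample_profiles) >= 2
        else None
    )
    embedding = embed_profiles(sample_profiles, method="pca", seed=config.seed) if len(sample_profiles) >= 3 else None

    ensembles = {}
    for key in group_keys:
        group = key.split("::", 1)[-1]
        ens = sample_fluxes(
            models[key].model, n_samples=config.n_samples, seed=config.seed,
            thinning=config.thinning, method=config.sampler,
        )
        verify_ensemble(models[key].model, ens)
        ensembles[group] = ens
    comparison = compare_groups(ensembles, reference=_reference_group(ensembles)) if len(ensembles) >= 2 else None
    return {
        "profiles": profiles,
        "sample_profiles": sample_profiles,
        "pfba_fluxes": pfba_fluxes,
        "similarity": similarity,
        "clusters": clusters,
        "embedding": embedding,
        "ensembles": ensembles,
        "comparison": comparison,
    }


def _reference_group(ensembles: Mapping[str, object]) -> Optional[str]:
    return "control" if "control" in ensembles else (next(iter(ensembles)) if ensembles else None)


def run_analyze(output_dir, config: RunConfig, built: Optional[Dict[str, object]] = None) -> Dict[str, object]:
    """Full analysis with TSV/JSON/SVG outputs and a provenance record."""
    t0 = time.time()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    built = built or run_build(output_dir, config)
    results = analyze_models(built["models"], config)

    subsystems = sorted({s for p in results["profiles"] for s in p.values})
    prof_df = pd.DataFrame(
        [[p.values.get(s, 0.0) for s in subsystems] for p in results["profiles"]],
        index=[p.label for p in results["profiles"]], columns=subsystems,
    )
    prof_df.to_csv(out / "subsystem_profiles.tsv", sep="\t")
    if results["similarity"] is not None:
        results["similarity"].to_frame().to_csv(out / "cosine_similarity.tsv", sep="\t")
    if results["clusters"] is not None:
        pd.DataFrame(
            {"label": results["clusters"].labels,
             "cluster": results["clusters"].flat if results["clusters"].flat is not None else []}
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    if results["embedding"] is not None:
        pd.DataFrame(
            results["embedding"], columns=["dim1", "dim2"],
            index=[p.label for p in results["sample_profiles"]],
        ).to_csv(out / "embedding.tsv", sep="\t")
    if results["comparison"] is not None:
        results["comparison"].to_csv(out / "group_comparison.tsv", sep="\t", index=False)
    flux_df = pd.DataFrame(results["pfba_fluxes"]).fillna(0.0)
    flux_df.to_csv(out / "pfba_fluxes.tsv", sep="\t")

    _write_figures(out, results)

    provenance = {
        "package": "gemflux",
        "version": __version__,
        "config": config.to_dict(),
        "runtime_s": round(time.time() - t0, 2),
        "n_models": len(built["models"]),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return results


def _write_figures(out: Path, results: Dict[str, object]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    profiles = results["sample_profiles"]
    if profiles:
        subsystems = sorted({s for p in profiles for s in p.values})
        X = np.array([[p.values.get(s, 0.0) for s in subsystems] for p in profiles])
        # z-score per subsystem for display only
        Z = (X - X.mean(axis=0)) / (X.std(axis=0) + 1e-12)
        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(Z.T, aspect="auto", cmap="coolwarm")
        ax.set_yticks(range(len(subsystems)), subsystems, fontsize=7)
        ax.set_xticks(range(len(profiles)), [p.label for p in profiles], rotation=90, fontsize=7)
        fig.colorbar(im, label="z-scored share")
        fig.tight_layout()
        fig.savefig(out / "profile_heatmap.svg")
        plt.close(fig)
    if results["clusters"] is not None:
        fig, ax = plt.subplots(figsize=(6, 3))
        hierarchy.dendrogram(results["clusters"].linkage,
                             labels=results["clusters"].labels, ax=ax, leaf_font_size=7)
        fig.tight_layout()
        fig.savefig(out / "dendrogram.svg")
        plt.close(fig)
    if results["embedding"] is not None:
        coords = results["embedding"]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(coords[:, 0], coords[:, 1], s=20)
        for (x, y), p in zip(coords, profiles):
            ax.annotate(p.label, (x, y), fontsize=6)
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
        fig.tight_layout()
        fig.savefig(out / "embedding.svg")
        plt.close(fig)
    ensembles = results.get("ensembles") or {}
    key_rxns = [r for r in ("ATPS", "CI", "CII", "PFK", "BOX")
                if all(r in e.reaction_ids for e in ensembles.values())]
    if ensembles and key_rxns:
        fig, axes = plt.subplots(1, len(key_rxns), figsize=(3 * len(key_rxns), 3), squeeze=False)
        for ax, rid in zip(axes[0], key_rxns):
            data = [e.column(rid) for e in ensembles.values()]
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(range(1, len(ensembles) + 1), list(ensembles), rotation=45, fontsize=7)
            ax.set_title(rid, fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "sampling_violins.svg")
        plt.close(fig)


def run_tasks(model_path, tasks_path, output_path=None) -> pd.DataFrame:
    """Check metabolic tasks against a model; optionally write a TSV."""
    model = read_model(model_path)
    tasks = load_tasks(tasks_path)
    results = check_tasks(model, tasks)
    df = pd.DataFrame([{"task_id": r.task_id, "feasible": r.feasible, "reason": r.reason}
                       for r in results])
    if output_path:
        df.to_csv(output_path, sep="\t", index=False)
    return df
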