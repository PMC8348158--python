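"""Subsystem flux profiles and group comparison.

A flux distribution is summarized by summing |v| within each subsystem
and normalizing the result to total 1 (L1), making profiles comparable
across context models of different sizes and invariant to uniform flux
scaling.  Profiles are compared with cosine similarity, grouped by
agglomerative clustering on cosine distance, embedded in 2-D (PCA or
UMAP), and sampled flux distributions are compared per reaction with
descriptive statistics (medians, overlap, rank-sum) — no significance
claims.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .model import FluxDistribution, MetabolicModel
from .solvers import SampleEnsemble

logger = logging.getLogger(__name__)


@dataclass
class SubsystemProfile:
    """Normalized summed |flux| per subsystem for one model/sample."""

    label: str
    values: Dict[str, float]

    def vector(self, subsystems: Sequence[str]) -> np.ndarray:
        return np.array([self.values.get(s, 0.0) for s in subsystems])


@dataclass
class SimilarityMatrix:
    labels: List[str]
    matrix: np.ndarray
    metric: str = "cosine"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def subsystem_profile(flux: FluxDistribution, model: MetabolicModel, label: str = "") -> SubsystemProfile:
    """Sum |v| per subsystem and L1-normalize to 1.

    Reactions without a subsystem pool into "other"; reactions absent
    from the flux distribution contribute 0.  An all-zero flux vector
    has no defined profile and raises.
    """
    sums: Dict[str, float] = {}
    for r in model.reactions:
        v = flux.fluxes.get(r.id, 0.0)
        key = r.subsystem or "other"
        sums[key] = sums.get(key, 0.0) + abs(v)
    total = sum(sums.values())
    if total <= 0:
        raise ValueError("all-zero flux vector: subsystem profile undefined")
    return SubsystemProfile(label=label, values={k: v / total for k, v in sums.items()})


def _profiles_to_matrix(profiles: Sequence[SubsystemProfile]):
    subsystems = sorted({s for p in profiles for s in p.values})
    X = np.vstack([p.vector(subsystems) for p in profiles])
    return X, subsystems, [p.label for p in profiles]


def cosine_similarity(
    vectors: Union[Sequence[SubsystemProfile], np.ndarray],
    labels: Optional[Sequence[str]] = None,
) -> SimilarityMatrix:
    """Pairwise cosine similarity; raises on any zero vector."""
    if len(vectors) and isinstance(vectors[0], SubsystemProfile):
        X, _, labels = _profiles_to_matrix(vectors)
    else:
        X = np.asarray(vectors, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(X))]
    norms = np.linalg.norm(X, axis=1)
    for lab, nm in zip(labels, norms):
        if nm <= 0:
            raise ValueError(f"zero vector: {lab}")
    M = (X / norms[:, None]) @ (X / norms[:, None]).T
    M = np.clip((M + M.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(labels=list(labels), matrix=M)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    labels: List[str]
    flat: Optional[np.ndarray] = None  # cluster ids when k was requested


def cluster_profiles(
    profiles: Sequence[SubsystemProfile],
    k: Optional[int] = None,
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering on cosine distance (1 - similarity)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    sim = cosine_similarity(profiles)
    dist = np.clip(1.0 - sim.matrix, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust") if k is not None else None
    return ClusterResult(linkage=Z, labels=sim.labels, flat=flat)


def embed_profiles(
    profiles: Sequence[SubsystemProfile],
    method: str = "pca",
    seed: int = 0,
) -> np.ndarray:
    """2-D embedding of profiles (PCA, or UMAP falling back to PCA)."""
    X, _, _ = _profiles_to_matrix(profiles)
    if method == "umap":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                import umap

                n_neighbors = max(2, min(15, len(profiles) - 1))
                return umap.UMAP(
                    n_components=2, random_state=int(seed), n_neighbors=n_neighbors
                ).fit_transform(X)
        except Exception as exc:  # pragma: no cover - environment dependent
            logger.warning("UMAP unavailable (%s); falling back to PCA", exc)
            method = "pca"
    if method != "pca":
        raise ValueError(f"unknown embedding method {method!r}")
    from sklearn.decomposition import PCA

    n_comp = min(2, len(profiles), X.shape[1])
    coords = PCA(n_components=n_comp, random_state=int(seed)).fit_transform(X)
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - coords.shape[1]))])
    return coords


def _overlap_coefficient(a: np.ndarray, b: np.ndarray, bins: int = 30) -> float:
    """Histogram overlap of two samples: sum of min(p_i, q_i)."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi - lo < 1e-12:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(a, bins=edges, density=False)
    q, _ = np.histogram(b, bins=edges, density=False)
    return float(np.minimum(p / len(a), q / len(b)).sum())


def compare_groups(
    ensembles: Mapping[str, SampleEnsemble],
    reactions: Optional[Sequence[str]] = None,
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Descriptive per-reaction comparison of sampled flux distributions.

    For each reaction: group medians, median difference vs the reference
    group, distribution overlap coefficient, and the rank-sum statistic.
    A reaction absent from a group's context model is reported "absent"
    and its flux treated as structurally zero.
    """
    if len(ensembles) < 2:
        raise ValueError("need at least 2 groups to compare")
    groups = list(ensembles)
    reference = reference or groups[0]
    if reference not in ensembles:
        raise ValueError(f"reference group {reference!r} not among ensembles")
    if reactions is None:
        reactions = sorted({r for ens in ensembles.values() for r in ens.reaction_ids})
    rows = []
    for rid in reactions:
        row: Dict[str, object] = {"reaction_id": rid}
        cols: Dict[str, np.ndarray] = {}
        for g in groups:
            ens = ensembles[g]
            if rid in ens.reaction_ids:
                cols[g] = ens.column(rid)
                row[f"median_{g}"] = float(np.median(cols[g]))
                row[f"absent_{g}"] = False
            else:
                cols[g] = np.zeros(ens.samples.shape[0])
                row[f"median_{g}"] = 0.0
                row[f"absent_{g}"] = True
        ref_col = cols[reference]
        for g in groups:
            if g == reference:
                continue
            row[f"median_diff_{g}"] = row[f"median_{g}"] - row[f"median_{reference}"]
            row[f"overlap_{g}"] = _overlap_coefficient(cols[g], ref_col)
            if np.ptp(cols[g]) < 1e-15 and np.ptp(ref_col) < 1e-15:
                row[f"ranksum_{g}"] = float("nan")
            else:
                row[f"ranksum_{g}"] = float(mannwhitneyu(cols[g], ref_col).statistic)
    # descriptive only: no p-values are reported by design
        rows.append(row)
    return pd.DataFrame(rows)
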