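"""Expression normalization and discretization.

Counts are normalized to transcripts per kilobase million (TPM): each
gene's count is divided by its length in kilobases to give a rate, and
rates are scaled so every sample sums to 10^6.  Discretization follows
the two-Gaussian ("expression curves") approach: the per-sample
distribution of log2(TPM+1) over detected genes is decomposed into a
low-expression and a high-expression Gaussian component, and each gene
is labelled expressed (+1), unknown (0), or unexpressed (-1) relative to
thresholds placed ``z_margin`` standard deviations inside each
component.  Genes with zero TPM are excluded from the fit and labelled
unexpressed directly, since the RNA-seq zero mass would distort the fit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TPM_TOTAL = 1_000_000.0


@dataclass
class ExpressionMatrix:
    """Genes x samples expression, as TPM (and optionally the raw counts)."""

    gene_ids: List[str]
    sample_ids: List[str]
    tpm: np.ndarray  # genes x samples, non-negative
    counts: Optional[np.ndarray] = None
    gene_lengths_bp: Optional[Dict[str, int]] = None

    def __post_init__(self):
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("tpm shape inconsistent with gene/sample ids")
        sums = self.tpm.sum(axis=0)
        if not np.allclose(sums, TPM_TOTAL, rtol=1e-3):
            raise ValueError("TPM columns must sum to 1e6 within 1e-3 relative tolerance")

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.tpm[:, self.sample_ids.index(sample_id)]

    def tpm_map(self, sample_id: str) -> Dict[str, float]:
        col = self.sample_column(sample_id)
        return dict(zip(self.gene_ids, col))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tpm, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class MixtureParams:
    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    w_low: float
    w_high: float
    fallback: bool = False  # True when the degenerate-fit quantile fallback fired


@dataclass
class GeneDiscretization:
    sample_id: str
    category: Dict[str, int]  # gene -> {+1, 0, -1}
    score: Dict[str, float]  # gene -> log2(TPM+1)
    mixture_params: MixtureParams


def tpm_from_counts(
    counts: np.ndarray,
    gene_lengths_bp: Mapping[str, int],
    gene_ids: List[str],
    sample_ids: List[str],
) -> ExpressionMatrix:
    """Length- and depth-normalize raw counts to TPM.

    Per sample: rate_g = count_g / (length_g / 1000); TPM_g = rate_g /
    sum(rates) * 1e6.  Errors name the offending gene (missing length)
    or sample (zero total rate).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(gene_ids), len(sample_ids)):
        raise ValueError("counts shape inconsistent with gene/sample ids")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = np.empty(len(gene_ids))
    for i, g in enumerate(gene_ids):
        if g not in gene_lengths_bp:
            if counts[i].sum() > 0:
                raise ValueError(f"missing gene length for gene {g!r}")
            lengths[i] = 1000.0
        else:
            lengths[i] = float(gene_lengths_bp[g])
            if lengths[i] <= 0:
                raise ValueError(f"non-positive gene length for gene {g!r}")
    rates = counts / (lengths[:, None] / 1000.0)
    totals = rates.sum(axis=0)
    for j, s in enumerate(sample_ids):
        if totals[j] <= 0:
            raise ValueError(f"zero total rate in sample {s!r}")
    tpm = rates / totals[None, :] * TPM_TOTAL
    return ExpressionMatrix(
        gene_ids=list(gene_ids),
        sample_ids=list(sample_ids),
        tpm=tpm,
        counts=counts,
        gene_lengths_bp=dict(gene_lengths_bp),
    )


def read_counts_tsv(counts_path, lengths_path, sep: str = "\t") -> ExpressionMatrix:
    """Read a gene x sample count table and a (gene_id, length_bp) table."""
    df = pd.read_csv(counts_path, sep=sep, index_col=0)
    lengths_df = pd.read_csv(lengths_path, sep=sep)
    lengths = dict(zip(lengths_df.iloc[:, 0].astype(str), lengths_df.iloc[:, 1].astype(int)))
    return tpm_from_counts(
        df.to_numpy(), lengths, [str(g) for g in df.index], [str(s) for s in df.columns]
    )


def read_tpm_tsv(path, sep: str = "\t") -> ExpressionMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        tpm=df.to_numpy(),
    )


# ---- two-Gaussian decomposition -------------------------------------------

def _quantile_fallback(values: np.ndarray) -> MixtureParams:
    """Quantile-threshold stand-in when the mixture fit degenerates."""
    lo, hi = np.quantile(values, [0.25, 0.75])
    spread = max(float(np.std(values)), 1e-3)
    # thresholds at z=1: expressed above ~q75 - spread, unexpressed below ~q25;
    # constant input labels everything expressed rather than unexpressed
    return MixtureParams(
        mu_low=float(lo) - spread,
        mu_high=float(max(hi, lo + 1e-6)),
        sigma_low=spread,
        sigma_high=spread,
        w_low=0.5,
        w_high=0.5,
        fallback=True,
    )


def fit_expression_mixture(
    log2_tpm_values: np.ndarray,
    min_nonzero: int = 20,
    zero_floor: float = 0.0,
    seed: int = 0,
) -> MixtureParams:
    """EM fit of a two-component Gaussian mixture to log2(TPM+1) values.

    Values at or below ``zero_floor`` are excluded (the zero-expression
    mass).  Initialization is deterministic: component means start at the
    25th/75th percentiles, so repeated fits agree.  A degenerate fit
    (vanishing sigma or component weight < 1e-3) falls back to quantile
    thresholds with a logged warning.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(log2_tpm_values, dtype=float)
    values = values[np.isfinite(values) & (values > zero_floor)]
    if values.size < min_nonzero:
        raise ValueError(
            f"need at least {min_nonzero} values above the zero floor, got {values.size}"
        )
    if np.ptp(values) < 1e-9:
        logger.warning("mixture fit degenerate (constant values); using quantile fallback")
        return _quantile_fallback(values)
    X = values.reshape(-1, 1)
    # several deterministic quantile-pair initializations; EM is prone to a
    # broad+narrow local optimum on zero-inflated data, so fits whose
    # components actually separate are preferred over raw likelihood
    candidates = []
    for q_lo, q_hi in ((0.10, 0.90), (0.25, 0.75), (0.02, 0.60), (0.05, 0.50)):
        init_means = np.quantile(values, [q_lo, q_hi]).reshape(-1, 1)
        if init_means[1, 0] - init_means[0, 0] < 1e-9:
            continue
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            means_init=init_means,
            weights_init=np.array([0.5, 0.5]),
            precisions_init=np.array([[[1.0 / max(np.var(values), 1e-6)]]] * 2),
            random_state=int(seed),
            max_iter=500,
            n_init=1,
        )
        try:
            gm.fit(X)
        except ValueError:
            continue
        means = gm.means_.ravel()
        sigmas = np.sqrt(gm.covariances_.reshape(-1))
        weights = gm.weights_.ravel()
        order = np.argsort(means)
        mu_low, mu_high = means[order]
        sd_low, sd_high = sigmas[order]
        w_low, w_high = weights[order]
        if min(sd_low, sd_high) < 1e-6 or min(w_low, w_high) < 1e-3 or mu_high - mu_low < 1e-9:
            continue
        separated = (mu_high - sd_high) >= (mu_low + sd_low)
        candidates.append(
            (separated, gm.score(X),
             MixtureParams(float(mu_low), float(mu_high), float(sd_low),
                           float(sd_high), float(w_low), float(w_high)))
        )
    if not candidates:
        logger.warning("mixture fit degenerate; using quantile fallback")
        return _quantile_fallback(values)
    candidates.sort(key=lambda c: (c[0], c[1]))
    return candidates[-1][2]


def discretize_genes(
    expr: ExpressionMatrix,
    sample_id: str,
    params: MixtureParams,
    z_margin: float = 1.0,
) -> GeneDiscretization:
    """Label genes expressed / unknown / unexpressed for one sample.

    A gene is expressed (+1) when log2(TPM+1) >= mu_high - z*sigma_high,
    unexpressed (-1) when <= mu_low + z*sigma_low, otherwise unknown (0).
    If the two thresholds cross, the midpoint of the component means
    splits the categories and no gene is left unknown.  Zero-TPM genes
    are unexpressed by definition.
    """
    col = expr.sample_column(sample_id)
    log2_vals = np.log2(col + 1.0)
    hi_thresh = params.mu_high - z_margin * params.sigma_high
    lo_thresh = params.mu_low + z_margin * params.sigma_low
    if hi_thresh < lo_thresh:  # crossing: fall back to the means' midpoint
        mid = 0.5 * (params.mu_low + params.mu_high)
        hi_thresh = lo_thresh = mid
    category: Dict[str, int] = {}
    score: Dict[str, float] = {}
    for gene, tpm_val, lv in zip(expr.gene_ids, col, log2_vals):
        score[gene] = float(lv)
        if tpm_val <= 0:
            category[gene] = -1
        elif lv >= hi_thresh:
            category[gene] = 1
        elif lv <= lo_thresh:
            category[gene] = -1
        else:
            category[gene] = 0
    return GeneDiscretization(
        sample_id=sample_id, category=category, score=score, mixture_params=params
    )


def pca_expression(expr: ExpressionMatrix, n_components: int = 2, seed: int = 0) -> np.ndarray:
    """Exploratory PCA of samples on log2(TPM+1) (samples x components)."""
    from sklearn.decomposition import PCA

    X = np.log2(expr.tpm + 1.0).T  # samples x genes
    n_components = min(n_components, *X.shape)
    return PCA(n_components=n_components, random_state=int(seed)).fit_transform(X)
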