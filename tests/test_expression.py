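"""TPM normalization and the two-Gaussian discretization."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemflux.expression import (
    ExpressionMatrix,
    discretize_genes,
    fit_expression_mixture,
    pca_expression,
    tpm_from_counts,
)


class TestTpm:
    def test_worked_example(self):
        """Two genes, equal counts, 1 kb vs 2 kb: rates 10 and 5."""
        expr = tpm_from_counts(
            np.array([[10], [10]]), {"g1": 1000, "g2": 2000}, ["g1", "g2"], ["s1"]
        )
        assert expr.tpm[:, 0] == pytest.approx([666666.67, 333333.33], abs=0.5)

    def test_single_gene_is_forced_to_total(self):
        expr = tpm_from_counts(np.array([[7]]), {"g": 500}, ["g"], ["s"])
        assert expr.tpm[0, 0] == pytest.approx(1e6)

    def test_equal_counts_equal_lengths_split_evenly(self):
        expr = tpm_from_counts(
            np.array([[5], [5]]), {"g1": 800, "g2": 800}, ["g1", "g2"], ["s"]
        )
        assert expr.tpm[:, 0] == pytest.approx([500000, 500000])

    def test_zero_sample_names_sample(self):
        with pytest.raises(ValueError, match="s2"):
            tpm_from_counts(
                np.array([[3, 0]]), {"g": 1000}, ["g"], ["s1", "s2"]
            )

    def test_missing_length_names_gene(self):
        with pytest.raises(ValueError, match="g2"):
            tpm_from_counts(
                np.array([[3], [4]]), {"g1": 1000}, ["g1", "g2"], ["s"]
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_column_sums_conserved_on_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(2, 40))
        n_samples = int(rng.integers(1, 5))
        counts = rng.integers(0, 500, (n_genes, n_samples))
        counts[rng.integers(0, n_genes)] += 1  # ensure non-degenerate samples
        genes = [f"g{i}" for i in range(n_genes)]
        lengths = {g: int(rng.integers(200, 5000)) for g in genes}
        expr = tpm_from_counts(counts, lengths, genes, [f"s{j}" for j in range(n_samples)])
        assert expr.tpm.sum(axis=0) == pytest.approx(np.full(n_samples, 1e6), rel=1e-9)


class TestMixtureFit:
    def test_parameter_recovery_from_known_mixture(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(1, 0.5, 500), rng.normal(6, 1, 500)])
        params = fit_expression_mixture(values, seed=0)
        assert 0.7 <= params.mu_low <= 1.3
        assert 5.5 <= params.mu_high <= 6.5
        assert not params.fallback

    def test_symmetric_sample_gives_equal_weights(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(2, 0.6, 800), rng.normal(8, 0.6, 800)])
        params = fit_expression_mixture(values, seed=0)
        assert abs(params.w_low - params.w_high) < 0.05

    def test_constant_values_trigger_fallback(self):
        params = fit_expression_mixture(np.full(100, 3.0), seed=0)
        assert params.fallback

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_expression_mixture(np.array([1.0, 2.0]), min_nonzero=20)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(1, 0.5, 300), rng.normal(7, 1, 300)])
        a = fit_expression_mixture(values, seed=5)
        b = fit_expression_mixture(values, seed=5)
        assert a == b


def _expr_from_tpm(tpm_col, genes):
    tpm = np.asarray(tpm_col, dtype=float)[:, None]
    tpm = tpm / tpm.sum() * 1e6
    return ExpressionMatrix(gene_ids=list(genes), sample_ids=["s"], tpm=tpm)


class TestDiscretize:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(2)
        low = rng.normal(2, 0.5, 400)
        high = rng.normal(9, 1.0, 600)
        values = np.concatenate([low, high])
        return fit_expression_mixture(values, seed=0)

    def test_gene_at_high_mean_is_expressed(self, fitted):
        tpm_val = 2 ** fitted.mu_high - 1
        expr = _expr_from_tpm([tpm_val, 1e6], ["g", "pad"])
        # renormalization shifts all log2 values by the same constant;
        # rebuild thresholds around the observed value instead
        observed = np.log2(expr.tpm[0, 0] + 1)
        shifted = type(fitted)(
            mu_low=fitted.mu_low, mu_high=observed, sigma_low=fitted.sigma_low,
            sigma_high=fitted.sigma_high, w_low=fitted.w_low, w_high=fitted.w_high,
        )
        disc = discretize_genes(expr, "s", shifted)
        assert disc.category["g"] == 1

    def test_gene_at_low_mean_is_unexpressed(self, fitted):
        expr = _expr_from_tpm([10, 1e6], ["g", "pad"])
        observed = np.log2(expr.tpm[0, 0] + 1)
        shifted = type(fitted)(
            mu_low=observed, mu_high=observed + 7, sigma_low=fitted.sigma_low,
            sigma_high=fitted.sigma_high, w_low=fitted.w_low, w_high=fitted.w_high,
        )
        disc = discretize_genes(expr, "s", shifted)
        assert disc.category["g"] == -1

    def test_gene_between_thresholds_is_unknown(self, fitted):
        expr = _expr_from_tpm([10, 1e6], ["g", "pad"])
        observed = np.log2(expr.tpm[0, 0] + 1)
        shifted = type(fitted)(
            mu_low=observed - 4, mu_high=observed + 4, sigma_low=1.0,
            sigma_high=1.0, w_low=0.5, w_high=0.5,
        )
        disc = discretize_genes(expr, "s", shifted)
        assert disc.category["g"] == 0

    def test_crossing_thresholds_leave_no_unknown(self, fitted):
        expr = _expr_from_tpm(np.linspace(1, 1e5, 50), [f"g{i}" for i in range(50)])
        params = type(fitted)(
            mu_low=8.0, mu_high=10.0, sigma_low=5.0, sigma_high=5.0, w_low=0.5, w_high=0.5,
        )
        disc = discretize_genes(expr, "s", params)
        assert set(disc.category.values()) <= {-1, 1}

    def test_zero_tpm_always_unexpressed(self, fitted):
        expr = _expr_from_tpm([0, 1e6], ["g", "pad"])
        disc = discretize_genes(expr, "s", fitted)
        assert disc.category["g"] == -1

    def test_monotone_in_tpm(self, fitted):
        """Raising TPM never demotes the category."""
        genes = [f"g{i}" for i in range(60)]
        base_tpm = np.geomspace(0.5, 5e4, 60)
        expr = _expr_from_tpm(base_tpm, genes)
        disc = discretize_genes(expr, "s", fitted)
        order = {-1: 0, 0: 1, 1: 2}
        cats = [disc.category[g] for g in genes]  # genes sorted by increasing TPM
        ranks = [order[c] for c in cats]
        assert ranks == sorted(ranks)


def test_pca_shapes():
    rng = np.random.default_rng(0)
    tpm = rng.uniform(1, 100, (30, 5))
    tpm = tpm / tpm.sum(axis=0) * 1e6
    expr = ExpressionMatrix([f"g{i}" for i in range(30)], [f"s{j}" for j in range(5)], tpm)
    coords = pca_expression(expr, n_components=2, seed=0)
    assert coords.shape == (5, 2)
    assert np.isfinite(coords).all()
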