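import numpy as np
import pytest
from scipy import integrate, interpolate, stats

from rmtnet import (
    SimilarityMatrix,
    build_similarity_matrix,
    chi2_pvalue,
    eigenvalues_symmetric,
    extract_network,
    find_threshold,
    generate_modular_expression,
    nnsd_chi_square,
    planted_edge_precision_recall,
    prune_at_threshold,
    unfold_eigenvalues,
)
from rmtnet.rmt_threshold import SpacingSet, _dedup
from rmtnet.errors import (
    AsymmetricMatrix,
    InsufficientEigenvalues,
    InvalidParameter,
    ThresholdNotFound,
)


def four_gene_sm():
    corr = np.array(
        [
            [1.0, 0.95, 0.1, 0.2],
            [0.95, 1.0, 0.15, 0.1],
            [0.1, 0.15, 1.0, 0.97],
            [0.2, 0.1, 0.97, 1.0],
        ]
    )
    return SimilarityMatrix(["g1", "g2", "g3", "g4"], corr, min_obs=1)


class TestPrune:
    def test_threshold_above_everything_empties_matrix(self):
        pruned, kept = prune_at_threshold(four_gene_sm(), 0.99)
        assert kept == [] and pruned.shape == (0, 0)

    def test_retains_only_strong_pairs(self):
        pruned, kept = prune_at_threshold(four_gene_sm(), 0.9)
        assert kept == ["g1", "g2", "g3", "g4"]
        off = pruned - np.eye(4)
        assert np.count_nonzero(off) == 4  # two symmetric pairs
        assert pruned[0, 1] == 0.95 and pruned[2, 3] == 0.97

    @pytest.mark.parametrize("t", [0.0, -0.5, 1.5])
    def test_threshold_domain(self, t):
        with pytest.raises(InvalidParameter):
            prune_at_threshold(four_gene_sm(), t)


class TestEigenvalues:
    def test_identity_spectrum(self):
        np.testing.assert_allclose(eigenvalues_symmetric(np.eye(5)), np.ones(5))

    def test_diagonal_spectrum(self):
        np.testing.assert_allclose(
            eigenvalues_symmetric(np.diag([3.0, 1.0, 2.0])), [1, 2, 3]
        )

    def test_trace_identity(self, rng):
        a = rng.normal(size=(10, 10))
        m = (a + a.T) / 2
        eigs = eigenvalues_symmetric(m)
        assert np.all(np.diff(eigs) >= 0)
        assert eigs.sum() == pytest.approx(np.trace(m), abs=1e-8)

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(AsymmetricMatrix):
            eigenvalues_symmetric(rng.normal(size=(4, 4)))


def wigner_cdf_by_quadrature():
    grid = np.linspace(0.0, 8.0, 4001)
    pdf = (np.pi / 2) * grid * np.exp(-np.pi * grid**2 / 4)
    cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
    return interpolate.interp1d(
        grid, cdf / cdf[-1], bounds_error=False, fill_value=(0.0, 1.0)
    )


class TestUnfolding:
    def test_linear_staircase_gives_unit_spacings(self):
        sp = unfold_eigenvalues(np.arange(1.0, 201.0))
        np.testing.assert_allclose(sp.spacings, 1.0, atol=1e-6)
        assert sp.mean_spacing == pytest.approx(1.0, abs=1e-12)

    def test_mean_spacing_is_one_by_construction(self, rng):
        sp = unfold_eigenvalues(np.sort(rng.normal(size=300)))
        assert sp.mean_spacing == pytest.approx(1.0, abs=1e-9)
        assert np.all(sp.spacings >= 0)

    def test_dedup_is_idempotent(self, rng):
        eigs = np.sort(np.repeat(rng.normal(size=100), 3) + rng.normal(scale=1e-9, size=300))
        once = _dedup(np.sort(eigs), 1e-6)
        twice = _dedup(once, 1e-6)
        np.testing.assert_array_equal(once, twice)

    def test_goe_spacings_match_wigner_surmise(self):
        """Unfolded GOE spectrum vs numerically integrated Wigner surmise."""
        rng = np.random.default_rng(42)
        a = rng.standard_normal((500, 500))
        sp = unfold_eigenvalues(np.linalg.eigvalsh((a + a.T) / np.sqrt(2)))
        ks = stats.kstest(sp.spacings, wigner_cdf_by_quadrature()).statistic
        assert ks < 0.05

    def test_too_few_unique_eigenvalues(self):
        with pytest.raises(InsufficientEigenvalues):
            unfold_eigenvalues(np.ones(50))


class TestNNSDChiSquare:
    def test_matches_definition(self, rng):
        """Independent re-evaluation of the binned statistic from its formula."""
        s = rng.exponential(1.0, 1500)
        got = nnsd_chi_square(SpacingSet.from_spacings(s))
        edges = np.linspace(0, 3, 61)
        kept = s[s <= 3.0]
        obs = np.array([(np.logical_and(kept >= a, kept < b)).sum() for a, b in zip(edges[:-1], edges[1:])])
        obs[-1] += (kept == 3.0).sum()
        exp = kept.size * (np.exp(-edges[:-1]) - np.exp(-edges[1:])) / (1 - np.exp(-3.0))
        assert got == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)

    def test_poisson_ensemble_accepted(self):
        crit = stats.chi2.ppf(1 - 0.001, 59)
        hits = 0
        for seed in range(20):
            s = np.random.default_rng(seed).exponential(1.0, 3000)
            hits += nnsd_chi_square(SpacingSet.from_spacings(s)) < crit
        assert hits >= 19

    def test_wigner_ensemble_rejected(self):
        for seed in range(5):
            u = np.random.default_rng(seed).uniform(size=3000)
            s = np.sqrt(-4 * np.log(1 - u) / np.pi)  # inverse Wigner-surmise CDF
            assert nnsd_chi_square(SpacingSet.from_spacings(s)) > 200

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameter):
            nnsd_chi_square(SpacingSet.from_spacings([]))


class TestChi2Pvalue:
    def test_paper_anchor(self):
        assert chi2_pvalue(100, 59) <= 0.001

    def test_zero_statistic(self):
        assert chi2_pvalue(0.0, 59) == 1.0

    def test_matches_quadrature(self):
        pdf = lambda x: stats.chi2.pdf(x, 59)
        expected, _ = integrate.quad(pdf, 59, np.inf)
        assert chi2_pvalue(59, 59) == pytest.approx(expected, abs=1e-6)
        assert chi2_pvalue(59, 59) == pytest.approx(0.47, abs=0.01)

    def test_invalid_df(self):
        with pytest.raises(InvalidParameter):
            chi2_pvalue(10, 0)


class TestFindThreshold:
    def test_planted_modules_confirmed_with_high_precision(self, planted_pipeline):
        em, truth, sm, result, net = planted_pipeline
        assert result.confirmed
        assert result.final_threshold == pytest.approx(
            result.divergence_threshold + 0.001, abs=1e-9
        )
        precision, recall = planted_edge_precision_recall(net, truth)
        assert precision >= 0.95

    def test_trace_contract(self, planted_pipeline):
        _, _, _, result, _ = planted_pipeline
        start, step, *_ = result.params
        ts = [r.threshold for r in result.trace]
        assert ts[0] == start
        np.testing.assert_allclose(np.diff(ts), -step, atol=1e-9)

    def test_pure_noise_has_no_transition(self):
        em, _ = generate_modular_expression(
            n_genes=600, n_samples=200, n_modules=0, module_size=1,
            loading=0.0, seed=7,
        )
        sm = build_similarity_matrix(em)
        with pytest.raises(ThresholdNotFound) as exc:
            find_threshold(sm)
        assert len(exc.value.trace) > 0

    def test_chi2_rises_through_confirmation_on_descent(self, planted_pipeline):
        """Poisson regime first, then a sustained rise through both levels."""
        _, _, _, result, _ = planted_pipeline
        defined = [(r.threshold, r.chi2) for r in result.trace if r.chi2 is not None]
        assert defined[-1][1] >= 200
        assert all(c >= 100 for t, c in defined if t <= result.divergence_threshold)

    def test_parameter_domains(self, planted_pipeline):
        _, _, sm, _, _ = planted_pipeline
        with pytest.raises(InvalidParameter):
            find_threshold(sm, start=0.9, t_min=0.95)
        with pytest.raises(InvalidParameter):
            find_threshold(sm, step=0.0)
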