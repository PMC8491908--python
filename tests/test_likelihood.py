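"""Dense, Woodbury/Sylvester, and low-rank likelihood paths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msfinemap.inference import compute_posteriors
from msfinemap.likelihood import (
    FastCache,
    LowrankCache,
    SingularLDError,
    eigen_ld,
    loglik_dense,
    loglik_fast,
    loglik_lowrank,
)
from msfinemap.model import (
    CausalConfig,
    InferenceParams,
    MultiStudyLocus,
    NcpModel,
    build_causal_covariance,
)

from _oracles import make_random_ld, make_random_locus, scipy_dense_loglik

LOG2PI = np.log(2 * np.pi)


def lowrank_constant(eigens):
    """Jacobian constant relating low-rank and dense log-likelihoods."""
    return 0.5 * sum(np.sum(np.log(e.eigenvalues)) for e in eigens)


class TestDense:
    def test_standard_normal_at_origin(self):
        locus = MultiStudyLocus(["a"], [np.array([0.0])], [np.eye(1)])
        cov = build_causal_covariance(CausalConfig([0]), NcpModel(), n_studies=1)
        assert loglik_dense(locus, cov) == pytest.approx(-0.5 * LOG2PI)

    def test_symmetric_in_sign_of_z(self, rng, ncp):
        locus = make_random_locus(rng, 6, 2)
        flipped = MultiStudyLocus(
            locus.snp_ids, [-z for z in locus.z], locus.ld
        )
        cfg = CausalConfig.from_indices([0, 3], 6)
        cov = build_causal_covariance(cfg, ncp, n_studies=2)
        assert loglik_dense(locus, cov) == pytest.approx(loglik_dense(flipped, cov))

    def test_matches_independent_mvn_density(self, rng, ncp):
        locus = make_random_locus(rng, 5, 2)
        cfg = CausalConfig.from_indices([1, 4], 5)
        cov = build_causal_covariance(cfg, ncp, n_studies=2)
        ours = loglik_dense(locus, cov)
        oracle = scipy_dense_loglik(locus, cov.matrix)
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_singular_ld_raises_with_guidance(self, ncp):
        ld = np.ones((2, 2))  # perfect LD
        locus = MultiStudyLocus(["a", "b"], [np.array([1.0, 1.0])], [ld])
        cov = build_causal_covariance(CausalConfig([1, 0]), ncp, n_studies=1)
        with pytest.raises(SingularLDError, match="low-rank"):
            loglik_dense(locus, cov)


class TestFast:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.integers(2, 12),
        st.integers(1, 3),
        st.integers(1, 3),
        st.integers(0, 2**30),
    )
    def test_equals_dense_on_random_instances(self, m, q, k, seed):
        rng = np.random.default_rng(seed)
        k = min(k, m)
        locus = make_random_locus(rng, m, q)
        ncp = NcpModel(ncp_scale=5.2, tau_sq=0.52)
        cfg = CausalConfig.from_indices(rng.choice(m, k, replace=False), m)
        dense = loglik_dense(
            locus, build_causal_covariance(cfg, ncp, n_studies=q)
        )
        fast = loglik_fast(locus, cfg, ncp)
        assert abs(fast - dense) / (1 + abs(dense)) < 1e-8

    def test_all_snps_causal_degenerate_k(self, rng, ncp):
        """K = M (no dimensionality saving) still equals the dense oracle."""
        m = 5
        locus = make_random_locus(rng, m, 2)
        cfg = CausalConfig(np.ones(m))
        dense = loglik_dense(locus, build_causal_covariance(cfg, ncp, n_studies=2))
        assert loglik_fast(locus, cfg, ncp) == pytest.approx(dense, rel=1e-9)

    def test_closed_form_no_ld_single_causal(self, rng):
        """Identity LD, one causal SNP, Q=1, tau^2=0: hand-derived density."""
        m, j = 6, 2
        z = rng.standard_normal(m) * 2
        locus = MultiStudyLocus([f"s{i}" for i in range(m)], [z], [np.eye(m)])
        ncp = NcpModel(ncp_scale=2.0, tau_sq=0.0)
        s2 = ncp.sigma_sq
        expected = -0.5 * (
            np.sum(z**2) - z[j] ** 2 * s2 / (1 + s2) + np.log(1 + s2) + m * LOG2PI
        )
        got = loglik_fast(locus, CausalConfig.from_indices([j], m), ncp)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_cache_reuse_is_bit_identical(self, rng, ncp):
        locus = make_random_locus(rng, 8, 2)
        cache = FastCache.from_locus(locus)
        for idx in ([0], [2, 5], [1, 3, 7]):
            cfg = CausalConfig.from_indices(idx, 8)
            cached = loglik_fast(locus, cfg, ncp, cache=cache)
            uncached = loglik_fast(locus, cfg, ncp)
            assert cached == uncached  # exact float equality

    def test_unequal_sample_sizes_agree_with_dense(self, rng, ncp):
        locus = make_random_locus(rng, 6, 2, sample_sizes=[800, 3200])
        cfg = CausalConfig.from_indices([1, 4], 6)
        dense = loglik_dense(
            locus,
            build_causal_covariance(cfg, ncp, locus.sample_sizes, 2),
        )
        assert loglik_fast(locus, cfg, ncp) == pytest.approx(dense, rel=1e-9)


class TestEigenLD:
    def test_identity_spectrum(self):
        e = eigen_ld(np.eye(4))
        assert e.rank == 4
        assert np.allclose(e.eigenvalues, 1.0)

    def test_duplicated_snps_reduce_rank(self, rng):
        base = make_random_ld(3, rng)
        ld = np.zeros((4, 4))
        ld[:3, :3] = base
        ld[3, :3] = base[2, :]
        ld[:3, 3] = base[:, 2]
        ld[3, 3] = 1.0
        assert eigen_ld(ld).rank == 3

    def test_reconstruction(self, rng):
        ld = make_random_ld(6, rng)
        e = eigen_ld(ld)
        assert np.allclose(e.reconstruct(), ld, atol=1e-8)

    def test_sign_convention_is_deterministic(self, rng):
        ld = make_random_ld(5, rng)
        w1 = eigen_ld(ld).eigenvectors
        w2 = eigen_ld(ld.copy()).eigenvectors
        assert np.array_equal(w1, w2)
        anchors = np.argmax(np.abs(w1), axis=0)
        assert np.all(w1[anchors, np.arange(w1.shape[1])] > 0)

    def test_asymmetric_input_rejected(self):
        bad = np.eye(3)
        bad[0, 2] = 0.4
        with pytest.raises(ValueError, match="symmetric"):
            eigen_ld(bad)


class TestLowrank:
    def test_differs_from_dense_by_constant(self, rng, ncp):
        """Full-rank LD: lowrank = dense + (config-independent Jacobian)."""
        locus = make_random_locus(rng, 7, 2)
        eigens = [eigen_ld(locus.ld[q], z=locus.z[q]) for q in range(2)]
        const = lowrank_constant(eigens)
        for idx in ([0], [1, 5], [2, 3, 6]):
            cfg = CausalConfig.from_indices(idx, 7)
            dense = loglik_dense(
                locus, build_causal_covariance(cfg, ncp, n_studies=2)
            )
            lr = loglik_lowrank(eigens, cfg, ncp)
            assert lr - const == pytest.approx(dense, rel=1e-9)

    def test_posteriors_match_dense_path(self, rng, ncp):
        locus = make_random_locus(rng, 8, 2)
        params = InferenceParams(max_causal=2)
        p_dense = compute_posteriors(locus, ncp, params, path="dense").posterior
        p_low = compute_posteriors(locus, ncp, params, path="lowrank").posterior
        assert np.max(np.abs(p_dense - p_low)) < 1e-6

    def test_rank_deficient_duplicate_snp(self, rng, ncp):
        """Perfect proxies: finite likelihoods and identical inclusion probs."""
        base = make_random_ld(4, rng)
        m = 5
        ld = np.zeros((m, m))
        ld[:4, :4] = base
        ld[4, :4] = base[3, :]
        ld[:4, 4] = base[:, 3]
        ld[4, 4] = 1.0
        z = np.array([1.0, 0.5, 4.8, 5.1, 5.1])
        locus = MultiStudyLocus([f"s{i}" for i in range(m)], [z], [ld])
        table = compute_posteriors(locus, ncp, InferenceParams(max_causal=2))
        assert np.all(np.isfinite(table.log_post))
        assert table.pip[3] == pytest.approx(table.pip[4], abs=1e-10)

    def test_identity_ld_posterior_invariant_to_rotation(self, rng, ncp):
        """With Sigma = I the eigenbasis is an arbitrary orthogonal choice;
        posteriors must not depend on it."""
        m = 5
        z = rng.standard_normal(m) * 3
        locus = MultiStudyLocus([f"s{i}" for i in range(m)], [z], [np.eye(m)])
        params = InferenceParams(max_causal=2)
        p_low = compute_posteriors(locus, ncp, params, path="lowrank").posterior
        p_fast = compute_posteriors(locus, ncp, params, path="fast").posterior
        assert np.max(np.abs(p_low - p_fast)) < 1e-8
        eigens = [eigen_ld(np.eye(m), z=z)]
        sprime = eigens[0].transformed_stats
        assert sorted(np.abs(sprime).round(10)) == sorted(np.abs(z).round(10))

    def test_printed_scale_variant_runs_and_differs(self, rng, ncp):
        """The printed I + m B Sigma_C B' convention is available for
        cross-checking but is not posterior-equivalent to the dense model."""
        locus = make_random_locus(rng, 6, 2)
        eigens = [eigen_ld(locus.ld[q], z=locus.z[q]) for q in range(2)]
        cfg = CausalConfig.from_indices([1, 4], 6)
        exact = loglik_lowrank(eigens, cfg, ncp)
        printed = loglik_lowrank(eigens, cfg, ncp, printed_form=True)
        assert np.isfinite(printed)
        assert printed != pytest.approx(exact)

    def test_lowrank_cache_is_bit_identical(self, rng, ncp):
        locus = make_random_locus(rng, 7, 2)
        eigens = [eigen_ld(locus.ld[q], z=locus.z[q]) for q in range(2)]
        cache = LowrankCache.from_eigens(eigens, 7)
        cfg = CausalConfig.from_indices([2, 5], 7)
        assert loglik_lowrank(eigens, cfg, ncp, cache=cache) == loglik_lowrank(
            eigens, cfg, ncp
        )


def test_single_causal_likelihood_monotone_in_signal(ncp):
    """For independent SNPs, raising |Z_j| raises the likelihood ratio of
    config {j} against the other single-SNP configs."""
    m = 4
    ratios = []
    for zj in (2.0, 3.5, 5.0, 6.5):
        z = np.array([zj, 1.0, 0.5, -0.8])
        locus = MultiStudyLocus([f"s{i}" for i in range(m)], [z], [np.eye(m)])
        ll_j = loglik_fast(locus, CausalConfig.from_indices([0], m), ncp)
        ll_alt = loglik_fast(locus, CausalConfig.from_indices([1], m), ncp)
        ratios.append(ll_j - ll_alt)
    assert all(b > a for a, b in zip(ratios, ratios[1:]))
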