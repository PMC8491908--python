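"""Independent reference implementations used as test oracles.

Everything here is deliberately coded from first principles (scipy density
calls, explicit enumeration) and shares no code with the package's
likelihood or inference paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import multivariate_normal

from msfinemap.model import MultiStudyLocus


def make_random_ld(m: int, rng: np.random.Generator) -> np.ndarray:
    """Random full-rank correlation matrix (Wishart-style)."""
    a = rng.standard_normal((m, 3 * m))
    return np.corrcoef(a)


def make_random_locus(
    rng: np.random.Generator, m: int, q: int, z_scale: float = 2.5,
    sample_sizes=None,
) -> MultiStudyLocus:
    ld = [make_random_ld(m, rng) for _ in range(q)]
    z = [z_scale * rng.standard_normal(m) for _ in range(q)]
    return MultiStudyLocus([f"s{i}" for i in range(m)], z, ld, sample_sizes)


def block_diag_ld(locus: MultiStudyLocus) -> np.ndarray:
    m, q = locus.n_snps, locus.n_studies
    sigma = np.zeros((m * q, m * q))
    for i in range(q):
        sigma[i * m:(i + 1) * m, i * m:(i + 1) * m] = locus.ld[i]
    return sigma


def scipy_dense_loglik(locus: MultiStudyLocus, causal_cov: np.ndarray) -> float:
    """MVN log-density of the stacked Z-scores via scipy (the dense oracle)."""
    sigma = block_diag_ld(locus)
    cov = sigma + sigma @ causal_cov @ sigma
    s = np.concatenate(locus.z)
    return float(
        multivariate_normal(mean=np.zeros(s.shape[0]), cov=cov).logpdf(s)
    )


def multi_study_causal_cov(
    indices, m: int, q: int, sigma_sq: float, tau_sq: float
) -> np.ndarray:
    """Study-major random-effects causal covariance, built elementwise."""
    cov = np.zeros((m * q, m * q))
    for j in indices:
        for q1 in range(q):
            for q2 in range(q):
                cov[q1 * m + j, q2 * m + j] = sigma_sq + (tau_sq if q1 == q2 else 0.0)
    return cov


def brute_force_posteriors(
    locus: MultiStudyLocus,
    sigma_sq: float,
    tau_sq: float,
    gamma: float,
    max_causal: int,
):
    """Posterior over all 1..max_causal configurations via scipy densities.

    Returns (list of index tuples, posterior array, pip array); normalization
    is done in probability space (only safe at small M).
    """
    m, q = locus.n_snps, locus.n_studies
    configs, weights = [], []
    for k in range(1, max_causal + 1):
        for combo in itertools.combinations(range(m), k):
            ll = scipy_dense_loglik(
                locus, multi_study_causal_cov(combo, m, q, sigma_sq, tau_sq)
            )
            prior = k * np.log(gamma) + (m - k) * np.log(1 - gamma)
            configs.append(combo)
            weights.append(ll + prior)
    weights = np.array(weights)
    post = np.exp(weights - weights.max())
    post /= post.sum()
    pip = np.zeros(m)
    for combo, p in zip(configs, post):
        for j in combo:
            pip[j] += p
    return configs, post, pip


def exhaustive_min_set_size(configs, post, m: int, rho_star: float) -> int:
    """Smallest subset of SNPs whose compatible-configuration mass >= rho*."""
    config_masks = [frozenset(c) for c in configs]
    for size in range(1, m + 1):
        for subset in itertools.combinations(range(m), size):
            s = set(subset)
            mass = sum(p for c, p in zip(config_masks, post) if c <= s)
            if mass >= rho_star - 1e-12:
                return size
    return m


def binomial_lower_bound(successes: int, n: int, alpha: float = 0.05) -> float:
    """One-sided Clopper-Pearson lower confidence bound for a proportion."""
    from scipy.stats import beta

    if successes == 0:
        return 0.0
    if successes == n:
        return float(alpha ** (1.0 / n))
    return float(beta.ppf(alpha, successes, n - successes + 1))
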