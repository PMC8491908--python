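"""Independent single-study fine-mapping model, used as a reduction oracle.

A from-scratch implementation of the classic single-study Bayesian
fine-mapping posterior: S ~ N(0, Sigma + Sigma Sigma_C Sigma) with
Sigma_C = diag(sigma^2 * C), Bernoulli(gamma) configuration prior, posterior
normalized over all configurations with 1..max_causal causal SNPs.  Shares
no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import multivariate_normal


def caviar_posteriors(
    z: np.ndarray,
    ld: np.ndarray,
    sigma_sq: float,
    gamma: float,
    max_causal: int,
):
    """(configs, posterior, pip) of the single-study model."""
    z = np.asarray(z, dtype=float)
    ld = np.asarray(ld, dtype=float)
    m = z.shape[0]
    configs, logw = [], []
    for k in range(1, max_causal + 1):
        for combo in itertools.combinations(range(m), k):
            diag = np.zeros(m)
            diag[list(combo)] = sigma_sq
            cov = ld + ld @ np.diag(diag) @ ld
            ll = multivariate_normal(mean=np.zeros(m), cov=cov).logpdf(z)
            logw.append(ll + k * np.log(gamma) + (m - k) * np.log(1 - gamma))
            configs.append(combo)
    logw = np.array(logw)
    post = np.exp(logw - logw.max())
    post /= post.sum()
    pip = np.zeros(m)
    for combo, p in zip(configs, post):
        for j in combo:
            pip[j] += p
    return configs, post, pip
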