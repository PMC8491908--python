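"""Scikit-learn-style front end for multi-study fine mapping.

``MultiStudyFineMapper`` wraps the posterior machinery in an estimator with
``fit``/``get_params``/``set_params`` so it composes with sklearn tooling;
fitted results live in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .inference import PosteriorTable, compute_posteriors, confidence_set
from .model import InferenceParams, MultiStudyLocus, NcpModel

__all__ = ["MultiStudyFineMapper"]


class MultiStudyFineMapper(BaseEstimator):
    """Bayesian fine mapper for one GWAS locus observed in one or more studies.

    Given per-study Z-scores and LD matrices over the same M SNPs, computes
    the posterior over causal configurations under a random-effects model of
    between-study effect-size heterogeneity, per-SNP posterior inclusion
    probabilities, and the minimal SNP set containing all causal SNPs with
    posterior probability at least ``rho_star``.

    Parameters
    ----------
    gamma : float, default 0.01
        Prior probability that any one SNP is causal.
    rho_star : float, default 0.95
        Confidence level of the returned causal set.
    max_causal : int, default 3
        Maximum number of simultaneously causal SNPs searched.
    tau_sq : float, default 0.52
        Between-study heterogeneity variance of causal non-centrality
        parameters.
    ncp_scale : float, default 5.2
        Standard deviation sigma of a causal SNP's mean non-centrality
        parameter, assigned to the smallest study (the genome-wide
        significance Z-score).
    path : {"lowrank", "fast", "dense"}, default "lowrank"
        Likelihood route; "lowrank" handles rank-deficient LD.
    include_null_config : bool, default False
        Include the all-zero configuration in the normalizing sum.
    epsilon : float, default 0.0
        Legacy ridge on non-causal diagonal entries of the causal covariance
        (dense path only).
    truncation_threshold : float, default 1e-8
        Relative eigenvalue cutoff of the low-rank path.

    Attributes
    ----------
    posterior_ : PosteriorTable
        Full per-configuration posterior table.
    pip_ : ndarray of shape (M,)
        Per-SNP posterior inclusion probabilities.
    credible_set_ : tuple of str
        SNP identifiers of the rho*-confidence causal set, PIP-descending.
    set_prob_ : float
        Exact posterior mass that the set contains all causal SNPs.
    snp_ids_ : tuple of str
    n_snps_ : int
    n_studies_ : int

    Examples
    --------
    >>> import numpy as np
    >>> from msfinemap import MultiStudyFineMapper
    >>> z = [np.array([5.4, 1.1, 0.3]), np.array([4.9, 0.2, 0.8])]
    >>> ld = [np.eye(3), np.eye(3)]
    >>> mapper = MultiStudyFineMapper().fit((["rs1", "rs2", "rs3"], z, ld))
    >>> mapper.credible_set_
    ('rs1',)
    """

    def __init__(
        self,
        gamma: float = 0.01,
        rho_star: float = 0.95,
        max_causal: int = 3,
        tau_sq: float = 0.52,
        ncp_scale: float = 5.2,
        path: str = "lowrank",
        include_null_config: bool = False,
        epsilon: float = 0.0,
        truncation_threshold: float = 1e-8,
    ):
        self.gamma = gamma
        self.rho_star = rho_star
        self.max_causal = max_causal
        self.tau_sq = tau_sq
        self.ncp_scale = ncp_scale
        self.path = path
        self.include_null_config = include_null_config
        self.epsilon = epsilon
        self.truncation_threshold = truncation_threshold

    def _as_locus(self, X) -> MultiStudyLocus:
        if isinstance(X, MultiStudyLocus):
            return X
        if isinstance(X, (tuple, list)):
            if len(X) == 3:
                snp_ids, z, ld = X
                return MultiStudyLocus(snp_ids, z, ld)
            if len(X) == 2:
                z, ld = X
                m = len(np.asarray(z[0]).ravel())
                return MultiStudyLocus([f"snp{i}" for i in range(m)], z, ld)
        raise TypeError(
            "X must be a MultiStudyLocus, (snp_ids, z_list, ld_list) or "
            "(z_list, ld_list)"
        )

    def fit(self, X, y=None) -> "MultiStudyFineMapper":
        """Run posterior inference on a locus.

        ``X`` is a :class:`MultiStudyLocus`, a ``(snp_ids, z_list, ld_list)``
        triple, or a ``(z_list, ld_list)`` pair; ``y`` is ignored (present
        for sklearn API compatibility).
        """
        locus = self._as_locus(X)
        ncp = NcpModel(ncp_scale=self.ncp_scale, tau_sq=self.tau_sq)
        params = InferenceParams(
            gamma=self.gamma,
            rho_star=self.rho_star,
            max_causal=min(self.max_causal, locus.n_snps),
            epsilon=self.epsilon,
            include_null=self.include_null_config,
        )
        table = compute_posteriors(
            locus,
            ncp,
            params,
            path=self.path,
            truncation_threshold=self.truncation_threshold,
        )
        self.posterior_ = table
        self.pip_ = table.pip
        self.credible_set_ = table.set_members
        self.set_prob_ = table.set_prob
        self.snp_ids_ = locus.snp_ids
        self.n_snps_ = locus.n_snps
        self.n_studies_ = locus.n_studies
        return self

    def get_credible_set(self, rho_star: float | None = None):
        """(members, probability) of the confidence set at ``rho_star``.

        Recomputes the greedy set from the fitted posterior table without
        refitting; defaults to the estimator's ``rho_star``.
        """
        self._check_fitted()
        if rho_star is None:
            return self.credible_set_, self.set_prob_
        table = self.posterior_
        members, prob = confidence_set(table, rho_star)
        # restore the fitted-level set on the table
        confidence_set(table, self.rho_star)
        return members, prob

    def _check_fitted(self):
        if not hasattr(self, "posterior_"):
            raise AttributeError("this MultiStudyFineMapper instance is not fitted yet")
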