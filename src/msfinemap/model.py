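"""Core probabilistic model: loci, causal configurations, priors and covariances.

A locus holds, for each of ``Q`` studies, a vector of signed Z-scores over the
same ``M`` SNPs plus that study's LD (Pearson correlation) matrix.  A causal
*configuration* is a binary vector ``C`` over the M SNPs.  Under the
random-effects model, each causal SNP ``m`` carries a global mean
non-centrality parameter (NCP) ``lambda_m ~ N(0, sigma^2)`` and each study's
NCP is drawn around it with heterogeneity variance ``tau^2``.  Integrating the
latent NCPs out yields the causal covariance

    Sigma_C = (tau^2 I_Q + sigma^2 1_Q 1_Q') (x) diag(C)

(a Q x Q study covariance Kronecker the M x M causal indicator), generalized to
unequal sample sizes by sigma^2_{q1 q2} = sqrt(N_q1 N_q2) sigma_g^2.

All MQ-length vectors and (MQ x MQ) matrices in this package use the
**study-major** layout: study 1's M SNPs first, then study 2's, and so on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "MultiStudyLocus",
    "CausalConfig",
    "NcpModel",
    "InferenceParams",
    "CausalCovariance",
    "config_prior_log",
    "build_causal_covariance",
    "enumerate_configs",
    "study_scale_matrix",
    "causal_block_covariance",
]

_LD_TOL = 1e-6


@dataclass(frozen=True)
class MultiStudyLocus:
    """Aligned per-study Z-scores and LD matrices for one locus.

    Parameters
    ----------
    snp_ids : sequence of str
        SNP identifiers, shared (and identically ordered) across studies.
    z : list of ndarray
        One signed Z-score vector of length M per study.
    ld : list of ndarray
        One symmetric M x M correlation matrix per study.
    sample_sizes : sequence of int, optional
        Per-study sample sizes N_q; used to scale causal-effect variances
        when studies differ in size.
    """

    snp_ids: tuple[str, ...]
    z: tuple[np.ndarray, ...]
    ld: tuple[np.ndarray, ...]
    sample_sizes: tuple[int, ...] | None = None

    def __init__(self, snp_ids, z, ld, sample_sizes=None):
        snp_ids = tuple(str(s) for s in snp_ids)
        z = tuple(np.asarray(v, dtype=float).ravel() for v in z)
        ld = tuple(np.asarray(m, dtype=float) for m in ld)
        if sample_sizes is not None:
            sample_sizes = tuple(int(n) for n in sample_sizes)
        object.__setattr__(self, "snp_ids", snp_ids)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "ld", ld)
        object.__setattr__(self, "sample_sizes", sample_sizes)
        self._validate()

    def _validate(self) -> None:
        M = len(self.snp_ids)
        Q = len(self.z)
        if M < 1:
            raise ValueError("locus must contain at least one SNP")
        if Q < 1 or len(self.ld) != Q:
            raise ValueError(
                f"need one Z vector and one LD matrix per study; got "
                f"{Q} Z vectors and {len(self.ld)} LD matrices"
            )
        if len(set(self.snp_ids)) != M:
            raise ValueError("SNP identifiers must be unique")
        for q, (zq, ldq) in enumerate(zip(self.z, self.ld)):
            if zq.shape != (M,):
                raise ValueError(f"study {q}: Z length {zq.shape[0]} != {M} SNPs")
            if ldq.shape != (M, M):
                raise ValueError(f"study {q}: LD shape {ldq.shape} != ({M}, {M})")
            if not np.allclose(ldq, ldq.T, atol=_LD_TOL):
                raise ValueError(f"study {q}: LD matrix is not symmetric")
            if not np.allclose(np.diag(ldq), 1.0, atol=_LD_TOL):
                raise ValueError(f"study {q}: LD diagonal must be 1")
            if np.any(np.abs(ldq) > 1.0 + _LD_TOL):
                raise ValueError(f"study {q}: LD entries must lie in [-1, 1]")
        if self.sample_sizes is not None:
            if len(self.sample_sizes) != Q:
                raise ValueError("sample_sizes must have one entry per study")
            if any(n <= 0 for n in self.sample_sizes):
                raise ValueError("sample sizes must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_studies(self) -> int:
        return len(self.z)

    def single_study(self, q: int) -> "MultiStudyLocus":
        """View of study ``q`` alone (for per-study comparison runs)."""
        ns = (self.sample_sizes[q],) if self.sample_sizes is not None else None
        return MultiStudyLocus(self.snp_ids, (self.z[q],), (self.ld[q],), ns)


@dataclass(frozen=True)
class CausalConfig:
    """Binary causal-status vector over the M SNPs of a locus."""

    status: np.ndarray

    def __init__(self, status):
        status = np.asarray(status)
        if status.ndim != 1:
            raise ValueError("configuration must be a 1-D vector")
        if not np.isin(status, (0, 1)).all():
            raise ValueError("configuration entries must be 0 or 1")
        object.__setattr__(self, "status", status.astype(np.int8))

    @classmethod
    def from_indices(cls, indices: Sequence[int], n_snps: int) -> "CausalConfig":
        status = np.zeros(n_snps, dtype=np.int8)
        status[list(indices)] = 1
        return cls(status)

    @property
    def k(self) -> int:
        """Number of causal SNPs in the configuration."""
        return int(self.status.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.status)

    def __len__(self) -> int:
        return self.status.shape[0]


@dataclass(frozen=True)
class NcpModel:
    """Variance model of the causal non-centrality parameters.

    ``ncp_scale`` is the standard deviation sigma assigned to a causal SNP's
    mean NCP in the *smallest* study; the default 5.2 is the Z-score whose
    two-sided p-value is the genome-wide threshold 5e-8, chosen so borderline
    genome-wide-significant SNPs carry appreciable prior signal variance.
    ``tau_sq`` is the between-study heterogeneity variance tau^2 (default
    0.52, i.e. 10% of sigma).  The latent per-SNP NCPs are integrated out
    analytically and never stored.
    """

    ncp_scale: float = 5.2
    tau_sq: float = 0.52

    def __post_init__(self):
        if self.ncp_scale <= 0:
            raise ValueError("ncp_scale (sigma) must be positive")
        if self.tau_sq < 0:
            raise ValueError("tau_sq must be nonnegative")

    @property
    def sigma_sq(self) -> float:
        """sigma^2 in the equal-sample-size (single-scale) setting."""
        return self.ncp_scale**2

    def sigma_g_sq(self, sample_sizes: Sequence[int]) -> float:
        """Abstract per-SNP genetic variance with sigma^2 = N_min * sigma_g^2."""
        n_min = min(sample_sizes)
        if n_min <= 0:
            raise ValueError("sample sizes must be positive")
        return self.ncp_scale**2 / n_min


@dataclass(frozen=True)
class InferenceParams:
    """Tuning parameters of the posterior search.

    gamma : prior probability that any one SNP is causal.
    rho_star : target posterior mass of the returned causal set.
    max_causal : maximum number of simultaneously causal SNPs searched (K).
    epsilon : ridge added to non-causal diagonal entries of Sigma_C in the
        legacy full-rank construction (0 disables; the low-rank likelihood
        path removes the need for it).
    include_null : include the all-zero configuration in the normalizing sum.
    """

    gamma: float = 0.01
    rho_star: float = 0.95
    max_causal: int = 3
    epsilon: float = 0.0
    include_null: bool = False

    def __post_init__(self):
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie strictly in (0, 1)")
        if not 0.0 < self.rho_star <= 1.0:
            raise ValueError("rho_star must lie in (0, 1]")
        if self.max_causal < 1:
            raise ValueError("max_causal must be at least 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")


@dataclass(frozen=True)
class CausalCovariance:
    """The (MQ x MQ) random-effects causal covariance, study-major layout."""

    matrix: np.ndarray
    layout: str = "study-major"


def config_prior_log(config: CausalConfig, params: InferenceParams) -> float:
    """Log prior of a configuration under independent Bernoulli(gamma) statuses."""
    c = config.status.astype(float)
    return float(np.sum(c * np.log(params.gamma) + (1.0 - c) * np.log1p(-params.gamma)))


def config_prior_log_by_count(k: int, n_snps: int, gamma: float) -> float:
    """Log prior of any configuration with exactly ``k`` causal SNPs."""
    return k * np.log(gamma) + (n_snps - k) * np.log1p(-gamma)


def study_scale_matrix(
    ncp: NcpModel,
    n_studies: int,
    sample_sizes: Sequence[int] | None = None,
) -> np.ndarray:
    """Q x Q covariance of a causal SNP's per-study NCPs.

    Entry (q1, q2) is sqrt(N_q1 N_q2) * sigma_g^2 off the diagonal and
    tau^2 + N_q * sigma_g^2 on it.  With equal (or absent) sample sizes every
    sigma^2 term equals ``ncp_scale**2``.
    """
    if sample_sizes is None:
        root_n = np.ones(n_studies)
        sigma_g_sq = ncp.sigma_sq
    else:
        if len(sample_sizes) != n_studies:
            raise ValueError("sample_sizes must have one entry per study")
        if any(n <= 0 for n in sample_sizes):
            raise ValueError("sample sizes must be positive")
        root_n = np.sqrt(np.asarray(sample_sizes, dtype=float))
        sigma_g_sq = ncp.sigma_g_sq(sample_sizes)
    psi = sigma_g_sq * np.outer(root_n, root_n)
    psi[np.diag_indices(n_studies)] += ncp.tau_sq
    return psi


def causal_block_covariance(
    k: int,
    ncp: NcpModel,
    n_studies: int,
    sample_sizes: Sequence[int] | None = None,
) -> np.ndarray:
    """The dense (kQ x kQ) block of Sigma_C restricted to k causal SNPs.

    With the study-major index ordering (study 0's k causal SNPs, then study
    1's, ...), the restriction of Sigma_C to its nonzero rows/columns is the
    Kronecker product of the study-scale matrix with I_k; it depends only on
    ``k``, not on which SNPs are causal.
    """
    psi = study_scale_matrix(ncp, n_studies, sample_sizes)
    return np.kron(psi, np.eye(k))


def build_causal_covariance(
    config: CausalConfig,
    ncp: NcpModel,
    sample_sizes: Sequence[int] | None = None,
    n_studies: int = 1,
    epsilon: float = 0.0,
) -> CausalCovariance:
    """Materialize the full (MQ x MQ) causal covariance Sigma_C.

    Block (q1, q2) of the Q x Q grid of M x M blocks is diagonal: a causal
    SNP contributes tau^2 + sigma^2_q on diagonal blocks and
    sigma^2_{q1 q2} = sqrt(N_q1 N_q2) sigma_g^2 on cross-study blocks; a
    non-causal SNP contributes 0 everywhere (``epsilon`` on within-study
    diagonals in legacy mode).  Used by the dense reference likelihood; the
    fast paths build only the kQ nonzero rows/columns via
    :func:`causal_block_covariance`.
    """
    indicator = config.status.astype(float)
    psi = study_scale_matrix(ncp, n_studies, sample_sizes)
    matrix = np.kron(psi, np.diag(indicator))
    if epsilon:
        matrix += epsilon * np.kron(np.eye(n_studies), np.diag(1.0 - indicator))
    return CausalCovariance(matrix=matrix)


def enumerate_configs(n_snps: int, max_causal: int) -> Iterator[CausalConfig]:
    """Yield all configurations with 1 <= k <= max_causal causal SNPs.

    Order: nondecreasing k, lexicographic by causal-index tuple within k.
    The all-zero configuration is excluded (the tool is run on loci with at
    least one signal); see :class:`InferenceParams` ``include_null``.
    """
    if max_causal > n_snps:
        raise ValueError(f"max_causal ({max_causal}) cannot exceed n_snps ({n_snps})")
    if max_causal < 1:
        raise ValueError("max_causal must be at least 1")
    for k in range(1, max_causal + 1):
        for combo in itertools.combinations(range(n_snps), k):
            yield CausalConfig.from_indices(combo, n_snps)


def enumerate_config_indices(n_snps: int, max_causal: int) -> list[np.ndarray]:
    """Causal-index tuples of :func:`enumerate_configs`, grouped by k.

    Returns one ``(n_configs_k, k)`` integer array per k in 1..max_causal —
    the batched representation the likelihood kernels consume.
    """
    if max_causal > n_snps:
        raise ValueError(f"max_causal ({max_causal}) cannot exceed n_snps ({n_snps})")
    out = []
    for k in range(1, max_causal + 1):
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n_snps), k)),
            dtype=np.int64,
        ).reshape(-1, k)
        out.append(combos)
    return out
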