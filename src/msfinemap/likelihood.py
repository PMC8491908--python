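"""Log-likelihood of observed Z-scores under a causal configuration.

Three routes to the same multivariate-normal density
``S ~ N(0, Sigma + Sigma Sigma_C Sigma)`` (Sigma block-diagonal across
studies, Sigma_C the random-effects causal covariance):

``loglik_dense``
    Literal (MQ x MQ) evaluation; the oracle for the other paths.
``loglik_fast``
    Factors Sigma out and applies the Woodbury identity
    ``(I + UV)^-1 = I - U(I_KQ + VU)^-1 V`` and Sylvester's determinant
    identity ``|I + UV| = |I_KQ + VU|``, so each configuration costs a
    (KQ x KQ) solve instead of an (MQ x MQ) one: O(K^3 Q^3) after a one-off
    per-locus O(M^3 Q) factorization.
``loglik_lowrank``
    Works in the eigenbasis of each study's LD matrix with near-null
    directions truncated, so rank-deficient LD (perfect proxies, collinear
    blocks) is handled without any ridge.  With full-rank LD it differs from
    the dense value by a configuration-independent Jacobian constant, so
    posteriors agree across paths.

The reduction used by both fast paths: for columns ``A_J`` of a transform A
restricted to the causal indices J,

    quad = quad0 - t' Sigma_cc (I + G Sigma_cc)^-1 t,
    logdet = logdet0 + log|I + G Sigma_cc|,

with ``G = A_J' A_J`` and ``t = A_J' s``.  For the fast path A is such that
G is the causal submatrix of the LD itself and t the causal Z-scores; for the
low-rank path G is the truncated-eigenbasis reconstruction of the LD and t
the projection of Z onto the retained eigenspace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .model import (
    CausalConfig,
    CausalCovariance,
    MultiStudyLocus,
    NcpModel,
    build_causal_covariance,
    causal_block_covariance,
)

__all__ = [
    "EigenLD",
    "eigen_ld",
    "loglik_dense",
    "loglik_fast",
    "loglik_lowrank",
    "FastCache",
    "LowrankCache",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class SingularLDError(np.linalg.LinAlgError):
    """Raised when a full-rank path meets a singular LD matrix."""


@dataclass(frozen=True)
class EigenLD:
    """Truncated eigendecomposition of one study's LD matrix.

    ``eigenvectors`` (M x rank, columns W) and ``eigenvalues`` (rank,
    descending, all above the truncation threshold) satisfy
    ``W diag(omega) W' ~= Sigma``.  ``projector`` is B = omega^(-1/2) W' and
    ``transformed_stats`` the rotated statistics S' = B S when Z-scores were
    supplied.  Eigenvector signs follow a fixed convention (largest-magnitude
    component positive) so results are reproducible.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    rank: int
    projector: np.ndarray
    transformed_stats: np.ndarray | None = None

    def reconstruct(self) -> np.ndarray:
        """W diag(omega) W' — the LD matrix restricted to retained directions."""
        return (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T


def eigen_ld(
    ld_matrix: np.ndarray,
    truncation_threshold: float = 1e-8,
    z: np.ndarray | None = None,
) -> EigenLD:
    """Eigendecompose an LD matrix, dropping near-null directions.

    ``truncation_threshold`` is relative to the largest eigenvalue.  The
    symmetric input contract is enforced (tolerance 1e-6).
    """
    ld_matrix = np.asarray(ld_matrix, dtype=float)
    if ld_matrix.ndim != 2 or ld_matrix.shape[0] != ld_matrix.shape[1]:
        raise ValueError("LD matrix must be square")
    if not np.allclose(ld_matrix, ld_matrix.T, atol=1e-6):
        raise ValueError("LD matrix is not symmetric")
    omega, w = np.linalg.eigh((ld_matrix + ld_matrix.T) / 2.0)
    # ascending from eigh -> descending for a deterministic retained order
    omega = omega[::-1]
    w = w[:, ::-1]
    cutoff = truncation_threshold * max(omega[0], 0.0)
    keep = omega > cutoff
    omega = omega[keep]
    w = w[:, keep]
    # sign convention: largest-magnitude component of each eigenvector positive
    anchor = np.argmax(np.abs(w), axis=0)
    signs = np.sign(w[anchor, np.arange(w.shape[1])])
    signs[signs == 0] = 1.0
    w = w * signs
    projector = (w / np.sqrt(omega)).T
    s_prime = projector @ np.asarray(z, dtype=float) if z is not None else None
    return EigenLD(
        eigenvectors=w,
        eigenvalues=omega,
        rank=int(omega.shape[0]),
        projector=projector,
        transformed_stats=s_prime,
    )


@dataclass(frozen=True)
class FastCache:
    """Per-locus precomputations for the Woodbury/Sylvester path."""

    gsrc: tuple[np.ndarray, ...]  # per-study LD matrices
    tsrc: tuple[np.ndarray, ...]  # per-study Z-score vectors
    quad0: float  # S' Sigma^-1 S
    logdet0: float  # log|Sigma|
    dim: int  # MQ
    n_studies: int

    @classmethod
    def from_locus(cls, locus: MultiStudyLocus) -> "FastCache":
        quad0 = 0.0
        logdet0 = 0.0
        for q in range(locus.n_studies):
            try:
                c, low = cho_factor(locus.ld[q])
            except np.linalg.LinAlgError as err:
                raise SingularLDError(
                    f"study {q}: LD matrix is singular (or not positive "
                    "definite); use the low-rank likelihood path"
                ) from err
            quad0 += float(locus.z[q] @ cho_solve((c, low), locus.z[q]))
            logdet0 += 2.0 * float(np.sum(np.log(np.diag(c))))
        return cls(
            gsrc=locus.ld,
            tsrc=locus.z,
            quad0=quad0,
            logdet0=logdet0,
            dim=locus.n_snps * locus.n_studies,
            n_studies=locus.n_studies,
        )


@dataclass(frozen=True)
class LowrankCache:
    """Per-locus precomputations for the truncated-eigenbasis path."""

    gsrc: tuple[np.ndarray, ...]
    tsrc: tuple[np.ndarray, ...]
    quad0: float
    logdet0: float
    dim: int
    n_studies: int

    @classmethod
    def from_eigens(
        cls,
        eigens: list[EigenLD],
        n_snps: int,
        printed_form: bool = False,
    ) -> "LowrankCache":
        gsrc, tsrc = [], []
        quad0 = 0.0
        dim = 0
        for e in eigens:
            if e.transformed_stats is None:
                raise ValueError("EigenLD must carry transformed statistics "
                                 "(pass z to eigen_ld)")
            s_prime = e.transformed_stats
            if printed_form:
                # covariance printed as I + m B Sigma_C B' with B = omega^(-1/2) W'
                g = n_snps * (e.eigenvectors / e.eigenvalues) @ e.eigenvectors.T
                t = np.sqrt(n_snps) * (e.projector.T @ s_prime)
            else:
                # exact transform of the dense model: A = omega^(1/2) W'
                g = e.reconstruct()
                t = e.eigenvectors @ (np.sqrt(e.eigenvalues) * s_prime)
            gsrc.append(g)
            tsrc.append(t)
            quad0 += float(s_prime @ s_prime)
            dim += e.rank
        return cls(
            gsrc=tuple(gsrc),
            tsrc=tuple(tsrc),
            quad0=quad0,
            logdet0=0.0,
            dim=dim,
            n_studies=len(eigens),
        )

    @classmethod
    def from_locus(
        cls,
        locus: MultiStudyLocus,
        truncation_threshold: float = 1e-8,
        printed_form: bool = False,
    ) -> "LowrankCache":
        eigens = [
            eigen_ld(locus.ld[q], truncation_threshold, z=locus.z[q])
            for q in range(locus.n_studies)
        ]
        return cls.from_eigens(eigens, locus.n_snps, printed_form=printed_form)


def batch_loglik(
    combos: np.ndarray,
    cache: FastCache | LowrankCache,
    sigma_cc: np.ndarray,
) -> np.ndarray:
    """Log-likelihood of every configuration in ``combos`` (n x k index array).

    ``sigma_cc`` is the (kQ x kQ) causal-block covariance shared by all
    k-causal configurations.  Vectorized over configurations: assembles the
    (kQ x kQ) Woodbury systems for all n configurations and solves them with
    stacked linear algebra.
    """
    combos = np.asarray(combos, dtype=np.int64)
    n, k = combos.shape
    if k == 0:
        value = -0.5 * (cache.dim * _LOG2PI + cache.logdet0 + cache.quad0)
        return np.full(n, value)
    q_count = cache.n_studies
    kq = k * q_count
    g = np.zeros((n, kq, kq))
    t = np.empty((n, kq))
    for q in range(q_count):
        sl = slice(q * k, (q + 1) * k)
        g[:, sl, sl] = cache.gsrc[q][combos[:, :, None], combos[:, None, :]]
        t[:, sl] = cache.tsrc[q][combos]
    mats = np.eye(kq)[None, :, :] + g @ sigma_cc
    sign, logdet = np.linalg.slogdet(mats)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError(
            "non-positive determinant in Woodbury core; LD input is not PSD"
        )
    y = np.linalg.solve(mats, t[..., None])[..., 0]
    reduction = np.einsum("ni,ij,nj->n", t, sigma_cc, y)
    quad = cache.quad0 - reduction
    return -0.5 * (cache.dim * _LOG2PI + cache.logdet0 + logdet + quad)


def loglik_dense(locus: MultiStudyLocus, causal_cov: CausalCovariance) -> float:
    """Dense MVN log-density of the stacked Z-scores; oracle for the fast paths.

    Builds the full (MQ x MQ) covariance Sigma + Sigma Sigma_C Sigma with
    Sigma block-diagonal across studies.  Requires full-rank LD.
    """
    m, q = locus.n_snps, locus.n_studies
    dim = m * q
    if causal_cov.matrix.shape != (dim, dim):
        raise ValueError(
            f"causal covariance is {causal_cov.matrix.shape}, expected ({dim}, {dim})"
        )
    sigma = np.zeros((dim, dim))
    for i in range(q):
        sigma[i * m:(i + 1) * m, i * m:(i + 1) * m] = locus.ld[i]
    s = np.concatenate(locus.z)
    cov = sigma + sigma @ causal_cov.matrix @ sigma
    try:
        c, low = cho_factor(cov)
    except np.linalg.LinAlgError as err:
        raise SingularLDError(
            "joint covariance is singular — the LD matrix is rank deficient; "
            "use the low-rank likelihood path"
        ) from err
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    quad = float(s @ cho_solve((c, low), s))
    return -0.5 * (dim * _LOG2PI + logdet + quad)


def loglik_fast(
    locus: MultiStudyLocus,
    config: CausalConfig,
    ncp: NcpModel,
    cache: FastCache | None = None,
    epsilon: float = 0.0,
) -> float:
    """Woodbury/Sylvester evaluation; equal to :func:`loglik_dense`.

    ``cache`` carries the per-locus S' Sigma^-1 S and log|Sigma|; pass one to
    reuse it across configurations.  Falls back to the dense path (with a
    warning) if the (KQ x KQ) Woodbury core is ill-conditioned.
    """
    if config.k < 1:
        raise ValueError("fast path requires at least one causal SNP")
    if epsilon:
        # legacy ridge breaks the low-rank structure of Sigma_C; dense only
        return loglik_dense(
            locus,
            build_causal_covariance(
                config, ncp, locus.sample_sizes, locus.n_studies, epsilon
            ),
        )
    if cache is None:
        cache = FastCache.from_locus(locus)
    sigma_cc = causal_block_covariance(
        config.k, ncp, locus.n_studies, locus.sample_sizes
    )
    combos = config.indices[None, :]
    # condition check on the single Woodbury core
    q_count = cache.n_studies
    k = config.k
    kq = k * q_count
    g = np.zeros((kq, kq))
    for q in range(q_count):
        sl = slice(q * k, (q + 1) * k)
        g[sl, sl] = cache.gsrc[q][np.ix_(config.indices, config.indices)]
    core = np.eye(kq) + g @ sigma_cc
    if np.linalg.cond(core) > 1e12:
        warnings.warn(
            "ill-conditioned Woodbury core; falling back to dense evaluation",
            RuntimeWarning,
            stacklevel=2,
        )
        return loglik_dense(
            locus,
            build_causal_covariance(config, ncp, locus.sample_sizes, locus.n_studies),
        )
    return float(batch_loglik(combos, cache, sigma_cc)[0])


def loglik_lowrank(
    eigens: list[EigenLD],
    config: CausalConfig,
    ncp: NcpModel,
    sample_sizes=None,
    n_snps: int | None = None,
    printed_form: bool = False,
    cache: LowrankCache | None = None,
) -> float:
    """Likelihood of the rotated statistics S' in the truncated eigenbasis.

    Finite for rank-deficient LD.  With full-rank LD the value equals the
    dense log-likelihood plus a configuration-independent constant (half the
    sum of log-eigenvalues), so normalized posteriors agree across paths.
    ``printed_form`` switches to the ``I + m B Sigma_C B'`` scale convention
    (m = number of SNPs) for cross-checking; it is not posterior-equivalent
    to the dense model and is off by default.
    """
    if n_snps is None:
        n_snps = eigens[0].projector.shape[1]
    if cache is None:
        cache = LowrankCache.from_eigens(eigens, n_snps, printed_form=printed_form)
    if config.k < 1:
        return float(batch_loglik(np.empty((1, 0), dtype=np.int64), cache, np.empty((0, 0)))[0])
    sigma_cc = causal_block_covariance(config.k, ncp, len(eigens), sample_sizes)
    return float(batch_loglik(config.indices[None, :], cache, sigma_cc)[0])
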