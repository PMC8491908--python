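"""Synthetic multi-study GWAS loci and the calibration harness.

Two generation routes:

* ``simulate_summary_direct`` — model-faithful draws in non-centrality
  parameter (NCP) space: each causal SNP gets a mean NCP ``|N(ncp_mean, 1)|``
  (non-negative, so causal signals point the same way in every study), each
  study's NCP is drawn around it with heterogeneity variance tau^2 and scaled
  by sqrt(N_q / N_min) for its sample size, LD propagates the causal NCPs to
  tag SNPs (Lambda_q = Sigma_q Lambda_Cq), and Z-scores are drawn from
  N(Lambda_q, Sigma_q).
* ``simulate_genotype_path`` — a genotype -> phenotype -> marginal-regression
  route: Gaussian-copula genotypes at a target LD and minor allele frequency,
  phenotype y = X beta + e with environmental variance scaled as
  var_g * (1/h^2 - 1) to hit the target heritability, and per-SNP linear
  regression Z-scores with in-sample LD.

The copula's latent correlations are inverse-adjusted (tetrachoric-style
root finding on the bivariate normal CDF) so the *realized* genotype
correlations match the target LD; plain thresholding would attenuate them
substantially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .estimator import MultiStudyFineMapper
from .inference import rank_until_causal
from .model import CausalConfig, MultiStudyLocus

__all__ = [
    "SimDesign",
    "SimReplicate",
    "CalibrationResult",
    "simulate_ld",
    "simulate_summary_direct",
    "simulate_genotype_path",
    "evaluate_calibration",
    "write_replicate",
]

LDSpec = str | tuple  # "identity" | ("ar1", r) | ("block", block_size, r)


@dataclass(frozen=True)
class SimDesign:
    """Study conditions of one simulation scenario.

    Defaults are the desk-scale two-study scenario: M=50 SNPs, AR(1) LD with
    r=0.9 in one study and r=0.5 in the other (two LD-distinct populations),
    1 or 2 causal SNPs shared between studies, mean causal NCP 5.2 (the
    genome-wide-significance Z-score) in the smallest study, heterogeneity
    tau^2 = 0.52, and 100 replicates.
    """

    n_studies: int = 2
    n_snps: int = 50
    ld_spec: tuple[LDSpec, ...] = (("ar1", 0.9), ("ar1", 0.5))
    n_causal: int | tuple[int, ...] = (1, 2)
    ncp_mean: float = 5.2
    tau_sq: float = 0.52
    sample_sizes: tuple[int, ...] | None = None
    heritability: float = 0.005
    n_individuals: int = 9000
    maf: float | tuple[float, ...] | None = None
    beta_sd: float = 0.0
    replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 1 or self.n_snps < 1:
            raise ValueError("need at least one study and one SNP")
        if len(self.ld_spec) not in (1, self.n_studies):
            raise ValueError("ld_spec must list one spec, or one per study")
        for c in self.causal_choices():
            if not 0 <= c <= self.n_snps:
                raise ValueError("n_causal must lie in [0, n_snps]")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must lie in (0, 1)")
        if self.sample_sizes is not None and len(self.sample_sizes) != self.n_studies:
            raise ValueError("sample_sizes must have one entry per study")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    def causal_choices(self) -> tuple[int, ...]:
        if isinstance(self.n_causal, int):
            return (self.n_causal,)
        return tuple(self.n_causal)

    def ld_matrices(self) -> list[np.ndarray]:
        specs = self.ld_spec
        if len(specs) == 1:
            specs = specs * self.n_studies
        return [simulate_ld(self.n_snps, s) for s in specs]


@dataclass(frozen=True)
class SimReplicate:
    """One simulated locus with its ground-truth causal configuration."""

    truth: CausalConfig
    locus: MultiStudyLocus
    provenance: dict = field(default_factory=dict)


def simulate_ld(n_snps: int, ld_spec: LDSpec, seed=None) -> np.ndarray:
    """Build a synthetic LD (correlation) matrix from a structural spec.

    ``"identity"`` gives independent SNPs; ``("ar1", r)`` gives
    Sigma_ij = r^|i-j|; ``("block", block_size, r)`` gives contiguous blocks
    with constant within-block correlation r.  All three are symmetric PSD
    with unit diagonal; ``seed`` is accepted for interface uniformity but the
    current specs are deterministic.
    """
    if ld_spec == "identity":
        return np.eye(n_snps)
    kind = ld_spec[0]
    if kind == "ar1":
        r = float(ld_spec[1])
        if not -1.0 < r < 1.0:
            raise ValueError("AR(1) correlation must lie in (-1, 1)")
        idx = np.arange(n_snps)
        return r ** np.abs(idx[:, None] - idx[None, :])
    if kind == "block":
        block_size, r = int(ld_spec[1]), float(ld_spec[2])
        if not -1.0 < r < 1.0:
            raise ValueError("block correlation must lie in (-1, 1)")
        mat = np.eye(n_snps)
        for start in range(0, n_snps, block_size):
            stop = min(start + block_size, n_snps)
            mat[start:stop, start:stop] = r
        np.fill_diagonal(mat, 1.0)
        return mat
    raise ValueError(f"unknown LD spec {ld_spec!r}")


def _sample_mvn(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """PSD-safe multivariate normal draw via eigendecomposition."""
    omega, w = np.linalg.eigh(cov)
    omega = np.clip(omega, 0.0, None)
    return mean + w @ (np.sqrt(omega) * rng.standard_normal(mean.shape[0]))


def _snp_ids(n_snps: int) -> list[str]:
    return [f"snp{i:04d}" for i in range(n_snps)]


def _draw_causal_set(
    rng: np.random.Generator, n_snps: int, c: int, ld: list[np.ndarray]
) -> np.ndarray:
    """Causal indices, resampled until all pairs are non-negatively correlated."""
    if c == 0:
        return np.array([], dtype=np.int64)
    for _ in range(10_000):
        idx = np.sort(rng.choice(n_snps, size=c, replace=False))
        ok = all(
            (mat[np.ix_(idx, idx)] >= 0).all() for mat in ld
        )
        if ok:
            return idx
    raise RuntimeError("could not draw a non-negatively correlated causal set")


def simulate_summary_direct(design: SimDesign, seed=None) -> SimReplicate:
    """Model-faithful summary-statistic draw (see module docstring)."""
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ld = design.ld_matrices()
    m, q_count = design.n_snps, design.n_studies
    c = int(rng.choice(design.causal_choices()))
    causal = _draw_causal_set(rng, m, c, ld)
    truth = CausalConfig.from_indices(causal, m)

    if design.sample_sizes is not None:
        n = np.asarray(design.sample_sizes, dtype=float)
        study_scale = np.sqrt(n / n.min())
    else:
        study_scale = np.ones(q_count)

    lam_mean = np.abs(rng.normal(design.ncp_mean, 1.0, size=c))
    tau = np.sqrt(design.tau_sq)
    z_list = []
    for q in range(q_count):
        lam_cq = np.zeros(m)
        lam_cq[causal] = rng.normal(lam_mean * study_scale[q], tau)
        mean_q = ld[q] @ lam_cq
        z_list.append(_sample_mvn(rng, mean_q, ld[q]))

    locus = MultiStudyLocus(_snp_ids(m), z_list, ld, design.sample_sizes)
    return SimReplicate(
        truth=truth,
        locus=locus,
        provenance={"path": "direct-mvn", "seed": seed, "n_causal": c},
    )


def _latent_correlation(target_r: float, maf_i: float, maf_j: float) -> float:
    """Latent Gaussian correlation whose thresholded alleles correlate at target_r.

    Alleles are indicators 1{Z > Phi^-1(1 - maf)}; the genotype (sum of two
    independent haplotypes) inherits the allele correlation.  Inverts the
    tetrachoric-style relation by root finding.
    """
    if abs(target_r) < 1e-12:
        return 0.0
    t_i, t_j = norm.ppf(1.0 - maf_i), norm.ppf(1.0 - maf_j)
    denom = np.sqrt(maf_i * (1 - maf_i) * maf_j * (1 - maf_j))

    def realized(rho):
        p11 = multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        ).cdf([-t_i, -t_j])
        return (p11 - maf_i * maf_j) / denom - target_r

    lo, hi = -0.999, 0.999
    if realized(lo) * realized(hi) > 0:  # target unreachable for these MAFs
        return np.clip(target_r, lo, hi)
    return brentq(realized, lo, hi, xtol=1e-6)


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    omega, w = np.linalg.eigh((mat + mat.T) / 2.0)
    omega = np.clip(omega, 1e-8, None)
    out = (w * omega) @ w.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _copula_genotypes(
    rng: np.random.Generator, n: int, target_ld: np.ndarray, maf: np.ndarray
) -> np.ndarray:
    m = target_ld.shape[0]
    latent = np.eye(m)
    cache: dict[tuple, float] = {}
    for i in range(m):
        for j in range(i + 1, m):
            key = (round(float(target_ld[i, j]), 4), round(float(maf[i]), 4),
                   round(float(maf[j]), 4))
            if key not in cache:
                cache[key] = _latent_correlation(*key)
            latent[i, j] = latent[j, i] = cache[key]
    latent = _nearest_correlation(latent)
    chol = np.linalg.cholesky(latent + 1e-10 * np.eye(m))
    thresh = norm.ppf(1.0 - maf)
    hap1 = (rng.standard_normal((n, m)) @ chol.T) > thresh
    hap2 = (rng.standard_normal((n, m)) @ chol.T) > thresh
    return (hap1.astype(np.int8) + hap2.astype(np.int8)).astype(float)


def simulate_genotype_path(design: SimDesign, seed=None) -> SimReplicate:
    """Genotype -> phenotype -> marginal-regression replicate.

    Heritability is interpreted per causal SNP; the environmental variance is
    scaled so the genetic component explains ``c * heritability`` of the
    phenotypic variance.  Causal effect magnitudes are 1 up to an optional
    spread ``beta_sd`` (effects are |N(1, beta_sd)|, equal by default so each
    causal SNP carries the stated heritability).  Z-scores come from per-SNP
    linear regression; LD is the in-sample genotype correlation.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    m, q_count, n = design.n_snps, design.n_studies, design.n_individuals
    target_ld = design.ld_matrices()
    c = int(rng.choice(design.causal_choices()))
    causal = _draw_causal_set(rng, m, c, target_ld)
    truth = CausalConfig.from_indices(causal, m)

    if design.maf is None:
        maf = rng.uniform(0.05, 0.5, size=m)
    elif np.isscalar(design.maf):
        maf = np.full(m, float(design.maf))
    else:
        maf = np.asarray(design.maf, dtype=float)
    if np.any((maf < 0.01) | (maf > 0.5)):
        raise ValueError("minor allele frequencies must lie in [0.01, 0.5]")

    beta = np.zeros(m)
    if c:
        beta[causal] = np.abs(rng.normal(1.0, design.beta_sd, size=c)) \
            if design.beta_sd > 0 else 1.0

    h2_total = c * design.heritability
    if h2_total >= 1.0:
        raise ValueError("total heritability c * h2 must be below 1")

    z_list, ld_list = [], []
    for q in range(q_count):
        geno = _copula_genotypes(rng, n, target_ld[q], maf)
        std = geno.std(axis=0, ddof=1)
        std[std == 0] = 1.0
        x = (geno - geno.mean(axis=0)) / std
        genetic = x @ beta
        var_g = float(genetic.var(ddof=1))
        if c == 0 or var_g == 0.0:
            y = rng.standard_normal(n)
        else:
            var_e = var_g * (1.0 / h2_total - 1.0)
            y = genetic + rng.normal(0.0, np.sqrt(var_e), size=n)
        yc = (y - y.mean()) / y.std(ddof=1)
        r = (x * yc[:, None]).sum(axis=0) / (n - 1)
        r = np.clip(r, -0.999999, 0.999999)
        z_list.append(r * np.sqrt((n - 2) / (1.0 - r**2)))
        ld = np.corrcoef(x, rowvar=False)
        ld = np.clip((ld + ld.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(ld, 1.0)
        ld_list.append(ld)

    locus = MultiStudyLocus(_snp_ids(m), z_list, ld_list, design.sample_sizes)
    return SimReplicate(
        truth=truth,
        locus=locus,
        provenance={"path": "genotype-regression", "seed": seed, "n_causal": c,
                    "n_individuals": n},
    )


@dataclass
class CalibrationResult:
    """Aggregate fine-mapping metrics over simulation replicates."""

    sensitivity: float
    mean_set_size: float
    median_set_size: float
    mean_rank_until_causal: float
    n_replicates: int
    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "mean_set_size": self.mean_set_size,
            "median_set_size": self.median_set_size,
            "mean_rank_until_causal": self.mean_rank_until_causal,
            "n_replicates": self.n_replicates,
        }


def _default_mapper(design: SimDesign, rho_star: float, max_causal: int):
    def mapper(locus: MultiStudyLocus):
        return MultiStudyFineMapper(
            rho_star=rho_star,
            max_causal=max_causal,
            tau_sq=design.tau_sq,
            ncp_scale=design.ncp_mean,
        ).fit(locus)

    return mapper


def evaluate_calibration(
    design: SimDesign,
    fine_mapper: Callable | None = None,
    replicates: int | Sequence[SimReplicate] | None = None,
    rho_star: float = 0.95,
    max_causal: int = 3,
) -> CalibrationResult:
    """Sensitivity and set-size metrics of a fine mapper on simulated loci.

    ``fine_mapper`` is a callable taking a locus and returning either a
    fitted :class:`MultiStudyFineMapper`, a posterior table, or simply a
    collection of SNP identifiers (the causal set).  Sensitivity is the
    fraction of replicates whose returned set contains every true causal
    SNP.  Replicate seeds are spawned deterministically from ``design.seed``.
    """
    if fine_mapper is None:
        fine_mapper = _default_mapper(design, rho_star, max_causal)
    if replicates is None or isinstance(replicates, int):
        count = design.replicates if replicates is None else replicates
        reps = [
            simulate_summary_direct(design, seed=[design.seed, i])
            for i in range(count)
        ]
    else:
        reps = list(replicates)

    rows = []
    for i, rep in enumerate(reps):
        result = fine_mapper(rep.locus)
        rank = np.nan
        set_prob = np.nan
        if isinstance(result, MultiStudyFineMapper):
            members = set(result.credible_set_)
            set_prob = result.set_prob_
            rank = rank_until_causal(result.posterior_, rep.truth)
        elif hasattr(result, "set_members"):  # PosteriorTable
            members = set(result.set_members or ())
            set_prob = result.set_prob
            rank = rank_until_causal(result, rep.truth)
        else:
            members = set(result)
        truth_ids = {rep.locus.snp_ids[j] for j in rep.truth.indices}
        rows.append(
            {
                "replicate": i,
                "n_causal": rep.truth.k,
                "set_size": len(members),
                "covered": truth_ids <= members,
                "set_prob": set_prob,
                "rank_until_causal": rank,
            }
        )
    table = pd.DataFrame(rows)
    ranks = table["rank_until_causal"].dropna()
    return CalibrationResult(
        sensitivity=float(table["covered"].mean()),
        mean_set_size=float(table["set_size"].mean()),
        median_set_size=float(table["set_size"].median()),
        mean_rank_until_causal=float(ranks.mean()) if len(ranks) else float("nan"),
        n_replicates=len(reps),
        table=table,
    )


def write_replicate(rep: SimReplicate, prefix: str) -> dict[str, list[str] | str]:
    """Write a replicate in the Z-file / LD-file dialect the readers consume.

    One ``<prefix>_study<q>.z`` (SNP id + Z) and ``<prefix>_study<q>.ld``
    per study, plus a ``<prefix>_truth.txt`` sidecar (SNP id, causal flag,
    tab-separated).
    """
    locus = rep.locus
    z_paths, ld_paths = [], []
    for q in range(locus.n_studies):
        z_path = f"{prefix}_study{q}.z"
        ld_path = f"{prefix}_study{q}.ld"
        with open(z_path, "w") as fh:
            for sid, z in zip(locus.snp_ids, locus.z[q]):
                fh.write(f"{sid}\t{z:.10g}\n")
        np.savetxt(ld_path, locus.ld[q], fmt="%.10g", delimiter="\t")
        z_paths.append(z_path)
        ld_paths.append(ld_path)
    truth_path = f"{prefix}_truth.txt"
    with open(truth_path, "w") as fh:
        for sid, flag in zip(locus.snp_ids, rep.truth.status):
            fh.write(f"{sid}\t{int(flag)}\n")
    return {"z": z_paths, "ld": ld_paths, "truth": truth_path}
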