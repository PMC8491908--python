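"""Plain-text readers/writers and multi-study harmonization.

File dialect (whitespace-separated, spaces or tabs, scientific notation
accepted):

* Z file — two columns per line: SNP identifier, signed Z statistic.  No
  header by default; a header line is auto-detected when its second field is
  not numeric.
* LD file — an M x M numeric matrix, one row per line.

Allele harmonization (sign-flipping Z-scores to a common effect allele) is
the caller's responsibility: these files carry no allele columns.  The reader
validates identifier agreement only and warns when Z-sign patterns among
high-LD pairs suggest strand inconsistencies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .inference import PosteriorTable
from .model import MultiStudyLocus

__all__ = ["StudyFileSet", "read_study", "harmonize_studies", "write_results",
           "read_truth", "load_locus"]

logger = logging.getLogger("msfinemap")

_ASYM_TOL = 1e-6


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class StudyFileSet:
    """Paths of one study's inputs plus optional metadata."""

    z_path: str
    ld_path: str
    sample_size: int | None = None
    label: str | None = None


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_study(fileset: StudyFileSet) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Parse one study's Z and LD files into (snp_ids, z, ld)."""
    z_path, ld_path = fileset.z_path, fileset.ld_path
    snp_ids: list[str] = []
    z_vals: list[float] = []
    with open(z_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise ParseError(f"{z_path}:{lineno}: expected 'snp_id z', got {line!r}")
            if lineno == 1 and not _is_number(fields[1]):
                logger.debug("%s: header line skipped", z_path)
                continue
            if not _is_number(fields[1]):
                raise ParseError(f"{z_path}:{lineno}: non-numeric Z value {fields[1]!r}")
            snp_ids.append(fields[0])
            z_vals.append(float(fields[1]))
    if not snp_ids:
        raise ParseError(f"{z_path}: no SNP rows found")
    if len(set(snp_ids)) != len(snp_ids):
        raise ParseError(f"{z_path}: duplicate SNP identifiers")

    try:
        ld = np.loadtxt(ld_path, dtype=float, ndmin=2)
    except ValueError as err:
        raise ParseError(f"{ld_path}: non-numeric matrix entry ({err})") from err
    if ld.shape[0] != ld.shape[1]:
        raise ParseError(f"{ld_path}: LD matrix is {ld.shape[0]}x{ld.shape[1]}, not square")
    if ld.shape[0] != len(snp_ids):
        raise ParseError(
            f"dimension mismatch: {z_path} has {len(snp_ids)} SNPs but "
            f"{ld_path} is {ld.shape[0]}x{ld.shape[1]}"
        )
    asym = float(np.max(np.abs(ld - ld.T))) if ld.size else 0.0
    if asym > _ASYM_TOL:
        raise ParseError(f"{ld_path}: LD matrix asymmetry {asym:.2e} exceeds tolerance")
    if asym > 0:
        logger.debug("%s: symmetrized LD (asymmetry %.2e)", ld_path, asym)
    ld = (ld + ld.T) / 2.0
    if np.any(np.abs(ld) > 1.0 + _ASYM_TOL):
        raise ParseError(f"{ld_path}: LD entries exceed [-1, 1]")
    diag_err = float(np.max(np.abs(np.diag(ld) - 1.0)))
    if diag_err > _ASYM_TOL:
        raise ParseError(f"{ld_path}: LD diagonal deviates from 1 by {diag_err:.2e}")
    np.fill_diagonal(ld, 1.0)
    np.clip(ld, -1.0, 1.0, out=ld)
    _warn_possible_strand_issues(z_path, np.asarray(z_vals), ld)
    return snp_ids, np.asarray(z_vals), ld


def _warn_possible_strand_issues(z_path: str, z: np.ndarray, ld: np.ndarray) -> None:
    """Flag many opposite-sign Z pairs among strongly positively-LD'd SNPs."""
    i, j = np.triu_indices(ld.shape[0], k=1)
    strong = (ld[i, j] > 0.9) & (np.abs(z[i]) > 2) & (np.abs(z[j]) > 2)
    if strong.sum() < 5:
        return
    discordant = np.sign(z[i][strong]) != np.sign(z[j][strong])
    if discordant.mean() > 0.2:
        logger.warning(
            "%s: %.0f%% of high-LD significant SNP pairs have opposite-sign "
            "Z-scores; check allele/strand harmonization",
            z_path, 100 * discordant.mean(),
        )


def harmonize_studies(
    studies: list[tuple[list[str], np.ndarray, np.ndarray]],
    sample_sizes=None,
) -> MultiStudyLocus:
    """Restrict all studies to their common SNPs, in the first study's order."""
    if not studies:
        raise ValueError("need at least one study")
    common = set(studies[0][0])
    for ids, _, _ in studies[1:]:
        common &= set(ids)
    if len(common) < 2:
        counts = ", ".join(f"study {q}: {len(ids)} SNPs" for q, (ids, _, _) in enumerate(studies))
        raise ValueError(
            f"fewer than 2 SNPs shared across studies ({counts}; intersection "
            f"{len(common)})"
        )
    order = [s for s in studies[0][0] if s in common]
    z_list, ld_list = [], []
    for q, (ids, z, ld) in enumerate(studies):
        dropped = [s for s in ids if s not in common]
        if dropped:
            logger.info("study %d: dropped %d SNPs absent elsewhere: %s",
                        q, len(dropped), ", ".join(dropped[:10]))
        pos = {s: i for i, s in enumerate(ids)}
        idx = np.array([pos[s] for s in order])
        z_list.append(z[idx])
        ld_list.append(ld[np.ix_(idx, idx)])
    return MultiStudyLocus(order, z_list, ld_list, sample_sizes)


def load_locus(filesets: list[StudyFileSet]) -> MultiStudyLocus:
    """Read and harmonize a list of per-study file pairs."""
    studies = [read_study(fs) for fs in filesets]
    sizes = [fs.sample_size for fs in filesets]
    sample_sizes = sizes if all(s is not None for s in sizes) else None
    if any(s is not None for s in sizes) and sample_sizes is None:
        raise ValueError("sample sizes must be given for all studies or none")
    return harmonize_studies(studies, sample_sizes)


def read_truth(path: str) -> dict[str, int]:
    """Read a truth sidecar (SNP id, causal flag) into a dict."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 2 or fields[1] not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: expected 'snp_id 0|1'")
            out[fields[0]] = int(fields[1])
    return out


def write_results(table: PosteriorTable, prefix: str, extra: dict | None = None) -> dict:
    """Write the confidence set, per-SNP table, and JSON summary.

    Produces ``<prefix>_set.txt`` (set members, PIP-descending, one per
    line), ``<prefix>_post.txt`` (tab-separated snp_id / pip / in_set with a
    header), and ``<prefix>_summary.json``.  Returns the summary dict.
    """
    prefix_path = Path(prefix)
    if prefix_path.parent != Path("."):
        prefix_path.parent.mkdir(parents=True, exist_ok=True)
    set_path = f"{prefix}_set.txt"
    post_path = f"{prefix}_post.txt"
    summary_path = f"{prefix}_summary.json"

    members = table.set_members or ()
    with open(set_path, "w") as fh:
        for sid in members:
            fh.write(f"{sid}\n")

    frame = table.to_frame()
    order = table.pip_order()
    frame = frame.iloc[order]
    with open(post_path, "w") as fh:
        fh.write("snp_id\tpip\tin_set\n")
        for _, row in frame.iterrows():
            fh.write(f"{row.snp_id}\t{row.pip:.10g}\t{int(row.in_set)}\n")

    summary = {
        "n_snps": table.n_snps,
        "max_causal": table.params.max_causal,
        "rho_star": table.params.rho_star,
        "tau_sq": table.ncp.tau_sq,
        "gamma": table.params.gamma,
        "ncp_scale": table.ncp.ncp_scale,
        "set_size": len(members),
        "set_prob": table.set_prob,
        "n_configs": len(table.configs),
    }
    if extra:
        summary.update(extra)
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
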