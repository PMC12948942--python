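"""Cross-role genomic relatedness matrices for trios.

The trio variance decomposition needs six n x n relatedness blocks over
families: within-role G_oo, G_mm, G_pp and cross-role G_om, G_op, G_mp,
where entry (i, j) is the mean cross-product of standardized genotypes
between the first role's member of family i and the second role's member
of family j.  Expectations: 1 on within-role diagonals, 0.5 on the
parent-offspring diagonals of G_om / G_op, ~0 on diag(G_mp) under random
mating, and 0 with standard deviation ~1/sqrt(M) between unrelated people.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .simulate import TrioGenotypes, standardize_by_freqs

__all__ = [
    "GRMSet",
    "standardize_genotypes",
    "compute_grm_block",
    "build_grm_set",
    "filter_unrelated",
    "write_grm_set",
    "read_grm_set",
]

#: role pair keys of the six stored blocks ('o' offspring, 'm' mother, 'p' father)
BLOCK_KEYS = ("oo", "mm", "pp", "om", "op", "mp")
_ROLE_OF_CODE = {"o": "offspring", "m": "mother", "p": "father"}


class MonomorphicError(ValueError):
    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"monomorphic SNPs at indices {self.indices[:20]}"
                         + ("..." if len(self.indices) > 20 else ""))


def standardize_genotypes(dosages: np.ndarray, allele_freqs: np.ndarray) -> np.ndarray:
    """z = (x - 2p) / sqrt(2p(1-p)) per SNP; rejects p in {0, 1}."""
    p = np.asarray(allele_freqs, dtype=float)
    mono = np.where((p <= 0) | (p >= 1))[0]
    if mono.size:
        raise MonomorphicError(mono)
    return (np.asarray(dosages, dtype=float) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def compute_grm_block(z_a: np.ndarray, z_b: np.ndarray) -> np.ndarray:
    """Relatedness block Z_A Z_B^T / M between two roles."""
    if z_a.shape[1] != z_b.shape[1]:
        raise ValueError(f"SNP dimensions differ: {z_a.shape[1]} vs {z_b.shape[1]}")
    m = z_a.shape[1]
    if m == 0:
        raise ValueError("no SNPs to average over")
    return z_a @ z_b.T / m


@dataclass
class GRMSet:
    """The six relatedness blocks over families plus identifiers."""

    family_ids: np.ndarray
    blocks: dict[str, np.ndarray]  # keyed by BLOCK_KEYS
    n_snps_used: int

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    def block(self, code_a: str, code_b: str) -> np.ndarray:
        """Block with rows = role ``code_a``, columns = role ``code_b``."""
        key = code_a + code_b
        if key in self.blocks:
            return self.blocks[key]
        return self.blocks[code_b + code_a].T

    def subset(self, idx: np.ndarray) -> "GRMSet":
        return GRMSet(
            family_ids=self.family_ids[idx],
            blocks={k: v[np.ix_(idx, idx)] for k, v in self.blocks.items()},
            n_snps_used=self.n_snps_used,
        )


def build_grm_set(
    geno: TrioGenotypes,
    *,
    allele_freqs: np.ndarray | None = None,
    min_maf: float = 0.01,
    keys: tuple[str, ...] = BLOCK_KEYS,
) -> GRMSet:
    """All (or a requested subset of) relatedness blocks for a cohort.

    Standardization uses the provided allele frequencies (the generating
    ones when simulating) or, by default, founder-sample frequencies.
    SNPs with sample MAF below ``min_maf`` among founders are excluded.
    """
    if allele_freqs is None:
        parents = np.vstack([geno.mother_dosages, geno.father_dosages])
        allele_freqs = parents.mean(axis=0) / 2.0
    p = np.asarray(allele_freqs, dtype=float)
    maf = np.minimum(p, 1 - p)
    keep = maf >= min_maf
    if not keep.any():
        raise ValueError("no SNPs pass the MAF filter")
    z = {}
    for code, role in _ROLE_OF_CODE.items():
        if any(code in k for k in keys):
            z[code] = standardize_genotypes(geno.dosages(role)[:, keep], p[keep])
    blocks = {k: compute_grm_block(z[k[0]], z[k[1]]) for k in keys}
    return GRMSet(family_ids=np.asarray(geno.family_ids), blocks=blocks,
                  n_snps_used=int(keep.sum()))


def filter_unrelated(grms: GRMSet, threshold: float = 0.05) -> np.ndarray:
    """Indices of families retained after the cross-family relatedness filter.

    For every pair of distinct families whose maximum absolute relatedness
    across all role-block entries exceeds ``threshold``, the higher family
    index is dropped (greedy, deterministic).  Within-family relatedness
    (the parent-offspring 0.5 on cross-role diagonals) never triggers
    removal.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n = grms.n_families
    worst = np.zeros((n, n))
    for v in grms.blocks.values():
        a = np.abs(v)
        worst = np.maximum(worst, np.maximum(a, a.T))
    np.fill_diagonal(worst, 0.0)
    keep = np.ones(n, dtype=bool)
    ii, jj = np.where(np.triu(worst > threshold, k=1))
    for i, j in zip(ii, jj):
        if keep[i] and keep[j]:
            keep[max(i, j)] = False
    return np.where(keep)[0]


def write_grm_set(grms: GRMSet, out_dir: str | Path) -> None:
    """Plain-text GRM: lower-triangle TSV per symmetric within-role block,
    full dense TSV per (non-symmetric) cross-role block, plus an ID file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "grm.ids.txt", grms.family_ids, fmt="%s")
    (out / "grm.meta.txt").write_text(f"n_snps_used\t{grms.n_snps_used}\n")
    for key, mat in grms.blocks.items():
        with open(out / f"grm.{key}.tsv", "w") as fh:
            if key[0] == key[1]:
                for i in range(mat.shape[0]):
                    fh.write("\t".join(f"{mat[i, j]:.10g}" for j in range(i + 1)) + "\n")
            else:
                for i in range(mat.shape[0]):
                    fh.write("\t".join(f"{v:.10g}" for v in mat[i]) + "\n")


def read_grm_set(in_dir: str | Path) -> GRMSet:
    src = Path(in_dir)
    fam = np.loadtxt(src / "grm.ids.txt", dtype=str, ndmin=1)
    n_snps = int((src / "grm.meta.txt").read_text().split("\t")[1])
    n = len(fam)
    blocks = {}
    for key in BLOCK_KEYS:
        path = src / f"grm.{key}.tsv"
        if not path.exists():
            continue
        if key[0] == key[1]:
            mat = np.zeros((n, n))
            with open(path) as fh:
                for i, line in enumerate(fh):
                    row = [float(x) for x in line.split("\t")]
                    mat[i, : i + 1] = row
            mat = mat + np.tril(mat, -1).T
        else:
            mat = np.loadtxt(path, ndmin=2)
        blocks[key] = mat
    return GRMSet(family_ids=fam, blocks=blocks, n_snps_used=n_snps)
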