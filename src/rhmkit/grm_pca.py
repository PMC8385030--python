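"""Genomic relationship matrices and GRM-based principal components.

The relatedness coefficient between individuals j and k is

    g_jk = (1/N) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with x the allele1 dosage, p_i the in-sample allele1 frequency and N the
number of SNPs used.  The whole-genome GRM uses all SNPs; a regional GRM
uses exactly the SNPs of one scan window.  Principal components are the
top eigenvectors of the (whole-genome) GRM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .geno_qc import MISSING, FormatError, GenotypeData


class DegenerateSnpError(ValueError):
    """A SNP in the requested subset is monomorphic in-sample."""


@dataclass
class Grm:
    """Symmetric relatedness matrix with its provenance.

    samples : DataFrame with FID, IID (row/column order of ``matrix``).
    matrix  : (n, n) float64, symmetric.
    n_snps  : number of SNPs that entered the average.
    freqs   : per-SNP allele1 frequencies used for centring/scaling.
    """

    samples: pd.DataFrame
    matrix: np.ndarray
    n_snps: int
    freqs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.samples)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM shape does not match sample count")
        if not np.isfinite(self.matrix).all():
            raise ValueError("GRM contains non-finite entries")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("GRM is not symmetric")


def compute_grm(
    geno: GenotypeData,
    snp_subset: Optional[Sequence[int]] = None,
    freqs: Optional[np.ndarray] = None,
) -> Grm:
    """Build a GRM from all SNPs or the given subset of SNP indices.

    Missing calls contribute zero to the sum for the affected pair while the
    divisor stays N.  ``freqs`` may supply pre-computed whole-sample allele
    frequencies (regional GRMs re-use the same per-SNP frequencies that the
    whole GRM used; frequencies do not change with windowing).
    """
    if snp_subset is None:
        idx = np.arange(geno.n_snps)
    else:
        idx = np.asarray(snp_subset, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= geno.n_snps):
            raise IndexError("snp_subset out of bounds")
    calls = geno.calls[:, idx].astype(np.float64)
    obs = calls != MISSING
    if freqs is not None:
        p = np.asarray(freqs, dtype=float)[idx]
    else:
        n_obs = obs.sum(axis=0)
        p = np.where(obs, calls, 0.0).sum(axis=0) / (2.0 * n_obs)
    bad = ~((p > 0.0) & (p < 1.0))
    if bad.any():
        raise DegenerateSnpError(
            f"{bad.sum()} monomorphic SNP(s) in GRM subset "
            f"(first: {geno.snps['SNP'].iloc[idx[np.flatnonzero(bad)[0]]]})"
        )
    w = (calls - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    w[~obs] = 0.0
    n = idx.size
    g = (w @ w.T) / n
    g = (g + g.T) / 2.0
    return Grm(geno.samples[["FID", "IID"]].copy(), g, n, p)


# ---------------------------------------------------------------------------
# GCTA binary GRM triplet (.grm.bin / .grm.N.bin / .grm.id)
# ---------------------------------------------------------------------------

def write_grm(grm: Grm, prefix) -> None:
    """Write the GCTA triplet: lower triangle (diagonal included) row by
    row as float32, per-pair SNP counts, and sample identifiers."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = len(grm.samples)
    tri = np.tril_indices(n)
    vals = grm.matrix[tri].astype(np.float32)
    Path(f"{prefix}.grm.bin").write_bytes(vals.tobytes())
    counts = np.full(vals.size, grm.n_snps, dtype=np.float32)
    Path(f"{prefix}.grm.N.bin").write_bytes(counts.tobytes())
    grm.samples[["FID", "IID"]].to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix) -> Grm:
    """Read a GCTA binary GRM triplet."""
    prefix = Path(prefix)
    ids = pd.read_csv(
        f"{prefix}.grm.id",
        sep="\t",
        header=None,
        names=["FID", "IID"],
        dtype=str,
    )
    n = len(ids)
    n_pairs = n * (n + 1) // 2
    vals = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype=np.float32)
    if vals.size != n_pairs:
        raise FormatError(
            f"{prefix}.grm.bin holds {vals.size} values, expected {n_pairs} "
            f"for {n} samples"
        )
    counts = np.frombuffer(
        Path(f"{prefix}.grm.N.bin").read_bytes(), dtype=np.float32
    )
    if counts.size != n_pairs:
        raise FormatError(f"{prefix}.grm.N.bin size mismatch")
    mat = np.zeros((n, n), dtype=np.float64)
    tri = np.tril_indices(n)
    mat[tri] = vals
    mat = mat + np.tril(mat, -1).T
    return Grm(ids, mat, int(round(float(counts[0]))))


def grm_pca(grm: Grm, k: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k eigenvectors of the GRM, by descending eigenvalue.

    Sign convention: the largest-magnitude loading of each eigenvector is
    positive.  Returns (eigenvector table with FID/IID/PC1..PCk, eigenvalues).
    """
    n = len(grm.samples)
    if not 0 < k < n:
        raise ValueError("k must satisfy 0 < k < n")
    vals, vecs = eigh(grm.matrix)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    out = grm.samples[["FID", "IID"]].copy()
    for j in range(k):
        out[f"PC{j + 1}"] = vecs[:, j]
    return out, vals
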