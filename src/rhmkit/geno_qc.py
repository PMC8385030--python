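"""Genotype container, PLINK 1 binary I/O, and cohort quality control.

The QC pipeline applies, in a fixed logged order, the per-individual and
per-SNP filters typical of array-based case-control studies: call rate
(samples, then SNPs), minor allele frequency, an exact Hardy-Weinberg
equilibrium test, greedy windowed LD pruning, and removal of related
samples by genomic-relationship-matrix off-diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

if TYPE_CHECKING:  # pragma: no cover
    from .grm_pca import Grm

MISSING = -1  # sentinel in the call matrix

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK bed

# 2-bit codes, per the PLINK 1 bed format, for calls counting allele1:
#   2 copies of A1 -> 00, missing -> 01, het -> 10, 0 copies of A1 -> 11
_CALL_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)


class FormatError(ValueError):
    """Malformed on-disk genotype data (bad magic bytes, truncation)."""


class ConsistencyError(ValueError):
    """bed/bim/fam triplet with mutually inconsistent dimensions."""


class EmptyDataError(ValueError):
    """A filter removed every sample."""


@dataclass
class GenotypeData:
    """Hard-call genotypes for a cohort.

    samples : DataFrame with columns FID, IID.
    snps    : DataFrame with columns SNP, CHR, BP, A1, A2, sorted by
              (chromosome block, position).
    calls   : int8 array (n_samples, n_snps); entries count copies of A1,
              with -1 for missing.
    meta    : free-form dict (the simulator stashes its generative state
              here so ascertainment can extend the cohort).
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ConsistencyError(
                f"call matrix {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        self._check_sorted()

    def _check_sorted(self) -> None:
        chrom = self.snps["CHR"].to_numpy()
        bp = self.snps["BP"].to_numpy()
        seen: set = set()
        prev = None
        for i, c in enumerate(chrom):
            if c != prev:
                if c in seen:
                    raise ConsistencyError(f"chromosome {c} not contiguous")
                seen.add(c)
                prev = c
            elif bp[i] < bp[i - 1]:
                raise ConsistencyError(
                    f"positions not sorted within chromosome {c}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(
        self,
        sample_idx: Optional[np.ndarray] = None,
        snp_idx: Optional[np.ndarray] = None,
    ) -> "GenotypeData":
        samples, snps, calls = self.samples, self.snps, self.calls
        if sample_idx is not None:
            samples = samples.iloc[sample_idx].reset_index(drop=True)
            calls = calls[np.asarray(sample_idx)]
        if snp_idx is not None:
            snps = snps.iloc[snp_idx].reset_index(drop=True)
            calls = calls[:, np.asarray(snp_idx)]
        return GenotypeData(samples, snps, calls.copy(), dict(self.meta))

    def allele1_freq(self) -> np.ndarray:
        """In-sample frequency of allele1 per SNP, over non-missing calls."""
        c = self.calls
        obs = c != MISSING
        n_obs = obs.sum(axis=0)
        s = np.where(obs, c, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, s / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele1_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class QcStep:
    name: str
    samples_removed: int
    snps_removed: int
    params: dict


@dataclass
class QcReport:
    """Ordered record of filters applied, with removal counts."""

    steps: list = field(default_factory=list)

    def add(self, name: str, samples_removed: int, snps_removed: int, **params) -> None:
        if samples_removed < 0 or snps_removed < 0:
            raise ValueError("negative removal count")
        self.steps.append(QcStep(name, samples_removed, snps_removed, params))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "samples_removed": s.samples_removed,
                    "snps_removed": s.snps_removed,
                    "params": ";".join(f"{k}={v}" for k, v in s.params.items()),
                }
                for s in self.steps
            ]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK 1 binary I/O (SNP-major bed + bim + fam)
# ---------------------------------------------------------------------------

def write_plink(geno: GenotypeData, prefix) -> None:
    """Write a bed/bim/fam triplet (bed in SNP-major mode)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = pd.DataFrame(
        {
            "FID": geno.samples["FID"],
            "IID": geno.samples["IID"],
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENO": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    bim = pd.DataFrame(
        {
            "CHR": geno.snps["CHR"],
            "SNP": geno.snps["SNP"],
            "CM": 0,
            "BP": geno.snps["BP"],
            "A1": geno.snps["A1"],
            "A2": geno.snps["A2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(_pack_bed(geno.calls))


def _pack_bed(calls: np.ndarray) -> bytes:
    n, m = calls.shape
    codes = np.empty_like(calls, dtype=np.uint8)
    for call, code in _CALL_TO_CODE.items():
        codes[calls == call] = code
    n_pad = (-n) % 4
    if n_pad:
        pad = np.zeros((n_pad, m), dtype=np.uint8)  # code 0b00 padding
        codes = np.vstack([codes, pad])
    codes = codes.T.reshape(m, -1, 4)  # SNP-major, 4 samples per byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts).sum(axis=2).astype(np.uint8)
    return packed.tobytes()


def read_plink(prefix) -> GenotypeData:
    """Read a bed/bim/fam triplet into a :class:`GenotypeData`."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["FID", "IID", "PAT", "MAT", "SEX", "PHENO"],
        dtype={"FID": str, "IID": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["CHR", "SNP", "CM", "BP", "A1", "A2"],
    )
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:3]!r}")
    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != bytes_per_snp * m:
        raise ConsistencyError(
            f"{prefix}.bed payload has {payload.size} bytes, expected "
            f"{bytes_per_snp * m} for {n} samples x {m} SNPs"
        )
    payload = payload.reshape(m, bytes_per_snp)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (payload[:, :, None] >> shifts) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    calls = _CODE_TO_CALL[codes].T.copy()
    samples = fam[["FID", "IID"]].copy()
    snps = bim[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    return GenotypeData(samples, snps, calls)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_call_rate(
    geno: GenotypeData,
    sample_min: float = 0.98,
    snp_min: float = 0.98,
    report: Optional[QcReport] = None,
) -> tuple[GenotypeData, QcReport]:
    """Drop samples, then SNPs, below their call-rate thresholds.

    The two stages alternate to a fixed point (dropping a sparse SNP can
    lower a sample's rate over the retained SNPs and vice versa), so on
    return every remaining sample and SNP meets its threshold and a second
    application is a no-op.
    """
    if not (0 <= sample_min <= 1 and 0 <= snp_min <= 1):
        raise ValueError("call-rate thresholds must lie in [0, 1]")
    report = report if report is not None else QcReport()
    samples_removed = snps_removed = 0
    while True:
        obs = geno.calls != MISSING
        sample_rate = obs.mean(axis=1) if geno.n_snps else np.ones(geno.n_samples)
        keep_s = np.flatnonzero(sample_rate >= sample_min)
        if keep_s.size == 0:
            raise EmptyDataError("call-rate filter removed all samples")
        samples_removed += geno.n_samples - keep_s.size
        if keep_s.size < geno.n_samples:
            geno = geno.subset(sample_idx=keep_s)
        obs = geno.calls != MISSING
        snp_rate = obs.mean(axis=0)
        keep_v = np.flatnonzero(snp_rate >= snp_min)
        snps_removed += geno.n_snps - keep_v.size
        if keep_v.size == geno.n_snps:
            break
        geno = geno.subset(snp_idx=keep_v)
    report.add("call_rate_samples", int(samples_removed), 0, sample_min=sample_min)
    report.add("call_rate_snps", 0, int(snps_removed), snp_min=snp_min)
    return geno, report


def filter_maf(
    geno: GenotypeData,
    maf_min: float = 0.01,
    report: Optional[QcReport] = None,
) -> tuple[GenotypeData, QcReport]:
    """Keep SNPs with in-sample minor allele frequency >= ``maf_min``."""
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    report = report if report is not None else QcReport()
    maf = geno.maf()
    keep = np.flatnonzero(maf >= maf_min)
    removed = geno.n_snps - keep.size
    geno = geno.subset(snp_idx=keep)
    report.add("maf", 0, int(removed), maf_min=maf_min)
    return geno, report


def hwe_exact_test(counts: Sequence[int]) -> float:
    """Exact two-sided Hardy-Weinberg test from genotype counts.

    ``counts`` is (n_hom1, n_het, n_hom2).  The p-value sums, over all
    heterozygote counts compatible with the observed allele totals, the
    probabilities of configurations no more probable than the observed one.
    """
    n_hom1, n_het, n_hom2 = (int(c) for c in counts)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("HWE test undefined for zero observations")
    n1 = 2 * n_hom1 + n_het  # allele1 total
    n_minor = min(n1, 2 * n - n1)
    # heterozygote count shares the parity of the minor-allele total
    ks = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - ks) // 2
    hom_maj = n - ks - hom_min
    logp = (
        ks * np.log(2.0)
        - gammaln(hom_min + 1)
        - gammaln(ks + 1)
        - gammaln(hom_maj + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(ks == n_het)[0]]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def filter_hwe(
    geno: GenotypeData,
    p_min: float = 1e-6,
    report: Optional[QcReport] = None,
) -> tuple[GenotypeData, QcReport]:
    """Keep SNPs consistent with Hardy-Weinberg equilibrium (p >= ``p_min``)."""
    report = report if report is not None else QcReport()
    keep = []
    for j in range(geno.n_snps):
        c = geno.calls[:, j]
        c = c[c != MISSING]
        counts = (int((c == 2).sum()), int((c == 1).sum()), int((c == 0).sum()))
        if sum(counts) == 0 or hwe_exact_test(counts) >= p_min:
            keep.append(j)
    removed = geno.n_snps - len(keep)
    geno = geno.subset(snp_idx=np.array(keep, dtype=int))
    report.add("hwe", 0, int(removed), p_min=p_min)
    return geno, report


def _pairwise_r2(cols: np.ndarray) -> np.ndarray:
    """Squared genotype correlation among columns, missing excluded pairwise."""
    if not (cols == MISSING).any():
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(cols.astype(float), rowvar=False)
        return np.nan_to_num(r) ** 2
    ma = np.ma.masked_equal(cols.astype(float), MISSING)
    r = np.ma.corrcoef(ma, rowvar=False).filled(0.0)
    return r**2


def ld_prune(
    geno: GenotypeData,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.8,
    report: Optional[QcReport] = None,
) -> tuple[list, QcReport]:
    """Greedy windowed LD pruning (the --indep-pairwise construction).

    Within each sliding window, while any retained pair has genotype r^2
    above ``r2_max``, the member with the lower MAF is removed (ties break
    by removing the later position).  Returns the kept SNP identifiers.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    report = report if report is not None else QcReport()
    maf = geno.maf()
    bp = geno.snps["BP"].to_numpy()
    kept = np.ones(geno.n_snps, dtype=bool)
    for chrom in geno.snps["CHR"].unique():
        idx = np.flatnonzero((geno.snps["CHR"] == chrom).to_numpy())
        m = idx.size
        start = 0
        while start < m:
            stop = min(start + window, m)
            win = idx[start:stop]
            win = win[kept[win]]
            if win.size >= 2:
                r2 = _pairwise_r2(geno.calls[:, win])
                np.fill_diagonal(r2, 0.0)
                alive = np.ones(win.size, dtype=bool)
                while True:
                    sub = np.where(np.outer(alive, alive), r2, 0.0)
                    a, b = np.unravel_index(np.argmax(sub), sub.shape)
                    if sub[a, b] <= r2_max:
                        break
                    ia, ib = win[a], win[b]
                    if maf[ia] < maf[ib]:
                        drop = a
                    elif maf[ib] < maf[ia]:
                        drop = b
                    else:
                        drop = a if bp[ia] > bp[ib] else b
                    alive[drop] = False
                    kept[win[drop]] = False
            if stop >= m:
                break
            start += step
    removed = int((~kept).sum())
    report.add("ld_prune", 0, removed, window=window, step=step, r2_max=r2_max)
    kept_ids = geno.snps.loc[kept, "SNP"].tolist()
    return kept_ids, report


def filter_relatedness(
    grm: "Grm",
    threshold: float = 0.1,
    report: Optional[QcReport] = None,
) -> tuple[list, QcReport]:
    """Iteratively drop one member of the most-related pair above ``threshold``.

    The member with the higher mean relatedness to the remaining cohort is
    removed first.  Returns the kept (FID, IID) pairs.
    """
    report = report if report is not None else QcReport()
    a = np.array(grm.matrix, dtype=float)
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    n = a.shape[0]
    np.fill_diagonal(a, 0.0)
    alive = np.ones(n, dtype=bool)
    while True:
        sub = np.where(np.outer(alive, alive), a, -np.inf)
        j, k = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[j, k] <= threshold:
            break
        mean_j = a[j, alive].sum() / max(alive.sum() - 1, 1)
        mean_k = a[k, alive].sum() / max(alive.sum() - 1, 1)
        alive[j if mean_j >= mean_k else k] = False
    removed = int((~alive).sum())
    report.add("relatedness", removed, 0, threshold=threshold)
    kept = [
        (grm.samples["FID"].iat[i], grm.samples["IID"].iat[i])
        for i in np.flatnonzero(alive)
    ]
    return kept, report


def run_qc(
    geno: GenotypeData,
    sample_min: float = 0.98,
    snp_min: float = 0.98,
    maf_min: float = 0.01,
    hwe_min: float = 1e-6,
    ld_window: int = 50,
    ld_step: int = 5,
    r2_max: float = 0.8,
    relatedness_max: float = 0.1,
) -> tuple[GenotypeData, QcReport]:
    """Full QC pipeline in fixed order: call rate (samples, SNPs), MAF,
    HWE, LD pruning, relatedness."""
    from .grm_pca import compute_grm

    report = QcReport()
    geno, _ = filter_call_rate(geno, sample_min, snp_min, report)
    geno, _ = filter_maf(geno, maf_min, report)
    geno, _ = filter_hwe(geno, hwe_min, report)
    kept_ids, _ = ld_prune(geno, ld_window, ld_step, r2_max, report)
    keep_idx = np.flatnonzero(geno.snps["SNP"].isin(kept_ids).to_numpy())
    geno = geno.subset(snp_idx=keep_idx)
    grm = compute_grm(geno)
    kept_pairs, _ = filter_relatedness(grm, relatedness_max, report)
    pairs = set(kept_pairs)
    keep_s = np.array(
        [
            (geno.samples["FID"].iat[i], geno.samples["IID"].iat[i]) in pairs
            for i in range(geno.n_samples)
        ]
    )
    geno = geno.subset(sample_idx=np.flatnonzero(keep_s))
    return geno, report
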