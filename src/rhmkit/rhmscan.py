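"""Regional heritability genome scan.

The genome is covered by overlapping windows of adjacent SNPs (50 SNPs,
shifted by 25 for a 50% overlap, by default).  For each window, a regional
GRM is built from the window's SNPs and a two-genetic-component mixed model
is fitted; the regional variance is tested against the genome-wide null fit
by a likelihood-ratio test referred to a 50-50 chi-square(0):chi-square(1)
mixture.  Bonferroni thresholds use half the number of tested regions
because overlapping windows are not independent tests.  Observed-scale
heritabilities are converted to the liability scale with the
ascertainment-corrected transformation for case-control samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .geno_qc import GenotypeData
from .grm_pca import DegenerateSnpError, Grm, compute_grm
from .remlcore import LrtResult, ModelSpec, VarianceEstimate, fit_reml, lrt_regional

logger = logging.getLogger("rhmkit")

DEFAULT_WINDOW_SIZE = 50
DEFAULT_WINDOW_SHIFT = 25


@dataclass(frozen=True)
class WindowSpec:
    """One scan window: a half-open SNP index range on one chromosome."""

    chrom: int
    start: int           # index within the full SNP table
    stop: int            # exclusive
    bp_first: int
    bp_last: int
    ordinal: int

    @property
    def width(self) -> int:
        return self.stop - self.start


@dataclass
class ThresholdSpec:
    """Bonferroni thresholds for the scan: the effective number of tests is
    half the number of regions, to account for the 50% window overlap."""

    alpha: float
    n_regions: int
    effective_tests: float
    p_threshold: float
    lrt_threshold: float


@dataclass
class LiabilityParams:
    """Prevalence K, sample case proportion P, and the threshold-model
    quantities t = Phi^-1(1-K) and z = phi(t)."""

    prevalence: float
    case_proportion: float

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0 and 0.0 < self.case_proportion < 1.0):
            raise ValueError("K and P must lie strictly inside (0, 1)")

    @property
    def threshold(self) -> float:
        return float(norm.isf(self.prevalence))

    @property
    def density_at_threshold(self) -> float:
        return float(norm.pdf(self.threshold))

    @property
    def factor(self) -> float:
        """Multiplier taking observed-scale to liability-scale heritability:
        K^2 (1-K)^2 / (z^2 P (1-P))."""
        k, p, z = self.prevalence, self.case_proportion, self.density_at_threshold
        return k**2 * (1.0 - k) ** 2 / (z**2 * p * (1.0 - p))


@dataclass
class ScanRecord:
    """One window's fit: LRT, regional variance, heritabilities, flags."""

    window: WindowSpec
    lrt: Optional[LrtResult]
    sigma_w2: float = np.nan
    h2_obs: float = np.nan          # sigma_w2 / (su2 + sw2 + se2)
    h2_obs_se: float = np.nan
    h2_liab: float = np.nan
    h2_liab_se: float = np.nan
    excluded: bool = False
    reason: str = ""


def make_windows(
    geno: GenotypeData,
    size: int = DEFAULT_WINDOW_SIZE,
    shift: int = DEFAULT_WINDOW_SHIFT,
) -> list:
    """Overlapping windows of ``size`` adjacent SNPs, shifted by ``shift``.

    Windows never span chromosomes; the final window of a chromosome is
    clipped at the chromosome end, and a chromosome with fewer than ``size``
    SNPs yields a single (short) window.
    """
    if size < 2:
        raise ValueError("window size must be >= 2")
    if not 1 <= shift <= size:
        raise ValueError("shift must lie in [1, size]")
    bp = geno.snps["BP"].to_numpy()
    chroms = geno.snps["CHR"].to_numpy()
    windows: list = []
    ordinal = 0
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        m = idx.size
        if m == 0:
            logger.info("chromosome %s has no SNPs; skipped", chrom)
            continue
        start = 0
        while start < m:
            stop = min(start + size, m)
            lo, hi = idx[start], idx[stop - 1]
            windows.append(
                WindowSpec(chrom, int(lo), int(hi) + 1, int(bp[lo]), int(bp[hi]), ordinal)
            )
            ordinal += 1
            # a clipped (short) window is always the chromosome's last
            if stop - start < size:
                break
            start += shift
    return windows


def fit_null_model(
    y: np.ndarray, X: np.ndarray, grm: Grm, **kwargs
) -> VarianceEstimate:
    """GREML null fit: genome-wide genetic component plus residual."""
    spec = ModelSpec(y, X, [("genomic", grm.matrix)])
    return fit_reml(spec, **kwargs)


def scan(
    geno: GenotypeData,
    y: np.ndarray,
    X: np.ndarray,
    windows: Sequence[WindowSpec],
    null_fit: VarianceEstimate,
    grm: Grm,
    liability: Optional[LiabilityParams] = None,
    extreme_multiple: float = 10.0,
) -> list:
    """Fit the regional model in every window and test against the null.

    Window fits start from the null estimates with the regional component
    near its floor.  Windows that fail to converge, or whose estimates are
    extreme (any component beyond ``extreme_multiple`` times the phenotypic
    variance), are flagged excluded and do not count toward the number of
    tested regions.
    """
    if not null_fit.converged:
        raise ValueError("null model fit did not converge")
    vp = float(np.var(np.asarray(y, dtype=float), ddof=1))
    floor = 1e-6 * vp
    su2 = null_fit.component("genomic")
    se2 = null_fit.component("residual")
    records: list = []
    for w in windows:
        try:
            qgrm = compute_grm(geno, np.arange(w.start, w.stop), freqs=grm.freqs)
        except DegenerateSnpError as exc:
            logger.warning("window %d excluded: %s", w.ordinal, exc)
            records.append(ScanRecord(w, None, excluded=True, reason="degenerate"))
            continue
        spec = ModelSpec(y, X, [("genomic", grm.matrix), ("regional", qgrm.matrix)])
        fit = fit_reml(spec, start=[su2, floor * 10.0, se2])
        rec = ScanRecord(w, lrt_regional(null_fit, fit))
        if not fit.converged:
            rec.excluded, rec.reason = True, "convergence"
        elif np.abs(fit.components).max() > extreme_multiple * vp:
            rec.excluded, rec.reason = True, "extreme-value"
        rec.sigma_w2 = fit.component("regional")
        rec.h2_obs = fit.ratio("regional")
        rec.h2_obs_se = fit.ratio_se("regional")
        if liability is not None:
            rec.h2_liab = rec.h2_obs * liability.factor
            rec.h2_liab_se = rec.h2_obs_se * liability.factor
        logger.info(
            "window %d chr%s [%d,%d): LRT=%.3f p=%.3g%s",
            w.ordinal, w.chrom, w.start, w.stop,
            rec.lrt.lrt, rec.lrt.p_value,
            f" excluded ({rec.reason})" if rec.excluded else "",
        )
        records.append(rec)
    return records


def thresholds(n_regions: int, alpha: float = 0.05) -> ThresholdSpec:
    """Bonferroni-corrected p and LRT thresholds for ``n_regions`` windows.

    The effective number of tests is n_regions/2 (50% window overlap); the
    LRT threshold solves 0.5 * S_chi2(1)(x) = p_threshold.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    eff = n_regions / 2.0
    p_thr = alpha / eff
    lrt_thr = float(chi2.isf(min(2.0 * p_thr, 1.0), df=1))
    return ThresholdSpec(alpha, n_regions, eff, p_thr, lrt_thr)


def observed_to_liability(
    h2_obs: float, lp: LiabilityParams, se: Optional[float] = None
):
    """Convert observed-scale (0/1) heritability to the liability scale with
    the ascertainment-corrected case-control transformation:

        h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)).

    SEs scale by the same factor; returns (h2_liab, se_liab) when ``se`` is
    given, else h2_liab.
    """
    if h2_obs < 0:
        raise ValueError("h2_obs must be >= 0")
    f = lp.factor
    if se is None:
        return h2_obs * f
    return h2_obs * f, se * f


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[ScanRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "ORDINAL": r.window.ordinal,
                "CHR": r.window.chrom,
                "START": r.window.start,
                "STOP": r.window.stop,
                "BP_FIRST": r.window.bp_first,
                "BP_LAST": r.window.bp_last,
                "LRT": r.lrt.lrt if r.lrt else np.nan,
                "P": r.lrt.p_value if r.lrt else np.nan,
                "SIGMA_W2": r.sigma_w2,
                "H2_OBS": r.h2_obs,
                "H2_OBS_SE": r.h2_obs_se,
                "H2_LIAB": r.h2_liab,
                "H2_LIAB_SE": r.h2_liab_se,
                "EXCLUDED": int(r.excluded),
                "REASON": r.reason or ".",
            }
        )
    return pd.DataFrame(rows)


def merge_significant(records: Sequence[ScanRecord], thr: ThresholdSpec) -> pd.DataFrame:
    """Merge adjacent significant windows sharing at least one SNP into
    regions, summarised in min/max LRT and heritability columns."""
    sig = [
        r for r in records
        if not r.excluded and r.lrt is not None and r.lrt.lrt >= thr.lrt_threshold
    ]
    sig.sort(key=lambda r: (r.window.chrom, r.window.start))
    cols = [
        "CHR", "FIRST_WINDOW", "LAST_WINDOW", "BP_FIRST", "BP_LAST",
        "MIN_LRT", "MAX_LRT", "MIN_REG_H2", "MAX_REG_H2", "AVERAGE_SE",
    ]
    groups: list = []
    for r in sig:
        if groups and groups[-1][-1].window.chrom == r.window.chrom and \
                r.window.start < groups[-1][-1].window.stop:
            groups[-1].append(r)
        else:
            groups.append([r])
    rows = []
    for grp in groups:
        h2 = [g.h2_liab if np.isfinite(g.h2_liab) else g.h2_obs for g in grp]
        se = [g.h2_liab_se if np.isfinite(g.h2_liab_se) else g.h2_obs_se for g in grp]
        rows.append(
            {
                "CHR": grp[0].window.chrom,
                "FIRST_WINDOW": grp[0].window.ordinal,
                "LAST_WINDOW": grp[-1].window.ordinal,
                "BP_FIRST": min(g.window.bp_first for g in grp),
                "BP_LAST": max(g.window.bp_last for g in grp),
                "MIN_LRT": min(g.lrt.lrt for g in grp),
                "MAX_LRT": max(g.lrt.lrt for g in grp),
                "MIN_REG_H2": min(h2),
                "MAX_REG_H2": max(h2),
                "AVERAGE_SE": float(np.mean(se)),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def qq_data(records: Sequence[ScanRecord]) -> pd.DataFrame:
    """Observed sorted LRTs vs expected 50-50 mixture quantiles."""
    obs = np.sort(
        [r.lrt.lrt for r in records if not r.excluded and r.lrt is not None]
    )
    m = obs.size
    u = (np.arange(1, m + 1) - 0.5) / m
    expected = np.where(u <= 0.5, 0.0, chi2.ppf(np.maximum(2.0 * u - 1.0, 0.0), df=1))
    return pd.DataFrame({"EXPECTED_LRT": expected, "OBSERVED_LRT": obs})


def report_scan(
    records: Sequence[ScanRecord],
    thr: ThresholdSpec,
    prefix,
    gwas: Optional[pd.DataFrame] = None,
) -> dict:
    """Write the scan TSV, merged significant-region table, QQ data, and
    (when a GWAS table is supplied) Miami-plot data.  Returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    frame = records_to_frame(records)
    paths["scan"] = f"{prefix}.scan.tsv"
    frame.to_csv(paths["scan"], sep="\t", index=False)
    paths["regions"] = f"{prefix}.regions.tsv"
    merge_significant(records, thr).to_csv(paths["regions"], sep="\t", index=False)
    paths["qq"] = f"{prefix}.qq.tsv"
    qq_data(records).to_csv(paths["qq"], sep="\t", index=False)
    if gwas is not None:
        miami = frame[["CHR", "BP_FIRST", "BP_LAST", "LRT"]].copy()
        paths["miami_rhm"] = f"{prefix}.miami_rhm.tsv"
        miami.to_csv(paths["miami_rhm"], sep="\t", index=False)
        g = gwas[["SNP", "CHR", "BP", "P"]].copy()
        g["NEGLOG10P"] = -np.log10(g["P"])
        paths["miami_gwas"] = f"{prefix}.miami_gwas.tsv"
        g.to_csv(paths["miami_gwas"], sep="\t", index=False)
    return paths


def read_scan(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
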