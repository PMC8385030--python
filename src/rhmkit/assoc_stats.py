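"""Single-SNP case-control GWAS and replication statistics.

Each SNP enters a logistic regression of disease status on the additive
count of its effect allele (the in-sample minor allele) with covariate
adjustment; Wald tests, 95% confidence intervals on the odds-ratio scale,
Bonferroni adjustment, and the genomic inflation factor lambda (median
chi-square over the chi-square(1) median) accompany the fits.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .geno_qc import MISSING, GenotypeData

CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))  # 0.4549364...


def _fit_one(y: np.ndarray, design: np.ndarray):
    """Newton/IRLS logistic fit; returns (beta, se, converged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(
                method="newton", maxiter=50, tol=1e-8, disp=0
            )
        except Exception:
            return np.nan, np.nan, False
        beta = res.params[-1]
        se = res.bse[-1]
        ok = bool(res.mle_retvals.get("converged", False))
        if not np.isfinite(beta) or not np.isfinite(se) or se > 100:
            return beta, se, False
        return float(beta), float(se), ok


def gwas_logistic(
    geno: GenotypeData,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    snp_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-SNP additive logistic regression with covariate adjustment.

    ``covariates`` is an (n, c) matrix WITHOUT intercept (one is added).
    Missing genotypes are dropped per SNP (complete-case).  Monomorphic
    SNPs and non-converged/separated fits are flagged and carry missing
    p-values.  Returns a table with SNP, CHR, BP, EA, BETA, SE, OR, P, N,
    FLAG columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    n = y.size
    if covariates is None:
        base = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        base = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise ValueError("covariate matrix (with intercept) not full rank")
    if snp_ids is None:
        snp_idx = np.arange(geno.n_snps)
    else:
        lookup = {s: j for j, s in enumerate(geno.snps["SNP"])}
        snp_idx = np.array([lookup[s] for s in snp_ids])
    rows = []
    for j in snp_idx:
        calls = geno.calls[:, j].astype(float)
        keep = calls != MISSING
        g = calls[keep]
        # effect allele = in-sample minor allele
        p1 = g.mean() / 2.0
        if p1 <= 0.5:
            ea, dose = geno.snps["A1"].iat[j], g
        else:
            ea, dose = geno.snps["A2"].iat[j], 2.0 - g
        flag = "."
        if np.ptp(dose) == 0:
            beta = se = np.nan
            flag = "monomorphic"
        else:
            design = np.column_stack([base[keep], dose])
            beta, se, ok = _fit_one(y[keep], design)
            if not ok:
                flag = "no_convergence"
        if flag == ".":
            z = beta / se
            p = 2.0 * float(norm.sf(abs(z)))
        else:
            p = np.nan
        rows.append(
            {
                "SNP": geno.snps["SNP"].iat[j],
                "CHR": geno.snps["CHR"].iat[j],
                "BP": geno.snps["BP"].iat[j],
                "EA": ea,
                "BETA": beta,
                "SE": se,
                "OR": np.exp(beta) if np.isfinite(beta) else np.nan,
                "P": p,
                "N": int(keep.sum()),
                "FLAG": flag,
            }
        )
    return pd.DataFrame(rows)


def wald_ci(
    or_value: float, se_log: float, level: float = 0.95
) -> tuple[float, float]:
    """Wald confidence interval for an odds ratio: exp(ln OR +/- z SE)."""
    if or_value <= 0 or se_log <= 0:
        raise ValueError("need OR > 0 and SE > 0")
    z = float(norm.ppf(0.5 + level / 2.0))
    log_or = np.log(or_value)
    return float(np.exp(log_or - z * se_log)), float(np.exp(log_or + z * se_log))


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """min(1, p * n_tests)."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def inflation_factor(p_values: Sequence[float]) -> float:
    """Genomic inflation factor: median of the p-values converted to
    chi-square(1) quantiles, divided by the chi-square(1) median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no valid p-values")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_1_MEDIAN)


def replicate(
    discovery_hits: Sequence[str],
    geno: GenotypeData,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Test discovery hits in an independent panel.

    Runs the covariate-adjusted logistic GWAS restricted to the hit SNPs,
    adds the odds-ratio confidence interval and the Bonferroni adjustment
    over the number of hits.  Hits absent from the panel are recorded as
    untested.
    """
    present = [s for s in discovery_hits if (geno.snps["SNP"] == s).any()]
    absent = [s for s in discovery_hits if s not in present]
    n_tests = len(discovery_hits)
    out = gwas_logistic(geno, y, covariates, snp_ids=present) if present else \
        pd.DataFrame(columns=["SNP", "CHR", "BP", "EA", "BETA", "SE", "OR", "P", "N", "FLAG"])
    lower, upper, adj = [], [], []
    for _, row in out.iterrows():
        if np.isfinite(row["OR"]) and np.isfinite(row["SE"]) and row["SE"] > 0:
            lo, hi = wald_ci(row["OR"], row["SE"], level)
        else:
            lo = hi = np.nan
        lower.append(lo)
        upper.append(hi)
        adj.append(
            bonferroni_adjust(row["P"], n_tests) if np.isfinite(row["P"]) else np.nan
        )
    out["L95"], out["U95"], out["ADJ_P"] = lower, upper, adj
    for s in absent:
        out = pd.concat(
            [out, pd.DataFrame([{"SNP": s, "FLAG": "untested"}])],
            ignore_index=True,
        )
    return out
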