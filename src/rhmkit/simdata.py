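"""Synthetic case-control cohorts under a liability-threshold model.

Genotypes are drawn from a founder-haplotype pool: each chromosome is split
into LD blocks of ``ld_block_size`` adjacent SNPs; every individual's two
haplotypes copy, block by block, a founder chosen uniformly from the pool
(free recombination between blocks, perfect co-inheritance within a block).
Founder alleles are drawn site-wise from per-SNP minor allele frequencies,
so a block with few founders yields strong multi-SNP tagging while block
size one gives independent binomial(2, MAF) genotypes.

Liability is the sum of a genome-wide polygenic term, designated regional
QTL terms, covariate shifts and a normal residual, scaled so the genetic
plus residual variance is one.  An individual is a case when liability
exceeds the threshold t = Phi^-1(1 - K) for population prevalence K.
Cases are oversampled: individuals are generated until the requested case
and control quotas are both met, emulating case-control ascertainment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geno_qc import GenotypeData


class InvalidConfigError(ValueError):
    """Simulation configuration violating its invariants."""


class AccrualError(RuntimeError):
    """Case accrual exceeded the attempt cap (prevalence too small)."""


@dataclass(frozen=True)
class RegionalSpec:
    """One designated causal region: ``n_qtls`` causal SNPs placed within
    the ``span`` SNPs starting at ``start`` on ``chrom``, jointly
    contributing ``var_frac`` of the liability variance."""

    chrom: int
    start: int
    n_qtls: int
    var_frac: float
    span: int = 50


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cohort (all randomness from ``seed``)."""

    n_cases: int
    n_controls: int
    n_snps_per_chrom: tuple = (1000,)
    maf_range: tuple = (0.01, 0.5)
    ld_block_size: int = 1
    n_founder_haplotypes: int = 1000
    prevalence: float = 0.1
    polygenic_variance: float = 0.0
    regional_specs: tuple = ()
    covariate_effects: tuple = (("SEX", 0.0), ("ARRAY", 0.0))
    seed: int = 0
    max_accrual_batches: int = 1000

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls <= 0 or min(self.n_cases, self.n_controls) < 0:
            raise InvalidConfigError("need a positive number of individuals")
        if not self.n_snps_per_chrom or min(self.n_snps_per_chrom) <= 0:
            raise InvalidConfigError("each chromosome needs >= 1 SNP")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if self.ld_block_size < 1 or self.n_founder_haplotypes < 2:
            raise InvalidConfigError("need block size >= 1 and >= 2 founders")
        if not 0.0 < self.prevalence < 1.0:
            raise InvalidConfigError("prevalence must lie in (0, 1)")
        total = self.polygenic_variance + sum(r.var_frac for r in self.regional_specs)
        if not 0.0 <= self.polygenic_variance < 1.0 or total >= 1.0:
            raise InvalidConfigError(
                "polygenic + regional variance fractions must sum to < 1"
            )
        for r in self.regional_specs:
            if not 1 <= r.n_qtls <= r.span:
                raise InvalidConfigError("n_qtls must lie in [1, span]")
            if not 1 <= r.chrom <= len(self.n_snps_per_chrom):
                raise InvalidConfigError(f"region on unknown chromosome {r.chrom}")
            if r.start < 0 or r.start >= self.n_snps_per_chrom[r.chrom - 1]:
                raise InvalidConfigError("region start outside chromosome")

    @property
    def n_individuals(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class SimTruth:
    """Ground-truth architecture of a simulated cohort."""

    causal_effects: dict            # SNP id -> standardized effect size
    sigma_u2: float                 # polygenic liability variance
    sigma_w2: dict                  # region label -> regional liability variance
    sigma_e2: float                 # residual liability variance
    threshold: float                # liability threshold t = Phi^-1(1 - K)
    prevalence: float               # target population prevalence K
    realized_prevalence: float      # case fraction among all generated
    n_generated: int                # individuals generated before ascertainment
    covariate_effects: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Genotype generation
# ---------------------------------------------------------------------------

class _SimState:
    """Frozen generative state: founder pools, MAFs, block maps, rng."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        lo, hi = config.maf_range
        self.mafs, self.founders, self.blocks = [], [], []
        for m in config.n_snps_per_chrom:
            maf = rng.uniform(lo, hi, size=m)
            pool = (
                rng.random((config.n_founder_haplotypes, m)) < maf
            ).astype(np.int8)
            # keep the founder pool polymorphic at every site
            mono = np.flatnonzero(pool.min(0) == pool.max(0))
            for j in mono:
                k = rng.integers(config.n_founder_haplotypes)
                pool[k, j] = 1 - pool[k, j]
            self.mafs.append(maf)
            self.founders.append(pool)
            self.blocks.append(
                np.arange(m) // config.ld_block_size
            )
        # population allele frequency implied by the pool (used to
        # standardize genotypes for effect application)
        self.pool_freq = np.concatenate([f.mean(axis=0) for f in self.founders])

    def draw(self, n: int) -> np.ndarray:
        """Generate ``n`` individuals' genotype rows (all chromosomes)."""
        cols = []
        for pool, blocks in zip(self.founders, self.blocks):
            n_blocks = blocks[-1] + 1
            pick = self.rng.integers(
                0, pool.shape[0], size=(n, 2, n_blocks)
            ).astype(np.int32)
            fidx = pick[:, :, blocks]  # (n, 2, m)
            alleles = pool[fidx, np.arange(pool.shape[1])[None, None, :]]
            cols.append(alleles.sum(axis=1, dtype=np.int8))
        return np.hstack(cols)


def _snp_map(config: SimConfig) -> pd.DataFrame:
    rows = []
    for c, m in enumerate(config.n_snps_per_chrom, start=1):
        for j in range(m):
            rows.append((f"snp{c}_{j}", c, (j + 1) * 1000, "A", "G"))
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2"])


def _sample_frame(ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({"FID": list(ids), "IID": list(ids)})


def _fix_monomorphic(calls: np.ndarray, rng: np.random.Generator) -> None:
    """Toggle one haplotype at one individual for any monomorphic column so
    every sample allele frequency is strictly inside (0, 1)."""
    mono = np.flatnonzero(calls.min(0) == calls.max(0))
    for j in mono:
        i = rng.integers(calls.shape[0])
        calls[i, j] = 1 if calls[i, j] != 1 else 0


def simulate_genotypes(config: SimConfig, n: Optional[int] = None) -> GenotypeData:
    """Simulate hard-call genotypes for ``n`` individuals (default: the
    configured cohort size).  The generative state is kept in ``meta`` so
    phenotype simulation can extend the cohort under ascertainment."""
    n = config.n_individuals if n is None else int(n)
    if n <= 0:
        raise InvalidConfigError("zero individuals requested")
    rng = np.random.default_rng(config.seed)
    state = _SimState(config, rng)
    calls = state.draw(n)
    _fix_monomorphic(calls, rng)
    geno = GenotypeData(
        _sample_frame([f"I{i}" for i in range(n)]),
        _snp_map(config),
        calls,
        meta={"sim_state": state, "sim_next_id": n},
    )
    return geno


# ---------------------------------------------------------------------------
# Phenotype generation under liability threshold + ascertainment
# ---------------------------------------------------------------------------

def _causal_effects(config: SimConfig, snps: pd.DataFrame, rng) -> tuple:
    """Per-SNP standardized effects: equal variance share per causal SNP
    within a component, random signs."""
    m = len(snps)
    beta = np.zeros(m)
    offsets = {}
    pos = 0
    for c, mc in enumerate(config.n_snps_per_chrom, start=1):
        offsets[c] = pos
        pos += mc
    region_idx = []
    sigma_w2 = {}
    for r in config.regional_specs:
        lo = offsets[r.chrom] + r.start
        hi = min(lo + r.span, offsets[r.chrom] + config.n_snps_per_chrom[r.chrom - 1])
        qtls = rng.choice(np.arange(lo, hi), size=r.n_qtls, replace=False)
        signs = rng.choice([-1.0, 1.0], size=r.n_qtls)
        beta[qtls] = signs * np.sqrt(r.var_frac / r.n_qtls)
        region_idx.append(set(range(lo, hi)))
        sigma_w2[f"chr{r.chrom}:{r.start}"] = r.var_frac
    if config.polygenic_variance > 0:
        in_region = set().union(*region_idx) if region_idx else set()
        poly = np.array(sorted(set(range(m)) - in_region))
        if poly.size == 0:
            raise InvalidConfigError("no SNPs left for the polygenic component")
        signs = rng.choice([-1.0, 1.0], size=poly.size)
        beta[poly] = signs * np.sqrt(config.polygenic_variance / poly.size)
    return beta, sigma_w2


def simulate_phenotypes(
    geno: GenotypeData, config: SimConfig
) -> tuple[GenotypeData, pd.DataFrame, SimTruth]:
    """Assign liabilities and ascertain the cohort to the configured quotas.

    Returns the emitted cohort's genotypes (the input individuals plus any
    generated to fill the case/control quotas), a phenotype/covariate table
    (FID, IID, PHENO in {0,1}, SEX, ARRAY), and the ground truth.
    """
    state: _SimState = geno.meta.get("sim_state")
    if state is None:
        raise InvalidConfigError(
            "genotypes lack simulator state; use simulate_genotypes first"
        )
    rng = state.rng
    beta, sigma_w2 = _causal_effects(config, geno.snps, rng)
    sigma_e2 = 1.0 - config.polygenic_variance - sum(sigma_w2.values())
    t = float(norm.ppf(1.0 - config.prevalence))
    f = state.pool_freq
    scale = np.sqrt(2.0 * f * (1.0 - f))
    cov_effects = dict(config.covariate_effects)

    def liabilities(calls: np.ndarray) -> tuple:
        z = (calls - 2.0 * f) / scale
        g = z @ beta
        sex = rng.integers(0, 2, size=calls.shape[0])
        arr = rng.integers(0, 2, size=calls.shape[0])
        shift = cov_effects.get("SEX", 0.0) * sex + cov_effects.get("ARRAY", 0.0) * arr
        liab = g + shift + rng.normal(0.0, np.sqrt(sigma_e2), size=calls.shape[0])
        return liab, sex, arr

    kept_calls, kept_rows = [], []
    n_case = n_ctrl = 0
    n_generated = 0
    n_case_generated = 0
    next_id = geno.meta.get("sim_next_id", geno.n_samples)

    batch_calls = geno.calls
    batch_ids = [geno.samples["IID"].iat[i] for i in range(geno.n_samples)]
    batches = 0
    while True:
        liab, sex, arr = liabilities(batch_calls)
        is_case = liab > t
        n_generated += batch_calls.shape[0]
        n_case_generated += int(is_case.sum())
        for i in range(batch_calls.shape[0]):
            if is_case[i] and n_case < config.n_cases:
                n_case += 1
            elif not is_case[i] and n_ctrl < config.n_controls:
                n_ctrl += 1
            else:
                continue
            kept_calls.append(batch_calls[i])
            kept_rows.append(
                (batch_ids[i], int(is_case[i]), int(sex[i]), int(arr[i]))
            )
        if n_case >= config.n_cases and n_ctrl >= config.n_controls:
            break
        batches += 1
        if batches > config.max_accrual_batches:
            raise AccrualError(
                f"case accrual incomplete after {batches} batches "
                f"({n_case}/{config.n_cases} cases); prevalence too small "
                f"for the attempt cap"
            )
        size = max(config.n_individuals, 500)
        batch_calls = state.draw(size)
        batch_ids = [f"I{next_id + i}" for i in range(size)]
        next_id += size

    calls = np.array(kept_calls, dtype=np.int8)
    _fix_monomorphic(calls, rng)
    ids = [r[0] for r in kept_rows]
    cohort = GenotypeData(
        _sample_frame(ids),
        geno.snps.copy(),
        calls,
        meta={"sim_state": state, "sim_next_id": next_id},
    )
    pheno = pd.DataFrame(
        {
            "FID": ids,
            "IID": ids,
            "PHENO": [r[1] for r in kept_rows],
            "SEX": [r[2] for r in kept_rows],
            "ARRAY": [r[3] for r in kept_rows],
        }
    )
    causal = {
        geno.snps["SNP"].iat[j]: float(beta[j])
        for j in np.flatnonzero(beta != 0.0)
    }
    truth = SimTruth(
        causal_effects=causal,
        sigma_u2=config.polygenic_variance,
        sigma_w2=sigma_w2,
        sigma_e2=sigma_e2,
        threshold=t,
        prevalence=config.prevalence,
        realized_prevalence=n_case_generated / n_generated,
        n_generated=n_generated,
        covariate_effects=cov_effects,
    )
    return cohort, pheno, truth


def simulate_cohort(config: SimConfig) -> tuple[GenotypeData, pd.DataFrame, SimTruth]:
    """Generate a full ascertained cohort: genotypes, phenotypes, truth."""
    geno = simulate_genotypes(config)
    return simulate_phenotypes(geno, config)


# ---------------------------------------------------------------------------
# Sidecar I/O
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, path) -> None:
    """Write ground truth as a key=value text sidecar.

    Scalar fields appear as ``key=value`` lines; causal effects as
    ``causal.<snp>=<beta>`` and regional variances as ``region.<label>=<v>``.
    """
    lines = [
        f"sigma_u2={truth.sigma_u2!r}",
        f"sigma_e2={truth.sigma_e2!r}",
        f"threshold={truth.threshold!r}",
        f"prevalence={truth.prevalence!r}",
        f"realized_prevalence={truth.realized_prevalence!r}",
        f"n_generated={truth.n_generated}",
    ]
    lines += [f"region.{k}={v!r}" for k, v in truth.sigma_w2.items()]
    lines += [f"covariate.{k}={v!r}" for k, v in truth.covariate_effects.items()]
    lines += [f"causal.{k}={v!r}" for k, v in truth.causal_effects.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path) -> SimTruth:
    scalars, causal, regions, covs = {}, {}, {}, {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, val = line.split("=", 1)
        if key.startswith("causal."):
            causal[key[7:]] = float(val)
        elif key.startswith("region."):
            regions[key[7:]] = float(val)
        elif key.startswith("covariate."):
            covs[key[10:]] = float(val)
        else:
            scalars[key] = val
    return SimTruth(
        causal_effects=causal,
        sigma_u2=float(scalars["sigma_u2"]),
        sigma_w2=regions,
        sigma_e2=float(scalars["sigma_e2"]),
        threshold=float(scalars["threshold"]),
        prevalence=float(scalars["prevalence"]),
        realized_prevalence=float(scalars["realized_prevalence"]),
        n_generated=int(scalars["n_generated"]),
        covariate_effects=covs,
    )


def write_pheno(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_pheno(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
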