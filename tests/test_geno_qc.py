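"""Genotype container, PLINK binary codec, and QC filters."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhmkit import (
    MISSING,
    GenotypeData,
    compute_grm,
    filter_call_rate,
    filter_hwe,
    filter_maf,
    filter_relatedness,
    hwe_exact_test,
    ld_prune,
    read_plink,
    simulate_genotypes,
    write_plink,
)
from rhmkit.geno_qc import ConsistencyError, EmptyDataError, FormatError
from rhmkit.simdata import SimConfig


def make_geno(calls, chrom=None, bp=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = pd.DataFrame({"FID": [f"F{i}" for i in range(n)],
                            "IID": [f"I{i}" for i in range(n)]})
    snps = pd.DataFrame(
        {
            "SNP": [f"s{j}" for j in range(m)],
            "CHR": chrom if chrom is not None else [1] * m,
            "BP": bp if bp is not None else [(j + 1) * 1000 for j in range(m)],
            "A1": "A",
            "A2": "G",
        }
    )
    return GenotypeData(samples, snps, calls)


# ---------------------------------------------------------------------------
# PLINK codec
# ---------------------------------------------------------------------------

class TestPlinkIO:
    def test_bed_payload_byte_oracle(self, tmp_path):
        """Two individuals with A1 dosages (0, 2) pack into the single byte
        0b00000011: code 11 (zero copies) in the low bits, 00 (two copies)
        above, zero padding to the byte boundary."""
        geno = make_geno([[0], [2]])
        write_plink(geno, tmp_path / "x")
        raw = (tmp_path / "x.bed").read_bytes()
        assert raw[:3] == bytes([0x6C, 0x1B, 0x01])
        assert raw[3:] == bytes([0b00000011])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_round_trip_identity(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 1, 2, MISSING], size=(17, 23), p=[0.3, 0.3, 0.3, 0.1])
        geno = make_geno(calls)
        write_plink(geno, tmp_path / "rt")
        back = read_plink(tmp_path / "rt")
        np.testing.assert_array_equal(back.calls, calls)
        assert list(back.snps["SNP"]) == list(geno.snps["SNP"])

    def test_simulated_cohort_round_trip(self, tmp_path, null_cohort):
        geno, _, _ = null_cohort
        write_plink(geno, tmp_path / "sim")
        back = read_plink(tmp_path / "sim")
        np.testing.assert_array_equal(back.calls, geno.calls)

    def test_bad_magic_bytes(self, tmp_path):
        geno = make_geno([[0], [2]])
        write_plink(geno, tmp_path / "bad")
        bed = tmp_path / "bad.bed"
        bed.write_bytes(b"\x00\x00\x00" + bed.read_bytes()[3:])
        with pytest.raises(FormatError):
            read_plink(tmp_path / "bad")

    def test_fam_bed_dimension_mismatch(self, tmp_path):
        # 4 samples pack into 1 byte/SNP; a 5th fam row demands 2
        geno = make_geno([[0], [2], [1], [2]])
        write_plink(geno, tmp_path / "mm")
        fam = tmp_path / "mm.fam"
        fam.write_text(fam.read_text() + "F9 I9 0 0 0 -9\n")
        with pytest.raises(ConsistencyError):
            read_plink(tmp_path / "mm")

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ConsistencyError):
            make_geno([[0, 1], [1, 2]], bp=[2000, 1000])


# ---------------------------------------------------------------------------
# Call rate / MAF
# ---------------------------------------------------------------------------

class TestCallRateMaf:
    def test_no_missing_nothing_removed(self):
        geno = make_geno(np.ones((10, 5)))
        out, rep = filter_call_rate(geno, 0.98, 0.98)
        assert out.n_samples == 10 and out.n_snps == 5
        assert all(s.samples_removed == 0 and s.snps_removed == 0 for s in rep.steps)

    def test_snp_below_call_rate_removed(self):
        calls = np.ones((100, 60), dtype=np.int8)
        calls[:3, 0] = MISSING  # SNP0 at 97/100 < 0.98; samples stay at 59/60
        out, rep = filter_call_rate(make_geno(calls), 0.98, 0.98)
        assert out.n_snps == 59
        assert rep.steps[0].samples_removed == 0
        assert rep.steps[1].snps_removed == 1

    def test_sample_below_call_rate_removed(self):
        calls = np.ones((4, 1000), dtype=np.int8)
        calls[0, :50] = MISSING  # 95% < 98%
        out, rep = filter_call_rate(make_geno(calls), 0.98, 0.98)
        assert out.n_samples == 3 and rep.steps[0].samples_removed == 1

    def test_all_samples_removed_raises(self):
        calls = np.full((3, 10), MISSING, dtype=np.int8)
        with pytest.raises(EmptyDataError):
            filter_call_rate(make_geno(calls), 0.98, 0.98)

    def test_monomorphic_removed_at_default(self):
        out, _ = filter_maf(make_geno(np.zeros((20, 1))), 0.01)
        assert out.n_snps == 0

    def test_maf_exactly_at_threshold_retained(self):
        # dosage counts 98x0, 2x1: allele1 count 2/200 -> MAF exactly 0.01
        calls = np.zeros((100, 1), dtype=np.int8)
        calls[:2, 0] = 1
        out, _ = filter_maf(make_geno(calls), 0.01)
        assert out.n_snps == 1

    def test_zero_threshold_is_noop(self):
        calls = np.zeros((20, 2), dtype=np.int8)
        calls[0, 1] = 1
        out, _ = filter_maf(make_geno(calls), 0.0)
        assert out.n_snps == 2

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 1, 2, MISSING], size=(50, 40), p=[0.4, 0.3, 0.2, 0.1])
        once, _ = filter_call_rate(make_geno(calls), 0.9, 0.9)
        once, _ = filter_maf(once, 0.05)
        twice, rep = filter_call_rate(once, 0.9, 0.9)
        twice, rep = filter_maf(twice, 0.05, rep)
        assert twice.n_samples == once.n_samples and twice.n_snps == once.n_snps


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_oracle(h1, het, h2):
    """Exact rational enumeration over all heterozygote counts."""
    n = h1 + het + h2
    n1 = 2 * h1 + het
    nm = min(n1, 2 * n - n1)
    probs = {}
    for k in range(nm % 2, nm + 1, 2):
        a = (nm - k) // 2
        b = n - k - a
        probs[k] = Fraction(2**k * factorial(n), factorial(a) * factorial(k) * factorial(b))
    tot = sum(probs.values())
    pobs = probs[het]
    return float(sum(p for p in probs.values() if p <= pobs) / tot)


class TestHweExact:
    def test_modal_configuration_gives_p_one(self):
        assert hwe_exact_test((25, 50, 25)) == pytest.approx(1.0, abs=1e-12)

    def test_frozen_enumeration_value(self):
        # independently computed by exact rational enumeration
        assert hwe_exact_test((57, 14, 50)) == pytest.approx(
            5.562047311095335e-19, rel=1e-9
        )

    def test_all_heterozygote_fails_paper_threshold(self):
        for n in (30, 60):
            assert hwe_exact_test((0, n, 0)) < 1e-6

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=70),
        st.integers(min_value=0, max_value=70),
        st.integers(min_value=0, max_value=60),
    )
    def test_matches_enumeration_oracle(self, h1, het, h2):
        if h1 + het + h2 == 0:
            return
        p = hwe_exact_test((h1, het, h2))
        assert p == pytest.approx(hwe_oracle(h1, het, h2), abs=1e-12)
        assert 0 < p <= 1

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test((0, 0, 0))

    def test_filter_hwe_removes_extreme_snp(self):
        calls = np.ones((40, 2), dtype=np.int8)  # SNP0: all het
        rng = np.random.default_rng(0)
        calls[:, 1] = rng.binomial(2, 0.4, size=40)
        out, rep = filter_hwe(make_geno(calls), 1e-6)
        assert list(out.snps["SNP"]) == ["s1"]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

class TestLdPrune:
    def test_duplicated_column_one_copy_removed(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.3, size=200)
        calls = np.column_stack([col, col, rng.binomial(2, 0.3, size=200)])
        kept, _ = ld_prune(make_geno(calls), window=3, step=1, r2_max=0.8)
        assert len(kept) == 2 and "s2" in kept
        assert ("s0" in kept) != ("s1" in kept)

    def test_independent_snps_rarely_pruned(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.3, size=(1000, 60)).astype(np.int8)
        kept, _ = ld_prune(make_geno(calls), window=50, step=5, r2_max=0.8)
        # null r^2 ~ 1/n << 0.8, so essentially nothing should go
        assert len(kept) >= 58

    def test_two_founder_block_collapses(self):
        cfg = SimConfig(
            n_cases=100, n_controls=100, n_snps_per_chrom=(50,),
            maf_range=(0.2, 0.5), ld_block_size=50,
            n_founder_haplotypes=2, prevalence=0.5, seed=3,
        )
        geno = simulate_genotypes(cfg, n=200)
        kept, _ = ld_prune(geno, window=50, step=5, r2_max=0.8)
        assert len(kept) <= 5

    def test_no_retained_pair_exceeds_r2max(self):
        cfg = SimConfig(
            n_cases=100, n_controls=100, n_snps_per_chrom=(80,),
            maf_range=(0.1, 0.5), ld_block_size=10,
            n_founder_haplotypes=6, prevalence=0.5, seed=4,
        )
        geno = simulate_genotypes(cfg, n=300)
        kept, _ = ld_prune(geno, window=20, step=5, r2_max=0.5)
        idx = np.flatnonzero(geno.snps["SNP"].isin(kept).to_numpy())
        sub = geno.calls[:, idx].astype(float)
        r2 = np.corrcoef(sub, rowvar=False) ** 2
        np.fill_diagonal(r2, 0.0)
        # windowed guarantee: pairs within one window span stay below r2_max
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if idx[b] - idx[a] < 20:
                    assert r2[a, b] <= 0.5 + 1e-9


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

class TestRelatedness:
    def test_identical_rows_one_removed(self):
        rng = np.random.default_rng(0)
        calls = rng.binomial(2, 0.3, size=(20, 300)).astype(np.int8)
        calls[1] = calls[0]
        grm = compute_grm(make_geno(calls))
        kept, rep = filter_relatedness(grm, 0.1)
        assert rep.steps[0].samples_removed >= 1
        assert sum(1 for f, _ in kept if f in ("F0", "F1")) == 1

    def test_unrelated_cohort_no_removals(self, null_grm):
        # null GRM off-diagonal SD ~ 1/sqrt(N_snps); threshold 0.25 clears it
        kept, rep = filter_relatedness(null_grm, 0.25)
        assert rep.steps[0].samples_removed == 0

    def test_three_clique_removes_two(self):
        mat = np.eye(4)
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            mat[a, b] = mat[b, a] = 0.5
        samples = pd.DataFrame({"FID": list("abcd"), "IID": list("abcd")})
        from rhmkit import Grm

        kept, rep = filter_relatedness(Grm(samples, mat, 10), 0.1)
        assert rep.steps[0].samples_removed == 2
        assert ("d", "d") in kept
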