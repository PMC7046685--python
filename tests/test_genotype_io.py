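"""PLINK text/binary round trips, HWE exact test, and QC filtering."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from rohscan.genotype_io import (
    PlinkFormatError, QCEmptyError, QCParams,
    HOM_A, HET, HOM_B, MISSING,
    apply_qc, hwe_chisq_test, hwe_exact_test,
    read_plink_binary, read_plink_text, write_plink_binary, write_plink_text,
)

from _panels import make_gm


def _random_gm(rng, n=10, m=100, missing_rate=0.05):
    calls = rng.choice([HOM_A, HET, HOM_B], size=(n, m)).astype(np.int8)
    calls[rng.random((n, m)) < missing_rate] = MISSING
    chrom = np.sort(rng.integers(1, 4, size=m))
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom):
        sel = chrom == c
        pos[sel] = np.cumsum(rng.integers(5000, 20000, size=sel.sum()))
    return make_gm(calls, pos=pos, chrom=chrom)


class TestPedMapText:
    def test_direct_encoding_and_missing(self, tmp_path):
        (tmp_path / "t.map").write_text("1 v1 0 1000\n1 v2 0 2000\n1 v3 0 3000\n")
        (tmp_path / "t.ped").write_text("fam1 s1 0 0 0 -9 A A G T 0 0\n")
        gm = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
        assert gm.calls.tolist() == [[HOM_A, HET, MISSING]]
        assert gm.samples["breed"].tolist() == ["fam1"]

    def test_unsorted_map_positions_are_sorted_with_calls(self, tmp_path):
        (tmp_path / "t.map").write_text("1 v1 0 9000\n1 v2 0 1000\n2 v3 0 500\n")
        (tmp_path / "t.ped").write_text("f s1 0 0 0 -9 A A A C C C\n")
        gm = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
        # sorted by (chrom, pos): v2@1:1000 (het), v1@1:9000 (hom), v3@2:500 (hom)
        assert gm.variants["vid"].tolist() == ["v2", "v1", "v3"]
        assert gm.calls.tolist() == [[HET, HOM_A, HOM_A]]

    def test_text_roundtrip_random_panel(self, rng, tmp_path):
        gm = _random_gm(rng)
        write_plink_text(gm, tmp_path / "rt")
        back = read_plink_text(tmp_path / "rt.ped", tmp_path / "rt.map")
        assert np.array_equal(gm.canonical_codes(), back.canonical_codes())
        pd.testing.assert_frame_equal(
            gm.variants[["chrom", "pos_bp"]], back.variants[["chrom", "pos_bp"]])

    def test_wrong_allele_count_raises(self, tmp_path):
        (tmp_path / "t.map").write_text("1 v1 0 1000\n1 v2 0 2000\n")
        (tmp_path / "t.ped").write_text("f s1 0 0 0 -9 A A\n")
        with pytest.raises(PlinkFormatError):
            read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")

    def test_three_alleles_raises(self, tmp_path):
        (tmp_path / "t.map").write_text("1 v1 0 1000\n")
        (tmp_path / "t.ped").write_text("f s1 0 0 0 -9 A C\nf s2 0 0 0 -9 G G\n")
        with pytest.raises(PlinkFormatError):
            read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")

    def test_empty_variant_matrix_writes_valid_files(self, tmp_path):
        gm = make_gm(np.empty((2, 0), dtype=np.int8), pos=[], chrom=[])
        ped, mp = write_plink_text(gm, tmp_path / "e")
        assert mp.read_text() == ""
        back = read_plink_text(ped, mp)
        assert back.n_samples == 2 and back.n_variants == 0


class TestBedBinary:
    def test_binary_roundtrip_random_panel(self, rng, tmp_path):
        gm = _random_gm(rng)
        write_plink_binary(gm, tmp_path / "rt")
        back = read_plink_binary(tmp_path / "rt.bed", tmp_path / "rt.bim",
                                 tmp_path / "rt.fam")
        assert np.array_equal(gm.calls, back.calls)
        assert back.variants["a1"].tolist() == gm.variants["a1"].tolist()

    def test_handpacked_bytes_five_samples(self, tmp_path):
        # one variant, 5 samples -> 2 bytes; codes decoded pair-by-pair from
        # the least significant bits: 00 hom_a1, 01 missing, 10 het, 11 hom_a2
        expected = [HOM_A, MISSING, HET, HOM_B, HET]
        byte1 = 0b11_10_01_00  # samples 1-4
        byte2 = 0b00_00_00_10  # sample 5 + padding
        (tmp_path / "t.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, byte1, byte2]))
        (tmp_path / "t.bim").write_text("1 v1 0 1000 A B\n")
        (tmp_path / "t.fam").write_text(
            "".join(f"f s{i} 0 0 0 -9\n" for i in range(5)))
        gm = read_plink_binary(tmp_path / "t.bed", tmp_path / "t.bim",
                               tmp_path / "t.fam")
        assert gm.calls[:, 0].tolist() == expected

    def test_bad_magic_raises(self, tmp_path):
        (tmp_path / "t.bed").write_bytes(bytes([0x00, 0x00, 0x01]))
        (tmp_path / "t.bim").write_text("1 v1 0 1000 A B\n")
        (tmp_path / "t.fam").write_text("f s1 0 0 0 -9\n")
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink_binary(tmp_path / "t.bed", tmp_path / "t.bim",
                              tmp_path / "t.fam")

    def test_sample_major_mode_unsupported(self, tmp_path):
        (tmp_path / "t.bed").write_bytes(bytes([0x6C, 0x1B, 0x00, 0x00]))
        (tmp_path / "t.bim").write_text("1 v1 0 1000 A B\n")
        (tmp_path / "t.fam").write_text("f s1 0 0 0 -9\n")
        with pytest.raises(PlinkFormatError, match="sample-major"):
            read_plink_binary(tmp_path / "t.bed", tmp_path / "t.bim",
                              tmp_path / "t.fam")


def _hwe_enumeration_oracle(n_hom_a, n_het, n_hom_b):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_hom_a + n_het + n_hom_b
    rare = 2 * min(n_hom_a, n_hom_b) + n_het
    common = 2 * n - rare
    probs = {}
    for h in range(rare % 2, min(rare, common) + 1, 2):
        a = (rare - h) // 2
        b = (common - h) // 2
        probs[h] = Fraction(
            math.factorial(n) * 2 ** h * math.factorial(rare) * math.factorial(common),
            math.factorial(a) * math.factorial(h) * math.factorial(b)
            * math.factorial(2 * n),
        )
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHWE:
    def test_exact_matches_enumeration_all_small_tables(self):
        """Agreement with brute-force enumeration for every table with <=30 alleles."""
        for n in range(1, 16):  # 2n <= 30 alleles
            for n_het in range(n + 1):
                for n_hom_a in range(n - n_het + 1):
                    n_hom_b = n - n_het - n_hom_a
                    expect = _hwe_enumeration_oracle(n_hom_a, n_het, n_hom_b)
                    got = hwe_exact_test(n_hom_a, n_het, n_hom_b)
                    assert got == pytest.approx(expect, abs=1e-10)

    def test_all_het_table(self):
        assert hwe_exact_test(0, 10, 0) == pytest.approx(
            _hwe_enumeration_oracle(0, 10, 0))

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_perfect_hwe_symmetric_table(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_all_zero_counts_raises(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_chisq_variant_tracks_exact_on_large_tables(self):
        p_exact = hwe_exact_test(300, 500, 200)
        p_chi = hwe_chisq_test(300, 500, 200)
        assert p_exact == pytest.approx(p_chi, rel=0.5)


class TestApplyQC:
    def _panel(self):
        """100 samples; 4 variants engineered around each threshold plus
        50 well-behaved fillers (so per-sample missingness stays low)."""
        rng = np.random.default_rng(5)
        n = 100
        filler = rng.choice([HOM_A, HET, HOM_B], p=[0.25, 0.5, 0.25],
                            size=(n, 50)).astype(np.int8)
        eng = np.zeros((n, 4), dtype=np.int8)
        # v_cr: call rate 0.89 (11 missing) -> removed
        eng[:, 0] = filler[:, 0]
        eng[:11, 0] = MISSING
        # v_maf_low: MAF 0.04 -> removed (8 B alleles in 200)
        eng[:, 1] = HOM_A
        eng[:8, 1] = HET
        # v_maf_ok: 12 het carriers -> MAF 0.06, near HWE expectation -> kept
        eng[:, 2] = HOM_A
        eng[:12, 2] = HET
        # v_hwe: gross HWE failure: half hom_a half hom_b, no het
        eng[:50, 3] = HOM_A
        eng[50:, 3] = HOM_B
        calls = np.hstack([eng, filler])
        m = calls.shape[1]
        gm = make_gm(calls, pos=np.arange(1, m + 1) * 1000)
        gm.variants.loc[:3, "vid"] = ["v_cr", "v_maf_low", "v_maf_ok", "v_hwe"]
        return gm

    def test_variant_filters_at_thresholds(self):
        gm, report = apply_qc(self._panel())
        kept = gm.variants["vid"].tolist()
        assert report.n_samples_removed == 0
        assert report.n_snps_removed_callrate == 1 and "v_cr" not in kept
        assert report.n_snps_removed_maf == 1 and "v_maf_low" not in kept
        assert report.n_snps_removed_hwe == 1 and "v_hwe" not in kept

    def test_maf_just_above_threshold_kept(self):
        gm, _ = apply_qc(self._panel())
        assert "v_maf_ok" in gm.variants["vid"].tolist()

    def test_sample_missingness_rule(self):
        calls = np.zeros((3, 50), dtype=np.int8)
        calls[:, :] = np.tile([HOM_A, HET], 25)[:50]
        calls[0, :6] = MISSING  # 12% missing -> removed
        calls[1, :5] = MISSING  # exactly 10% -> kept
        gm = make_gm(calls, pos=np.arange(1, 51) * 1000)
        out, report = apply_qc(gm, QCParams(min_maf=0.0, min_call_rate=0.0,
                                            hwe_p_threshold=0.0))
        assert report.n_samples_removed == 1
        assert out.samples["sample_id"].tolist() == ["s1", "s2"]

    def test_nonautosomal_variants_dropped_first(self):
        calls = np.tile([HOM_A, HET, HOM_B, HET], (8, 1)).astype(np.int8)
        gm = make_gm(calls, pos=[1000, 2000, 1000, 2000], chrom=[1, 1, 30, 30])
        out, report = apply_qc(gm, QCParams(min_maf=0.0, min_call_rate=0.0,
                                            hwe_p_threshold=0.0))
        assert report.n_snps_removed_nonautosomal == 2
        assert (out.variants["chrom"] <= 29).all()

    def test_idempotent(self, rng):
        calls = rng.choice([HOM_A, HET, HOM_B], size=(40, 200)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.02] = MISSING
        gm = make_gm(calls, pos=np.arange(1, 201) * 5000)
        once, _ = apply_qc(gm)
        twice, report2 = apply_qc(once)
        assert np.array_equal(once.calls, twice.calls)
        assert report2.n_snps_removed_callrate == 0
        assert report2.n_snps_removed_maf == 0
        assert report2.n_snps_removed_hwe == 0

    def test_all_samples_removed_raises_with_report(self):
        calls = np.full((2, 10), MISSING, dtype=np.int8)
        gm = make_gm(calls, pos=np.arange(1, 11) * 1000)
        with pytest.raises(QCEmptyError) as exc:
            apply_qc(gm)
        assert exc.value.report.n_samples_removed == 2

    def test_every_retained_variant_beats_call_rate(self, rng):
        calls = rng.choice([HOM_A, HET, HOM_B], size=(50, 300)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.08] = MISSING
        gm = make_gm(calls, pos=np.arange(1, 301) * 4000)
        out, _ = apply_qc(gm)
        if out.n_variants:
            cr = (out.calls != MISSING).mean(axis=0)
            assert (cr > 0.90).all()
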