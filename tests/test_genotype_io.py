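import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geascan import genotype_io as gio
from geascan.genotype_io import MISSING

from conftest import make_vcf, matrix_from_calls


class TestReadGenotypes:
    def test_vcf_basic_transcription(self, tmp_path):
        p = make_vcf(tmp_path / "a.vcf",
                     [("1", 100, "rs1", "A", "G", ["0/0", "0/1"])])
        g = gio.read_genotypes(p, "vcf")
        assert g.samples == ["s1", "s2"]
        assert g.calls.tolist() == [[0], [1]]
        assert g.snps.loc[0, "ref"] == "A" and g.snps.loc[0, "alt"] == "G"

    def test_vcf_skips_triallelic(self, tmp_path):
        recs = [("1", 100 * (i + 1), f"rs{i}", "A", "G", ["0/0", "0/1"])
                for i in range(4)]
        recs.insert(2, ("1", 250, "tri", "A", "G,T", ["0/0", "0/1"]))
        p = make_vcf(tmp_path / "b.vcf", recs)
        g = gio.read_genotypes(p, "vcf")
        assert g.n_snps == 4
        assert "tri" not in list(g.snps["name"])

    def test_vcf_skips_indels(self, tmp_path):
        p = make_vcf(tmp_path / "c.vcf", [
            ("1", 100, "rs1", "A", "G", ["0/0", "1/1"]),
            ("1", 200, "indel", "AT", "A", ["0/0", "0/1"]),
        ])
        assert gio.read_genotypes(p, "vcf").n_snps == 1

    def test_vcf_missing_call(self, tmp_path):
        p = make_vcf(tmp_path / "d.vcf",
                     [("1", 100, "rs1", "A", "G", ["./.", "1/1"])])
        g = gio.read_genotypes(p, "vcf")
        assert g.calls.tolist() == [[MISSING], [2]]

    def test_vcf_no_snps_fatal(self, tmp_path):
        p = make_vcf(tmp_path / "e.vcf",
                     [("1", 100, "x", "AT", "A", ["0/0", "0/1"])])
        with pytest.raises(gio.GenotypeError):
            gio.read_genotypes(p, "vcf")

    def test_unreadable_fatal(self, tmp_path):
        with pytest.raises(gio.GenotypeError):
            gio.read_genotypes(tmp_path / "nope.vcf", "vcf")

    def test_ped_first_allele_is_ref(self, tmp_path):
        (tmp_path / "g.map").write_text("1 snp1 0 100\n1 snp2 0 200\n")
        (tmp_path / "g.ped").write_text(
            "f1 i1 0 0 0 0 A A G G\n"
            "f2 i2 0 0 0 0 A G G A\n"
            "f3 i3 0 0 0 0 G G 0 0\n"
        )
        g = gio.read_genotypes(tmp_path / "g.ped", "ped")
        assert g.samples == ["i1", "i2", "i3"]
        # snp1: A encountered first -> ref; "A A" -> dosage 0
        assert g.snps.loc[0, "ref"] == "A"
        assert g.calls[:, 0].tolist() == [0, 1, 2]
        assert g.calls[2, 1] == MISSING

    def test_ped_bad_field_count(self, tmp_path):
        (tmp_path / "h.map").write_text("1 snp1 0 100\n")
        (tmp_path / "h.ped").write_text("f1 i1 0 0 0 0 A\n")
        with pytest.raises(gio.GenotypeError, match="expected 8 fields"):
            gio.read_genotypes(tmp_path / "h.ped", "ped")


class TestMaf:
    def test_arithmetic(self):
        g = matrix_from_calls(np.array([[0], [1], [2], [2]]))
        assert gio.compute_maf(g)[0] == pytest.approx(0.375)

    def test_monomorphic(self):
        g = matrix_from_calls(np.array([[0], [0], [0]]))
        assert gio.compute_maf(g)[0] == 0.0

    def test_missing_excluded(self):
        g = matrix_from_calls(np.array([[MISSING], [1], [1]]))
        assert gio.compute_maf(g)[0] == pytest.approx(0.5)

    def test_all_missing_is_nan(self):
        g = matrix_from_calls(np.array([[MISSING], [MISSING]]))
        assert np.isnan(gio.compute_maf(g)[0])


class TestApplyQC:
    def test_monomorphic_removed(self):
        calls = np.array([
            [0, 0, 1, 2, 1],
            [1, 0, 2, 1, 0],
            [2, 0, 1, 0, 1],
            [1, 0, 0, 1, 2],
        ])
        g = matrix_from_calls(calls)
        out, rep = gio.apply_qc(g, gio.QCThresholds(maf_min=0.05, missing_max=1.0))
        assert out.n_snps == 4
        assert rep["n_discarded_maf"] == 1

    def test_missingness_removed(self):
        calls = np.ones((10, 2), dtype=np.int8)
        calls[0, 0] = 0  # keep snp1 polymorphic
        calls[1, 0] = 2
        calls[:3, 1] = MISSING
        calls[3, 1] = 0
        g = matrix_from_calls(calls)
        out, rep = gio.apply_qc(g, gio.QCThresholds(maf_min=0.0, missing_max=0.1))
        assert list(out.snps["name"]) == ["snp1"]
        assert rep["n_discarded_missingness"] == 1

    def test_noop_thresholds_identity(self, small_dataset):
        g = small_dataset.genotypes
        out, _ = gio.apply_qc(g, gio.QCThresholds(maf_min=0.0, missing_max=1.0))
        assert out.n_snps == g.n_snps
        assert np.array_equal(out.calls, g.calls)

    def test_all_removed_fatal(self):
        g = matrix_from_calls(np.zeros((4, 3), dtype=np.int8))
        with pytest.raises(gio.GenotypeError):
            gio.apply_qc(g, gio.QCThresholds(maf_min=0.05, missing_max=1.0))

    def test_idempotent(self, small_dataset):
        t = gio.QCThresholds(maf_min=0.05, missing_max=0.1, ld_r2_max=0.5)
        once, _ = gio.apply_qc(small_dataset.genotypes, t)
        twice, _ = gio.apply_qc(once, t)
        assert list(once.snps["name"]) == list(twice.snps["name"])
        assert np.array_equal(once.calls, twice.calls)

    def test_retained_respect_thresholds(self, small_dataset):
        t = gio.QCThresholds(maf_min=0.1, missing_max=0.05)
        out, _ = gio.apply_qc(small_dataset.genotypes, t)
        assert (gio.compute_maf(out) >= 0.1).all()
        assert (gio.compute_missingness(out) <= 0.05).all()

    def test_report_histograms(self, small_dataset):
        _, rep = gio.apply_qc(small_dataset.genotypes,
                              gio.QCThresholds(ld_r2_max=0.5))
        assert len(rep["maf_hist"]["counts"]) == 20
        assert len(rep["missingness_hist"]["counts"]) == 20


def brute_force_prune(calls, r2_max):
    """All-pairs greedy oracle: scan left to right, drop the later SNP of any
    high-r2 pair with an already-kept SNP (independent of geascan's path)."""
    kept = []
    for j in range(calls.shape[1]):
        ok = True
        for i in kept:
            a, b = calls[:, i].astype(float), calls[:, j].astype(float)
            m = (calls[:, i] != MISSING) & (calls[:, j] != MISSING)
            if m.sum() >= 2 and a[m].std() > 0 and b[m].std() > 0:
                r = np.corrcoef(a[m], b[m])[0, 1]
                if r * r > r2_max:
                    ok = False
                    break
        if ok:
            kept.append(j)
    return kept


class TestLdPrune:
    def test_identical_pair_drops_later(self):
        col = np.array([0, 1, 2, 1, 0, 2])
        g = matrix_from_calls(np.column_stack([col, col]))
        out = gio.ld_prune(g, r2_max=0.2)
        assert list(out.snps["name"]) == ["snp1"]

    def test_orthogonal_pair_kept(self):
        a = np.array([0, 0, 2, 2])
        b = np.array([0, 2, 0, 2])
        g = matrix_from_calls(np.column_stack([a, b]))
        out = gio.ld_prune(g, r2_max=0.2)
        assert out.n_snps == 2

    def test_cross_chromosome_pairs_ignored(self):
        col = np.array([0, 1, 2, 1, 0, 2])
        g = matrix_from_calls(np.column_stack([col, col]),
                              chrom=["1", "2"])
        assert gio.ld_prune(g, r2_max=0.2).n_snps == 2

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        base = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
        # plant 10 duplicate columns to force correlated pairs
        dup_src = rng.choice(40, size=10, replace=False)
        dups = base[:, dup_src].copy()
        calls = np.concatenate([base, dups], axis=1)
        order = rng.permutation(50)
        calls = calls[:, order]
        g = matrix_from_calls(calls)
        out = gio.ld_prune(g, r2_max=0.2, window=50)
        expected = brute_force_prune(calls, 0.2)
        assert list(out.snps["name"]) == [f"snp{j+1}" for j in expected]

    def test_no_remaining_high_r2_pair(self, small_dataset):
        g = small_dataset.genotypes
        out = gio.ld_prune(g, r2_max=0.3, window=50)
        calls = out.calls
        for i in range(out.n_snps):
            for j in range(i + 1, min(i + 50, out.n_snps)):
                assert gio._pairwise_r2(calls[:, i], calls[:, j]) <= 0.3


class TestEncodeIndicators:
    def test_count_is_three_per_snp(self, small_dataset):
        ind = gio.encode_indicators(small_dataset.genotypes)
        assert ind.n_indicators == 3 * small_dataset.genotypes.n_snps

    def test_counting_rule(self):
        assert gio.indicator_count(38_335) == 115_005
        assert gio.indicator_count(20_226_452) == 60_679_356

    def test_het_call_pattern(self):
        g = matrix_from_calls(np.array([[1]]))
        ind = gio.encode_indicators(g)
        assert list(ind.indicators["label"]) == ["snp1_AA", "snp1_AG", "snp1_GG"]
        assert ind.values.tolist() == [[0, 1, 0]]

    def test_missing_call_all_missing(self):
        g = matrix_from_calls(np.array([[MISSING], [2]]))
        ind = gio.encode_indicators(g)
        assert ind.values.tolist() == [[MISSING] * 3, [0, 0, 1]]

    def test_row_sums_one_where_called(self, small_dataset):
        g = small_dataset.genotypes
        ind = gio.encode_indicators(g)
        vals = ind.values.reshape(g.n_samples, g.n_snps, 3)
        called = g.calls != MISSING
        assert (vals[called].sum(axis=1) == 1).all()
        assert (vals[~called] == MISSING).all()

    @given(st.integers(min_value=0, max_value=10**9))
    def test_count_rule_is_linear(self, n):
        assert gio.indicator_count(n) == 3 * n


class TestSambadaFormat:
    def test_layout(self, tmp_path):
        g = matrix_from_calls(np.array([[0], [2]]))
        ind = gio.encode_indicators(g)
        path = tmp_path / "geno.txt"
        gio.write_sambada_format(ind, path)
        lines = path.read_text().splitlines()
        assert lines[0].split() == ["ID", "snp1_AA", "snp1_AG", "snp1_GG"]
        assert len(lines) == 3
        assert lines[1].split() == ["i1", "1", "0", "0"]

    def test_round_trip_identity(self, tmp_path, small_dataset):
        ind = gio.encode_indicators(small_dataset.genotypes)
        path = tmp_path / "geno.txt"
        gio.write_sambada_format(ind, path)
        back = gio.read_sambada_format(path)
        assert back == ind

    def test_bad_row_length_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("ID snp1_AA snp1_AG snp1_GG\ni1 1 0 0\ni2 1 0\n")
        with pytest.raises(gio.GenotypeError, match=":3"):
            gio.read_sambada_format(path)

    def test_tab_tolerant(self, tmp_path):
        path = tmp_path / "tabs.txt"
        path.write_text("ID\tsnp1_AA  snp1_AG\tsnp1_GG\ni1\t0  1\t0\n")
        back = gio.read_sambada_format(path)
        assert back.values.tolist() == [[0, 1, 0]]


class TestValidation:
    def test_duplicate_samples_rejected(self):
        with pytest.raises(gio.GenotypeError):
            g = matrix_from_calls(np.zeros((2, 1), dtype=np.int8))
            gio.GenotypeMatrix(samples=["a", "a"], snps=g.snps, calls=g.calls)

    def test_illegal_call_rejected(self):
        with pytest.raises(gio.GenotypeError):
            matrix_from_calls(np.array([[5]]))

    def test_threshold_ranges(self):
        with pytest.raises(gio.GenotypeError):
            gio.QCThresholds(maf_min=0.7)
        with pytest.raises(gio.GenotypeError):
            gio.QCThresholds(missing_max=1.5)
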