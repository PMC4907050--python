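"""Genotype container, I/O, QC statistics, filtering, imputation, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from croaker_gs.exceptions import (
    ConfigurationError,
    GenotypeParseError,
    GenotypeValidationError,
    MonomorphicMarkerError,
)
from croaker_gs.genotype_data import (
    GenotypeMatrix,
    compute_marker_stats,
    filter_markers,
    impute_missing,
    read_genotypes,
    standardize,
    write_genotypes,
)

from conftest import make_matrix

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def _write_vcf(path, records):
    path.write_text(VCF_HEADER + "".join(records))
    return str(path)


class TestReadGenotypes:
    def test_vcf_gt_to_dosage(self, tmp_path):
        """GT fields 0/0, 0/1, 1/1 map to ALT-allele dosages 0, 1, 2."""
        p = _write_vcf(tmp_path / "a.vcf",
                       ["1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
                        "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/0\t./.\n"])
        g = read_genotypes(p, format="vcf")
        assert g.sample_ids == ["S1", "S2", "S3"]
        np.testing.assert_array_equal(g.codes[:, 0], [0, 1, 2])
        assert g.missing[2, 1] and not g.missing[:, 0].any()
        assert list(g.markers["pos"]) == [100, 200]

    def test_vcf_skips_multiallelic(self, tmp_path):
        recs = [f"1\t{100*i}\trs{i}\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
                for i in range(1, 6)]
        recs[2] = "1\t300\trs3\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/2\n"
        g = read_genotypes(_write_vcf(tmp_path / "b.vcf", recs), format="vcf")
        assert g.n_markers == 4
        assert "rs3" not in set(g.markers["marker_id"])

    def test_matrix_text_missing_cell(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\tm1\tm2\ns1\t0\tNA\ns2\t2\t1\n")
        g = read_genotypes(str(path))
        assert g.missing.sum() == 1 and g.missing[0, 1]

    def test_matrix_text_bad_cell_names_line(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\tm1\ns1\t0\ns2\tXX\n")
        with pytest.raises(GenotypeParseError, match=":3"):
            read_genotypes(str(path))

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\tm1\tm1\ns1\t0\t1\n")
        with pytest.raises(GenotypeValidationError, match="duplicate marker"):
            read_genotypes(str(path))

    def test_matrix_text_round_trip(self, tmp_path, rng):
        codes = rng.integers(0, 3, size=(8, 12)).astype(float)
        missing = rng.random((8, 12)) < 0.2
        g = make_matrix(codes, missing)
        write_genotypes(g, str(tmp_path / "rt.tsv"), sidecar=str(tmp_path / "rt.markers.tsv"))
        g2 = read_genotypes(str(tmp_path / "rt.tsv"), sidecar=str(tmp_path / "rt.markers.tsv"))
        np.testing.assert_array_equal(g.missing, g2.missing)
        np.testing.assert_array_equal(g.codes[~g.missing], g2.codes[~g2.missing])
        assert g2.markers.equals(g.markers)


class TestMarkerStats:
    def test_exact_hwe_proportions(self):
        codes = np.repeat([[0], [1], [2]], [25, 50, 25], axis=0)
        s = compute_marker_stats(make_matrix(codes))
        assert s.p_coded[0] == pytest.approx(0.5)
        assert s.hwe_p[0] == pytest.approx(1.0)

    def test_hwe_chi_square_hand_example(self):
        """Counts (30, 60, 10): p=0.4, chi2 = 1 + 3 + 2.25 = 6.25, p ≈ 0.0124."""
        codes = np.repeat([[0], [1], [2]], [30, 60, 10], axis=0)
        s = compute_marker_stats(make_matrix(codes))
        assert s.p_coded[0] == pytest.approx(0.40)
        assert s.hwe_p[0] == pytest.approx(0.012419, abs=1e-5)

    def test_missing_rate_and_all_missing_flag(self):
        codes = np.zeros((10, 2))
        missing = np.zeros((10, 2), bool)
        missing[:2, 0] = True
        missing[:, 1] = True
        s = compute_marker_stats(make_matrix(codes, missing))
        assert s.missing_rate[0] == pytest.approx(0.2)
        assert s.all_missing[1] and np.isnan(s.p_coded[1])

    def test_maf_folds_coded_frequency(self):
        codes = np.repeat([[2], [2], [1]], [8, 0, 2], axis=0)  # p large
        s = compute_marker_stats(make_matrix(codes))
        assert s.p_coded[0] == pytest.approx(0.9)
        assert s.maf[0] == pytest.approx(0.1)


class TestFilterMarkers:
    def _five_marker_fixture(self):
        rng = np.random.default_rng(1)
        n = 40
        codes = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
        missing = np.zeros((n, 5), bool)
        missing[: int(0.25 * n), 0] = True          # missing 0.25
        codes[:, 1] = np.repeat([0, 1], [38, 2])    # maf 0.025
        codes[:, 2] = np.repeat([0, 2], [20, 20])   # extreme HWE violation
        return make_matrix(codes, missing)

    def test_each_rule_removes_its_marker(self):
        g = self._five_marker_fixture()
        s = compute_marker_stats(g)
        out = filter_markers(g, s)
        assert out.n_markers == 2
        assert list(out.markers["marker_id"]) == ["m3", "m4"]

    def test_missing_threshold_is_inclusive(self):
        codes = np.zeros((10, 1))
        codes[5:] = 1
        missing = np.zeros((10, 1), bool)
        missing[:2, 0] = True   # exactly 0.20
        g = make_matrix(codes, missing)
        out = filter_markers(g, compute_marker_stats(g))
        assert out.n_markers == 0

    def test_clean_input_identity_and_idempotence(self, rng):
        codes = rng.binomial(2, 0.4, size=(60, 10)).astype(float)
        g = make_matrix(codes)
        s = compute_marker_stats(g)
        once = filter_markers(g, s)
        twice = filter_markers(once, compute_marker_stats(once))
        np.testing.assert_array_equal(once.codes, twice.codes)
        assert list(once.markers["marker_id"]) == list(twice.markers["marker_id"])

    def test_bad_threshold_rejected(self):
        g = make_matrix(np.ones((4, 1)))
        with pytest.raises(ConfigurationError):
            filter_markers(g, compute_marker_stats(g), {"min_maf": 1.5})


class TestImputeMissing:
    def test_mean_dosage_writes_2p(self):
        codes = np.array([[0.0], [2.0], [1.0], [1.0], [0.0]])
        missing = np.array([[False], [False], [False], [False], [True]])
        g = make_matrix(codes, missing)
        s = compute_marker_stats(g)   # p = 0.5 over 4 calls
        out = impute_missing(g, s, "mean-dosage")
        assert out.codes[4, 0] == pytest.approx(1.0)
        assert not out.missing.any()

    def test_no_missing_is_identity_both_modes(self, rng):
        g = make_matrix(rng.binomial(2, 0.3, size=(10, 5)).astype(float))
        s = compute_marker_stats(g)
        for mode in ("mean-dosage", "hwe-sample"):
            np.testing.assert_array_equal(impute_missing(g, s, mode).codes, g.codes)

    def test_hwe_sample_mean_dosage(self):
        rng = np.random.default_rng(3)
        n = 10000
        codes = rng.binomial(2, 0.25, size=(n, 1)).astype(float)
        missing = np.ones((n, 1), bool)
        missing[:100] = False   # few observed calls pin p̂ near 0.25
        codes[:100, 0] = np.repeat([0, 1, 2], [57, 37, 6])
        g = make_matrix(codes, missing)
        s = compute_marker_stats(g)
        out = impute_missing(g, s, "hwe-sample", seed=11)
        assert out.codes[missing].mean() == pytest.approx(2 * s.p_coded[0], abs=0.05)

    def test_unknown_mode(self):
        g = make_matrix(np.ones((4, 1)))
        with pytest.raises(ConfigurationError):
            impute_missing(g, compute_marker_stats(g), "magic")


class TestStandardize:
    def test_direct_substitution(self):
        g = make_matrix(np.array([[1.0], [2.0]]))
        x = standardize(g, freqs=np.array([0.5]))
        assert x[0, 0] == pytest.approx(0.0)
        x2 = standardize(np.array([[2.0]]), freqs=np.array([0.25]))
        assert x2[0, 0] == pytest.approx((2 - 0.5) / np.sqrt(0.375), abs=1e-4)

    def test_hwe_column_moments(self):
        rng = np.random.default_rng(9)
        codes = rng.binomial(2, 0.3, size=(10000, 1)).astype(float)
        x = standardize(codes, freqs=np.array([0.3]))
        assert abs(x.mean()) < 0.05
        assert abs(x.var() - 1) < 0.1

    def test_monomorphic_rejected_or_zeroed(self):
        codes = np.zeros((5, 1))
        with pytest.raises(MonomorphicMarkerError):
            standardize(codes, freqs=np.array([0.0]))
        x = standardize(codes, freqs=np.array([0.0]), monomorphic="zero")
        np.testing.assert_array_equal(x, np.zeros((5, 1)))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_filtering_idempotent_property(seed):
    """filter(filter(g)) == filter(g) on random matrices with random missingness."""
    rng = np.random.default_rng(seed)
    codes = rng.binomial(2, rng.uniform(0.02, 0.98, 6), size=(30, 6)).astype(float)
    missing = rng.random((30, 6)) < 0.3
    g = make_matrix(codes, missing)
    once = filter_markers(g, compute_marker_stats(g))
    twice = filter_markers(once, compute_marker_stats(once))
    assert list(once.markers["marker_id"]) == list(twice.markers["marker_id"])
    np.testing.assert_array_equal(once.missing, twice.missing)
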