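import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gxescan import data_io
from gxescan.types import GenotypeMatrix, QcThresholds, QcTier, ScanTable, SCAN_COLUMNS

from conftest import make_genotypes


def _write_dosage_tsv(path, rows, samples=("sA", "sB")):
    header = "\t".join(["variant_id", "effect_allele", "other_allele",
                        "imputation_r2", *samples])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


class TestReadDosageMatrix:
    def test_maf_from_two_samples(self, tmp_path):
        p = tmp_path / "d.tsv"
        _write_dosage_tsv(p, [("v1", "A", "G", 0.9, 0, 2)])
        g = data_io.read_dosage_matrix(p)
        assert g.maf[0] == pytest.approx(0.5)
        assert g.sample_ids == ["sA", "sB"]

    def test_out_of_range_dosage_clipped_and_counted(self, tmp_path):
        p = tmp_path / "d.tsv"
        _write_dosage_tsv(p, [("v1", "A", "G", 0.9, 2.04, 1.0)])
        g = data_io.read_dosage_matrix(p)
        assert g.dosages[0, 0] == 2.0
        assert g.n_clipped == 1

    def test_duplicate_variant_id_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        _write_dosage_tsv(p, [("v1", "A", "G", 0.9, 0, 1), ("v1", "A", "G", 0.9, 1, 1)])
        with pytest.raises(data_io.ParseError, match="duplicate"):
            data_io.read_dosage_matrix(p)

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("variant\teffect\tsA\n")
        with pytest.raises(data_io.ParseError, match="line 1"):
            data_io.read_dosage_matrix(p)

    def test_typed_variant_keeps_missing_r2(self, tmp_path):
        p = tmp_path / "d.tsv"
        _write_dosage_tsv(p, [("v1", "A", "G", "NA", 1, 1)])
        g = data_io.read_dosage_matrix(p)
        assert np.isnan(g.variants["imputation_r2"].iloc[0])

    def test_write_read_round_trip(self, tmp_path, bundle_dir):
        g = data_io.read_dosage_matrix(bundle_dir["dosages"])
        out = tmp_path / "again.tsv"
        data_io.write_dosage_matrix(g, out)
        g2 = data_io.read_dosage_matrix(out)
        np.testing.assert_array_equal(g.dosages, g2.dosages)
        assert g.sample_ids == g2.sample_ids


class TestReadDosageVcf:
    VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=R2,Number=1,Type=Float,Description="imputation quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="dosage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB
1\t100\trs1\tG\tA\t.\tPASS\tR2=0.85\tGT:DS\t0/1:0.9\t1/1:2.0
1\t200\trs2\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/1
"""

    def test_ds_field_and_hard_call_fallback(self, tmp_path):
        pytest.importorskip("cyvcf2")
        p = tmp_path / "t.vcf"
        p.write_text(self.VCF_TEXT)
        g = data_io.read_dosage_vcf(p)
        assert g.sample_ids == ["sA", "sB"]
        assert g.variant_ids == ["rs1", "rs2"]
        # alt allele is the counted (effect) allele
        assert list(g.variants["effect_allele"]) == ["A", "C"]
        np.testing.assert_allclose(g.dosages[:, 0], [0.9, 2.0])  # DS field
        np.testing.assert_allclose(g.dosages[:, 1], [0.0, 1.0])  # hard calls
        assert g.variants["imputation_r2"].iloc[0] == pytest.approx(0.85)
        assert np.isnan(g.variants["imputation_r2"].iloc[1])


class TestVariantQc:
    @pytest.mark.parametrize(
        "maf,r2,kept",
        [
            (0.02, 0.4, True),     # common variant, modest quality passes
            (0.007, 0.45, False),  # low-frequency tier needs r2 > 0.5
            (0.007, 0.6, True),
            (0.0003, 1.0, True),   # rare tier needs r2 > 0.99
            (0.003, 0.95, False),
        ],
    )
    def test_tiered_filter(self, maf, r2, kept):
        n = 5000
        dosage = np.zeros((n, 1))
        dosage[: int(round(2 * maf * n)) , 0] = 1.0  # achieves target MAF
        g = make_genotypes(dosage, r2=[r2])
        assert abs(g.maf[0] - maf) < 1e-9
        out = data_io.apply_variant_qc(g)
        assert (out.n_variants == 1) == kept

    def test_typed_variants_always_kept(self):
        g = make_genotypes(np.array([[0.0], [1.0], [2.0], [1.0]]), r2=[np.nan])
        assert data_io.apply_variant_qc(g).n_variants == 1

    def test_idempotent(self, bundle_dir):
        g = data_io.read_dosage_matrix(bundle_dir["dosages"])
        once = data_io.apply_variant_qc(g)
        twice = data_io.apply_variant_qc(once)
        assert once.variant_ids == twice.variant_ids

    @given(bump=st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=25, deadline=None)
    def test_raising_threshold_shrinks_kept_set(self, bump):
        rng = np.random.default_rng(99)
        dosages = rng.uniform(0, 2, size=(200, 30))
        r2 = rng.uniform(0, 1, size=30)
        g = make_genotypes(dosages, r2=list(r2))
        base = QcThresholds()
        stricter = QcThresholds(tiers=tuple(
            QcTier(t.maf_bound, min(1.0, t.min_r2 + bump)) for t in base.tiers))
        kept_base = set(data_io.apply_variant_qc(g, base).variant_ids)
        kept_strict = set(data_io.apply_variant_qc(g, stricter).variant_ids)
        assert kept_strict <= kept_base

    def test_tier_ordering_enforced(self):
        with pytest.raises(ValueError):
            QcThresholds(tiers=(QcTier(0.005, 0.5), QcTier(0.01, 0.3)))


class TestHweFilter:
    def test_extreme_disequilibrium_removed(self, small_cohort):
        g, cohort, _ = small_cohort
        n = g.n_samples
        # all-heterozygote column is wildly out of HWE; balanced column is fine
        balanced = np.repeat([0, 1, 2], [n // 4, n // 2, n - n // 4 - n // 2])
        np.random.default_rng(7).shuffle(balanced)  # decouple from case order
        dosages = np.column_stack([np.ones(n), balanced])
        gg = make_genotypes(dosages)
        gg.sample_ids = list(g.sample_ids)
        out = data_io.apply_hwe_filter(gg, cohort)
        assert out.variant_ids == ["v1"]


class TestReadPhenotypes:
    def test_bmi_unit_conversion_and_exclusion(self, tmp_path):
        p = tmp_path / "ph.tsv"
        pd.DataFrame({
            "sample_id": ["a", "b", "c"],
            "outcome": [1, 0, 1],
            "bmi": [27.5, 17.9, 30.0],
            "diabetes": [0, 1, 1],
            "sex": ["male", "female", "male"],
            "age": [60, 62, 58],
            "study": ["s1", "s1", "s2"],
            "pc1": [0.1, -0.2, 0.0],
        }).to_csv(p, sep="\t", index=False)
        c = data_io.read_phenotypes(p)
        assert c.data.loc[0, "bmi"] == pytest.approx(5.5)
        # underweight sample leaves BMI analyses but keeps its diabetes row
        assert np.isnan(c.data.loc[1, "bmi"])
        assert c.n_excluded_bmi == 1
        bmi_cohort = c.for_exposure("bmi")
        assert list(bmi_cohort.data["sample_id"]) == ["a", "c"]
        dia_cohort = c.for_exposure("diabetes")
        assert len(dia_cohort.data) == 3
        assert dia_cohort.data.loc[1, "diabetes"] == 1.0

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "ph.tsv"
        pd.DataFrame({"sample_id": ["a"], "outcome": [1]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(data_io.ParseError, match="bmi"):
            data_io.read_phenotypes(p)


class TestResultsRoundTrip:
    def _table(self, n, seed=0):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-8, 1, size=n)
        df = pd.DataFrame({
            "gene": [f"gene{i:03d}" for i in range(n)],
            "stratum": ["male"] * n,
            "n_snps": rng.integers(1, 90, n),
            "r2": rng.uniform(0.01, 0.3, n),
            "p_fixed": p,
            "p_random": rng.uniform(1e-8, 1, n),
            "p_adaptive": rng.uniform(1e-8, 1, n),
            "q_value": np.minimum(1.0, p * 2),
            "significant": p < 0.05,
        })
        return ScanTable(data=df)

    def test_single_row_layout(self, tmp_path):
        t = self._table(1)
        path = tmp_path / "r.tsv"
        data_io.write_results(t, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2
        assert lines[0].split("\t") == SCAN_COLUMNS

    def test_scientific_notation_preserved(self, tmp_path):
        t = self._table(1)
        t.data.loc[0, "p_adaptive"] = 3.15e-05
        path = tmp_path / "r.tsv"
        data_io.write_results(t, path)
        assert "3.15e-05" in path.read_text()
        back = data_io.read_results(path)
        assert back.data.loc[0, "p_adaptive"] == 3.15e-05

    def test_hundred_row_round_trip(self, tmp_path):
        t = self._table(100, seed=3)
        path = tmp_path / "r.tsv"
        data_io.write_results(t, path)
        back = data_io.read_results(path)
        for col in ("p_fixed", "p_random", "p_adaptive", "q_value", "r2"):
            np.testing.assert_allclose(back.data[col], t.data[col], rtol=1e-11)
        assert (back.data["significant"] == t.data["significant"]).all()

    def test_empty_table_refused(self, tmp_path):
        t = self._table(1)
        t.data = t.data.iloc[:0]
        with pytest.raises(ValueError):
            data_io.write_results(t, tmp_path / "r.tsv")
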