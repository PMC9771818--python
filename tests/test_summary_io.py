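import io

import numpy as np
import pandas as pd
import pytest

from transmeta import summary_io
from transmeta.summary_io import (
    CHI2_MEDIAN,
    ConfigurationError,
    InputError,
    apply_meta_filters,
    apply_study_qc,
    genomic_control_correct,
    harmonize_variants,
    read_cohort_summary,
    write_cohort_summary,
)
from conftest import make_cohort, make_record


HEADER = "CHR\tPOS\tREF\tALT\tAF\tBETA\tSE\tZ\tRSQ\tN\n"


def _tsv(tmp_path, rows, header=HEADER):
    p = tmp_path / "study.tsv"
    p.write_text(header + "".join(rows))
    return p


class TestReadCohortSummary:
    def test_well_formed_table_parses_all_rows(self, tmp_path):
        rows = [f"1\t{100+i}\tA\tG\t0.3\t0.1\t0.05\t2.0\t0.9\t5000\n" for i in range(3)]
        c = read_cohort_summary(_tsv(tmp_path, rows), study_id="s1")
        assert len(c.records) == 3
        assert c.n == 5000
        assert c.records[0].key == ("1", 100, "A", "G")

    def test_unparseable_numeric_row_dropped_and_counted(self, tmp_path):
        rows = [
            "1\t100\tA\tG\t0.3\t0.1\t0.05\t2.0\t0.9\t5000\n",
            "1\t101\tA\tG\tNA\t0.1\t0.05\t2.0\t0.9\t5000\n",
            "1\t102\tA\tG\t0.4\t0.1\t0.05\t2.0\t0.9\t5000\n",
        ]
        c = read_cohort_summary(_tsv(tmp_path, rows), study_id="s1")
        assert len(c.records) == 2
        assert c.n_dropped_rows == 1

    def test_round_trip_preserves_all_fields_exactly(self, tmp_path, rng):
        records = [
            make_record(pos=100 + i, freq=rng.uniform(0.01, 0.99), beta=rng.normal(0, 0.1),
                        se=rng.uniform(0.01, 0.2), rsq=rng.uniform(0.3, 1))
            for i in range(20)
        ]
        original = make_cohort(records=records)
        path = tmp_path / "rt.tsv"
        write_cohort_summary(original, path)
        back = read_cohort_summary(path, study_id=original.study_id, n=original.n,
                                   lambda_gc=original.lambda_gc)
        assert len(back.records) == len(original.records)
        for a, b in zip(original.records, back.records):
            assert a == b

    def test_missing_required_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("CHR\tPOS\tREF\tALT\n1\t100\tA\tG\n")
        with pytest.raises(ConfigurationError):
            read_cohort_summary(p, study_id="s1", n=1000)

    def test_chr_prefix_stripped_and_z_reconstructed(self, tmp_path):
        p = tmp_path / "z.tsv"
        p.write_text("CHR\tPOS\tREF\tALT\tAF\tBETA\tSE\tRSQ\tN\n"
                     "chr2\t100\tA\tG\t0.3\t0.1\t0.05\t0.9\t5000\n")
        c = read_cohort_summary(p, study_id="s1")
        assert c.records[0].chrom == "2"
        assert c.records[0].z == pytest.approx(2.0)

    def test_beta_se_reconstructed_from_z(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("CHR\tPOS\tREF\tALT\tAF\tZ\tRSQ\tN\n"
                     "1\t100\tA\tG\t0.25\t3.0\t0.8\t10000\n")
        c = read_cohort_summary(p, study_id="s1")
        r = c.records[0]
        denom = np.sqrt(2 * 10000 * 0.25 * 0.75 * 0.8)
        assert r.beta == pytest.approx(3.0 / denom)
        assert r.se == pytest.approx(1.0 / denom)


class TestStudyQC:
    def test_small_study_dropped(self):
        kept, log = apply_study_qc([make_cohort(n=90)])
        assert kept == []
        assert "N<100" in log["reason"].iloc[0]

    def test_lambda_rule_exempts_large_studies(self):
        small = make_cohort(study_id="small", n=5_000, lam=1.15)
        large = make_cohort(study_id="large", n=50_000, lam=1.15)
        kept, log = apply_study_qc([small, large])
        assert [c.study_id for c in kept] == ["large"]
        assert log["study_id"].tolist() == ["small"]

    def test_low_imputation_variant_removed(self):
        records = [make_record(pos=1, rsq=0.29), make_record(pos=2, rsq=0.31)]
        kept, log = apply_study_qc([make_cohort(records=records)])
        assert [r.pos for r in kept[0].records] == [2]
        assert (log["reason"] == "rsq<0.3").sum() == 1

    def test_qc_is_idempotent(self):
        cohorts = [
            make_cohort(study_id="a", n=5_000, lam=1.15),
            make_cohort(study_id="b", n=20_000, lam=1.0,
                        records=[make_record(pos=1, rsq=0.1), make_record(pos=2)]),
        ]
        once, log1 = apply_study_qc(cohorts)
        twice, log2 = apply_study_qc(once)
        assert [c.study_id for c in twice] == [c.study_id for c in once]
        assert all(len(a.records) == len(b.records) for a, b in zip(once, twice))
        assert log2.empty
        # conservation: kept + dropped = input, per stage
        assert len(once) + log1["variant"].eq("").sum() == len(cohorts)


class TestHarmonize:
    def test_allele_swap_symmetry(self):
        a = make_cohort(study_id="A", records=[make_record(freq=0.3, beta=0.1)])
        b_rec = summary_io.VariantRecord("1", 100, "G", "A", 0.7, -0.1, 0.05, -2.0, 0.95)
        b = make_cohort(study_id="B", records=[b_rec])
        merged = harmonize_variants([a, b])
        assert merged.n_variants == 1
        np.testing.assert_allclose(merged.beta[0], [0.1, 0.1])
        np.testing.assert_allclose(merged.freq[0], [0.3, 0.3])

    def test_mismatched_allele_pair_dropped(self):
        a = make_cohort(study_id="A", records=[make_record(ref="A", alt="G")])
        b = make_cohort(study_id="B", records=[make_record(ref="A", alt="T", freq=0.3)])
        merged = harmonize_variants([a, b])
        # A/T in study B (palindromic vs A/G reference pair) is a mismatch
        assert merged.n_variants == 1
        assert np.isnan(merged.beta[0, 1])

    def test_duplicate_variant_key_is_input_error(self):
        recs = [make_record(pos=100), make_record(pos=100)]
        with pytest.raises(InputError):
            harmonize_variants([make_cohort(records=recs)])

    def test_matches_brute_force_join(self, random_cohort_pair):
        merged = harmonize_variants(random_cohort_pair)
        # brute-force: align study B to study A's orientation per position
        a, b = random_cohort_pair
        by_pos_a = {r.pos: r for r in a.records}
        by_pos_b = {r.pos: r for r in b.records}
        assert merged.n_variants == 50
        for j, pos in enumerate(merged.variants["pos"]):
            ra, rb = by_pos_a[pos], by_pos_b[pos]
            assert merged.beta[j, 0] == pytest.approx(ra.beta)
            if (rb.ref, rb.alt) == (ra.ref, ra.alt):
                exp_beta, exp_freq = rb.beta, rb.freq
            else:
                exp_beta, exp_freq = -rb.beta, 1 - rb.freq
            assert merged.beta[j, 1] == pytest.approx(exp_beta)
            assert merged.freq[j, 1] == pytest.approx(exp_freq)

    def test_split_recovers_per_study_values_up_to_orientation(self, random_cohort_pair):
        merged = harmonize_variants(random_cohort_pair)
        b_orig = {r.pos: r for r in random_cohort_pair[1].records}
        for j, pos in enumerate(merged.variants["pos"]):
            r = b_orig[pos]
            same = np.isclose(merged.beta[j, 1], r.beta) and np.isclose(merged.freq[j, 1], r.freq)
            flipped = np.isclose(merged.beta[j, 1], -r.beta) and np.isclose(
                merged.freq[j, 1], 1 - r.freq
            )
            assert same or flipped


class TestGenomicControl:
    def _merged_with_maf(self, mafs):
        cohorts = [make_cohort(records=[make_record(pos=i + 1, freq=m) for i, m in enumerate(mafs)])]
        return harmonize_variants(cohorts)

    def test_unit_lambda_leaves_statistics_unchanged(self):
        merged = self._merged_with_maf([0.005] * 5)
        chisq = np.full(5, CHI2_MEDIAN)
        corrected, lam = genomic_control_correct(merged, chisq)
        assert lam == pytest.approx(1.0)
        np.testing.assert_allclose(corrected, chisq)

    def test_deflation_never_applied(self):
        merged = self._merged_with_maf([0.005] * 5)
        chisq = np.full(5, 0.8 * CHI2_MEDIAN)
        corrected, lam = genomic_control_correct(merged, chisq)
        assert lam == pytest.approx(0.8)
        np.testing.assert_allclose(corrected, chisq)

    def test_double_median_halves_rare_statistics_only(self):
        merged = self._merged_with_maf([0.005, 0.005, 0.005, 0.3, 0.3])
        chisq = np.array([2 * CHI2_MEDIAN] * 3 + [5.0, 6.0])
        corrected, lam = genomic_control_correct(merged, chisq)
        assert lam == pytest.approx(2.0)
        np.testing.assert_allclose(corrected[:3], CHI2_MEDIAN)
        np.testing.assert_allclose(corrected[3:], [5.0, 6.0])

    def test_no_rare_variants_warns_and_returns_input(self):
        merged = self._merged_with_maf([0.3, 0.4])
        chisq = np.array([1.0, 2.0])
        corrected, lam = genomic_control_correct(merged, chisq)
        assert lam == 1.0
        np.testing.assert_allclose(corrected, chisq)


class TestMetaFilters:
    def _merged(self):
        cohorts = []
        for sid in ("A", "B", "C", "D"):
            records = [make_record(pos=1, freq=0.3)]
            if sid in ("A", "B"):
                records.append(make_record(pos=2, freq=0.3))  # only 2 studies
            if sid != "D":
                records.append(make_record(pos=3, freq=0.005))  # low MAF
            records.append(make_record(pos=4, freq=0.3, rsq=0.31))
            cohorts.append(make_cohort(study_id=sid, records=records))
        return harmonize_variants(cohorts)

    def test_requires_three_studies(self):
        out = apply_meta_filters(self._merged(), "multi")
        assert 2 not in out.variants["pos"].tolist()

    def test_maf_floor_depends_on_analysis_kind(self):
        merged = self._merged()
        eur = apply_meta_filters(merged, "EUR")
        eas = apply_meta_filters(merged, "EAS")
        assert 3 in eur.variants["pos"].tolist()
        assert 3 not in eas.variants["pos"].tolist()

    def test_effective_n_ratio(self):
        merged = self._merged()
        # shrink one variant's effective N below 10% of the maximum
        j = merged.variants.index[merged.variants["pos"] == 4][0]
        merged.variants.loc[j, "effective_n"] = 0.05 * merged.variants["effective_n"].max()
        out = apply_meta_filters(merged, "multi")
        assert 4 not in out.variants["pos"].tolist()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_meta_filters(self._merged(), "SAS")

    def test_filters_idempotent(self):
        once = apply_meta_filters(self._merged(), "multi")
        twice = apply_meta_filters(once, "multi")
        pd.testing.assert_frame_equal(once.variants, twice.variants)
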