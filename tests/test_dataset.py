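"""Genotype I/O, quality control and stratified splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sraselect import (
    MISSING,
    GenotypeDataset,
    QcConfig,
    apply_qc,
    read_vcf,
    split_train_test,
    write_vcf,
)
from conftest import make_dataset


class TestVcfRoundTrip:
    def test_write_then_read_identity(self, small_sim, tmp_path):
        ds, _ = small_sim
        vcf = tmp_path / "panel.vcf"
        labels = tmp_path / "labels.tsv"
        write_vcf(ds, str(vcf), labels_path=str(labels))
        back = read_vcf(str(vcf), labels_path=str(labels))
        np.testing.assert_array_equal(back.dosages, ds.dosages)
        np.testing.assert_array_equal(back.pos, ds.pos)
        np.testing.assert_array_equal(back.snp_ids, ds.snp_ids)
        np.testing.assert_array_equal(back.labels, ds.labels)

    def test_gt_codes_and_missing(self, tmp_path):
        # 0/0 -> 0, 0|1 -> 1 (phased accepted), 1/1 -> 2, ./. -> sentinel
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\td\n"
            "1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0|1\t1/1\t./.\n"
            "1\t200\tsnp2\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\t1/1\n"
        )
        ds = read_vcf(str(vcf))
        np.testing.assert_array_equal(ds.dosages[:, 0], [0, 1, 2, MISSING])
        assert ds.multiallelic.tolist() == [False, True]

    def test_empty_body_keeps_samples(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        )
        ds = read_vcf(str(vcf))
        assert ds.n_snps == 0 and ds.n_samples == 3

    def test_missing_sample_in_labels_raises(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "1\t100\ts\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\n"
        )
        labels = tmp_path / "labels.tsv"
        labels.write_text("a\tholstein\n")
        with pytest.raises(ValueError, match="b"):
            read_vcf(str(vcf), labels_path=str(labels))


class TestQc:
    def _toy(self):
        # 10 individuals, 5 SNPs: one multiallelic, one MAF 0.02 analogue
        # (here 1 alt allele of 20 -> MAF 0.025), one with call rate 0.9,
        # and two clean ones.
        n = 10
        dos = np.zeros((n, 5), dtype=np.int8)
        dos[:, 0] = [0, 1, 2, 0, 1, 2, 0, 1, 2, 1]  # clean, multiallelic flag
        dos[:, 1] = [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]  # MAF 0.05 exactly
        dos[0, 2] = MISSING                          # call rate 0.9
        dos[:, 2][1:] = [0, 1, 2, 0, 1, 2, 0, 1, 2]
        dos[:, 3] = [0, 1, 2, 0, 1, 2, 0, 1, 2, 1]  # clean
        dos[:, 4] = [2, 1, 0, 2, 1, 0, 2, 1, 0, 1]  # clean
        multi = np.array([True, False, False, False, False])
        return make_dataset(dos, multiallelic=multi)

    def test_filter_by_filter_hand_count(self):
        ds = self._toy()
        out, report = apply_qc(
            ds, QcConfig(call_rate_min=0.95, maf_min=0.06), return_report=True
        )
        assert report.n_multiallelic == 1
        assert report.n_low_call_rate == 1
        assert report.n_low_maf == 1
        assert out.n_snps == 2
        assert out.snp_ids.tolist() == ["s3", "s4"]

    def test_maf_exactly_at_threshold_is_retained(self):
        # removal is strict: MAF exactly 0.05 stays
        ds = self._toy()
        out = apply_qc(ds, QcConfig(call_rate_min=0.9, maf_min=0.05))
        assert "s1" in out.snp_ids

    def test_clean_dataset_unchanged(self, small_sim):
        ds, _ = small_sim
        clean = apply_qc(ds)
        again, report = apply_qc(clean, return_report=True)
        np.testing.assert_array_equal(again.dosages, clean.dosages)
        assert report.n_multiallelic == report.n_low_call_rate == report.n_low_maf == 0

    def test_mode_imputation(self):
        dos = np.tile([2, 2, 2, 1, 0, 1, 2, 2, 1, 0], (2, 1)).T.astype(np.int8)
        dos[0, 0] = MISSING
        ds = make_dataset(dos)
        out = apply_qc(ds, QcConfig(call_rate_min=0.9, maf_min=0.01))
        assert out.dosages[0, 0] == 2  # modal dosage
        assert not out.has_missing()

    def test_all_removed_raises(self):
        ds = make_dataset(np.zeros((4, 2), dtype=np.int8))  # monomorphic
        with pytest.raises(ValueError, match="empty dataset after QC"):
            apply_qc(ds)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_qc_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        dos = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
        dos[rng.random(dos.shape) < 0.1] = MISSING
        ds = make_dataset(dos)
        try:
            once = apply_qc(ds)
        except ValueError:
            return  # everything filtered: nothing to be idempotent about
        twice = apply_qc(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)
        np.testing.assert_array_equal(once.snp_ids, twice.snp_ids)


class TestSplit:
    def _labelled(self, sizes):
        n = sum(sizes)
        labels = np.concatenate([np.full(m, f"c{k}") for k, m in enumerate(sizes)])
        dos = np.random.default_rng(0).integers(0, 3, size=(n, 4)).astype(np.int8)
        return make_dataset(dos, labels=labels)

    def test_balanced_per_class_counts(self):
        ds = self._labelled([20] * 5)
        train, test = split_train_test(ds, 0.2, seed=3)
        assert test.n_samples == 20
        for c in np.unique(ds.labels):
            assert (test.labels == c).sum() == 4

    def test_zero_fraction_all_train(self):
        ds = self._labelled([5, 5])
        train, test = split_train_test(ds, 0.0, seed=0)
        assert train.n_samples == 10 and test.n_samples == 0

    def test_partition_property(self):
        ds = self._labelled([7, 9, 11])
        for seed in (0, 1, 2):
            train, test = split_train_test(ds, 0.3, seed=seed)
            ids = np.concatenate([train.sample_ids, test.sample_ids])
            assert sorted(ids) == sorted(ds.sample_ids)
            assert not set(train.sample_ids) & set(test.sample_ids)

    def test_paper_shaped_split(self):
        # 1825 individuals over 5 classes; 20% test -> 365/1460 with the
        # per-class proportions preserved within one individual
        sizes = [600, 400, 350, 275, 200]
        ds = self._labelled(sizes)
        train, test = split_train_test(ds, 0.2, seed=9)
        assert (train.n_samples, test.n_samples) == (1460, 365)
        for c in np.unique(ds.labels):
            total = (ds.labels == c).sum()
            got = (test.labels == c).sum()
            assert abs(got - 0.2 * total) <= 1

    def test_deterministic_given_seed(self):
        ds = self._labelled([10, 10])
        a = split_train_test(ds, 0.3, seed=5)[1].sample_ids
        b = split_train_test(ds, 0.3, seed=5)[1].sample_ids
        np.testing.assert_array_equal(a, b)

    def test_singleton_class_raises(self):
        ds = self._labelled([5, 1])
        with pytest.raises(ValueError, match="c1"):
            split_train_test(ds, 0.2, seed=0)


def test_dosage_matrix_text_export(small_sim, tmp_path):
    from sraselect.dataset import write_dosage_matrix

    ds, _ = small_sim
    path = tmp_path / "dosages.txt"
    write_dosage_matrix(ds, str(path))
    lines = path.read_text().splitlines()
    assert lines[0].split()[1:] == list(map(str, ds.snp_ids))
    row0 = lines[1].split()
    assert row0[0] == str(ds.sample_ids[0])
    np.testing.assert_array_equal(np.array(row0[1:], dtype=int), ds.dosages[0])
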