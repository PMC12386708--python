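"""Genotype containers, VCF I/O, quality control and train/test splitting.

The universal in-memory object is :class:`GenotypeDataset`: an N x P matrix of
ALT-allele dosages (0/1/2, with ``MISSING`` = -1 allowed before QC) together
with SNP coordinates, sample identifiers and optional class labels (breeds).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing genotype (pre-QC only)

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "QcConfig",
    "QcReport",
    "apply_qc",
    "split_train_test",
    "read_vcf",
    "write_vcf",
    "read_labels",
]


@dataclass
class GenotypeDataset:
    """Individuals x SNPs dosage matrix with coordinates and labels.

    Parameters
    ----------
    dosages : ndarray of shape (N, P)
        ALT-allele counts in {0, 1, 2}; ``MISSING`` (-1) marks a missing
        genotype and is only legal before :func:`apply_qc`.
    snp_ids, chrom, pos : arrays of length P
        SNP identifiers, chromosome labels, and 1-based base-pair positions.
    sample_ids : array of length N
    labels : array of length N, optional
        Class labels (e.g. breed names); required for supervised stages.
    multiallelic : bool array of length P, optional
        Flags records whose ALT field listed more than one allele; set by the
        VCF reader, consumed by QC.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray | None = None
    multiallelic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
        if self.multiallelic is None:
            self.multiallelic = np.zeros(self.n_snps, dtype=bool)
        else:
            self.multiallelic = np.asarray(self.multiallelic, dtype=bool)
        n, p = self.dosages.shape
        for name, arr, expect in (
            ("snp_ids", self.snp_ids, p),
            ("chrom", self.chrom, p),
            ("pos", self.pos, p),
            ("multiallelic", self.multiallelic, p),
            ("sample_ids", self.sample_ids, n),
        ):
            if len(arr) != expect:
                raise ValueError(f"{name} has length {len(arr)}, expected {expect}")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError(f"labels has length {len(self.labels)}, expected {n}")
        bad = (self.dosages > 2) | (self.dosages < MISSING)
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or MISSING (-1)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def classes(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return np.unique(self.labels)

    def has_missing(self) -> bool:
        return bool((self.dosages == MISSING).any())

    def subset_snps(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return dataclasses.replace(
            self,
            dosages=self.dosages[:, index],
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            multiallelic=self.multiallelic[index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return dataclasses.replace(
            self,
            dosages=self.dosages[index],
            sample_ids=self.sample_ids[index],
            labels=None if self.labels is None else self.labels[index],
        )

    def positions_sorted(self) -> bool:
        """True when pos is strictly increasing within every chromosome."""
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                return False
        return True


@dataclass
class QcConfig:
    """SNP quality-control thresholds.

    A SNP is *removed* when its call rate is strictly below ``call_rate_min``,
    its minor allele frequency is strictly below ``maf_min``, or (with
    ``biallelic_only``) its record was multiallelic. Equality retains.
    """

    call_rate_min: float = 0.95
    maf_min: float = 0.05
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must be in [0, 1]")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")


@dataclass
class QcReport:
    n_multiallelic: int = 0
    n_low_call_rate: int = 0
    n_low_maf: int = 0
    n_retained: int = 0
    n_imputed_genotypes: int = 0


def _maf(dosages: np.ndarray) -> np.ndarray:
    """MAF per SNP from non-missing dosages; monomorphic -> 0."""
    d = np.ma.masked_equal(dosages, MISSING)
    freq = d.mean(axis=0) / 2.0
    freq = np.ma.filled(freq, 0.0)
    return np.minimum(freq, 1.0 - freq)


def apply_qc(
    ds: GenotypeDataset,
    cfg: QcConfig | None = None,
    return_report: bool = False,
    impute: bool = True,
):
    """Filter SNPs on biallelicity, call rate and MAF; impute leftovers.

    Each removed SNP is counted against the first filter that rejects it, in
    the order multiallelic -> call rate -> MAF. Missing genotypes surviving
    the call-rate filter are imputed to the per-SNP modal dosage (ties break
    to the smaller dosage); ``impute=False`` raises instead if any remain.
    """
    cfg = cfg or QcConfig()
    keep = np.ones(ds.n_snps, dtype=bool)
    report = QcReport()

    if cfg.biallelic_only:
        multi = ds.multiallelic & keep
        report.n_multiallelic = int(multi.sum())
        keep &= ~multi

    call_rate = (ds.dosages != MISSING).mean(axis=0)
    low_cr = (call_rate < cfg.call_rate_min) & keep
    report.n_low_call_rate = int(low_cr.sum())
    keep &= ~low_cr

    low_maf = (_maf(ds.dosages) < cfg.maf_min) & keep
    report.n_low_maf = int(low_maf.sum())
    keep &= ~low_maf

    if not keep.any():
        raise ValueError("empty dataset after QC: all SNPs removed")

    out = ds.subset_snps(np.flatnonzero(keep))
    if out.has_missing():
        if not impute:
            raise ValueError("missing genotypes remain after QC and impute=False")
        dos = out.dosages.copy()
        miss = dos == MISSING
        cols = np.flatnonzero(miss.any(axis=0))
        for j in cols:
            col = dos[:, j]
            obs = col[col != MISSING]
            counts = np.bincount(obs, minlength=3)
            mode = int(np.argmax(counts))  # argmax ties -> smallest dosage
            col[col == MISSING] = mode
        report.n_imputed_genotypes = int(miss.sum())
        out = dataclasses.replace(out, dosages=dos)
    report.n_retained = out.n_snps
    return (out, report) if return_report else out


def split_train_test(
    ds: GenotypeDataset, test_fraction: float, seed: int
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Class-stratified split into (train, test).

    Per class, ``round(test_fraction * class_size)`` individuals go to test,
    so test proportions are within one individual of the target. The split is
    a disjoint, exhaustive partition and deterministic given ``seed``.
    """
    if ds.labels is None:
        raise ValueError("split requires labels")
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for cls in ds.classes:
        members = np.flatnonzero(ds.labels == cls)
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_test = int(round(test_fraction * len(members)))
        chosen = rng.permutation(members)[:n_test]
        test_idx.append(chosen)
    test_mask = np.zeros(ds.n_samples, dtype=bool)
    if test_idx:
        test_mask[np.concatenate(test_idx)] = True
    return ds.subset_samples(np.flatnonzero(~test_mask)), ds.subset_samples(
        np.flatnonzero(test_mask)
    )


def read_labels(labels_path: str) -> pd.Series:
    """Two-column TSV (sample_id, class) -> Series indexed by sample id."""
    df = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample_id", "label"], dtype=str
    )
    # tolerate a header row
    if df.iloc[0, 0] in ("sample_id", "sample", "id"):
        df = df.iloc[1:]
    return df.set_index("sample_id")["label"]


def read_vcf(path: str, labels_path: str | None = None) -> GenotypeDataset:
    """Read biallelic genotypes (GT field) from a VCF 4.x file.

    Phased and unphased genotypes are both accepted; a missing GT becomes the
    ``MISSING`` sentinel. Records with a comma in ALT are kept but flagged
    multiallelic (QC removes them). When ``labels_path`` is given, every VCF
    sample must appear in the table; extra table rows are ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = np.asarray(vcf.samples)
    dosages_rows: list[np.ndarray] = []
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    multi: list[bool] = []
    for rec in vcf:
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        gt[gt == 3] = MISSING
        dosages_rows.append(gt)
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        multi.append(len(rec.ALT) > 1)
    vcf.close()
    dosages = (
        np.vstack(dosages_rows).T
        if dosages_rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    labels = None
    if labels_path is not None:
        table = read_labels(labels_path)
        missing = [s for s in samples if s not in table.index]
        if missing:
            raise ValueError(f"samples absent from labels table: {missing}")
        labels = table.loc[samples].to_numpy()
    return GenotypeDataset(
        dosages=dosages,
        snp_ids=np.asarray(snp_ids),
        chrom=np.asarray(chroms),
        pos=np.asarray(positions),
        sample_ids=samples,
        labels=labels,
        multiallelic=np.asarray(multi, dtype=bool),
    )


def write_dosage_matrix(ds: GenotypeDataset, path: str) -> None:
    """Whitespace-delimited dosage export: header of SNP ids, one row per sample."""
    with open(path, "w") as fh:
        fh.write("sample_id " + " ".join(map(str, ds.snp_ids)) + "\n")
        for i in range(ds.n_samples):
            fh.write(str(ds.sample_ids[i]) + " "
                     + " ".join(map(str, ds.dosages[i])) + "\n")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ds: GenotypeDataset, path: str, labels_path: str | None = None) -> None:
    """Write the dataset as a minimal uncompressed VCF 4.2 file.

    REF/ALT are placeholder alleles (A/G); the paper's pipeline only consumes
    the GT dosage coding, which round-trips exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms_seen: list[str] = []
        for c in ds.chrom:
            if c not in chroms_seen:
                chroms_seen.append(c)
        for c in chroms_seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, ds.sample_ids))
            + "\n"
        )
        for j in range(ds.n_snps):
            gts = "\t".join(_GT_CODE[int(d)] for d in ds.dosages[:, j])
            fh.write(
                f"{ds.chrom[j]}\t{ds.pos[j]}\t{ds.snp_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )
    if labels_path is not None:
        if ds.labels is None:
            raise ValueError("dataset has no labels to write")
        pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.labels}).to_csv(
            labels_path, sep="\t", header=False, index=False
        )
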