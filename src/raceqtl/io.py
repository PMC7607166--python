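"""Readers and writers for every file the pipeline touches.

TSV dialect: tab-separated, UTF-8, ``.`` for missing, no quoting.  Floats
are written with six significant digits.  The VCF writer emits the minimal
VCF 4.2 subset the reader consumes (CHROM, 1-based POS, ID, REF, ALT, GT);
reading goes through cyvcf2.  Internal coordinates keep the VCF 1-based
convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from raceqtl.errors import FormatError
from raceqtl.sim import CountMatrix, GenotypeMatrix

_FLOAT_FMT = "%.6g"


@dataclass
class EqtlInput:
    """One SNP-gene association row from an eQTL table (e.g. GTEx export)."""

    snp_id: str
    gene_id: str
    ref: str
    alt: str
    slope: float
    p: float


@dataclass
class Dataset:
    """A loaded analysis input bundle with consistent sample ids."""

    counts: CountMatrix
    clinical: pd.DataFrame
    genotypes: GenotypeMatrix | None = None
    eqtls: list[EqtlInput] | None = None
    freqs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        count_samples = set(self.counts.sample_ids)
        clin_samples = set(self.clinical["sample_id"])
        if not clin_samples <= count_samples:
            raise FormatError("clinical table contains samples absent from counts")
        if self.genotypes is not None:
            geno_samples = set(self.genotypes.sample_ids)
            if not count_samples <= geno_samples:
                raise FormatError("count matrix contains samples absent from genotypes")


# ---------------------------------------------------------------------------
# counts


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene-by-sample count TSV (gene ids in column 1, sample header).

    Rejects duplicate gene or sample ids, ragged rows, and negative or
    non-integer cells.  Sample metadata (race, cancer type) lives in the
    clinical table, so the returned metadata frame is empty.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse count matrix {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise FormatError("duplicate gene ids in count matrix")
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample ids in count matrix")
    if df.isna().any().any():
        raise FormatError("ragged or missing cells in count matrix")
    try:
        mat = df.astype("int64")
    except ValueError as exc:
        raise FormatError(f"non-integer count cell: {exc}") from exc
    if (mat.to_numpy() < 0).any():
        raise FormatError("negative counts are not allowed")
    mat.index.name = "gene_id"
    meta = pd.DataFrame(index=pd.Index(mat.columns, name="sample_id"))
    return CountMatrix(counts=mat, sample_meta=meta)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# clinical

_CLINICAL_COLS = ["sample_id", "race", "cancer_type", "time", "event"]


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "race": str, "cancer_type": str})
    missing = [c for c in _CLINICAL_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in clinical table")
    if (df["time"] < 0).any():
        raise FormatError("negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise FormatError("event must be 0 or 1")
    return df[_CLINICAL_COLS]


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical[_CLINICAL_COLS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# genotypes (VCF 4.2 minimal subset)


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as unphased biallelic GT calls; missing as ``./.``."""
    samples = gm.sample_ids
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(gm.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for snp in gm.snp_ids:
            row = gm.dosages.loc[snp]
            gts = "\t".join(
                "./." if pd.isna(row[s]) else gt_map[int(row[s])] for s in samples
            )
            fh.write(
                f"{gm.chrom[snp]}\t{gm.pos[snp]}\t{snp}\t{gm.ref[snp]}\t{gm.alt[snp]}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a minimal VCF into an alt-allele dosage matrix.

    Dosage is the count of alt alleles in GT; ``./.`` is recorded as missing
    (pandas NA) and excluded per-SNP downstream.  Multi-allelic records are
    rejected: the consistency calculus is biallelic, and a clear error beats
    silent mishandling.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, refs, alts, chroms, poss, rows = [], [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {v.CHROM}:{v.POS} ({v.ID}); split or drop it"
            )
        snp_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        dosages = []
        for g in v.genotypes:
            alleles = g[:-1]  # last element is the phasing flag
            if any(a < 0 for a in alleles):
                dosages.append(pd.NA)
            else:
                dosages.append(int(sum(1 for a in alleles if a == 1)))
        ids.append(snp_id)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        chroms.append(v.CHROM)
        poss.append(v.POS)
        rows.append(dosages)
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate SNP ids in VCF")
    idx = pd.Index(ids, name="snp_id")
    return GenotypeMatrix(
        dosages=pd.DataFrame(rows, index=idx, columns=samples, dtype="object").astype("Int64"),
        ref=pd.Series(refs, index=idx),
        alt=pd.Series(alts, index=idx),
        chrom=pd.Series(chroms, index=idx),
        pos=pd.Series(poss, index=idx),
        sample_population=pd.Series(pd.NA, index=samples),
    )


# ---------------------------------------------------------------------------
# eQTL table

_VALID_ALLELES = {"A", "C", "G", "T"}


def read_eqtl_table(path: str | Path) -> list[EqtlInput]:
    """Read a TSV of SNP-gene associations (snp_id, gene_id, ref, alt, slope, p).

    The slope is the change in expression per alt-allele copy, so alt is the
    candidate expression-increasing allele when slope > 0.  A zero slope
    parses; orientation flags it undetermined downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    required = ["snp_id", "gene_id", "ref", "alt", "slope", "p"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"eQTL table missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        if row.ref not in _VALID_ALLELES or row.alt not in _VALID_ALLELES:
            raise FormatError(f"invalid alleles {row.ref}/{row.alt} for {row.snp_id}")
        if not 0.0 < row.p <= 1.0:
            raise FormatError(f"p-value {row.p} outside (0, 1] for {row.snp_id}")
        records.append(
            EqtlInput(
                snp_id=row.snp_id,
                gene_id=row.gene_id,
                ref=row.ref,
                alt=row.alt,
                slope=float(row.slope),
                p=float(row.p),
            )
        )
    return records


def write_eqtl_table(records: list[EqtlInput], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.snp_id, r.gene_id, r.ref, r.alt, r.slope, r.p)
            for r in records
        ],
        columns=["snp_id", "gene_id", "ref", "alt", "slope", "p"],
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# allele-frequency table


def read_freq_table(path: str | Path) -> pd.DataFrame:
    """Read (snp_id, population, alt_freq) rows; alt-allele frequency stored.

    Effect-allele frequencies are always derived at use time from the eQTL
    orientation, never stored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "population": str})
    required = ["snp_id", "population", "alt_freq"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"frequency table missing columns {missing}")
    if df.duplicated(["snp_id", "population"]).any():
        raise FormatError("duplicate (snp, population) rows in frequency table")
    if ((df["alt_freq"] < 0) | (df["alt_freq"] > 1)).any():
        raise FormatError("alt_freq outside [0, 1]")
    pops_per_snp = df.groupby("snp_id")["population"].nunique()
    if pops_per_snp.nunique() > 1:
        raise FormatError("every SNP must be present for all populations")
    return df[required]


def write_freq_table(freqs: pd.DataFrame, path: str | Path) -> None:
    freqs.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# truth table (planted drivers, for recovery scoring)


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
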