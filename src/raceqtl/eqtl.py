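"""Per-SNP-gene association on additive genotype dosage and effect-allele
orientation.

The eQTL fit is ordinary least squares of normalized expression on alt-allele
dosage (0/1/2) with a two-sided t-test on the slope — the additive coding
GTEx uses.  The expression-increasing allele is alt when the slope is
positive and ref when negative; the consistency stage is stated in terms of
that allele's per-population frequency, which is derived here from stored
alt-allele frequencies at use time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from raceqtl.errors import ConfigError
from raceqtl.de import bh_adjust
from raceqtl.sim import GenotypeMatrix

DEFAULT_EQTL_ALPHA = 0.05


@dataclass
class EqtlRecord:
    """One fitted SNP-gene association.

    slope is the change in log2 expression per alt-allele copy;
    increasing_allele is 'alt' iff slope > 0, 'ref' iff slope < 0,
    'undetermined' for a zero slope.  Monomorphic SNPs are flagged
    untestable and excluded downstream.
    """

    snp_id: str
    gene_id: str
    ref: str
    alt: str
    slope: float
    p: float
    padj: float | None = None
    untestable: bool = False

    @property
    def increasing_allele(self) -> str:
        if self.untestable or self.slope == 0.0:
            return "undetermined"
        return "alt" if self.slope > 0 else "ref"


def fit_eqtl(
    dosages, expression, snp_id: str = "snp", gene_id: str = "gene",
    ref: str = "A", alt: str = "G",
) -> EqtlRecord:
    """OLS of expression on dosage; pairs with missing dosage are dropped."""
    d = pd.array(dosages)
    x = np.asarray(expression, dtype=float)
    mask = ~pd.isna(d)
    dv = np.asarray(d[mask], dtype=float)
    xv = x[np.asarray(mask)]
    if len(np.unique(dv)) < 2:
        return EqtlRecord(snp_id, gene_id, ref, alt, 0.0, 1.0, untestable=True)
    fit = stats.linregress(dv, xv)
    p = fit.pvalue
    if np.isnan(p):  # zero residual variance: perfect fit
        p = 0.0
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return EqtlRecord(snp_id, gene_id, ref, alt, float(fit.slope), p)


def eqtl_scan(
    genotypes: GenotypeMatrix,
    norm_matrix: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> list[EqtlRecord]:
    """Fit every requested (snp, gene) pair and BH-adjust across testable fits."""
    samples = [s for s in norm_matrix.columns if s in genotypes.dosages.columns]
    records = []
    for snp, gene in pairs:
        if snp not in genotypes.dosages.index:
            raise ConfigError(f"SNP {snp} absent from genotypes")
        if gene not in norm_matrix.index:
            raise ConfigError(f"gene {gene} absent from expression")
        rec = fit_eqtl(
            genotypes.dosages.loc[snp, samples],
            norm_matrix.loc[gene, samples],
            snp_id=snp,
            gene_id=gene,
            ref=str(genotypes.ref[snp]),
            alt=str(genotypes.alt[snp]),
        )
        records.append(rec)
    testable = [r for r in records if not r.untestable]
    if testable:
        padj = bh_adjust([r.p for r in testable])
        adj_iter = iter(padj)
        records = [
            replace(r, padj=float(next(adj_iter))) if not r.untestable else r
            for r in records
        ]
    return records


def orient_effect_allele(record: EqtlRecord, freqs: pd.DataFrame) -> dict[str, float]:
    """Per-population frequency of the expression-increasing allele.

    ``freqs`` stores alt-allele frequencies (snp_id, population, alt_freq);
    when the increasing allele is ref the complement is returned.  The
    result is invariant to relabelling ref<->alt with the slope negated and
    frequencies complemented.
    """
    if record.increasing_allele == "undetermined":
        raise ConfigError(f"{record.snp_id}: effect-allele orientation undetermined")
    sub = freqs[freqs["snp_id"] == record.snp_id]
    if sub.empty:
        raise ConfigError(f"{record.snp_id} missing from allele-frequency table")
    out = {}
    for row in sub.itertuples(index=False):
        f = float(row.alt_freq)
        out[row.population] = f if record.increasing_allele == "alt" else 1.0 - f
    return out


def eqtl_records_to_frame(records: list[EqtlRecord]) -> pd.DataFrame:
    """Tabular export mirroring the input format plus padj and orientation."""
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "gene_id": r.gene_id,
                "ref": r.ref,
                "alt": r.alt,
                "slope": r.slope,
                "p": r.p,
                "padj": r.padj if r.padj is not None else np.nan,
                "increasing_allele": r.increasing_allele,
                "untestable": r.untestable,
            }
            for r in records
        ]
    )
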