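"""Readers, writers and variant-level filters for the pipeline's file formats.

Formats
-------
Dosage TSV
    One variant per row, header
    ``variant_id effect_allele other_allele imputation_r2 <sample1> ...``;
    dosages count the effect allele on the [0, 2] scale.  ``imputation_r2``
    may be ``NA`` for directly typed variants.
Phenotype TSV
    ``sample_id outcome bmi diabetes sex age study pc1..pcK`` with raw BMI in
    kg/m**2 (converted to per-5 units on load) and diabetes coded 0/1.
Weight TSV
    ``gene_id variant_id effect_allele other_allele weight`` plus a gene-level
    companion ``gene_id pred_r2 n_snps``.  The PredictDB SQLite dialect
    (tables ``weights`` and ``extra``) is also accepted.
Results TSV
    As written by :func:`write_results`; floats carry 12 significant digits so
    a read-back reproduces the table.
"""

from __future__ import annotations

import logging
import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    PHENOTYPE_COLUMNS,
    SCAN_COLUMNS,
    VARIANT_COLUMNS,
    CohortTable,
    GenotypeMatrix,
    QcThresholds,
    ScanTable,
    WeightSet,
)

logger = logging.getLogger("gxescan.data_io")

__all__ = [
    "read_dosage_matrix",
    "read_dosage_vcf",
    "write_dosage_matrix",
    "apply_variant_qc",
    "apply_hwe_filter",
    "read_phenotypes",
    "write_phenotypes",
    "read_weight_sets",
    "read_predictdb",
    "write_weight_sets",
    "write_results",
    "read_results",
]

#: Raw-BMI floor: underweight participants are excluded from BMI analyses.
BMI_MINIMUM = 18.5


class ParseError(ValueError):
    """A file did not conform to its documented dialect."""


def read_dosage_matrix(path: str | Path) -> GenotypeMatrix:
    """Load a dosage TSV into a :class:`GenotypeMatrix`.

    Out-of-range dosages are clipped to [0, 2] and the clip count logged;
    duplicate variant ids raise.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[: len(VARIANT_COLUMNS)] != VARIANT_COLUMNS:
        raise ParseError(
            f"{path}: line 1: dosage header must start with "
            f"{' '.join(VARIANT_COLUMNS)}, got {' '.join(header[:4])}"
        )
    sample_ids = header[len(VARIANT_COLUMNS):]
    if not sample_ids:
        raise ParseError(f"{path}: line 1: no sample columns in dosage header")
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={"variant_id": str})
    if df["variant_id"].duplicated().any():
        dupes = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
        raise ParseError(f"{path}: duplicate variant ids {dupes}")
    dosages = df[sample_ids].to_numpy(dtype=float).T  # samples x variants
    n_clip = int(np.sum((dosages < 0) | (dosages > 2)))
    if n_clip:
        logger.warning("%s: clipped %d out-of-range dosage values to [0, 2]", path, n_clip)
        dosages = np.clip(dosages, 0.0, 2.0)
    variants = df[VARIANT_COLUMNS].copy()
    g = GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)
    g.n_clipped = n_clip  # type: ignore[attr-defined]
    return g


def write_dosage_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage TSV (inverse of :func:`read_dosage_matrix`)."""
    df = g.variants.copy()
    dose = pd.DataFrame(g.dosages.T, columns=g.sample_ids)
    out = pd.concat([df.reset_index(drop=True), dose.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_dosage_vcf(path: str | Path) -> GenotypeMatrix:
    """Load dosages from a VCF using the per-genotype ``DS`` field.

    Falls back to hard genotype counts when ``DS`` is absent.  Imputation
    quality is taken from an ``R2`` or ``DR2`` INFO key when present.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, dosage_rows = [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        r2 = rec.INFO.get("R2", rec.INFO.get("DR2", None))
        raw = rec.format("DS")
        if raw is not None:
            ds = np.asarray(raw, dtype=float).ravel()
        else:
            gts = np.asarray(rec.gt_types, dtype=float)
            gts[gts == 2] = np.nan  # UNKNOWN
            gts[gts == 3] = 2.0  # HOM_ALT
            ds = gts
        rows.append((vid, rec.ALT[0], rec.REF, np.nan if r2 is None else float(r2)))
        dosage_rows.append(ds)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.clip(np.asarray(dosage_rows, dtype=float).T, 0.0, 2.0)
    if variants["variant_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate variant ids in VCF")
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)


def apply_variant_qc(g: GenotypeMatrix, thresholds: QcThresholds | None = None) -> GenotypeMatrix:
    """Keep variants passing the MAF-tiered imputation-quality filter.

    Directly typed variants (missing ``imputation_r2``) always pass.  Sample
    order is preserved; the result may be empty.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    maf = g.maf
    r2 = g.variants["imputation_r2"].to_numpy(dtype=float)
    keep = []
    for j in range(g.n_variants):
        if np.isnan(r2[j]):
            keep.append(j)
        elif r2[j] > thresholds.min_r2_for(maf[j]):
            keep.append(j)
    dropped = g.n_variants - len(keep)
    if dropped:
        logger.info("variant QC removed %d of %d variants", dropped, g.n_variants)
    return g.take_variants(keep)


def _hwe_exact_pvalue(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of probabilities <= observed).

    Standard exact conditional test on the heterozygote count given the
    minor-allele count.
    """
    n = n_het + n_hom_rare + n_hom_common
    n_rare = 2 * n_hom_rare + n_het
    if n == 0 or n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # log-probability of each possible het count, same parity as n_rare
    from scipy.special import gammaln

    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.searchsorted(hets, n_het)
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def apply_hwe_filter(
    g: GenotypeMatrix,
    cohort: CohortTable,
    p_threshold: float = 1e-4,
) -> GenotypeMatrix:
    """Optional Hardy-Weinberg filter on hard-called genotypes in controls.

    Dosages are rounded to 0/1/2; variants whose exact HWE test among
    controls falls below ``p_threshold`` are removed.  Off by default in the
    pipeline because HWE on imputed dosages is ill-defined.
    """
    sample_index = {s: i for i, s in enumerate(g.sample_ids)}
    ctrl_ids = cohort.data.loc[cohort.data["outcome"] == 0, "sample_id"]
    rows = [sample_index[s] for s in ctrl_ids if s in sample_index]
    hard = np.rint(g.dosages[rows, :]).astype(int)
    keep = []
    for j in range(g.n_variants):
        counts = np.bincount(hard[:, j], minlength=3)
        n_hom_a, n_het, n_hom_b = int(counts[0]), int(counts[1]), int(counts[2])
        if n_hom_a < n_hom_b:
            n_hom_a, n_hom_b = n_hom_b, n_hom_a
        if _hwe_exact_pvalue(n_het, n_hom_b, n_hom_a) >= p_threshold:
            keep.append(j)
    dropped = g.n_variants - len(keep)
    if dropped:
        logger.info("HWE filter removed %d of %d variants", dropped, g.n_variants)
    return g.take_variants(keep)


def read_phenotypes(path: str | Path) -> CohortTable:
    """Load a phenotype TSV, converting BMI to per-5 kg/m**2 units.

    Raw BMI below 18.5 kg/m**2 is masked to NaN so those samples drop out of
    BMI analyses (but remain available for diabetes); rows missing the
    outcome are dropped.  Both counts are logged and stored on the table.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    n0 = len(df)
    df = df[df["outcome"].notna()].copy()
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing outcome", path, n_dropped)
    df["outcome"] = df["outcome"].astype(int)
    underweight = df["bmi"].notna() & (df["bmi"] < BMI_MINIMUM)
    n_excluded = int(underweight.sum())
    if n_excluded:
        logger.info(
            "%s: excluded %d samples with BMI < %.1f from BMI analyses",
            path, n_excluded, BMI_MINIMUM,
        )
    df.loc[underweight, "bmi"] = np.nan
    df["bmi"] = df["bmi"] / 5.0
    df["sample_id"] = df["sample_id"].astype(str)
    return CohortTable(data=df.reset_index(drop=True),
                       n_excluded_bmi=n_excluded, n_dropped_missing=n_dropped)


def write_phenotypes(cohort: CohortTable, path: str | Path) -> None:
    """Write a phenotype TSV with BMI back on the raw kg/m**2 scale."""
    df = cohort.data.copy()
    df["bmi"] = df["bmi"] * 5.0
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_weight_sets(weights_path: str | Path, genes_path: str | Path) -> list[WeightSet]:
    """Load the TSV weight dialect into per-gene :class:`WeightSet` objects."""
    wdf = pd.read_csv(weights_path, sep="\t", dtype={"gene_id": str, "variant_id": str})
    gdf = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "variant_id", "effect_allele", "other_allele", "weight"):
        if col not in wdf.columns:
            raise ParseError(f"{weights_path}: missing column {col!r}")
    for col in ("gene_id", "pred_r2"):
        if col not in gdf.columns:
            raise ParseError(f"{genes_path}: missing column {col!r}")
    r2 = dict(zip(gdf["gene_id"], gdf["pred_r2"].astype(float)))
    out = []
    for gene, grp in wdf.groupby("gene_id", sort=True):
        out.append(
            WeightSet(
                gene_id=str(gene),
                variant_ids=grp["variant_id"].tolist(),
                effect_alleles=grp["effect_allele"].tolist(),
                other_alleles=grp["other_allele"].tolist(),
                weights=grp["weight"].to_numpy(dtype=float),
                predictive_r2=float(r2.get(str(gene), np.nan)),
            )
        )
    return out


def write_weight_sets(weight_sets: list[WeightSet], weights_path: str | Path,
                      genes_path: str | Path) -> None:
    rows, gene_rows = [], []
    for ws in weight_sets:
        for vid, ea, oa, w in zip(ws.variant_ids, ws.effect_alleles,
                                  ws.other_alleles, ws.weights):
            rows.append((ws.gene_id, vid, ea, oa, w))
        gene_rows.append((ws.gene_id, ws.predictive_r2, ws.n_snps))
    pd.DataFrame(rows, columns=["gene_id", "variant_id", "effect_allele",
                                "other_allele", "weight"]).to_csv(
        weights_path, sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(gene_rows, columns=["gene_id", "pred_r2", "n_snps"]).to_csv(
        genes_path, sep="\t", index=False, float_format="%.10g")


def read_predictdb(path: str | Path) -> list[WeightSet]:
    """Load a PredictDB-style SQLite weight database (tables weights/extra)."""
    con = sqlite3.connect(str(path))
    try:
        wdf = pd.read_sql_query(
            "SELECT gene, rsid, eff_allele, ref_allele, weight FROM weights", con)
        edf = pd.read_sql_query("SELECT gene, [pred.perf.R2] AS r2 FROM extra", con)
    finally:
        con.close()
    r2 = dict(zip(edf["gene"], edf["r2"].astype(float)))
    out = []
    for gene, grp in wdf.groupby("gene", sort=True):
        out.append(
            WeightSet(
                gene_id=str(gene),
                variant_ids=grp["rsid"].tolist(),
                effect_alleles=grp["eff_allele"].tolist(),
                other_alleles=grp["ref_allele"].tolist(),
                weights=grp["weight"].to_numpy(dtype=float),
                predictive_r2=float(r2.get(str(gene), np.nan)),
            )
        )
    return out


def write_results(table: ScanTable, path: str | Path) -> None:
    """Write a scan results TSV; floats keep 12 significant digits."""
    if len(table.data) == 0:
        raise ValueError("refusing to write an empty results table")
    df = table.data[SCAN_COLUMNS].copy()
    df["significant"] = df["significant"].astype(bool)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path, fdr_threshold: float = 0.2) -> ScanTable:
    df = pd.read_csv(path, sep="\t")
    df["significant"] = df["significant"].astype(bool)
    return ScanTable(data=df, fdr_threshold=fdr_threshold)
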