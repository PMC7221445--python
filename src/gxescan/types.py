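"""Core data containers shared across the pipeline.

Conventions used throughout:

* dosages are effect-allele counts on the ``[0, 2]`` scale (imputed values
  may be fractional), one row per sample, one column per variant;
* BMI exposures are expressed in units of 5 kg/m**2 (raw BMI divided by 5);
* diabetes exposure is a 0/1 indicator;
* minor-allele frequency (MAF) is always the folded frequency in ``[0, 0.5]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QcTier",
    "QcThresholds",
    "CohortTable",
    "WeightSet",
    "PredictedExpression",
    "GeneResult",
    "ScanTable",
]

VARIANT_COLUMNS = ["variant_id", "effect_allele", "other_allele", "imputation_r2"]


@dataclass
class GenotypeMatrix:
    """Sample-by-variant effect-allele dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids
        Opaque sample identifiers, one per dosage row.
    variants
        DataFrame with columns ``variant_id``, ``effect_allele``,
        ``other_allele`` and ``imputation_r2`` (NaN marks directly typed
        variants with no imputation-quality score).
    dosages
        ``(n_samples, n_variants)`` float array with values in ``[0, 2]``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        vids = self.variants["variant_id"]
        if vids.duplicated().any():
            dupes = vids[vids.duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dupes}")
        if self.dosages.size and (
            np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2
        ):
            raise ValueError("dosage values must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def maf(self) -> np.ndarray:
        """Folded allele frequency recomputed from the dosages."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variants["variant_id"])}

    def take_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def take_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :],
        )


@dataclass(frozen=True)
class QcTier:
    """One (MAF bound, minimum imputation quality) rung of the variant filter."""

    maf_bound: float
    min_r2: float


@dataclass(frozen=True)
class QcThresholds:
    """Tiered imputation-quality filter: rarer variants need better imputation.

    Tiers are matched from common to rare; a variant falls in the first tier
    whose ``maf_bound`` it strictly exceeds, and the last tier is the
    catch-all for the rarest variants.  With the defaults, a variant is kept
    when ``r2 > 0.3`` for MAF > 1%, ``r2 > 0.5`` for 0.5% < MAF <= 1%, and
    ``r2 > 0.99`` for MAF <= 0.5%.
    """

    tiers: tuple[QcTier, ...] = (
        QcTier(0.01, 0.3),
        QcTier(0.005, 0.5),
        QcTier(0.0005, 0.99),
    )

    def __post_init__(self) -> None:
        bounds = [t.maf_bound for t in self.tiers]
        if bounds != sorted(bounds, reverse=True):
            raise ValueError("tiers must be ordered by descending maf_bound")
        r2s = [t.min_r2 for t in self.tiers]
        if r2s != sorted(r2s):
            raise ValueError("min_r2 must be nondecreasing as maf_bound decreases")

    def min_r2_for(self, maf: float) -> float:
        for tier in self.tiers[:-1]:
            if maf > tier.maf_bound:
                return tier.min_r2
        return self.tiers[-1].min_r2


#: Phenotype-table columns that must always be present.
PHENOTYPE_COLUMNS = ["sample_id", "outcome", "bmi", "diabetes", "sex", "age", "study"]


@dataclass
class CohortTable:
    """Per-sample outcome, exposures and covariates.

    ``data`` holds one row per sample with columns ``sample_id``, ``outcome``
    (0 control / 1 case), ``bmi`` (per-5 kg/m**2 units; NaN when the raw BMI
    was below 18.5 or missing), ``diabetes`` (0/1), ``sex`` ("male"/"female"),
    ``age`` (years), ``study`` (categorical label) and ``pc1..pcK``.
    """

    data: pd.DataFrame
    n_excluded_bmi: int = 0
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        outcome = self.data["outcome"]
        if not outcome.isin([0, 1]).all():
            raise ValueError("outcome must be binary 0/1")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def pc_columns(self) -> list[str]:
        cols = [c for c in self.data.columns if c.startswith("pc") and c[2:].isdigit()]
        return sorted(cols, key=lambda c: int(c[2:]))

    def exposure(self, name: str) -> np.ndarray:
        if name not in ("bmi", "diabetes"):
            raise ValueError(f"unknown exposure {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def for_exposure(self, name: str) -> "CohortTable":
        """Subset to samples with a usable value of the given exposure."""
        keep = self.data[name].notna()
        return replace(self, data=self.data[keep].reset_index(drop=True))

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return replace(self, data=self.data[np.asarray(mask)].reset_index(drop=True))


@dataclass
class WeightSet:
    """One gene's eQTL weights with allele orientation and predictive R^2.

    ``dosage_complement`` marks variants whose stored weight applies to the
    complemented dosage ``2 - d`` (set during allele harmonization when the
    weight table and the dosage file count opposite alleles).
    """

    gene_id: str
    variant_ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    weights: np.ndarray
    predictive_r2: float
    dosage_complement: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.variant_ids) == 0:
            raise ValueError(f"weight set for {self.gene_id} has no eQTLs")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError(f"duplicate variant ids in weight set {self.gene_id}")
        n = len(self.variant_ids)
        if not (len(self.effect_alleles) == len(self.other_alleles) == len(self.weights) == n):
            raise ValueError("weight set field lengths disagree")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.dosage_complement is None:
            self.dosage_complement = np.zeros(n, dtype=bool)
        else:
            self.dosage_complement = np.asarray(self.dosage_complement, dtype=bool)

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)


@dataclass
class PredictedExpression:
    """Genetically predicted expression x-hat for one gene across a cohort."""

    gene_id: str
    values: np.ndarray
    n_snps_used: int
    n_snps_dropped: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GeneResult:
    """Per-gene interaction test result (one stratum)."""

    gene_id: str
    stratum: str
    n_snps: int
    predictive_r2: float
    p_fixed: float
    p_random: float
    p_adaptive: float
    chosen_weight: float


#: Column order of a results table on disk.
SCAN_COLUMNS = [
    "gene",
    "stratum",
    "n_snps",
    "r2",
    "p_fixed",
    "p_random",
    "p_adaptive",
    "q_value",
    "significant",
]


@dataclass
class ScanTable:
    """Genome-wide scan results with BH q-values and a significance flag."""

    data: pd.DataFrame
    fdr_threshold: float = 0.2

    def __post_init__(self) -> None:
        missing = [c for c in SCAN_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"scan table missing columns: {missing}")
        q = self.data["q_value"]
        if len(q) and ((q < 0).any() or (q > 1).any()):
            raise ValueError("q-values must lie in [0, 1]")
        self.data = self.data.reset_index(drop=True)

    def significant_genes(self) -> pd.DataFrame:
        return self.data[self.data["significant"]]
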