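"""Genome-wide orchestration: stratification, per-gene tests, FDR, main effects.

BMI analyses run separately in men and women (the BMI-disease association
differs by sex); diabetes analyses pool the sexes with sex as a covariate.
Benjamini-Hochberg q-values are computed within each exposure-by-stratum
scan and genes flagged at q below the FDR threshold (0.2 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import misti_core
from .expression import UnpredictableGeneError, filter_genes_by_heritability
from .types import SCAN_COLUMNS, CohortTable, GeneResult, GenotypeMatrix, ScanTable, WeightSet

logger = logging.getLogger("gxescan.scan")

__all__ = [
    "ExposureSpec",
    "BMI_SPEC",
    "DIABETES_SPEC",
    "bh_fdr",
    "run_scan",
    "estimate_exposure_main_effect",
    "qq_plot",
]


@dataclass(frozen=True)
class ExposureSpec:
    """How one exposure is analysed: stratified by sex or sex-adjusted."""

    name: str
    stratify_by_sex: bool
    adjust_sex: bool
    n_pcs: int = 3

    def __post_init__(self) -> None:
        if self.name not in ("bmi", "diabetes"):
            raise ValueError(f"unknown exposure {self.name!r}")
        if self.stratify_by_sex and self.adjust_sex:
            raise ValueError("stratify_by_sex and adjust_sex are mutually exclusive")


BMI_SPEC = ExposureSpec("bmi", stratify_by_sex=True, adjust_sex=False)
DIABETES_SPEC = ExposureSpec("diabetes", stratify_by_sex=False, adjust_sex=True)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _strata(spec: ExposureSpec, cohort: CohortTable) -> list[tuple[str, np.ndarray]]:
    if spec.stratify_by_sex:
        sex = cohort.data["sex"].astype(str)
        return [("male", (sex == "male").to_numpy()),
                ("female", (sex == "female").to_numpy())]
    return [("all", np.ones(cohort.n_samples, dtype=bool))]


def run_scan(
    weight_sets: list[WeightSet],
    genotypes: GenotypeMatrix,
    cohort: CohortTable,
    spec: ExposureSpec,
    r2_min: float = 0.01,
    fdr_threshold: float = 0.2,
    combiner: str = "adaptive_grid",
) -> ScanTable:
    """Test every eligible gene in every stratum and control the FDR.

    Rows are ordered by (gene id, stratum); q-values are computed within
    each stratum.  Genes that cannot be tested (unpredictable, separated or
    non-converged models) are skipped with a log entry; strata without both
    cases and controls are skipped with a warning.
    """
    eligible = filter_genes_by_heritability(weight_sets, r2_min)
    if not eligible:
        raise ValueError("no gene passes the heritability filter")
    cohort_e = cohort.for_exposure(spec.name)
    sample_index = {sid: i for i, sid in enumerate(genotypes.sample_ids)}
    rows: list[tuple[GeneResult, float]] = []
    for stratum, mask in _strata(spec, cohort_e):
        sub = cohort_e.subset(mask)
        y = sub.data["outcome"]
        if len(sub.data) == 0 or y.nunique() < 2:
            logger.warning("stratum %s skipped: no cases or no controls", stratum)
            continue
        g_idx = [sample_index[sid] for sid in sub.data["sample_id"]]
        g_sub = genotypes.take_samples(g_idx)
        stratum_rows: list[GeneResult] = []
        for ws in eligible:
            try:
                res = misti_core.test_gene(
                    ws, g_sub, sub, spec.name,
                    include_sex=spec.adjust_sex,
                    n_pcs=spec.n_pcs,
                    combiner=combiner,
                    stratum=stratum,
                )
            except (UnpredictableGeneError, misti_core.ConvergenceError,
                    misti_core.RankDeficiencyError) as exc:
                logger.warning("gene %s (%s) skipped: %s", ws.gene_id, stratum, exc)
                continue
            stratum_rows.append(res)
        if stratum_rows:
            q = bh_fdr(np.array([r.p_adaptive for r in stratum_rows]))
            rows.extend(zip(stratum_rows, q))
        logger.info("stratum %s: tested %d genes", stratum, len(stratum_rows))
    if not rows:
        raise ValueError("scan produced no results")
    df = pd.DataFrame(
        {
            "gene": [r.gene_id for r, _ in rows],
            "stratum": [r.stratum for r, _ in rows],
            "n_snps": [r.n_snps for r, _ in rows],
            "r2": [r.predictive_r2 for r, _ in rows],
            "p_fixed": [r.p_fixed for r, _ in rows],
            "p_random": [r.p_random for r, _ in rows],
            "p_adaptive": [r.p_adaptive for r, _ in rows],
            "q_value": [q for _, q in rows],
        }
    )
    df["significant"] = df["q_value"] < fdr_threshold
    df = df.sort_values(["gene", "stratum"], kind="stable").reset_index(drop=True)
    return ScanTable(data=df[SCAN_COLUMNS], fdr_threshold=fdr_threshold)


def estimate_exposure_main_effect(
    cohort: CohortTable,
    spec: ExposureSpec,
) -> tuple[float, tuple[float, float]]:
    """Pooled logistic main effect of the exposure: OR and Wald 95% CI.

    The model adjusts for age, study, principal components and (when the
    spec says so) sex.  Raises on a constant exposure or separation.
    """
    sub = cohort.for_exposure(spec.name)
    e = sub.exposure(spec.name)
    if np.ptp(e) == 0:
        raise ValueError(f"exposure {spec.name} is constant; main effect undefined")
    X, names = misti_core.build_design(sub, spec.name, xhat=None,
                                       include_sex=spec.adjust_sex,
                                       n_pcs=spec.n_pcs)
    y = sub.data["outcome"].to_numpy(dtype=float)
    res = sm.Logit(y, X).fit(disp=False, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise misti_core.ConvergenceError("main-effect logistic fit did not converge")
    j = names.index(f"E_{spec.name}")
    coef = res.params[j]
    if abs(coef) > 30:
        raise misti_core.SeparationError("main-effect coefficient diverged")
    se = res.bse[j]
    lo, hi = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
    return float(np.exp(coef)), (float(np.exp(lo)), float(np.exp(hi)))


def qq_plot(scan: ScanTable, path: str) -> None:
    """Basic QQ plot of the adaptive p-values against the uniform."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(scan.data["p_adaptive"].to_numpy(dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(expected, observed, "o", ms=3)
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
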