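"""Secondary analyses for genes flagged by the genome-wide scan.

Two procedures:

* forward sequential conditional SNP-by-exposure selection - starting from
  the most significant single SNP interaction, repeatedly add the next most
  significant candidate conditional on everything already selected, until
  the best remaining conditional Wald p-value reaches 0.05;
* exposure-stratified associations of predicted expression with the outcome
  (BMI quartiles, cut in controls, or diabetes yes/no).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import misti_core
from .scan import ExposureSpec
from .types import CohortTable, GenotypeMatrix, PredictedExpression, WeightSet

logger = logging.getLogger("gxescan.followup")

__all__ = ["SequentialReport", "sequential_snp_selection",
           "stratified_expression_association"]


@dataclass
class SequentialReport:
    """Outcome of the forward conditional SNP-by-exposure search."""

    gene_id: str
    selected: list[tuple[str, float, float]] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def variant_ids(self) -> list[str]:
        return [v for v, _, _ in self.selected]


def _wald_interaction(
    X_base: np.ndarray,
    y: np.ndarray,
    snp: np.ndarray,
    e: np.ndarray,
) -> tuple[float, float]:
    """Wald p-value and log-OR of the SNP-by-exposure term in a full fit."""
    X = np.column_stack([X_base, snp, snp * e])
    beta, mu, _, _ = misti_core.irls_logistic(X, y)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    j = X.shape[1] - 1
    se = np.sqrt(cov[j, j])
    z = beta[j] / se
    return float(chi2.sf(z * z, df=1)), float(beta[j])


def sequential_snp_selection(
    ws: WeightSet,
    g: GenotypeMatrix,
    cohort: CohortTable,
    spec: ExposureSpec,
    alpha: float = 0.05,
) -> SequentialReport:
    """Forward conditional selection of eQTLs driving a gene's interaction.

    At each step every not-yet-selected eQTL is added (main effect plus
    interaction with the exposure) on top of the covariates, the exposure
    and all previously selected SNP and SNP-by-exposure terms; the candidate
    with the smallest interaction Wald p is selected if that p is below
    ``alpha``.  Ties break toward the smaller variant index.  Candidates
    whose model fails to converge are skipped with a log entry.
    """
    sub = cohort.for_exposure(spec.name)
    y = sub.data["outcome"].to_numpy(dtype=float)
    e = sub.exposure(spec.name)
    X_cov, _ = misti_core.build_design(sub, spec.name, xhat=None,
                                       include_sex=spec.adjust_sex,
                                       n_pcs=spec.n_pcs)
    index = g.variant_index()
    sample_index = {sid: i for i, sid in enumerate(g.sample_ids)}
    rows = [sample_index[sid] for sid in sub.data["sample_id"]]
    candidates: list[tuple[str, np.ndarray]] = []
    for vid, cmpl in zip(ws.variant_ids, ws.dosage_complement):
        j = index.get(vid)
        if j is None:
            continue
        d = g.dosages[rows, j]
        candidates.append((vid, 2.0 - d if cmpl else d))

    report = SequentialReport(gene_id=ws.gene_id)
    selected_cols: list[np.ndarray] = []
    remaining = list(range(len(candidates)))
    for _ in range(len(candidates)):
        X_base = (np.column_stack([X_cov] + selected_cols)
                  if selected_cols else X_cov)
        best: tuple[float, int, float] | None = None
        for k in remaining:
            vid, dose = candidates[k]
            try:
                p, logor = _wald_interaction(X_base, y, dose, e)
            except (misti_core.ConvergenceError, np.linalg.LinAlgError) as exc:
                logger.warning("gene %s: candidate %s skipped (%s)",
                               ws.gene_id, vid, exc)
                continue
            if best is None or (p, k) < (best[0], best[1]):
                best = (p, k, logor)
        if best is None:
            report.stop_reason = "no candidate model converged"
            break
        p, k, logor = best
        if p >= alpha:
            report.stop_reason = "no candidate below alpha"
            break
        vid, dose = candidates[k]
        report.selected.append((vid, p, float(np.exp(logor))))
        selected_cols.extend([dose, dose * e])
        remaining.remove(k)
    else:
        report.stop_reason = "all eQTLs selected"
    return report


def stratified_expression_association(
    xhat: PredictedExpression,
    cohort: CohortTable,
    strata: str = "bmi_quartiles",
    n_pcs: int | None = 3,
) -> pd.DataFrame:
    """Association of predicted expression with the outcome within exposure strata.

    ``bmi_quartiles`` cuts BMI at control-only quartiles; ``diabetes`` splits
    by the indicator.  Within each stratum a logistic model of the outcome on
    predicted expression plus covariates (age, sex, study, PCs) is fitted;
    returns one row per stratum with the OR per unit predicted expression and
    its Wald 95% CI.  Strata without both cases and controls are omitted
    with a warning; a constant predicted expression raises.
    """
    x = np.asarray(xhat.values, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predicted expression is constant; association undefined")
    df = cohort.data
    if strata == "bmi_quartiles":
        bmi = df["bmi"]
        ctrl = bmi[df["outcome"] == 0].dropna()
        cuts = np.quantile(ctrl, [0.25, 0.5, 0.75])
        labels = np.full(len(df), "Q4", dtype=object)
        labels[bmi <= cuts[2]] = "Q3"
        labels[bmi <= cuts[1]] = "Q2"
        labels[bmi <= cuts[0]] = "Q1"
        labels[bmi.isna()] = "NA"
        order = ["Q1", "Q2", "Q3", "Q4"]
    elif strata == "diabetes":
        labels = np.where(df["diabetes"] == 1, "diabetic", "nondiabetic").astype(object)
        labels[df["diabetes"].isna()] = "NA"
        order = ["nondiabetic", "diabetic"]
    else:
        raise ValueError(f"unknown stratification {strata!r}")

    out = []
    for name in order:
        mask = labels == name
        sub = cohort.subset(mask)
        if len(sub.data) == 0 or sub.data["outcome"].nunique() < 2:
            logger.warning("stratum %s omitted: no cases or no controls", name)
            continue
        xs = x[mask]
        if np.ptp(xs) == 0:
            raise ValueError(f"predicted expression constant within stratum {name}")
        cols = [np.ones(mask.sum()), sub.data["age"].to_numpy(dtype=float),
                (sub.data["sex"].astype(str) == "female").to_numpy(dtype=float)]
        for s in sorted(sub.data["study"].astype(str).unique())[1:]:
            cols.append((sub.data["study"].astype(str) == s).to_numpy(dtype=float))
        pcs = sub.pc_columns if n_pcs is None else sub.pc_columns[:n_pcs]
        for c in pcs:
            cols.append(sub.data[c].to_numpy(dtype=float))
        cols.append(xs)
        X = np.column_stack(cols)
        yv = sub.data["outcome"].to_numpy(dtype=float)
        beta, mu, _, _ = misti_core.irls_logistic(X, yv)
        w = mu * (1.0 - mu)
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        j = X.shape[1] - 1
        se = float(np.sqrt(cov[j, j]))
        out.append({
            "stratum": name,
            "n": int(mask.sum()),
            "or_per_unit": float(np.exp(beta[j])),
            "ci_low": float(np.exp(beta[j] - 1.959963984540054 * se)),
            "ci_high": float(np.exp(beta[j] + 1.959963984540054 * se)),
        })
    return pd.DataFrame(out)
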