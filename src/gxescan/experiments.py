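"""Reusable simulation studies: calibration, power attribution, recovery.

These drivers run the full pipeline (generator -> predicted expression ->
score tests -> combination) over replicated synthetic scenarios.  They back
both the verification suite and the reproducibility script; problem sizes
are arguments so callers choose their own compute budget.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .expression import harmonize_alleles, predict_expression
from .followup import sequential_snp_selection
from .misti_core import fit_null_logistic, fixed_effect_score_test, test_gene
from .scan import ExposureSpec, estimate_exposure_main_effect
from .synthetic_data import SimScenario, simulate_cohort

logger = logging.getLogger("gxescan.experiments")

__all__ = [
    "BURDEN_TAU",
    "DISPERSED_THETA",
    "SINGLE_SNP_BETA",
    "null_pvalue_replicates",
    "component_pvalue_replicates",
    "score_vs_lrt_ratios",
    "main_effect_recovery",
    "main_effect_coverage",
    "sequential_first_hit_rate",
]

#: Frozen study conditions for the power scenarios: a burden-type
#: interaction of tau = 0.15 per (predicted-expression x exposure) unit, a
#: dispersed per-SNP interaction variance theta = 0.002, and a targeted
#: single-SNP interaction log-OR of 0.3.
BURDEN_TAU = 0.15
DISPERSED_THETA = 0.002
SINGLE_SNP_BETA = 0.3

_POOLED_BMI = ExposureSpec("bmi", stratify_by_sex=False, adjust_sex=True)


def _seeds(seed: int, n: int) -> np.ndarray:
    """Derive independent per-replicate seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def _scenario(seed: int, **overrides) -> SimScenario:
    base = dict(n_cases=1000, n_controls=1000, n_genes=1, snps_per_gene=30)
    base.update(overrides)
    return SimScenario(seed=int(seed), **base)


def component_pvalue_replicates(
    n_reps: int,
    seed: int,
    tau: float = 0.0,
    theta: float = 0.0,
    n_cases: int = 1000,
    n_controls: int = 1000,
) -> pd.DataFrame:
    """Replicate the per-gene test; one row of (p_fixed, p_random, p_adaptive)
    per replicate.  The sex-adjusted pooled analysis is used so all samples
    inform each replicate."""
    rows = []
    for s_rep in _seeds(seed, n_reps):
        sc = _scenario(s_rep, tau=tau, theta=theta,
                       n_cases=n_cases, n_controls=n_controls)
        g, cohort, wss = simulate_cohort(sc)
        r = test_gene(wss[0], g, cohort, "bmi", include_sex=True, n_pcs=3)
        rows.append((r.p_fixed, r.p_random, r.p_adaptive))
    return pd.DataFrame(rows, columns=["p_fixed", "p_random", "p_adaptive"])


def null_pvalue_replicates(n_reps: int, seed: int, **kw) -> pd.DataFrame:
    """Null-scenario (tau = theta = 0) replicates of the per-gene test."""
    return component_pvalue_replicates(n_reps, seed, tau=0.0, theta=0.0, **kw)


def score_vs_lrt_ratios(n_reps: int, seed: int, tau: float = BURDEN_TAU) -> np.ndarray:
    """Ratio of -log10 p between the fixed-component score test and a
    likelihood-ratio test from a full-model refit, across replicates."""
    ratios = []
    for s_rep in _seeds(seed, n_reps):
        sc = _scenario(s_rep, tau=tau)
        g, cohort, wss = simulate_cohort(sc)
        ws = harmonize_alleles(wss[0], g)
        xhat = predict_expression(ws, g)
        e = cohort.exposure("bmi")
        f0 = fit_null_logistic(cohort, xhat, "bmi", include_sex=True, n_pcs=3)
        score = fixed_effect_score_test(f0, xhat.values * e)
        f1 = fit_null_logistic(cohort, xhat, "bmi",
                               include_fixed_interaction=True,
                               include_sex=True, n_pcs=3)
        p_lrt = float(chi2.sf(2.0 * (f1.loglik - f0.loglik), df=1))
        ratios.append(np.log10(score.p_value) / np.log10(p_lrt))
    return np.asarray(ratios)


def main_effect_recovery(
    seed: int,
    n_cases: int = 10000,
    n_controls: int = 10000,
    beta_E: float | None = None,
) -> tuple[float, tuple[float, float]]:
    """Single large-sample recovery of the exposure main-effect OR."""
    overrides = dict(n_cases=n_cases, n_controls=n_controls,
                     snps_per_gene=5, weight_sparsity=0.6)
    if beta_E is not None:
        overrides["beta_E"] = beta_E
    sc = _scenario(seed, **overrides)
    g, cohort, _ = simulate_cohort(sc)
    return estimate_exposure_main_effect(cohort, _POOLED_BMI)


def main_effect_coverage(
    n_reps: int,
    seed: int,
    n_cases: int = 1000,
    n_controls: int = 1000,
) -> float:
    """Fraction of replicates whose 95% CI covers the null OR = 1 when the
    exposure truly has no effect."""
    covered = 0
    for s_rep in _seeds(seed, n_reps):
        sc = _scenario(s_rep, beta_E=0.0, n_cases=n_cases, n_controls=n_controls,
                       snps_per_gene=5, weight_sparsity=0.6)
        g, cohort, _ = simulate_cohort(sc)
        _, (lo, hi) = estimate_exposure_main_effect(cohort, _POOLED_BMI)
        covered += int(lo <= 1.0 <= hi)
    return covered / n_reps


def sequential_first_hit_rate(
    n_reps: int,
    seed: int,
    beta: float = SINGLE_SNP_BETA,
    target_index: int = 3,
) -> tuple[float, int]:
    """How often the truly interacting SNP is selected first.

    Returns ``(hit_rate, max_selected)`` over replicates of a 10-SNP gene at
    2000 cases / 2000 controls with a single targeted SNP-by-exposure
    effect.
    """
    hits = 0
    max_selected = 0
    for s_rep in _seeds(seed, n_reps):
        sc = _scenario(s_rep, n_cases=2000, n_controls=2000, snps_per_gene=10,
                       weight_sparsity=0.8, snp_interaction_beta=beta,
                       snp_interaction_index=target_index)
        g, cohort, wss = simulate_cohort(sc)
        ws = wss[0]
        target = ws.variant_ids[target_index % ws.n_snps]
        report = sequential_snp_selection(ws, g, cohort, _POOLED_BMI)
        max_selected = max(max_selected, len(report.selected))
        if report.selected and report.selected[0][0] == target:
            hits += 1
    return hits / n_reps, max_selected
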