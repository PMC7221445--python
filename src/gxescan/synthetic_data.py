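"""Synthetic multi-study case-control cohorts with separable interaction effects.

The generator emulates the statistical structure the analysis assumes:

* LD-correlated genotypes — a latent Gaussian AR-1 process per gene,
  thresholded into two haplotypes at each variant's minor-allele frequency;
* sparse elastic-net-like eQTL weight vectors with an empirical predictive
  R^2 (the variance fraction of the genetic score in a noisy expression
  trait);
* exposures — raw BMI from a normal truncated below at 18.5 kg/m**2
  (stored in per-5 units) and a diabetes indicator whose probability rises
  with BMI, so the two exposure analyses are correlated as in real cohorts;
* a logistic disease model whose interaction effects split into a
  burden-type part ``tau * (x * E)`` acting through predicted expression and
  a dispersed part ``sum_j u_j G_j E`` with ``u_j ~ N(0, theta)``;
* retrospective case-control sampling: a population is simulated at a
  calibrated prevalence and cases/controls are drawn to the requested counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm, truncnorm

from . import data_io
from .types import CohortTable, GenotypeMatrix, WeightSet

logger = logging.getLogger("gxescan.synthetic_data")

__all__ = [
    "SimScenario",
    "simulate_genotypes",
    "simulate_weight_set",
    "simulate_cohort",
    "write_fixture_bundle",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"),
                 ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters of one simulated study.

    Defaults describe a desk-scale null cohort: 1000 cases / 1000 controls
    drawn from a population with 10% disease prevalence, 50 genes of 30
    SNPs, moderate LD (AR-1 rho 0.5), elastic-net-like sparsity 0.3, and a
    BMI main effect of log(1.25) per 5 kg/m**2.  ``tau`` and ``theta``
    (burden and dispersed interaction effects, both zero by default) act on
    the single ``causal_gene``.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    n_genes: int = 50
    snps_per_gene: int = 30
    maf_range: tuple[float, float] = (0.05, 0.45)
    ld_rho: float = 0.5
    weight_sparsity: float = 0.3
    target_r2: float = 0.1
    #: which exposure drives the generative interaction terms
    exposure: str = "bmi"
    beta_E: float = math.log(1.25)
    beta_g: float = 0.1
    tau: float = 0.0
    theta: float = 0.0
    snp_interaction_beta: float = 0.0
    snp_interaction_index: int = 0
    causal_gene: int = 0
    prevalence: float = 0.1
    n_studies: int = 4
    n_pcs: int = 3
    study_sd: float = 0.2
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    diabetes_intercept: float = -2.2
    diabetes_bmi_slope: float = 0.5
    beta_age: float = 0.02
    beta_sex: float = -0.2
    beta_pc: float = 0.05
    age_mean: float = 62.0
    age_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case/control counts must be positive")
        if not (0.0 < self.prevalence < 0.5):
            raise ValueError("prevalence must lie in (0, 0.5)")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.005 < lo <= hi < 0.5):
            raise ValueError("maf_range must be within (0.005, 0.5)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _gene_mafs(s: SimScenario, rng: np.random.Generator) -> np.ndarray:
    lo, hi = s.maf_range
    return rng.uniform(lo, hi, size=(s.n_genes, s.snps_per_gene))


def _haplotypes(n: int, mafs: np.ndarray, rho: float,
                rng: np.random.Generator) -> np.ndarray:
    """One haplotype per sample from a latent AR-1 Gaussian per gene."""
    m = mafs.shape[0]
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if m > 1:
        eps = rng.standard_normal((n, m - 1))
        scale = math.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j - 1]
    thresholds = norm.ppf(mafs)
    return (z < thresholds[None, :]).astype(float)


def simulate_genotypes(
    s: SimScenario,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
    mafs: np.ndarray | None = None,
    sample_offset: int = 0,
) -> GenotypeMatrix:
    """Simulate dosages for all genes (columns blocked gene by gene).

    Each gene is an independent AR-1(ld_rho) latent-Gaussian block; the
    dosage is the sum of two independent haplotypes.  Imputation quality is
    drawn uniformly from (0.3, 1].
    """
    rng = s.rng() if rng is None else rng
    n = (s.n_cases + s.n_controls) if n_samples is None else n_samples
    if mafs is None:
        mafs = _gene_mafs(s, rng)
    blocks = []
    for gi in range(s.n_genes):
        h1 = _haplotypes(n, mafs[gi], s.ld_rho, rng)
        h2 = _haplotypes(n, mafs[gi], s.ld_rho, rng)
        blocks.append(h1 + h2)
    dosages = np.concatenate(blocks, axis=1)
    n_var = s.n_genes * s.snps_per_gene
    alleles = [_ALLELE_PAIRS[k % len(_ALLELE_PAIRS)] for k in range(n_var)]
    variants = pd.DataFrame({
        "variant_id": [f"g{gi:03d}_snp{sj:03d}"
                       for gi in range(s.n_genes) for sj in range(s.snps_per_gene)],
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "imputation_r2": rng.uniform(0.3, 1.0, size=n_var),
    })
    sample_ids = [f"s{sample_offset + i:06d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)


def simulate_weight_set(
    s: SimScenario,
    g: GenotypeMatrix,
    gene_index: int = 0,
    rng: np.random.Generator | None = None,
) -> WeightSet:
    """Fabricate one gene's sparse eQTL weight vector.

    A ``weight_sparsity`` fraction of the gene's variants receive standard
    normal weights (at least one; an all-pruned draw is resampled once).
    The reported predictive R^2 is the empirical variance fraction
    ``Var(Gw) / (Var(Gw) + sigma_e^2)`` with the expression-noise variance
    ``sigma_e^2`` chosen so R^2 centres on ``target_r2``.
    """
    rng = s.rng() if rng is None else rng
    lo = gene_index * s.snps_per_gene
    cols = np.arange(lo, lo + s.snps_per_gene)
    nz = rng.random(s.snps_per_gene) < s.weight_sparsity
    if not nz.any():
        nz = rng.random(s.snps_per_gene) < s.weight_sparsity
        if not nz.any():
            raise ValueError("all weights pruned twice; increase weight_sparsity")
    weights = np.zeros(s.snps_per_gene)
    weights[nz] = rng.standard_normal(int(nz.sum()))
    if not np.any(weights != 0):
        weights[np.argmax(nz)] = 1.0  # degenerate normal draw of exactly 0
    keep = weights != 0.0
    cols = cols[keep]
    weights = weights[keep]
    score = g.dosages[:, cols] @ weights
    var_gw = float(np.var(score))
    if var_gw <= 0:
        raise ValueError("genetic score has zero variance; monomorphic gene")
    sigma2_e = var_gw * (1.0 - s.target_r2) / s.target_r2
    r2 = var_gw / (var_gw + sigma2_e)
    sub = g.variants.iloc[cols]
    return WeightSet(
        gene_id=f"gene{gene_index:03d}",
        variant_ids=sub["variant_id"].tolist(),
        effect_alleles=sub["effect_allele"].tolist(),
        other_alleles=sub["other_allele"].tolist(),
        weights=weights,
        predictive_r2=float(r2),
    )


def _covariates(s: SimScenario, n: int, rng: np.random.Generator,
                offset: int) -> pd.DataFrame:
    a = (18.5 - s.bmi_mean) / s.bmi_sd
    bmi_raw = truncnorm.rvs(a, np.inf, loc=s.bmi_mean, scale=s.bmi_sd,
                            size=n, random_state=rng)
    bmi = bmi_raw / 5.0
    p_diab = expit(s.diabetes_intercept + s.diabetes_bmi_slope * (bmi - s.bmi_mean / 5.0))
    df = pd.DataFrame({
        "sample_id": [f"s{offset + i:06d}" for i in range(n)],
        "bmi": bmi,
        "diabetes": (rng.random(n) < p_diab).astype(float),
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "age": rng.normal(s.age_mean, s.age_sd, size=n),
        "study": [f"study{k:02d}" for k in rng.integers(0, s.n_studies, size=n)],
    })
    for k in range(s.n_pcs):
        df[f"pc{k + 1}"] = rng.normal(0.0, 1.0, size=n)
    return df


def _linear_predictor(
    s: SimScenario,
    cov: pd.DataFrame,
    xhat: np.ndarray,
    dose_causal: np.ndarray,
    u: np.ndarray,
    study_shifts: np.ndarray,
    snp_dose: np.ndarray | None = None,
) -> np.ndarray:
    e = cov[s.exposure].to_numpy(dtype=float)
    study_idx = cov["study"].str.slice(5).astype(int).to_numpy()
    eta = (
        study_shifts[study_idx]
        + s.beta_age * (cov["age"].to_numpy(dtype=float) - s.age_mean)
        + s.beta_sex * (cov["sex"] == "female").to_numpy(dtype=float)
        + s.beta_pc * cov[[f"pc{k + 1}" for k in range(s.n_pcs)]].to_numpy().sum(axis=1)
        + s.beta_E * e
        + s.beta_g * xhat
        + s.tau * xhat * e
    )
    if s.theta > 0:
        eta = eta + (dose_causal @ u) * e
    if snp_dose is not None and s.snp_interaction_beta != 0.0:
        eta = eta + s.snp_interaction_beta * snp_dose * e
    return eta


def simulate_cohort(
    s: SimScenario,
) -> tuple[GenotypeMatrix, CohortTable, list[WeightSet]]:
    """Simulate a retrospectively sampled case-control cohort.

    A population is generated in chunks until the requested numbers of cases
    and controls exist; the baseline log-odds is calibrated by root-finding
    so the population prevalence matches the scenario target.  Burden
    (``tau``) and dispersed (``theta``) interaction effects act on
    ``causal_gene`` only.  All randomness flows from the scenario seed.
    """
    rng = s.rng()
    mafs = _gene_mafs(s, rng)
    # weight blueprints come from a dedicated genotype draw so chunked
    # population generation cannot shift them
    g_ref = simulate_genotypes(s, n_samples=2000, rng=rng, mafs=mafs)
    weight_sets = [simulate_weight_set(s, g_ref, gi, rng) for gi in range(s.n_genes)]
    u = (rng.normal(0.0, math.sqrt(s.theta), size=s.snps_per_gene)
         if s.theta > 0 else np.zeros(s.snps_per_gene))
    study_shifts = rng.normal(0.0, s.study_sd, size=s.n_studies)

    ws_causal = weight_sets[s.causal_gene]
    vindex = {v: j for j, v in enumerate(g_ref.variants["variant_id"])}
    causal_cols = np.arange(s.causal_gene * s.snps_per_gene,
                            (s.causal_gene + 1) * s.snps_per_gene)
    wcols = np.array([vindex[v] for v in ws_causal.variant_ids])
    wvec = ws_causal.weights
    # targeted single-SNP interaction acts on one of the causal gene's eQTLs
    snp_col = (wcols[s.snp_interaction_index % len(wcols)]
               if s.snp_interaction_beta != 0.0 else None)

    need_cases, need_controls = s.n_cases, s.n_controls
    chunk = int(1.3 * max(need_cases / s.prevalence,
                          need_controls / (1.0 - s.prevalence)))
    alpha0: float | None = None
    kept_g, kept_cov, kept_y = [], [], []
    n_cases = n_controls = 0
    offset = 0
    for attempt in range(6):
        g_chunk = simulate_genotypes(s, n_samples=chunk, rng=rng, mafs=mafs,
                                     sample_offset=offset)
        cov = _covariates(s, chunk, rng, offset)
        offset += chunk
        xhat = g_chunk.dosages[:, wcols] @ wvec
        dose_causal = g_chunk.dosages[:, causal_cols]
        eta = _linear_predictor(
            s, cov, xhat, dose_causal, u, study_shifts,
            snp_dose=None if snp_col is None else g_chunk.dosages[:, snp_col],
        )
        if alpha0 is None:
            alpha0 = _calibrate_intercept(eta, s.prevalence)
        y = (rng.random(chunk) < expit(alpha0 + eta)).astype(int)
        kept_g.append(g_chunk.dosages)
        kept_cov.append(cov)
        kept_y.append(y)
        n_cases += int(y.sum())
        n_controls += int((1 - y).sum())
        if n_cases >= need_cases and n_controls >= need_controls:
            break
    else:
        raise RuntimeError(
            f"could not accumulate {need_cases} cases / {need_controls} controls"
        )

    dosages = np.concatenate(kept_g, axis=0)
    cov = pd.concat(kept_cov, ignore_index=True)
    y = np.concatenate(kept_y)
    case_idx = np.flatnonzero(y == 1)[:need_cases]
    control_idx = np.flatnonzero(y == 0)[:need_controls]
    sel = np.concatenate([case_idx, control_idx])
    sel = sel[np.argsort(sel, kind="stable")]

    cov = cov.iloc[sel].reset_index(drop=True)
    cov.insert(1, "outcome", y[sel])
    genotypes = GenotypeMatrix(
        sample_ids=cov["sample_id"].tolist(),
        variants=simulate_genotypes(s, n_samples=1, rng=np.random.default_rng(0),
                                    mafs=mafs).variants,
        dosages=dosages[sel],
    )
    cohort = CohortTable(data=cov)
    return genotypes, cohort, weight_sets


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Root-find the baseline log-odds giving the target mean risk."""
    def f(a: float) -> float:
        return float(np.mean(expit(a + eta))) - prevalence

    lo, hi = -30.0, 10.0
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError("prevalence calibration failed to bracket a root")
    return float(brentq(f, lo, hi, xtol=1e-10))


def write_fixture_bundle(s: SimScenario, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a cohort and write it as a loadable file bundle.

    Emits ``dosages.tsv``, ``weights.tsv``, ``genes.tsv``, ``phenotypes.tsv``
    and ``manifest.json`` (the scenario plus seed).  The same seed reproduces
    the bundle byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes, cohort, weight_sets = simulate_cohort(s)
    paths = {
        "dosages": out / "dosages.tsv",
        "weights": out / "weights.tsv",
        "genes": out / "genes.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "manifest": out / "manifest.json",
    }
    data_io.write_dosage_matrix(genotypes, paths["dosages"])
    data_io.write_weight_sets(weight_sets, paths["weights"], paths["genes"])
    data_io.write_phenotypes(cohort, paths["phenotypes"])
    manifest = {"scenario": dataclasses.asdict(s)}
    manifest["scenario"]["maf_range"] = list(s.maf_range)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote fixture bundle to %s", out)
    return paths
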