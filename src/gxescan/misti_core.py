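"""Set-based mixed-effects score tests of gene-environment interaction.

For one gene with eQTL dosages ``G`` (n x m), predicted expression
``x = G w`` and exposure ``E``, the interaction with case-control outcome
``y`` is decomposed into two components under a logistic model:

fixed (burden-type) component
    A 1-df score test of the ``x * E`` term added to the null model
    ``logit P(y=1) = covariates + E + x``.  The score is
    ``U = sum_i (y_i - mu_i) s_i`` with ``s_i = x_i E_i``; its efficient
    variance projects the null-model columns out of ``s`` under the IRLS
    weights ``mu (1 - mu)``, and ``U^2 / V`` is referred to chi-square(1).

random (variance-component) component
    A SKAT-type test of residual per-SNP interactions ``E * G_j`` not
    captured by the burden term.  The null model here *includes* the fixed
    interaction term, which renders the two component p-values
    asymptotically independent.  ``Q = || C'(y - mu) ||^2`` with columns
    ``C_j = E * G_j``; its null law is a mixture of chi-squares with weights
    given by the eigenvalues of ``C' P C``, where
    ``P = W - W X (X' W X)^{-1} X' W``.

The two p-values are combined either by Fisher's rule (chi-square(4)) or by
a data-adaptive grid of log-weighted combinations whose minimum-p statistic
is referred to its exact null distribution under independent uniforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.special import expit, xlogy
from scipy.stats import chi2, ncx2

from .expression import harmonize_alleles, predict_expression
from .types import CohortTable, GeneResult, GenotypeMatrix, PredictedExpression, WeightSet

logger = logging.getLogger("gxescan.misti_core")

__all__ = [
    "NullFit",
    "ComponentResult",
    "ConvergenceError",
    "SeparationError",
    "RankDeficiencyError",
    "build_design",
    "irls_logistic",
    "fit_null_logistic",
    "fixed_effect_score_test",
    "random_effect_score_test",
    "mixture_chisq_pvalue",
    "combine_components",
    "test_gene",
]

P_FLOOR = 1e-300
ADAPTIVE_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


class SeparationError(ConvergenceError):
    """Coefficients diverged, indicating (quasi-)complete separation."""


class RankDeficiencyError(ValueError):
    """Design matrix rank-deficient beyond droppable study indicators."""


@dataclass
class NullFit:
    """Converged logistic null model.

    Holds the design matrix and fitted probabilities needed by the score
    tests; ``mu`` is clipped away from {0, 1}.
    """

    X: np.ndarray
    y: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    loglik: float
    converged: bool
    column_names: list[str]

    @property
    def weights(self) -> np.ndarray:
        return self.mu * (1.0 - self.mu)


@dataclass
class ComponentResult:
    """Score statistic, variance and p-value of one interaction component."""

    u_stat: float
    variance: float
    p_value: float
    q_stat: float | None = None
    eigenvalues: np.ndarray | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# logistic null model
# ---------------------------------------------------------------------------

def build_design(
    cohort: CohortTable,
    exposure: str,
    xhat: PredictedExpression | None = None,
    include_sex: bool = False,
    include_interaction: bool = False,
    n_pcs: int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the null-model design matrix.

    Columns: intercept, age, optional female indicator, study indicators
    (first study is the reference; indicators that are collinear with the
    rest of the design are dropped), principal components, the exposure E,
    the predicted-expression main effect and optionally the fixed
    interaction term ``x * E``.
    """
    df = cohort.data
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    cols.append(df["age"].to_numpy(dtype=float))
    names.append("age")
    if include_sex:
        cols.append((df["sex"].astype(str) == "female").to_numpy(dtype=float))
        names.append("sex_female")
    studies = sorted(df["study"].astype(str).unique())
    for s in studies[1:]:
        cols.append((df["study"].astype(str) == s).to_numpy(dtype=float))
        names.append(f"study_{s}")
    pc_cols = cohort.pc_columns
    if n_pcs is not None:
        pc_cols = pc_cols[:n_pcs]
    for c in pc_cols:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    e = cohort.exposure(exposure)
    # constant E or x-hat carries no information; dropping it here lets the
    # score tests report their degenerate p = 1 instead of a rank error
    if np.ptp(e) > 0:
        cols.append(e)
        names.append(f"E_{exposure}")
    else:
        logger.warning("exposure %s is constant; omitted from the design", exposure)
    if xhat is not None:
        if np.ptp(xhat.values) > 0:
            cols.append(xhat.values)
            names.append("xhat")
        else:
            logger.warning("predicted expression is constant; omitted from design")
        if include_interaction and np.ptp(xhat.values * e) > 0:
            cols.append(xhat.values * e)
            names.append("xhat_x_E")
    X = np.column_stack(cols)
    return _drop_collinear(X, names)


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop linearly dependent study indicators; anything else dependent raises."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank == X.shape[1]:
        return X, names
    dependent = sorted(piv[rank:])
    bad = [names[j] for j in dependent if not names[j].startswith("study_")]
    if bad:
        raise RankDeficiencyError(f"design matrix rank-deficient in columns {bad}")
    keep = [j for j in range(X.shape[1]) if j not in set(dependent)]
    logger.debug("dropped collinear study indicators: %s",
                 [names[j] for j in dependent])
    return X[:, keep], [names[j] for j in keep]


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    coef_bound: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Fit logistic regression by iteratively reweighted least squares.

    Returns ``(beta, mu, loglik, converged)``.  Raises
    :class:`SeparationError` when any coefficient exceeds ``coef_bound`` (a
    symptom of complete separation) and :class:`ConvergenceError` when the
    coefficient change does not fall below ``tol`` within ``max_iter``
    iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ybar = min(max(y.mean(), 1e-8), 1 - 1e-8)
    beta[0] = math.log(ybar / (1 - ybar)) if np.allclose(X[:, 0], 1.0) else 0.0
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ xw, xw.T @ z)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
            raise RankDeficiencyError("weighted normal equations singular") from exc
        if np.max(np.abs(beta_new)) > coef_bound:
            raise SeparationError(
                "coefficient magnitude exceeded bound; likely complete "
                "separation - drop this term/gene"
            )
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    loglik = float(np.sum(xlogy(y, mu) + xlogy(1 - y, 1 - mu)))
    return beta, mu, loglik, converged


def fit_null_logistic(
    cohort: CohortTable,
    xhat: PredictedExpression | None,
    exposure: str,
    include_fixed_interaction: bool = False,
    include_sex: bool = False,
    n_pcs: int | None = None,
) -> NullFit:
    """Fit the logistic null model for the interaction score tests."""
    y = cohort.data["outcome"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("null fit requires at least one case and one control")
    X, names = build_design(
        cohort, exposure, xhat,
        include_sex=include_sex,
        include_interaction=include_fixed_interaction,
        n_pcs=n_pcs,
    )
    beta, mu, loglik, converged = irls_logistic(X, y)
    return NullFit(X=X, y=y, beta=beta, mu=mu, loglik=loglik,
                   converged=converged, column_names=names)


# ---------------------------------------------------------------------------
# score tests
# ---------------------------------------------------------------------------

def _project_out(fit: NullFit, cols: np.ndarray) -> np.ndarray:
    """Weighted residual of ``cols`` after projecting out the null design.

    Returns ``sqrt(W) cols - sqrt(W) X (X'WX)^{-1} X'W cols`` so that the
    squared column norms are efficient score variances.
    """
    sw = np.sqrt(fit.weights)
    xw = fit.X * sw[:, None]
    cw = cols * sw[:, None]
    coefs, *_ = np.linalg.lstsq(xw, cw, rcond=None)
    return cw - xw @ coefs


def fixed_effect_score_test(fit: NullFit, s: np.ndarray) -> ComponentResult:
    """1-df score test of the burden interaction term ``s = x * E``.

    ``fit`` must be the null model *without* the interaction term.  A
    variance at numerical zero (e.g. constant exposure) yields the
    degenerate result ``p = 1``.
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("interaction term contains non-finite values")
    u = float((fit.y - fit.mu) @ s)
    resid = _project_out(fit, s[:, None])[:, 0]
    v = float(resid @ resid)
    if v <= 1e-12:
        return ComponentResult(u_stat=u, variance=v, p_value=1.0, degenerate=True)
    stat = u * u / v
    p = float(np.clip(chi2.sf(stat, df=1), P_FLOOR, 1.0))
    return ComponentResult(u_stat=u, variance=v, p_value=p)


def random_effect_score_test(fit: NullFit, c_matrix: np.ndarray) -> ComponentResult:
    """Variance-component score test of residual SNP-level interactions.

    ``fit`` must be the null model fitted *with* the fixed interaction term;
    ``c_matrix`` holds one column ``E * G_j`` per SNP.  The statistic
    ``Q = ||C'(y - mu)||^2`` is referred to its mixture-of-chi-squares null
    with weights from the eigenvalues of ``C' P C``.
    """
    c_matrix = np.asarray(c_matrix, dtype=float)
    if c_matrix.ndim != 2 or c_matrix.shape[1] < 1:
        raise ValueError("c_matrix must be n x m with m >= 1")
    u = c_matrix.T @ (fit.y - fit.mu)
    q = float(u @ u)
    m = _project_out(fit, c_matrix)
    k = m.T @ m
    lam = np.linalg.eigvalsh(k)
    lam = np.where(lam < 0, 0.0, lam)
    # scale for "numerically zero": the pre-projection weighted column energy;
    # columns lying in the null design leave only round-off behind
    scale = float(np.sum(fit.weights[:, None] * c_matrix**2))
    if lam.max(initial=0.0) <= 1e-12 * max(scale, 1.0):
        return ComponentResult(u_stat=q, variance=0.0, p_value=1.0,
                               q_stat=q, eigenvalues=lam, degenerate=True)
    lam = lam[lam > 1e-8 * lam.max()]
    p = mixture_chisq_pvalue(q, lam)
    return ComponentResult(u_stat=q, variance=float(lam.sum()), p_value=p,
                           q_stat=q, eigenvalues=np.sort(lam)[::-1])


# ---------------------------------------------------------------------------
# mixture-of-chi-squares tail
# ---------------------------------------------------------------------------

def _imhof_pvalue(q: float, lam: np.ndarray, epsabs: float = 1e-9) -> tuple[float, float]:
    """Tail probability P(sum lam_k Z_k^2 > q) by characteristic-function
    inversion (Imhof's integral)."""

    def theta(u: float) -> float:
        return 0.5 * float(np.sum(np.arctan(lam * u))) - 0.5 * q * u

    def rho(u: float) -> float:
        return float(np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2))))

    def integrand(u: float) -> float:
        return math.sin(theta(u)) / (u * rho(u))

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(integrand, 0.0, np.inf, epsabs=epsabs,
                                  epsrel=1e-10, limit=500)
    return 0.5 + val / math.pi, err


def _ruben_pvalue(q: float, lam: np.ndarray, max_terms: int = 8000) -> float | None:
    """Mixture tail as a Ruben series of central chi-square tails.

    P(sum lam_k Z_k^2 > q) = sum_j a_j P(chi2_{k + 2j} > q / beta) with
    beta = 2 lam_min lam_max / (lam_min + lam_max) and coefficients from
    Ruben's recursion.  The coefficients sum to one, which gives a built-in
    truncation check; returns None when the series cannot reach ~1e-12
    accuracy within ``max_terms`` (caller falls back to integration).
    """
    lmin, lmax = float(lam.min()), float(lam.max())
    beta = 2.0 * lmin * lmax / (lmin + lmax)
    c = 1.0 - beta / lam
    r = float(np.max(np.abs(c)))
    if r >= 1.0:
        return None
    n_terms = int(math.ceil(math.log(1e-13) / math.log(r))) + 10
    if n_terms > max_terms:
        return None
    k = lam.size
    a = np.empty(n_terms + 1)
    a[0] = math.exp(0.5 * float(np.sum(np.log(beta / lam))))
    # b_j = sum_i c_i^j, built incrementally
    b = np.empty(n_terms + 1)
    c_pow = np.ones_like(c)
    for j in range(1, n_terms + 1):
        c_pow = c_pow * c
        b[j] = float(np.sum(c_pow))
    for j in range(1, n_terms + 1):
        a[j] = float(b[1:j + 1][::-1] @ a[:j]) / (2.0 * j)
    mass = float(a.sum())
    if abs(mass - 1.0) > 1e-9 or not np.all(np.isfinite(a)):
        return None
    dfs = k + 2 * np.arange(n_terms + 1)
    tails = chi2.sf(q / beta, dfs)
    return float(a @ tails)


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Four-moment (Liu-Tang-Zhang) approximation to the mixture tail."""
    c1 = float(np.sum(lam))
    c2 = float(np.sum(lam**2))
    c3 = float(np.sum(lam**3))
    c4 = float(np.sum(lam**4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = math.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    if s1**2 > s2:
        a = 1 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1 / s2
        a = math.sqrt(df)
    mu_x = df + delta
    sigma_x = math.sqrt(2) * a
    x = t_star * sigma_x + mu_x
    if delta > 0:
        return float(ncx2.sf(x, df, delta))
    return float(chi2.sf(x, df))


def mixture_chisq_pvalue(q: float, lambdas: np.ndarray) -> float:
    """P(sum_k lambda_k Z_k^2 > q) for independent standard normals Z_k.

    Uses Imhof characteristic-function inversion with absolute accuracy
    about 1e-9, falling back to a four-moment match when the integration is
    unreliable.  The result is clipped to (1e-300, 1].
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.size == 0 or np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative and nonempty")
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("at least one eigenvalue must be positive")
    if q <= 0:
        return 1.0
    if np.ptp(lam) <= 1e-12 * lam[0]:
        # equal weights: exact chi-square tail, no integration needed
        return float(np.clip(chi2.sf(q / lam[0], df=lam.size), P_FLOOR, 1.0))
    p = _ruben_pvalue(q, lam)
    if p is None:
        try:
            p, err = _imhof_pvalue(q, lam)
        except Exception:  # pragma: no cover - quad failure
            p, err = np.nan, np.inf
        if not np.isfinite(p) or err > 1e-4 or p < -1e-8 or p > 1 + 1e-8:
            p = _liu_pvalue(q, lam)
    return float(np.clip(p, P_FLOOR, 1.0))


# ---------------------------------------------------------------------------
# combining the two components
# ---------------------------------------------------------------------------

def _exp_mix_tail(s: float, w: float) -> float:
    """P(w X + (1-w) Y > s) for independent standard exponentials X, Y."""
    if s <= 0:
        return 1.0
    a, b = w, 1.0 - w
    if a == 0.0:
        return math.exp(-s / b)
    if b == 0.0:
        return math.exp(-s / a)
    if abs(a - b) < 1e-12:
        r = s / a
        return math.exp(-r) * (1.0 + r)
    return (a * math.exp(-s / a) - b * math.exp(-s / b)) / (a - b)


def _exp_mix_tail_inverse(m: float, w: float) -> float:
    """Solve ``_exp_mix_tail(s, w) = m`` for s (tail is strictly decreasing)."""
    if m >= 1.0:
        return 0.0
    hi = 800.0 * max(w, 1.0 - w)
    if _exp_mix_tail(hi, w) >= m:
        return hi
    return float(optimize.brentq(lambda s: _exp_mix_tail(s, w) - m, 0.0, hi,
                                 xtol=1e-13, rtol=1e-14))


def _grid_min_pvalue(m: float, grid: tuple[float, ...]) -> float:
    """P(min_w p_w <= m) for independent uniform component p-values.

    Writing x = -ln p_fix and y = -ln p_ran (independent exponentials), the
    event 'all per-weight p-values exceed m' is the region below the lines
    ``w x + (1-w) y <= t_w`` with ``t_w`` the per-weight tail inverses; its
    complement's probability is accumulated as a sum of positive terms so
    small combined p-values keep full relative accuracy.
    """
    if m >= 1.0:
        return 1.0
    if m <= 0.0:
        return 0.0
    t = {w: _exp_mix_tail_inverse(m, w) for w in grid}
    interior = [w for w in grid if 0.0 < w < 1.0]
    x_hi = t.get(1.0, np.inf)

    def y_bound(x: float) -> float:
        y = t.get(0.0, np.inf)
        for w in interior:
            y = min(y, (t[w] - w * x) / (1.0 - w))
        return y

    # the active constraint changes at intersections of the bounding lines
    lines = [(0.0, t.get(0.0, np.inf))] + [(w, t[w]) for w in interior]
    breaks = set()
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            w1, t1 = lines[i]
            w2, t2 = lines[j]
            den = w1 * (1.0 - w2) - w2 * (1.0 - w1)
            if abs(den) > 1e-12:
                x = (t1 * (1.0 - w2) - t2 * (1.0 - w1)) / den
                if 0.0 < x < x_hi:
                    breaks.add(x)
    for w, tw in lines:  # where a bound crosses zero
        if w > 0:
            x = tw / w
            if 0.0 < x < x_hi:
                breaks.add(x)

    def integrand(x: float) -> float:
        y = y_bound(x)
        return math.exp(-x - max(y, 0.0)) if np.isfinite(y) else 0.0

    if np.isfinite(x_hi):
        tail_x = math.exp(-x_hi)
        val, _ = integrate.quad(integrand, 0.0, x_hi, epsabs=1e-12,
                                epsrel=1e-10, limit=300,
                                points=sorted(breaks) if breaks else None)
    else:  # pragma: no cover - grid always contains w=1
        tail_x = 0.0
        val, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-12, limit=300)
    return float(np.clip(tail_x + val, P_FLOOR, 1.0))


def combine_components(
    p_fix: float,
    p_ran: float,
    method: str = "adaptive_grid",
    grid: tuple[float, ...] = ADAPTIVE_GRID,
) -> tuple[float, float]:
    """Combine the two component p-values into one gene-level p-value.

    ``fisher`` refers ``-2 (ln p_fix + ln p_ran)`` to chi-square(4), valid
    because the components are asymptotically independent by construction.
    ``adaptive_grid`` (default) scans weights ``w`` over the grid, computes
    the exact tail p of ``-2 (w ln p_fix + (1-w) ln p_ran)`` for each, takes
    the minimum, and returns the exact null probability of that minimum
    under independent uniforms.  Returns ``(p_combined, chosen_weight)``;
    for Fisher the reported weight is 0.5.
    """
    for name, p in (("p_fix", p_fix), ("p_ran", p_ran)):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{name}={p} outside (0, 1]")
    x = -math.log(max(p_fix, P_FLOOR))
    y = -math.log(max(p_ran, P_FLOOR))
    if method == "fisher":
        t = 2.0 * (x + y)
        return float(np.clip(chi2.sf(t, df=4), P_FLOOR, 1.0)), 0.5
    if method != "adaptive_grid":
        raise ValueError(f"unknown combination method {method!r}")
    per_w = [(_exp_mix_tail(w * x + (1.0 - w) * y, w), w) for w in grid]
    m, chosen = min(per_w, key=lambda t: (t[0], t[1]))
    return _grid_min_pvalue(m, grid), chosen


# ---------------------------------------------------------------------------
# whole-gene test
# ---------------------------------------------------------------------------

def test_gene(
    ws: WeightSet,
    g: GenotypeMatrix,
    cohort: CohortTable,
    exposure: str,
    include_sex: bool = False,
    n_pcs: int | None = None,
    combiner: str = "adaptive_grid",
    stratum: str = "all",
    harmonize: bool = True,
) -> GeneResult:
    """Run the full per-gene interaction test.

    Pipeline: harmonize alleles -> predict expression -> fit the null model
    -> fixed-component score test -> refit with the fixed interaction term
    -> random-component score test -> adaptive combination.
    """
    if harmonize:
        ws = harmonize_alleles(ws, g)
    xhat = predict_expression(ws, g)
    e = cohort.exposure(exposure)
    fit0 = fit_null_logistic(cohort, xhat, exposure,
                             include_fixed_interaction=False,
                             include_sex=include_sex, n_pcs=n_pcs)
    fixed = fixed_effect_score_test(fit0, xhat.values * e)
    fit1 = fit_null_logistic(cohort, xhat, exposure,
                             include_fixed_interaction=True,
                             include_sex=include_sex, n_pcs=n_pcs)
    index = g.variant_index()
    cols = [index[v] for v in ws.variant_ids if v in index]
    dose = g.dosages[:, cols]
    cmpl = np.asarray([c for v, c in zip(ws.variant_ids, ws.dosage_complement)
                       if v in index], dtype=bool)
    if cmpl.any():
        dose = np.where(cmpl[None, :], 2.0 - dose, dose)
    random_res = random_effect_score_test(fit1, dose * e[:, None])
    p_adaptive, weight = combine_components(fixed.p_value, random_res.p_value,
                                            method=combiner)
    return GeneResult(
        gene_id=ws.gene_id,
        stratum=stratum,
        n_snps=xhat.n_snps_used,
        predictive_r2=ws.predictive_r2,
        p_fixed=fixed.p_value,
        p_random=random_res.p_value,
        p_adaptive=p_adaptive,
        chosen_weight=weight,
    )
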