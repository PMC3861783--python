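"""Two-phase sampling frames and joint estimators for a rare-variant burden.

Phase 1 is a parent case-control GWAS: disease ``Y`` and common-SNP
genotypes on ``N`` subjects, summarized into a risk-index stratum ``V``
(low/medium/high, cut at the 25th and 75th percentiles of a multiple
logistic risk score).  Phase 2 sequences a subsample selected on (Y, V) and
measures the expensive covariate ``X`` — here the Madsen-Browning burden
index, the count of rare alleles weighted by 1/sqrt(allele frequency).

Four estimators of the burden log-odds ratio are provided, in increasing
order of statistical efficiency:

* **imputation** — regress X on V in the subsample, carry the prediction
  (observed X where measured) into a full-cohort logistic fit;
* **weighted likelihood (WL)** — Horvitz-Thompson weighted logistic score
  equation with weights ``N_yv / n_yv``;
* **pseudo-likelihood (PL)** — Breslow-Cain offset logistic regression on
  the subsample with fixed stratum offsets ``log(n1v/n0v) - log(N1v/N0v)``;
* **semiparametric maximum likelihood (SPML)** — profile likelihood for the
  full two-phase model, leaving X|V nonparametric, maximized by iterating a
  logistic fit with stratum offsets against nuisance-probability constraint
  updates.

All four collapse to the ordinary complete-data logistic MLE when the
subsample is the whole cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy import stats

from .disease_models import Cohort

__all__ = [
    "RiskIndex",
    "TwoPhaseData",
    "EstimateResult",
    "gwas_gate",
    "fit_risk_index",
    "madsen_browning_index",
    "draw_subsample",
    "make_two_phase_data",
    "estimate_complete",
    "estimate_imputation",
    "estimate_wl",
    "estimate_pl",
    "estimate_spml",
    "spml_profile_loglik",
    "wald_test",
]


# ---------------------------------------------------------------------------
# Phase-1 machinery: GWAS gate and risk index
# ---------------------------------------------------------------------------


def allelic_test_pvalues(genotypes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided allelic (2x2 allele count) association p-value per SNP."""
    y = np.asarray(y)
    g1 = genotypes[y == 1]
    g0 = genotypes[y == 0]
    n1, n0 = 2.0 * g1.shape[0], 2.0 * g0.shape[0]
    p1 = g1.sum(axis=0) / n1
    p0 = g0.sum(axis=0) / n0
    pbar = (g1.sum(axis=0) + g0.sum(axis=0)) / (n1 + n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
        z = np.where(se > 0, (p1 - p0) / se, 0.0)
    return 2 * stats.norm.sf(np.abs(z))


def gwas_gate(
    cohort: Cohort,
    maf_common: float = 0.05,
    alpha: float = 0.05,
):
    """Retain a replicate only if a common SNP reaches Bonferroni-adjusted
    significance in the parent case-control sample.

    Returns ``(passed, significant_snp_indices, common_snp_indices)``.
    """
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must lie in [0, 1]")
    maf = cohort.pop.maf
    common = np.flatnonzero(maf > maf_common)
    if common.size == 0:
        raise ValueError("no common SNPs in region")
    g = cohort.genotypes(common)
    pvals = allelic_test_pvalues(g, cohort.y)
    thresh = alpha / common.size
    sig = common[pvals < thresh]
    return sig.size > 0, sig, common


@dataclass
class RiskIndex:
    """Logistic risk score on non-redundant common SNPs, cut into 3 strata."""

    linear_predictor: np.ndarray
    stratum: np.ndarray  # 0 low, 1 medium, 2 high
    snp_idx: np.ndarray
    coef: np.ndarray
    n_strata: int = 3


def _prune_r2(g: np.ndarray, order: np.ndarray, r2_threshold: float) -> np.ndarray:
    """Greedy LD pruning: walk SNPs in ``order``, keep those with max r^2
    below threshold against every SNP already kept."""
    kept: list[int] = []
    gs = g.astype(float)
    sd = gs.std(axis=0)
    for j in order:
        if sd[j] == 0:
            continue
        ok = True
        for k in kept:
            r = np.corrcoef(gs[:, j], gs[:, k])[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.array(kept, dtype=int)


def fit_risk_index(
    cohort: Cohort,
    snp_set: np.ndarray,
    r2_threshold: float = 0.8,
    cutpoints: tuple[float, float] = (25.0, 75.0),
) -> RiskIndex:
    """Multiple logistic regression of disease on pruned common SNPs.

    The linear predictor is cut at the 25th/75th percentiles into low,
    medium, and high risk strata.  Separation or non-convergence falls back
    to an L2-penalized fit; a constant predictor collapses to a single
    'medium' stratum.
    """
    snp_set = np.asarray(snp_set)
    if snp_set.size == 0:
        raise ValueError("snp_set must be non-empty")
    g_all = cohort.genotypes(snp_set).astype(float)
    pv = allelic_test_pvalues(g_all, cohort.y)
    order = np.argsort(pv)
    kept = _prune_r2(g_all, order, r2_threshold)
    if kept.size == 0:
        lp = np.zeros(cohort.n)
        return RiskIndex(lp, np.ones(cohort.n, dtype=int), snp_set[:0], np.zeros(0))
    g = g_all[:, kept]
    X = np.column_stack([np.ones(cohort.n), g])
    beta, _, converged = _logistic_irls(X, cohort.y.astype(float))
    if not converged or not np.all(np.isfinite(beta)):
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(g, cohort.y)
        beta = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    lp = X @ beta
    if np.ptp(lp) == 0:
        return RiskIndex(lp, np.ones(cohort.n, dtype=int), snp_set[kept], beta[1:])
    lo, hi = np.percentile(lp, cutpoints)
    stratum = np.ones(cohort.n, dtype=int)
    stratum[lp < lo] = 0
    stratum[lp >= hi] = 2
    return RiskIndex(lp, stratum, snp_set[kept], beta[1:])


def madsen_browning_index(
    genotypes: np.ndarray, maf: np.ndarray, rare_threshold: float = 0.05
) -> np.ndarray:
    """Burden index: X_i = sum over rare variants of g_iv / sqrt(q_v)."""
    if not (0 < rare_threshold <= 0.5):
        raise ValueError("rare_threshold must lie in (0, 0.5]")
    maf = np.asarray(maf, dtype=float)
    rare = maf < rare_threshold
    q = maf[rare]
    if np.any(q <= 0):
        raise ValueError("zero allele frequency in the weight set")
    g = np.asarray(genotypes, dtype=float)[:, rare]
    return g @ (1.0 / np.sqrt(q))


def control_reference_maf(cohort: Cohort, floor: float | None = None) -> np.ndarray:
    """Allele frequencies in the parent-study controls, floored at
    1/(2 n_controls) so that observed-in-cases-only variants keep a finite
    Madsen-Browning weight."""
    ctrl = np.flatnonzero(cohort.y == 0)
    g = cohort.genotypes()[ctrl]
    q = g.sum(axis=0) / (2.0 * ctrl.size)
    if floor is None:
        floor = 1.0 / (2.0 * ctrl.size)
    return np.minimum(np.maximum(q, floor), 1 - floor)


# ---------------------------------------------------------------------------
# Two-phase frame
# ---------------------------------------------------------------------------


@dataclass
class TwoPhaseData:
    """Full-study (Y, V) table plus the sequenced subsample with its X."""

    y_full: np.ndarray
    v_full: np.ndarray
    sub_idx: np.ndarray
    x_sub: np.ndarray
    adj_full: np.ndarray | None = None
    N_yv: np.ndarray = field(default=None)  # (2, n_strata)
    n_yv: np.ndarray = field(default=None)
    weights: np.ndarray = field(default=None)  # per subsample subject
    n_strata: int = 3

    @property
    def y_sub(self) -> np.ndarray:
        return self.y_full[self.sub_idx]

    @property
    def v_sub(self) -> np.ndarray:
        return self.v_full[self.sub_idx]

    @property
    def adj_sub(self) -> np.ndarray | None:
        return None if self.adj_full is None else self.adj_full[self.sub_idx]

    def is_full(self) -> bool:
        return self.sub_idx.size == self.y_full.size


def _cell_counts(y, v, n_strata):
    N = np.zeros((2, n_strata))
    for yy in (0, 1):
        for vv in range(n_strata):
            N[yy, vv] = np.sum((y == yy) & (v == vv))
    return N


def make_two_phase_data(
    y_full, v_full, sub_idx, x_sub, adj_full=None, n_strata: int = 3
) -> TwoPhaseData:
    y_full = np.asarray(y_full)
    v_full = np.asarray(v_full)
    sub_idx = np.asarray(sub_idx)
    N_yv = _cell_counts(y_full, v_full, n_strata)
    n_yv = _cell_counts(y_full[sub_idx], v_full[sub_idx], n_strata)
    with np.errstate(divide="ignore", invalid="ignore"):
        Wc = np.where(n_yv > 0, N_yv / np.maximum(n_yv, 1), np.nan)
    weights = Wc[y_full[sub_idx], v_full[sub_idx]]
    return TwoPhaseData(
        y_full, v_full, sub_idx, np.asarray(x_sub, dtype=float), adj_full,
        N_yv, n_yv, weights, n_strata,
    )


def draw_subsample(
    y_full,
    v_full,
    scheme: str = "balanced",
    n_total: int = 600,
    sizes: np.ndarray | None = None,
    seed: int | None = None,
    n_strata: int = 3,
    on_infeasible: str = "truncate",
) -> np.ndarray:
    """Sample subject indices without replacement within (Y, V) cells.

    Schemes: ``case-control`` (n_total/2 cases, n_total/2 controls ignoring
    V), ``balanced`` (n_total / (2 * n_strata) per cell), ``optimal``
    (explicit per-cell ``sizes`` array of shape (2, n_strata)), ``full``
    (everyone).  Requests exceeding a cell are truncated with a warning, or
    raise if ``on_infeasible='raise'``.
    """
    rng = np.random.default_rng(seed)
    y_full = np.asarray(y_full)
    v_full = np.asarray(v_full)
    N_yv = _cell_counts(y_full, v_full, n_strata)
    if scheme == "full":
        return np.arange(y_full.size)
    if scheme == "case-control":
        idx = []
        for yy in (0, 1):
            pool = np.flatnonzero(y_full == yy)
            take = n_total // 2
            if take > pool.size:
                msg = f"requested {take} of {pool.size} subjects with Y={yy}"
                if on_infeasible == "raise":
                    raise ValueError(msg)
                warnings.warn(msg + "; truncating")
                take = pool.size
            idx.append(rng.choice(pool, size=take, replace=False))
        return np.sort(np.concatenate(idx))
    if scheme == "balanced":
        sizes = np.full((2, n_strata), n_total // (2 * n_strata))
    elif scheme == "optimal":
        if sizes is None:
            raise ValueError("scheme 'optimal' requires explicit cell sizes")
        sizes = np.asarray(sizes)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    idx = []
    for yy in (0, 1):
        for vv in range(n_strata):
            pool = np.flatnonzero((y_full == yy) & (v_full == vv))
            take = int(sizes[yy, vv])
            if take > pool.size:
                msg = f"requested {take} of {pool.size} in cell (Y={yy}, V={vv})"
                if on_infeasible == "raise":
                    raise ValueError(msg)
                warnings.warn(msg + "; truncating")
                take = pool.size
            idx.append(rng.choice(pool, size=take, replace=False))
    return np.sort(np.concatenate(idx))


# ---------------------------------------------------------------------------
# Logistic IRLS helper
# ---------------------------------------------------------------------------


def _logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    prior_weights: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
):
    """Newton-Raphson logistic fit.  Returns (beta, info_matrix, converged)."""
    n, k = X.shape
    off = np.zeros(n) if offset is None else offset
    w0 = np.ones(n) if prior_weights is None else prior_weights
    beta = np.zeros(k) if beta0 is None else beta0.copy()
    info = np.eye(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + off
        p = expit(eta)
        wt = w0 * p * (1 - p)
        score = X.T @ (w0 * (y - p))
        info = (X * wt[:, None]).T @ X
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(k), score)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps to survive near-separation
        nrm = np.linalg.norm(step)
        if nrm > 10:
            step *= 10 / nrm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta, info, converged


def _design(x: np.ndarray, adj: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(x.size), x]
    if adj is not None:
        a = np.atleast_2d(np.asarray(adj, dtype=float))
        if a.shape[0] != x.size:
            a = a.T
        cols.append(a)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class EstimateResult:
    """Burden log-odds estimate with its SE and Wald Z."""

    method: str
    beta: float
    se: float
    converged: bool = True
    coef: np.ndarray | None = None
    n_iter: int = 0

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 else np.nan


def wald_test(result: EstimateResult):
    """Two-sided Wald test; returns (Z, p)."""
    if not (result.se > 0):
        raise ValueError("standard error must be positive")
    z = result.beta / result.se
    return z, 2 * stats.norm.sf(abs(z))


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

_X_COL = 1  # index of the burden covariate in the design matrix


def estimate_complete(y, x, adj=None) -> EstimateResult:
    """Ordinary logistic MLE of Y on (X, adjustment) — the complete-data
    reference all two-phase estimators collapse to under full sampling."""
    X = _design(np.asarray(x, dtype=float), adj)
    beta, info, conv = _logistic_irls(X, np.asarray(y, dtype=float))
    cov = np.linalg.inv(info)
    return EstimateResult(
        "complete", beta[_X_COL], np.sqrt(cov[_X_COL, _X_COL]), conv, beta
    )


def estimate_imputation(data: TwoPhaseData) -> EstimateResult:
    """Impute X from V (linear model on the subsample), then logistic fit on
    the full study using observed X where measured and the stratum
    prediction elsewhere; robust (sandwich) SE."""
    n_str = data.n_strata
    v_s = data.v_sub
    for vv in range(n_str):
        if np.sum(v_s == vv) < 2 and np.sum(data.v_full == vv) > 0:
            raise ValueError(f"subsample stratum {vv} has fewer than 2 subjects")
    # X | V (+ adjustment) linear fit on the subsample
    D = np.column_stack(
        [np.eye(n_str)[v_s]]
        + ([np.atleast_2d(data.adj_sub.T).T] if data.adj_sub is not None else [])
    )
    coef, *_ = np.linalg.lstsq(D, data.x_sub, rcond=None)
    D_full = np.column_stack(
        [np.eye(n_str)[data.v_full]]
        + ([np.atleast_2d(data.adj_full.T).T] if data.adj_full is not None else [])
    )
    x_hat = D_full @ coef
    x_hat[data.sub_idx] = data.x_sub
    if np.ptp(data.x_sub) == 0:
        return EstimateResult("imputation", 0.0, np.nan, False)
    X = _design(x_hat, data.adj_full)
    y = data.y_full.astype(float)
    beta, info, conv = _logistic_irls(X, y)
    p = expit(X @ beta)
    U = X * (y - p)[:, None]
    A = np.linalg.inv(info)
    cov = A @ (U.T @ U) @ A
    return EstimateResult(
        "imputation", beta[_X_COL], np.sqrt(cov[_X_COL, _X_COL]), conv, beta
    )


def estimate_wl(data: TwoPhaseData, weight_cap_flag: float = 100.0) -> EstimateResult:
    """Horvitz-Thompson weighted logistic score equation with stratified
    sandwich variance (finite-population corrected)."""
    if np.any(~np.isfinite(data.weights)):
        raise ValueError("sampled stratum with n_yv = 0")
    W = data.weights
    if np.max(W) > weight_cap_flag:
        warnings.warn(
            f"extreme sampling weight {np.max(W):.0f}; WL may be unstable"
        )
    X = _design(data.x_sub, data.adj_sub)
    y = data.y_sub.astype(float)
    beta, info, conv = _logistic_irls(X, y, prior_weights=W)
    p = expit(X @ beta)
    U = X * (W * (y - p))[:, None]
    A = np.linalg.inv(info)
    B = np.zeros((X.shape[1], X.shape[1]))
    for yy in (0, 1):
        for vv in range(data.n_strata):
            cell = (y == yy) & (data.v_sub == vv)
            m = int(cell.sum())
            if m < 2:
                continue
            Uc = U[cell] - U[cell].mean(axis=0)
            fpc = 1.0 - data.n_yv[yy, vv] / max(data.N_yv[yy, vv], 1)
            B += fpc * m / (m - 1) * (Uc.T @ Uc)
    cov = A @ B @ A
    se = np.sqrt(max(cov[_X_COL, _X_COL], 0))
    if se == 0:  # full sampling: fall back to model-based
        se = np.sqrt(np.linalg.inv(info)[_X_COL, _X_COL])
    return EstimateResult("wl", beta[_X_COL], se, conv, beta)


def _pl_offsets(data: TwoPhaseData) -> np.ndarray:
    N, n = data.N_yv, data.n_yv
    if np.any(N <= 0):
        raise ValueError("zero cell in phase-1 table N_yv")
    off_v = np.log(n[1] / np.maximum(n[0], 1e-300)) - np.log(N[1] / N[0])
    return off_v


def estimate_pl(data: TwoPhaseData) -> EstimateResult:
    """Breslow-Cain pseudo-likelihood: offset logistic on the subsample.

    Offsets are the log sampling-odds ratios ``log(n1v/n0v) - log(N1v/N0v)``
    (equivalently, the phase-1 log odds ``log(N1v/N0v)`` inserted into the
    conditional phase-2 model).  Variance is the conditional sandwich plus a
    delta-method term for the estimated phase-1 log odds.
    """
    if np.any(data.n_yv < 1):
        raise ValueError("every (Y, V) cell must be sampled for the PL")
    off_v = _pl_offsets(data)
    off = off_v[data.v_sub]
    X = _design(data.x_sub, data.adj_sub)
    y = data.y_sub.astype(float)
    beta, info, conv = _logistic_irls(X, y, offset=off)
    A = np.linalg.inv(info)
    p = expit(X @ beta + off)
    U = X * (y - p)[:, None]
    B = np.zeros_like(info)
    for yy in (0, 1):
        for vv in range(data.n_strata):
            cell = (y == yy) & (data.v_sub == vv)
            m = int(cell.sum())
            if m < 2:
                continue
            Uc = U[cell] - U[cell].mean(axis=0)
            B += m / (m - 1) * (Uc.T @ Uc)
    # phase-1 log-odds estimation adds variance through the offsets
    for vv in range(data.n_strata):
        cell = data.v_sub == vv
        d_v = (p * (1 - p))[cell] @ X[cell]
        var_delta = 1.0 / data.N_yv[1, vv] + 1.0 / data.N_yv[0, vv]
        B += var_delta * np.outer(d_v, d_v)
    cov = A @ B @ A
    se = np.sqrt(max(cov[_X_COL, _X_COL], 0))
    if se == 0:
        se = np.sqrt(A[_X_COL, _X_COL])
    return EstimateResult("pl", beta[_X_COL], se, conv, beta)


def _spml_full_loglik(beta, g, X, y, v_sub, Nbar, n_strata):
    """Full semiparametric log-likelihood (up to constants): phase-2 terms
    log p + log g plus phase-1-only multinomial terms Nbar_yv log pi_yv,
    with g the per-stratum covariate masses on the observed support."""
    eta = X @ beta
    p1 = expit(eta)
    py = np.where(y == 1, p1, 1 - p1)
    ll = np.sum(np.log(np.maximum(py, 1e-300))) + np.sum(
        np.log(np.maximum(g, 1e-300))
    )
    for vv in range(n_strata):
        cell = v_sub == vv
        if not np.any(cell):
            continue
        pi1 = np.sum(p1[cell] * g[cell])
        ll += Nbar[1, vv] * np.log(max(pi1, 1e-300))
        ll += Nbar[0, vv] * np.log(max(1 - pi1, 1e-300))
    return ll


def _spml_g_em(beta, g, X, y, v_sub, Nbar, N_plus, n_strata, n_iter=1):
    """EM updates of the nonparametric covariate masses at fixed beta.

    E-step: phase-1-only subjects in cell (y, v) distribute over the
    observed phase-2 support with posterior weight p_y(x) g_v(x) / pi_yv.
    M-step: g_v(x) proportional to observed count plus posterior mass.
    Solving this to a fixed point enforces the nuisance-probability
    constraint equations pi_yv = sum_x p_y(x) g_v(x).
    """
    p1 = expit(X @ beta)
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(n_iter):
            new = np.empty_like(g)
            for vv in range(n_strata):
                cell = v_sub == vv
                if not np.any(cell):
                    continue
                gv = g[cell]
                pi1 = np.sum(p1[cell] * gv)
                pi1 = min(max(pi1, 1e-9), 1 - 1e-9)
                w = (
                    1.0
                    + Nbar[1, vv] * p1[cell] * gv / pi1
                    + Nbar[0, vv] * (1 - p1[cell]) * gv / (1 - pi1)
                )
                new[cell] = w / N_plus[vv]
                s = new[cell].sum()
                if not np.isfinite(s) or s <= 0:
                    new[cell] = gv  # stop moving a degenerate stratum
                else:
                    new[cell] /= s
            delta = np.max(np.abs(new - g))
            g = new
            if not np.isfinite(delta) or delta < 1e-14:
                break
    return g


def spml_profile_loglik(beta, data: "TwoPhaseData", inner_iter: int = 2000):
    """Profile log-likelihood of the semiparametric model at a given
    coefficient vector, maximizing the covariate masses out by EM."""
    X = _design(data.x_sub, data.adj_sub)
    y = data.y_sub.astype(float)
    v_sub = data.v_sub
    Nbar = data.N_yv - data.n_yv
    N_plus = data.N_yv.sum(axis=0)
    g = np.empty(y.size)
    for vv in range(data.n_strata):
        cell = v_sub == vv
        if np.any(cell):
            g[cell] = 1.0 / cell.sum()
    g = _spml_g_em(beta, g, X, y, v_sub, Nbar, N_plus, data.n_strata, inner_iter)
    return _spml_full_loglik(beta, g, X, y, v_sub, Nbar, data.n_strata)


def estimate_spml(
    data: TwoPhaseData, tol: float = 1e-8, max_iter: int = 200
) -> EstimateResult:
    """Semiparametric maximum likelihood for the two-phase model.

    The X|V distributions are left nonparametric (masses on the observed
    phase-2 covariate support within each stratum).  The fit alternates a
    weighted logistic maximization in beta against updates of the masses
    and the implied stratum case probabilities pi_yv from their constraint
    equations; the alternation is the EM form of the profile iteration and
    increases the semiparametric likelihood monotonically.  Standard errors
    come from the curvature of the profile log-likelihood at the maximum.

    With full sampling (no phase-1-only subjects) the procedure reduces to
    the ordinary complete-data logistic MLE in a single step.
    """
    X = _design(data.x_sub, data.adj_sub)
    y = data.y_sub.astype(float)
    v_sub = data.v_sub
    N_yv, n_yv = data.N_yv, data.n_yv
    Nbar = N_yv - n_yv
    N_plus = N_yv.sum(axis=0)
    n_strata = data.n_strata
    n = y.size

    g = np.empty(n)
    for vv in range(n_strata):
        cell = v_sub == vv
        if np.any(cell):
            g[cell] = 1.0 / cell.sum()
    beta, info, _ = _logistic_irls(X, y)  # complete-data start
    converged = False
    it = 0
    X3 = np.vstack([X, X, X])
    y3 = np.concatenate([y, np.ones(n), np.zeros(n)])
    for it in range(1, max_iter + 1):
        # E-step: posterior weights for phase-1-only subjects over support
        p1 = expit(X @ beta)
        w1 = np.zeros(n)
        w0 = np.zeros(n)
        for vv in range(n_strata):
            cell = v_sub == vv
            if not np.any(cell):
                continue
            pi1 = min(max(np.sum(p1[cell] * g[cell]), 1e-12), 1 - 1e-12)
            w1[cell] = Nbar[1, vv] * p1[cell] * g[cell] / pi1
            w0[cell] = Nbar[0, vv] * (1 - p1[cell]) * g[cell] / (1 - pi1)
        # M-step: masses, then weighted logistic for beta
        g = (1.0 + w1 + w0) / N_plus[v_sub]
        wts = np.concatenate([np.ones(n), w1, w0])
        keep = wts > 0
        new_beta, info, _ = _logistic_irls(
            X3[keep], y3[keep], prior_weights=wts[keep], beta0=beta
        )
        delta = np.abs(new_beta[_X_COL] - beta[_X_COL])
        beta = new_beta
        if delta < tol and it > 1:
            converged = True
            break
    # profile-likelihood SE via numerical Hessian
    k = X.shape[1]
    h = 1e-4 * np.maximum(np.abs(beta), 1.0)
    H = np.zeros((k, k))

    def f(b):
        return spml_profile_loglik(b, data)

    f0 = f(beta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(beta + ei) - 2 * f0 + f(beta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(beta + ei + ej) - f(beta + ei - ej)
                    - f(beta - ei + ej) + f(beta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(cov[_X_COL, _X_COL])
    except (np.linalg.LinAlgError, FloatingPointError):
        se = np.nan
    if not np.isfinite(se) or se <= 0:
        se = np.sqrt(np.linalg.inv(info)[_X_COL, _X_COL])
    return EstimateResult("spml", beta[_X_COL], se, converged, beta, it)
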