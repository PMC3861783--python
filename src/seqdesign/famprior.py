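"""Variant prioritization criteria for ascertained families.

Given families with phenotypes on every member but genotypes only on a
sequenced subset, four criteria rank discovered variants by their evidence
of co-segregation with disease:

* **rule count** — number of families in which every sequenced case
  carries the variant and no sequenced control does;
* **retrospective likelihood ratio** — Pr(G_obs | Y; beta, q) /
  Pr(G_obs | q), the observed genotypes' probability given the phenotypes
  of the whole pedigree under a single-locus penetrance model versus under
  genotype-phenotype independence, with unobserved genotypes summed out by
  pedigree peeling;
* **Bayes factor** — the same ratio with (q, beta) integrated over prior
  draws under the alternative and the null;
* **kinship score test** — T_v = sum_f sum_{i,j} (Y_fi - p_f) K_fij
  (G_fjv - q_fv) with genotype deviations zeroed for untyped members, so
  untyped phenotypes still contribute through kinship cross terms;
  variance sum_f t_fv^2.

A regional aggregate Q = sum_v T_v^2 with a moment-matched null reference
(the family-data analogue of SKAT) and ROC tooling complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logsumexp

from .pedsim import FamilyDataset, Pedigree

__all__ = [
    "PriorSpec",
    "ScoreResult",
    "rule_count",
    "pedigree_peel_loglik",
    "retrospective_lr",
    "bayes_factor",
    "bayes_factor_many",
    "family_score",
    "regional_score",
    "roc",
]


# ---------------------------------------------------------------------------
# Rule-based criterion
# ---------------------------------------------------------------------------


def rule_count(dataset: FamilyDataset, variant: int) -> int:
    """Families in which all sequenced cases carry the variant (at least one
    sequenced case) and no sequenced control carries it."""
    G = dataset.genotypes(variant)
    carrier = G > 0
    seq = dataset.sequenced
    case = (dataset.y == 1) & seq
    ctrl = (dataset.y == 0) & seq
    has_case = case.any(axis=1)
    all_cases_carry = np.all(~case | carrier, axis=1)
    no_ctrl_carries = np.all(~ctrl | ~carrier, axis=1)
    return int(np.sum(has_case & all_cases_carry & no_ctrl_carries))


# ---------------------------------------------------------------------------
# Pedigree peeling (vectorized across families and parameter draws)
# ---------------------------------------------------------------------------

# Mendelian transmission tensor T[gf, gm, gc]
_T = np.zeros((3, 3, 3))
for _gf in range(3):
    for _gm in range(3):
        pf = _gf / 2.0  # P(transmit derived allele)
        pm = _gm / 2.0
        _T[_gf, _gm, 0] = (1 - pf) * (1 - pm)
        _T[_gf, _gm, 1] = pf * (1 - pm) + (1 - pf) * pm
        _T[_gf, _gm, 2] = pf * pm


def _hwe(q: np.ndarray) -> np.ndarray:
    q = np.atleast_1d(np.asarray(q, dtype=float))
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)


def penetrance_from(beta, q, intercept):
    """P(Y=1 | g) = expit(intercept + beta g); arrays broadcast over
    parameter draws.  Returns shape (n_param, 3)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    return expit(intercept + beta[:, None] * np.arange(3)[None, :])


def pedigree_peel_loglik(
    ped: Pedigree,
    q,
    y: np.ndarray | None = None,
    g_obs: np.ndarray | None = None,
    penetrance: np.ndarray | None = None,
):
    """log Pr(G_obs, Y) for a single diallelic variant by pedigree peeling.

    Founders are HWE(q); transmission is Mendelian.  ``y`` (n_fam,
    n_member) phenotypes are scored through ``penetrance`` (n_param, 3);
    pass ``penetrance=None`` for the genotype-only law Pr(G_obs), or
    ``g_obs`` entries of -1 for unobserved genotypes (``g_obs=None`` means
    all unobserved, giving Pr(Y)).  Vectorized over families and parameter
    draws; returns (n_fam, n_param) log probabilities.

    The peeling order assumes each non-root couple includes exactly one
    married-in founder (true of the shipped pedigree structures); root
    couples (both parents founders) are combined last.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    n_param = q.size if penetrance is None else max(q.size, penetrance.shape[0])
    if y is not None:
        y = np.atleast_2d(y)
        n_fam = y.shape[0]
    elif g_obs is not None:
        g_obs = np.atleast_2d(g_obs)
        n_fam = g_obs.shape[0]
    else:
        n_fam = 1
    if g_obs is not None:
        g_obs = np.atleast_2d(g_obs)
    hwe = np.broadcast_to(_hwe(q), (n_param, 3))

    def pen_obs(i):
        out = np.ones((n_fam, n_param, 3))
        if penetrance is not None and y is not None:
            p1 = penetrance[None, :, :]  # (1, n_param, 3)
            yi = y[:, i, None, None]
            out = out * np.where(yi == 1, p1, 1 - p1)
        if g_obs is not None:
            gi = g_obs[:, i]
            obs = gi >= 0
            if np.any(obs):
                ind = np.ones((n_fam, 3))
                ind[obs] = np.eye(3)[gi[obs].astype(int)]
                out = out * ind[:, None, :]
        return out

    couples: dict[tuple[int, int], list[int]] = {}
    for c in range(ped.n):
        f, m = ped.father[c], ped.mother[c]
        if f >= 0:
            couples.setdefault((f, m), []).append(c)

    down = [None] * ped.n  # (n_fam, n_param, 3) messages

    def get_down(i):
        if down[i] is None:
            down[i] = pen_obs(i)
        return down[i]

    founder = ped.founder
    root_terms = []
    # children precede parents in reverse id order
    for (f, m), kids in sorted(couples.items(), key=lambda kv: -max(kv[0])):
        child_prod = np.ones((n_fam, n_param, 3, 3))
        for c in kids:
            child_prod = child_prod * np.einsum(
                "fpc,abc->fpab", get_down(c), _T
            )
        if founder[f] and founder[m]:
            term = np.einsum(
                "pa,fpa,pb,fpb,fpab->fp",
                hwe, get_down(f), hwe, get_down(m), child_prod,
            )
            root_terms.append(term)
        else:
            parent, spouse = (f, m) if not founder[f] else (m, f)
            axis_sp = 3 if parent == f else 2
            if axis_sp == 3:  # spouse is the mother axis b
                term = np.einsum(
                    "pb,fpb,fpab->fpa", hwe, get_down(spouse), child_prod
                )
            else:
                term = np.einsum(
                    "pa,fpa,fpab->fpb", hwe, get_down(spouse), child_prod
                )
            down[parent] = get_down(parent) * term
    # isolated founders (no couple) and root couples
    total = np.zeros((n_fam, n_param))
    in_couple = {i for fm in couples for i in fm}
    for i in range(ped.n):
        if i not in in_couple and founder[i]:
            total = total + np.log(
                np.maximum(np.einsum("pa,fpa->fp", hwe, get_down(i)), 1e-300)
            )
    for term in root_terms:
        total = total + np.log(np.maximum(term, 1e-300))
    return total


# ---------------------------------------------------------------------------
# Retrospective likelihood ratio and Bayes factor
# ---------------------------------------------------------------------------


def _masked_gobs(dataset: FamilyDataset, variant: int) -> np.ndarray:
    g = dataset.genotypes(variant).astype(np.int8)
    g = np.where(dataset.sequenced, g, -1)
    return g


def retrospective_lr(
    dataset: FamilyDataset,
    variant: int,
    beta: float,
    q: float,
    intercept: float,
    per_family: bool = False,
):
    """Log retrospective likelihood ratio summed over families.

    log LR_v = sum_f [log Pr(G_obs, Y) - log Pr(Y) - log Pr(G_obs)], the
    alternative evaluated at penetrance expit(intercept + beta g) and the
    null at genotype-phenotype independence.  Exactly 0 when beta = 0.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    if beta == 0:
        out = np.zeros(dataset.n_fam)
        return out if per_family else 0.0
    ped = dataset.pedigree
    gobs = _masked_gobs(dataset, variant)
    pen = penetrance_from(beta, q, intercept)
    l_gy = pedigree_peel_loglik(ped, q, dataset.y, gobs, pen)[:, 0]
    l_y = pedigree_peel_loglik(ped, q, dataset.y, None, pen)[:, 0]
    l_g = pedigree_peel_loglik(ped, q, None, gobs, None)[:, 0]
    ll = l_gy - l_y - l_g
    return ll if per_family else float(ll.sum())


@dataclass
class PriorSpec:
    """Joint prior over (q, beta) for the Bayes factor.

    ``q1, beta1`` are alternative-hypothesis support points (equal weight
    unless ``w1`` given); ``q0`` the null MAF draws (beta = 0).  A single
    support point under each hypothesis makes the BF collapse to the
    likelihood ratio exactly.
    """

    q1: np.ndarray
    beta1: np.ndarray
    q0: np.ndarray
    w1: np.ndarray | None = None
    w0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q1 = np.atleast_1d(np.asarray(self.q1, dtype=float))
        self.beta1 = np.atleast_1d(np.asarray(self.beta1, dtype=float))
        self.q0 = np.atleast_1d(np.asarray(self.q0, dtype=float))
        if self.q1.shape != self.beta1.shape:
            raise ValueError("q1 and beta1 must have the same length")
        for name in ("w1", "w0"):
            w = getattr(self, name)
            n = self.q1.size if name == "w1" else self.q0.size
            if w is None:
                w = np.full(n, 1.0 / n)
            else:
                w = np.asarray(w, dtype=float)
                if w.size != n or abs(w.sum() - 1) > 1e-8:
                    raise ValueError(f"{name} must be {n} weights summing to 1")
            setattr(self, name, w)

    @classmethod
    def from_generating_model(
        cls, pop, effect_config, n_draws: int = 100, seed=None,
        rare_threshold: float = 0.05,
    ) -> "PriorSpec":
        """Draws (q, beta) from the simulation's own generating
        distributions: q resampled from the population's rare-variant MAF
        spectrum, beta | q half-normal with the config's MAF-dependent
        scale.  One draw set is shared across variants (common random
        numbers) so rankings are not churned by prior noise."""
        rng = np.random.default_rng(seed)
        qpool = pop.maf[pop.maf < rare_threshold]
        if qpool.size == 0:
            raise ValueError("no rare variants to build the MAF prior from")
        q1 = rng.choice(qpool, n_draws)
        b1 = np.abs(rng.normal(0, 1, n_draws)) * effect_config.effect_scale(q1)
        q0 = rng.choice(qpool, n_draws)
        return cls(q1, np.maximum(b1, 1e-12), q0)

    @classmethod
    def sample(
        cls, maf_sampler, beta_sampler, n_draws: int = 100, seed=None
    ) -> "PriorSpec":
        """Draw ``n_draws`` (q, beta) pairs under H1 and q under H0 from
        user samplers ``maf_sampler(rng, n)`` / ``beta_sampler(rng, q)``."""
        rng = np.random.default_rng(seed)
        q1 = maf_sampler(rng, n_draws)
        b1 = beta_sampler(rng, q1)
        q0 = maf_sampler(rng, n_draws)
        return cls(q1, b1, q0)


def bayes_factor(
    dataset: FamilyDataset,
    variant: int,
    prior: PriorSpec,
    intercept: float,
) -> float:
    """Log Bayes factor: marginal probability of the observed genotypes
    given all phenotypes, averaged over alternative prior draws, against
    the genotype-only marginal averaged over null draws."""
    ped = dataset.pedigree
    gobs = _masked_gobs(dataset, variant)
    pen = penetrance_from(prior.beta1, prior.q1, intercept)
    l_gy = pedigree_peel_loglik(ped, prior.q1, dataset.y, gobs, pen)
    l_y = pedigree_peel_loglik(ped, prior.q1, dataset.y, None, pen)
    num = logsumexp(np.sum(l_gy - l_y, axis=0) + np.log(prior.w1))
    l_g = pedigree_peel_loglik(ped, prior.q0, None, gobs, None)
    den = logsumexp(np.sum(l_g, axis=0) + np.log(prior.w0))
    return float(num - den)


def bayes_factor_many(
    dataset: FamilyDataset,
    variants,
    prior: PriorSpec,
    intercept: float,
) -> np.ndarray:
    """Log Bayes factors for many variants sharing one prior (common random
    numbers); the phenotype-marginal term Pr(Y) is computed once."""
    ped = dataset.pedigree
    pen = penetrance_from(prior.beta1, prior.q1, intercept)
    l_y = pedigree_peel_loglik(ped, prior.q1, dataset.y, None, pen)
    out = np.empty(len(variants))
    for k, v in enumerate(variants):
        gobs = _masked_gobs(dataset, v)
        l_gy = pedigree_peel_loglik(ped, prior.q1, dataset.y, gobs, pen)
        num = logsumexp(np.sum(l_gy - l_y, axis=0) + np.log(prior.w1))
        l_g = pedigree_peel_loglik(ped, prior.q0, None, gobs, None)
        den = logsumexp(np.sum(l_g, axis=0) + np.log(prior.w0))
        out[k] = num - den
    return out


# ---------------------------------------------------------------------------
# Kinship score test
# ---------------------------------------------------------------------------


@dataclass
class ScoreResult:
    """Score statistic for one variant: T, var(T) = sum_f t_f^2, and the
    per-family contributions."""

    T: float
    var: float
    t_fam: np.ndarray
    mode: str

    @property
    def statistic(self) -> float:
        return self.T**2 / self.var if self.var > 0 else np.nan

    @property
    def informative(self) -> bool:
        return self.var > 0

    @property
    def p_value(self) -> float:
        s = self.statistic
        return float(stats.chi2.sf(s, 1)) if np.isfinite(s) else np.nan


def _score_contributions(
    dataset: FamilyDataset, variant: int, mode: str, kinship_inverse: bool
) -> np.ndarray:
    G = dataset.genotypes(variant).astype(float)
    seq = dataset.sequenced
    y = dataset.y.astype(float)
    K = np.linalg.inv(dataset.K) if kinship_inverse else dataset.K
    nseq = seq.sum(axis=1)
    if np.any(nseq == 0):
        raise ValueError("every family must have at least one sequenced member")
    if mode == "within":
        p_f = y.mean(axis=1)
        q_f = np.where(seq, G, 0).sum(axis=1) / nseq
    elif mode == "combined":
        p_f = np.full(dataset.n_fam, y.mean())
        q_f = np.full(dataset.n_fam, G[seq].mean())
    else:
        raise ValueError("mode must be 'within' or 'combined'")
    ydev = y - p_f[:, None]
    gdev = np.where(seq, G - q_f[:, None], 0.0)  # untyped deviations zeroed
    return np.einsum("fi,ij,fj->f", ydev, K, gdev)


def family_score(
    dataset: FamilyDataset,
    variant: int,
    mode: str = "within",
    kinship_inverse: bool = False,
) -> ScoreResult:
    """Kinship-weighted score test of genotype-phenotype co-segregation.

    ``within`` centers by family-specific prevalence and sequenced-member
    genotype mean (pure within-family comparison; families whose sequenced
    members are all carriers or all non-carriers are uninformative);
    ``combined`` centers by the across-family grand means, recovering
    between-family information.  ``kinship_inverse=True`` weights by the
    entries of K^-1 instead of K.
    """
    t = _score_contributions(dataset, variant, mode, kinship_inverse)
    return ScoreResult(float(t.sum()), float(np.sum(t**2)), t, mode)


def regional_score(
    dataset: FamilyDataset,
    region_variants,
    mode: str = "within",
    kinship_inverse: bool = False,
):
    """Regional aggregate Q = sum_v T_v^2 with a moment-matched null.

    The null distribution of (T_v)_v is centered normal with covariance
    C_vw = sum_f t_fv t_fw estimated from the per-family contributions; Q
    is referred to a Satterthwaite scaled chi-square with scale
    tr(C^2)/tr(C) and degrees of freedom tr(C)^2/tr(C^2).  A single-variant
    region reproduces the score test's chi-square p-value.
    """
    region_variants = np.atleast_1d(np.asarray(region_variants, dtype=int))
    if region_variants.size == 0:
        raise ValueError("empty region")
    tmat = np.stack(
        [
            _score_contributions(dataset, v, mode, kinship_inverse)
            for v in region_variants
        ],
        axis=1,
    )  # (n_fam, n_var)
    T = tmat.sum(axis=0)
    C = tmat.T @ tmat
    Q = float(np.sum(T**2))
    lam = np.linalg.eigvalsh(C)
    lam = lam[lam > 1e-12 * max(lam.max(), 1e-300)]
    if lam.size == 0:
        return Q, np.nan
    p = _weighted_chi2_sf(Q, lam)
    return Q, p


def _weighted_chi2_sf(x, lam):
    """Survival function of sum_i lam_i chi2_1 by Imhof's inversion
    integral, with a Satterthwaite moment-match as fallback."""
    from scipy.integrate import quad

    lam = np.asarray(lam, dtype=float)
    if lam.size == 1:
        return float(stats.chi2.sf(x / lam[0], 1))

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            val, err = quad(integrand, 0, np.inf, limit=400)
        p = 0.5 + val / np.pi
        if err < 1e-4 and -1e-6 <= p <= 1 + 1e-6:
            return float(min(max(p, 1e-300), 1.0))
    except Exception:  # pragma: no cover - integration failure
        pass
    scale = np.sum(lam**2) / np.sum(lam)
    df = np.sum(lam) ** 2 / np.sum(lam**2)
    return float(stats.chi2.sf(x / scale, df))


# ---------------------------------------------------------------------------
# ROC comparison
# ---------------------------------------------------------------------------


def roc(causal_scores, null_scores):
    """ROC curve and AUC for separating causal from null variant scores.

    Returns (fpr, tpr, auc); ties handled by the trapezoid rule (AUC equals
    the Mann-Whitney U statistic / (n1 n0)).
    """
    from sklearn.metrics import roc_curve, auc

    causal_scores = np.asarray(causal_scores, dtype=float)
    null_scores = np.asarray(null_scores, dtype=float)
    if causal_scores.size == 0 or null_scores.size == 0:
        raise ValueError("both score sets must be non-empty")
    scores = np.concatenate([causal_scores, null_scores])
    labels = np.concatenate(
        [np.ones(causal_scores.size), np.zeros(null_scores.size)]
    )
    finite_min = np.nanmin(scores[np.isfinite(scores)]) if np.any(
        np.isfinite(scores)
    ) else 0.0
    scores = np.where(np.isfinite(scores), scores, finite_min - 1.0)
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(auc(fpr, tpr))
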