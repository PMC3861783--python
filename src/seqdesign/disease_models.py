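"""Rare-variant disease models and phenotyped cohort simulation.

Two generating models are provided:

* a *flat* model in which each variant is causal with a probability that
  decreases with its MAF and causal variants carry a log relative risk drawn
  from a half-normal whose scale also decreases with MAF;
* a *multilevel* model in which the region is partitioned into pathways,
  genes, and gene-regions; a variant is causal only if its pathway, gene,
  and the variant itself are all flagged causal, and its log RR is the sum
  of half-normal pathway-, gene-, and variant-level effects.

Subjects are diplotypes (unordered pairs of haplotype rows) drawn with
replacement from a :class:`~seqdesign.hapsim.HaplotypePopulation`; disease
is Bernoulli with logistic risk ``expit(intercept + genetic log RR)`` where
the genetic log RR is additive per derived allele over causal variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit, logit

from .hapsim import HaplotypePopulation

__all__ = [
    "EffectConfig",
    "VariantEffectModel",
    "MultilevelEffectConfig",
    "MultilevelAnnotation",
    "Cohort",
    "assign_variant_effects",
    "genetic_log_rr",
    "haplotype_scores",
    "calibrate_intercept",
    "simulate_case_control_cohort",
    "simulate_multilevel_cohort",
    "assign_multilevel_effects",
    "select_stratified_subsample",
]

HALF_NORMAL_MEAN = np.sqrt(2.0 / np.pi)


# ---------------------------------------------------------------------------
# Flat effect model
# ---------------------------------------------------------------------------


@dataclass
class EffectConfig:
    """MAF-dependent causal-probability and effect-size curves.

    P(causal | q) = pi0 * min(1, q0 / q): constant at ``pi0`` for the rarest
    variants and decaying as 1/q above ``q0``.  For causal variants,
    beta | q = |N(0, tau(q)^2)| with tau(q) = c / sqrt(q), capped so that the
    relative risk scale never exceeds ``rr_cap`` (reached at q = q_cap).
    """

    pi0: float = 0.05
    q0: float = 0.001
    rr_cap: float = 20.0
    q_cap: float = 1e-4
    tau_coef: float | None = None  # c in tau(q) = c/sqrt(q); derived if None
    fixed_beta: float | None = None  # every causal variant gets exactly this

    def __post_init__(self) -> None:
        if not (0 <= self.pi0 <= 1):
            raise ValueError("pi0 must lie in [0, 1]")
        if self.tau_coef is None:
            # scale chosen so tau(q_cap) = log(rr_cap)
            self.tau_coef = np.log(self.rr_cap) * np.sqrt(self.q_cap)

    def p_causal(self, maf: np.ndarray) -> np.ndarray:
        q = np.asarray(maf, dtype=float)
        p = self.pi0 * np.minimum(1.0, self.q0 / np.maximum(q, 1e-300))
        if np.any((p < 0) | (p > 1)):
            raise ValueError("configuration yields P(causal) outside [0, 1]")
        return p

    def effect_scale(self, maf: np.ndarray) -> np.ndarray:
        q = np.asarray(maf, dtype=float)
        return np.minimum(self.tau_coef / np.sqrt(np.maximum(q, 1e-300)),
                          np.log(self.rr_cap))


@dataclass
class VariantEffectModel:
    """Per-variant causal indicators and log relative risks (>= 0)."""

    causal: np.ndarray  # bool per variant
    log_rr: np.ndarray  # beta_v >= 0; 0 iff non-causal
    config: EffectConfig | None = None

    def __post_init__(self) -> None:
        self.causal = np.asarray(self.causal, dtype=bool)
        self.log_rr = np.asarray(self.log_rr, dtype=float)
        if self.causal.shape != self.log_rr.shape:
            raise ValueError("causal and log_rr must have the same length")
        if not np.all(np.isfinite(self.log_rr)):
            raise ValueError("log_rr must be finite")
        if np.any((self.log_rr != 0) != self.causal):
            raise ValueError("log_rr must be nonzero exactly for causal variants")

    @property
    def n_variant(self) -> int:
        return self.log_rr.size


def assign_variant_effects(
    pop: HaplotypePopulation,
    effect_config: EffectConfig | None = None,
    seed: int | None = None,
) -> VariantEffectModel:
    """Draw causal indicators and half-normal log RRs for every variant."""
    cfg = effect_config or EffectConfig()
    rng = np.random.default_rng(seed)
    maf = pop.maf
    p = cfg.p_causal(maf)
    causal = rng.random(maf.size) < p
    beta = np.zeros(maf.size)
    if cfg.fixed_beta is not None:
        beta[causal] = cfg.fixed_beta
    else:
        scale = cfg.effect_scale(maf)
        draw = np.abs(rng.normal(0.0, 1.0, maf.size)) * scale
        # guard against a zero draw breaking the causal<->nonzero link
        beta[causal] = np.maximum(draw[causal], 1e-12)
    return VariantEffectModel(causal, beta, cfg)


def genetic_log_rr(model: VariantEffectModel, genotypes: np.ndarray) -> np.ndarray:
    """Additive genetic log relative risk: sum_v beta_v * g_v, g in {0,1,2}.

    ``genotypes`` may be a single genotype vector or an (n_subject, n_variant)
    matrix; returns a scalar or a per-subject vector accordingly.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.shape[-1] != model.n_variant:
        raise ValueError("genotype vector length does not match model")
    return g @ model.log_rr


def haplotype_scores(pop: HaplotypePopulation, model: VariantEffectModel) -> np.ndarray:
    """Per-haplotype sum of causal betas; a diplotype's log RR is the sum of
    its two haplotype scores (equivalent to, and much faster than, forming
    genotype vectors)."""
    return pop.haplotypes @ model.log_rr


def calibrate_intercept(
    pop: HaplotypePopulation,
    model: VariantEffectModel,
    target_prevalence: float = 0.05,
    tolerance: float = 1e-4,
    seed: int | None = None,
    n_mc: int = 200_000,
) -> float:
    """Logistic intercept yielding a given population prevalence.

    Solves ``mean(expit(a + logRR_i)) = target`` over a Monte-Carlo sample of
    random diplotypes by bisection (the prevalence curve is strictly
    increasing in the intercept).  With no causal variants the closed form
    ``logit(target)`` is returned exactly.
    """
    if not (0 < target_prevalence < 1):
        raise ValueError("target_prevalence must lie in (0, 1)")
    scores = haplotype_scores(pop, model)
    if np.all(scores == 0):
        return float(logit(target_prevalence))
    rng = np.random.default_rng(seed)
    s = scores[rng.integers(0, pop.n_hap, n_mc)] + scores[
        rng.integers(0, pop.n_hap, n_mc)
    ]

    def prev(a: float) -> float:
        return float(np.mean(expit(a + s)))

    lo, hi = logit(target_prevalence) - np.max(s) - 1.0, logit(target_prevalence) + 1.0
    if prev(hi) < target_prevalence:  # pragma: no cover - defensive
        raise ValueError("target prevalence unattainable under this model")
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if prev(mid) < target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Phenotyped subjects as diplotype row-index pairs into a population.

    ``y`` is 0/1 (control/case) for the flat model; the multilevel simulator
    additionally records a three-category disease state (0 unaffected,
    1 unilateral, 2 bilateral) in ``disease_state`` plus age and family-
    history strata.
    """

    pop: HaplotypePopulation
    hap1: np.ndarray
    hap2: np.ndarray
    y: np.ndarray
    log_rr: np.ndarray
    disease_state: np.ndarray | None = None
    age_stratum: np.ndarray | None = None
    fh: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.y.size

    def genotypes(self, variant_idx: np.ndarray | slice | None = None) -> np.ndarray:
        """Genotype matrix g in {0,1,2} for the requested variants."""
        H = self.pop.haplotypes
        if variant_idx is None:
            variant_idx = slice(None)
        return (
            H[self.hap1][:, variant_idx].astype(np.int16)
            + H[self.hap2][:, variant_idx].astype(np.int16)
        )

    def to_frame(self):
        import pandas as pd

        d = {
            "id": np.arange(self.n),
            "y": self.y,
            "hap1": self.hap1,
            "hap2": self.hap2,
            "log_rr": self.log_rr,
        }
        for name in ("disease_state", "age_stratum", "fh"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, pop: HaplotypePopulation, frame) -> "Cohort":
        """Rebuild a cohort from a :meth:`to_frame` table and its pool."""
        opt = {
            name: frame[name].to_numpy()
            for name in ("disease_state", "age_stratum", "fh")
            if name in frame.columns
        }
        return cls(
            pop,
            frame["hap1"].to_numpy(),
            frame["hap2"].to_numpy(),
            frame["y"].to_numpy(),
            frame["log_rr"].to_numpy(),
            **opt,
        )


def simulate_case_control_cohort(
    pop: HaplotypePopulation,
    model: VariantEffectModel,
    n_case: int,
    n_control: int,
    intercept: float,
    seed: int | None = None,
) -> Cohort:
    """Sample random diplotypes until the target case/control counts are met.

    Disease is Bernoulli(expit(intercept + log RR)); subjects beyond the
    target count for their outcome are discarded, so the returned cohort has
    exactly ``n_case`` cases followed by ``n_control`` controls (in sampling
    order within outcome).
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("case and control counts must be positive")
    rng = np.random.default_rng(seed)
    scores = haplotype_scores(pop, model)
    h1_parts, h2_parts, y_parts, s_parts = [], [], [], []
    need_case, need_control = n_case, n_control
    p_typ = float(expit(intercept + 2 * scores.mean()))
    while need_case > 0 or need_control > 0:
        m = int(3 * max(need_case / max(p_typ, 1e-3),
                        need_control / max(1 - p_typ, 1e-3)))
        m = min(max(m, 2048), 4_000_000)
        h1 = rng.integers(0, pop.n_hap, m)
        h2 = rng.integers(0, pop.n_hap, m)
        s = scores[h1] + scores[h2]
        y = rng.random(m) < expit(intercept + s)
        for val, need in ((True, need_case), (False, need_control)):
            take = np.flatnonzero(y == val)[:need]
            h1_parts.append(h1[take])
            h2_parts.append(h2[take])
            y_parts.append(np.full(take.size, val, dtype=np.int8))
            s_parts.append(s[take])
            if val:
                need_case -= take.size
            else:
                need_control -= take.size
    h1 = np.concatenate(h1_parts)
    h2 = np.concatenate(h2_parts)
    y = np.concatenate(y_parts)
    s = np.concatenate(s_parts)
    order = np.argsort(-y, kind="stable")  # cases first, stable in draw order
    return Cohort(pop, h1[order], h2[order], y[order], s[order])


# ---------------------------------------------------------------------------
# Multilevel (pathway / gene / region) model
# ---------------------------------------------------------------------------


@dataclass
class MultilevelEffectConfig:
    """Hierarchical causal structure: pathways > genes > 3 region classes.

    A variant is causal only if its pathway, gene, and the variant itself are
    all selected (three-level AND rule); its log RR is then the sum of
    |N(0, sigma2_P)|, |N(0, sigma2_G)|, and |N(0, sigma2_v)| draws.  The
    variant-level probability ``pi_v`` and variance ``sigma2_v`` depend on
    the region class (index 0-2, e.g. exon / promoter / enhancer) and are
    scaled by min(1, q0/q) so rarer variants are more likely causal.
    """

    n_pathways: int = 100
    genes_per_pathway: tuple[int, int] = (1, 20)
    pi_pathway: float = 0.1
    pi_gene: float = 0.3
    pi_variant: tuple[float, float, float] = (0.3, 0.15, 0.05)
    sigma2_pathway: float = 0.05**2
    sigma2_gene: float = 0.1**2
    sigma2_variant: tuple[float, float, float] = (0.4**2, 0.2**2, 0.1**2)
    q0: float = 0.001

    def __post_init__(self) -> None:
        probs = [self.pi_pathway, self.pi_gene, *self.pi_variant]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("causal probabilities must lie in [0, 1]")
        if self.sigma2_pathway < 0 or self.sigma2_gene < 0 or any(
            s < 0 for s in self.sigma2_variant
        ):
            raise ValueError("variance components must be non-negative")


@dataclass
class MultilevelAnnotation:
    """Variant -> (pathway, gene, region-class) map plus the effect model."""

    pathway: np.ndarray  # per variant
    gene: np.ndarray
    region_class: np.ndarray  # 0, 1, 2
    model: VariantEffectModel
    n_genes: int


def assign_multilevel_effects(
    pop: HaplotypePopulation,
    config: MultilevelEffectConfig | None = None,
    seed: int | None = None,
) -> MultilevelAnnotation:
    """Partition the region into pathways/genes/region-classes and draw
    hierarchical causal effects."""
    cfg = config or MultilevelEffectConfig()
    rng = np.random.default_rng(seed)
    n_v = pop.n_site

    n_genes_per_pw = rng.integers(
        cfg.genes_per_pathway[0], cfg.genes_per_pathway[1] + 1, cfg.n_pathways
    )
    n_genes = int(n_genes_per_pw.sum())
    gene_pathway = np.repeat(np.arange(cfg.n_pathways), n_genes_per_pw)

    # genes tile the region contiguously; each gene splits into 3 classes
    gene_of_variant = rng.integers(0, n_genes, n_v) if n_genes else np.zeros(n_v, int)
    gene_of_variant.sort()
    pathway_of_variant = gene_pathway[gene_of_variant]
    region_class = rng.integers(0, 3, n_v)

    causal_pw = rng.random(cfg.n_pathways) < cfg.pi_pathway
    causal_gene = rng.random(n_genes) < cfg.pi_gene
    maf = pop.maf
    pi_v = np.asarray(cfg.pi_variant)[region_class] * np.minimum(
        1.0, cfg.q0 / np.maximum(maf, 1e-300)
    )
    causal_v = rng.random(n_v) < pi_v

    causal = causal_pw[pathway_of_variant] & causal_gene[gene_of_variant] & causal_v

    eff_pw = np.abs(rng.normal(0, np.sqrt(cfg.sigma2_pathway), cfg.n_pathways))
    eff_gene = np.abs(rng.normal(0, np.sqrt(cfg.sigma2_gene), n_genes))
    sd_v = np.sqrt(np.asarray(cfg.sigma2_variant)[region_class])
    eff_v = np.abs(rng.normal(0, 1, n_v)) * sd_v

    beta = np.zeros(n_v)
    beta[causal] = (
        eff_pw[pathway_of_variant[causal]]
        + eff_gene[gene_of_variant[causal]]
        + eff_v[causal]
    )
    beta[causal] = np.maximum(beta[causal], 1e-12)
    model = VariantEffectModel(causal, beta)
    return MultilevelAnnotation(
        pathway_of_variant, gene_of_variant, region_class, model, n_genes
    )


DEFAULT_STRATUM_TARGETS = {
    # (age_stratum, fh) -> (n_unaffected, n_unilateral, n_bilateral)
    (0, 0): (250, 120, 60),
    (0, 1): (50, 40, 30),
    (1, 0): (300, 150, 50),
    (1, 1): (60, 50, 40),
}


def simulate_multilevel_cohort(
    pop: HaplotypePopulation,
    annotation: MultilevelAnnotation,
    stratum_targets: dict | None = None,
    seed: int | None = None,
    *,
    base_rates: tuple[float, float] = (0.10, 0.03),
    fh_coef: float = 0.5,
    age_effect: float = 0.5,
    max_draws: int = 20_000_000,
) -> Cohort:
    """Sample subjects until every (age, FH, disease-state) cell is filled.

    Each subject draws a random diplotype and an age stratum; unilateral and
    bilateral disease probabilities scale the base rates by exp(genetic log
    RR) and the age effect; FH is Bernoulli with log-odds increasing in the
    genetic RR (a single-first-degree-relative liability approximation).
    Disease state 2 (bilateral) is the "case" phenotype ``y=1`` and state 1
    (unilateral) the control, matching a contralateral-vs-unilateral
    case-control definition.
    """
    targets = DEFAULT_STRATUM_TARGETS if stratum_targets is None else stratum_targets
    rng = np.random.default_rng(seed)
    scores = haplotype_scores(pop, annotation.model)
    mean_diplo = 2.0 * scores.mean()  # base rates refer to average genetic load
    n_ages = len({k[0] for k in targets})
    need = {
        (a, f, d): targets[(a, f)][d]
        for (a, f) in targets
        for d in range(3)
    }
    out = {k: [] for k in need}
    drawn = 0
    batch = 20_000
    while any(v > 0 for v in need.values()) and drawn < max_draws:
        h1 = rng.integers(0, pop.n_hap, batch)
        h2 = rng.integers(0, pop.n_hap, batch)
        s = scores[h1] + scores[h2]
        age = rng.integers(0, n_ages, batch)
        rr = np.exp(np.clip(s - mean_diplo, -5.0, 5.0))
        p_uni = np.minimum(base_rates[0] * rr * (1 + age_effect * age), 0.9)
        p_bil = np.minimum(base_rates[1] * rr * (1 + age_effect * age), 0.9 - p_uni)
        u = rng.random(batch)
        state = np.zeros(batch, dtype=np.int8)
        state[u < p_uni + p_bil] = 1
        state[u < p_bil] = 2
        p_fh = expit(-2.0 + fh_coef * (s - mean_diplo) + 0.3 * state)
        fh = (rng.random(batch) < p_fh).astype(np.int8)
        drawn += batch
        for k in need:
            if need[k] <= 0:
                continue
            a, f, d = k
            take = np.flatnonzero((age == a) & (fh == f) & (state == d))[: need[k]]
            if take.size:
                out[k].append((h1[take], h2[take], s[take]))
                need[k] -= take.size
    unmet = [k for k, v in need.items() if v > 0]
    if unmet:
        raise RuntimeError(
            f"stratum targets unreachable within {max_draws} draws: {unmet}"
        )
    h1_l, h2_l, s_l, st_l, age_l, fh_l = [], [], [], [], [], []
    for (a, f, d), chunks in out.items():
        for h1, h2, s in chunks:
            h1_l.append(h1)
            h2_l.append(h2)
            s_l.append(s)
            st_l.append(np.full(h1.size, d, dtype=np.int8))
            age_l.append(np.full(h1.size, a, dtype=np.int8))
            fh_l.append(np.full(h1.size, f, dtype=np.int8))
    state = np.concatenate(st_l)
    return Cohort(
        pop,
        np.concatenate(h1_l),
        np.concatenate(h2_l),
        (state == 2).astype(np.int8),
        np.concatenate(s_l),
        disease_state=state,
        age_stratum=np.concatenate(age_l),
        fh=np.concatenate(fh_l),
    )


def select_stratified_subsample(
    cohort: Cohort,
    priority_order: Sequence[tuple],
    n_target: int,
    seed: int | None = None,
) -> np.ndarray:
    """Select ``n_target`` subjects filling highest-priority cells first.

    ``priority_order`` is an ordered list of cells; each cell is a tuple of
    ``(attribute_name, value)`` pairs matched conjunctively against cohort
    attributes (``y``, ``disease_state``, ``age_stratum``, ``fh``).  Cells
    are consumed in order; ties within a cell are broken by a seeded shuffle.
    Subjects matching no cell are used last (in shuffled order).
    """
    if n_target > cohort.n:
        raise ValueError("n_target exceeds cohort size")
    rng = np.random.default_rng(seed)
    remaining = np.ones(cohort.n, dtype=bool)
    chosen: list[np.ndarray] = []
    n_left = n_target
    for cell in priority_order:
        mask = remaining.copy()
        for attr, val in cell:
            mask &= np.asarray(getattr(cohort, attr)) == val
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        take = idx[:n_left]
        chosen.append(take)
        remaining[take] = False
        n_left -= take.size
        if n_left == 0:
            break
    if n_left > 0:
        idx = np.flatnonzero(remaining)
        rng.shuffle(idx)
        chosen.append(idx[:n_left])
    return np.sort(np.concatenate(chosen))
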