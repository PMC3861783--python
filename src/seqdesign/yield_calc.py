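"""Analytic expected-yield calculations for two-phase sequencing designs.

Over a grid of (MAF, RR) bins, the machinery computes for each bin

* the probability of *discovering* a variant — seeing at least ``c`` copies
  in a genetically enriched sequencing subsample, from a Poisson
  approximation to the copy count;
* the probability the variant is *novel* — at most ``c'`` copies in a
  reference panel of population controls;
* the *power* of a stratified Mantel-Haenszel association test in the main
  study, via a normal approximation with Bonferroni correction over the
  expected number of variants carried forward;

and sums variant counts times these probabilities to an expected yield
table (variants prioritized / prioritized-and-causal / significant causal).

The aggregate prioritization path scans a sequenced subsample for variants,
regions, genes, or pathways whose rare-allele burden exceeds its population
expectation, then tests the survivors by Cochran-Mantel-Haenszel in the
main cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .disease_models import Cohort, MultilevelAnnotation, VariantEffectModel
from .hapsim import HaplotypePopulation

__all__ = [
    "MafRrGrid",
    "discovery_prob",
    "novelty_prob",
    "case_allele_freq",
    "mh_power",
    "expected_yield",
    "aggregate_prioritize_test",
    "cmh_test",
]


# ---------------------------------------------------------------------------
# Probabilities
# ---------------------------------------------------------------------------


def case_allele_freq(q, rr):
    """Allele frequency among cases under a per-allele relative risk:
    q' = q RR / (1 - q + q RR)."""
    q = np.asarray(q, dtype=float)
    rr = np.asarray(rr, dtype=float)
    return q * rr / (1.0 - q + q * rr)


def discovery_prob(maf, n_subjects, c_min, enrichment=1.0):
    """P(at least ``c_min`` copies in ``n_subjects`` diploid subjects).

    Poisson approximation with rate 2 n q * enrichment, the enrichment
    factor reflecting carrier excess in the sampled strata.
    """
    if np.any(np.asarray(c_min) < 1):
        raise ValueError("c_min must be >= 1")
    rate = 2.0 * n_subjects * np.asarray(maf, dtype=float) * enrichment
    return stats.poisson.sf(np.asarray(c_min) - 1, rate)


def novelty_prob(maf, n_reference, c_prime):
    """P(at most ``c_prime`` copies among ``n_reference`` panel subjects)."""
    if np.isinf(c_prime):
        return np.ones_like(np.asarray(maf, dtype=float))
    rate = 2.0 * n_reference * np.asarray(maf, dtype=float)
    return stats.poisson.cdf(c_prime, rate)


def _stratified_ncp(q, rr, n_cases, n_controls, strata):
    """Inverse-variance-weighted NCP of the stratified allele-count test.

    ``strata`` is a list of (case_fraction, control_fraction, rr_multiplier)
    tuples; a single stratum reduces to the usual two-proportion formula.
    """
    num = 0.0
    den = 0.0
    for cf, kf, mult in strata:
        n1 = 2.0 * n_cases * cf
        n0 = 2.0 * n_controls * kf
        if n1 <= 0 or n0 <= 0:
            continue
        p1 = case_allele_freq(q, rr * mult)
        p0 = q
        if p1 >= 1 or p0 <= 0 or p0 >= 1:
            warnings.warn("degenerate stratum excluded from the MH NCP")
            continue
        var = p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0
        w = 1.0 / var
        num += w * (p1 - p0)
        den += w
    if den == 0:
        return 0.0
    return num**2 / den


def mh_power(q, rr, n_cases, n_controls, strata=None, alpha=0.05, n_tests=1):
    """Two-sided power of the (stratified) Mantel-Haenszel allele test.

    power = Phi(sqrt(NCP) - z_{1-a/2}) + Phi(-sqrt(NCP) - z_{1-a/2}),
    with a = alpha / n_tests (Bonferroni).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    strata = strata or [(1.0, 1.0, 1.0)]
    ncp = _stratified_ncp(q, rr, n_cases, n_controls, strata)
    z = stats.norm.isf(alpha / (2.0 * n_tests))
    root = np.sqrt(ncp)
    return float(stats.norm.cdf(root - z) + stats.norm.cdf(-root - z))


# ---------------------------------------------------------------------------
# Grid and yield table
# ---------------------------------------------------------------------------


@dataclass
class MafRrGrid:
    """Variant counts binned by MAF and relative risk.

    ``counts_total`` includes all variants (null variants live in the RR=1
    bin, index 0); ``counts_causal`` the causal subset.  Bin representative
    values are geometric midpoints.
    """

    maf_edges: np.ndarray
    rr_edges: np.ndarray
    counts_total: np.ndarray  # (n_maf_bins, n_rr_bins)
    counts_causal: np.ndarray

    def __post_init__(self) -> None:
        self.maf_edges = np.asarray(self.maf_edges, dtype=float)
        self.rr_edges = np.asarray(self.rr_edges, dtype=float)
        if np.any(self.counts_total < 0) or np.any(self.counts_causal < 0):
            raise ValueError("bin counts must be non-negative")

    @property
    def maf_mid(self) -> np.ndarray:
        return np.sqrt(self.maf_edges[:-1] * self.maf_edges[1:])

    @property
    def rr_mid(self) -> np.ndarray:
        return np.sqrt(self.rr_edges[:-1] * self.rr_edges[1:])

    @classmethod
    def from_effect_model(
        cls,
        pop: HaplotypePopulation,
        model: VariantEffectModel,
        maf_edges=None,
        rr_edges=None,
    ) -> "MafRrGrid":
        """Bin a simulated population's variants; null variants go to the
        first RR bin (RR = 1)."""
        if maf_edges is None:
            maf_edges = np.array([1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.5])
        if rr_edges is None:
            rr_edges = np.concatenate([[1.0], np.geomspace(1.2, 20, 6)])
        maf_edges = np.asarray(maf_edges, dtype=float)
        rr_edges = np.asarray(rr_edges, dtype=float)
        rr = np.exp(model.log_rr)
        mi = np.clip(np.digitize(pop.maf, maf_edges) - 1, 0, maf_edges.size - 2)
        ri = np.clip(np.digitize(rr, rr_edges) - 1, 0, rr_edges.size - 2)
        ri[~model.causal] = 0
        nt = np.zeros((maf_edges.size - 1, rr_edges.size - 1))
        nc = np.zeros_like(nt)
        np.add.at(nt, (mi, ri), 1)
        np.add.at(nc, (mi[model.causal], ri[model.causal]), 1)
        return cls(maf_edges, rr_edges, nt, nc)


def expected_yield(
    grid: MafRrGrid,
    n_subsample: int,
    c_values=(1, 2, 3),
    c_prime_values=(0, 1, 2),
    n_reference: int = 1000,
    n_cases: int = 700,
    n_controls: int = 1400,
    strata=None,
    alpha: float = 0.05,
    case_fraction: float = 1.0,
) -> dict:
    """Expected-yield panels over (c, c') filter combinations.

    Returns a dict of three DataFrames indexed by c' with columns c:
    ``prioritized`` (expected variants passing both filters),
    ``prioritized_causal``, and ``significant_causal`` (expected causal
    variants also reaching Bonferroni-corrected MH significance in the main
    study, the correction spanning the expected prioritized count).

    The subsample's carrier enrichment treats a ``case_fraction`` of its
    subjects as cases with allele frequency q RR/(1-q+q RR).
    """
    if grid.counts_total.sum() == 0:
        z = pd.DataFrame(
            0.0, index=list(c_prime_values), columns=list(c_values)
        )
        return {"prioritized": z.copy(), "prioritized_causal": z.copy(),
                "significant_causal": z.copy()}
    qs = grid.maf_mid
    rrs = grid.rr_mid
    panels = {
        k: pd.DataFrame(0.0, index=list(c_prime_values), columns=list(c_values))
        for k in ("prioritized", "prioritized_causal", "significant_causal")
    }
    # per-bin probabilities
    nq, nr = qs.size, rrs.size
    pdisc = {c: np.zeros((nq, nr)) for c in c_values}
    pnov = {cp: np.zeros(nq) for cp in c_prime_values}
    for i, q in enumerate(qs):
        for cp in c_prime_values:
            pnov[cp][i] = novelty_prob(q, n_reference, cp)
        for j, rr in enumerate(rrs):
            qc = case_allele_freq(q, rr)
            q_eff = case_fraction * qc + (1 - case_fraction) * q
            enr = q_eff / q
            for c in c_values:
                pdisc[c][i, j] = discovery_prob(q, n_subsample, c, enr)
    for cp in c_prime_values:
        for c in c_values:
            pboth = pdisc[c] * pnov[cp][:, None]
            n_prio = float(np.sum(grid.counts_total * pboth))
            n_prio_causal = float(np.sum(grid.counts_causal * pboth))
            panels["prioritized"].loc[cp, c] = n_prio
            panels["prioritized_causal"].loc[cp, c] = n_prio_causal
            n_tests = max(n_prio, 1.0)
            sig = 0.0
            for i, q in enumerate(qs):
                for j, rr in enumerate(rrs):
                    if grid.counts_causal[i, j] == 0:
                        continue
                    pw = mh_power(q, rr, n_cases, n_controls, strata,
                                  alpha, n_tests)
                    sig += grid.counts_causal[i, j] * pboth[i, j] * pw
            panels["significant_causal"].loc[cp, c] = sig
    return panels


# ---------------------------------------------------------------------------
# Aggregate (variant/region/gene/pathway) prioritization
# ---------------------------------------------------------------------------


def cmh_test(carrier, y, strata):
    """Cochran-Mantel-Haenszel test of a binary exposure, stratified.

    Returns (statistic, p).  Strata contributing no information (constant
    exposure or outcome) drop out of the sums.
    """
    carrier = np.asarray(carrier, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    num = 0.0
    den = 0.0
    for s in np.unique(strata):
        m = strata == s
        n = m.sum()
        if n < 2:
            continue
        a = np.sum(carrier[m] * y[m])  # exposed cases
        r1 = np.sum(y[m])  # cases
        c1 = np.sum(carrier[m])  # exposed
        if r1 in (0, n) or c1 in (0, n):
            continue
        e = r1 * c1 / n
        v = r1 * (n - r1) * c1 * (n - c1) / (n**2 * (n - 1))
        num += a - e
        den += v
    if den == 0:
        return 0.0, 1.0
    stat = num**2 / den
    return float(stat), float(stats.chi2.sf(stat, 1))


_LEVEL_ATTR = {"region": "region_class", "gene": "gene", "pathway": "pathway"}


def _unit_labels(annotation: MultilevelAnnotation, level: str) -> np.ndarray:
    if level == "variant":
        return np.arange(annotation.model.n_variant)
    if level == "region":
        # region units are gene x region-class combinations
        return annotation.gene * 3 + annotation.region_class
    return getattr(annotation, _LEVEL_ATTR[level])


def aggregate_prioritize_test(
    cohort: Cohort,
    annotation: MultilevelAnnotation,
    subsample_idx: np.ndarray,
    level: str = "gene",
    alpha1: float | None = None,
    alpha2: float = 0.05,
    reference_maf: np.ndarray | None = None,
    rare_threshold: float = 0.05,
    min_copies: int = 2,
) -> pd.DataFrame:
    """Screen subsample burdens against population expectation, then
    CMH-test the survivors in the main cohort.

    A unit (variant, gene-region, gene, or pathway) is *discovered* when its
    rare-allele count in the subsample reaches ``min_copies``; it is
    *prioritized* when a one-sided Poisson exceedance test against the
    expectation from reference MAFs falls below ``alpha1`` (default 0.01 /
    number of discovered units).  Prioritized units are tested for
    case-control association in the full cohort by a CMH test stratified on
    age and family history, Bonferroni-adjusted over the survivors.
    """
    if level not in ("variant", "region", "gene", "pathway"):
        raise ValueError(f"unknown aggregation level {level!r}")
    pop = cohort.pop
    ref_q = pop.maf if reference_maf is None else np.asarray(reference_maf)
    if np.any(ref_q <= 0):
        raise ValueError("reference MAF must be positive for tested units")
    rare = ref_q < rare_threshold
    labels = _unit_labels(annotation, level)
    units = np.unique(labels[rare])

    g_sub = cohort.genotypes()[subsample_idx]
    n_sub = subsample_idx.size
    rows = []
    for u in units:
        vset = np.flatnonzero((labels == u) & rare)
        count = float(g_sub[:, vset].sum())
        expected = 2.0 * n_sub * float(ref_q[vset].sum())
        p_exc = float(stats.poisson.sf(count - 1, expected)) if count > 0 else 1.0
        rows.append((u, vset, count, expected, p_exc))
    discovered = [r for r in rows if r[2] >= min_copies]
    a1 = alpha1 if alpha1 is not None else 0.01 / max(len(discovered), 1)
    prioritized = [r for r in discovered if r[4] < a1]

    # main-study CMH on case (bilateral) vs control (unilateral) subjects
    cc = np.flatnonzero(
        np.isin(cohort.disease_state, (1, 2))
        if cohort.disease_state is not None
        else np.ones(cohort.n, bool)
    )
    y_cc = cohort.y[cc]
    strat = (
        cohort.age_stratum[cc] * 2 + cohort.fh[cc]
        if cohort.age_stratum is not None
        else np.zeros(cc.size, int)
    )
    g_cc = cohort.genotypes()[cc]
    out = []
    n_surv = max(len(prioritized), 1)
    for u, vset, count, expected, p_exc in rows:
        is_prio = any(u == r[0] for r in prioritized)
        stat, p = (np.nan, np.nan)
        if is_prio:
            carrier = (g_cc[:, vset].sum(axis=1) > 0).astype(float)
            stat, p = cmh_test(carrier, y_cc, strat)
        causal = bool(np.any(annotation.model.causal[vset]))
        out.append({
            "unit": u,
            "level": level,
            "n_variants": len(vset),
            "causal": causal,
            "count": count,
            "expected": expected,
            "p_exceedance": p_exc,
            "discovered": count >= min_copies,
            "prioritized": is_prio,
            "cmh_stat": stat,
            "p_cmh": p,
            "significant": bool(is_prio and p < alpha2 / n_surv),
        })
    return pd.DataFrame(out)
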