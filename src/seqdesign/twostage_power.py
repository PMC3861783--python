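"""Two-stage design evaluation: discovery, prioritization, replication.

Stage 1 sequences a subset (families with a sequenced member subset, or
case-control pairs) to *discover* variants (at least ``c_min`` copies seen)
and *prioritize* them (score statistic above a threshold, or association
p-value below one).  Stage 2 genotypes the prioritized variants in the
remaining sample and tests them with Bonferroni correction over the number
carried forward.  With independent samples in the two stages, overall
power is the product of the stage powers.

All quantities are computed analytically on a (MAF, RR) binned grid whose
per-bin inputs — expected carrier count per sampling unit and score-test
non-centrality per unit — come either from a family gene-dropping
simulation (:func:`family_grid_from_simulation`) or in closed form for
case-control sampling (:func:`case_control_grid`).  Rescaling to a
proposed sample size is linear in both quantities; discovery uses the
Poisson tail and prioritization/replication the non-central chi-square.
Null variants are scaled up to a genome-wide count (default 20 million
total, 1000 causal).  Designs are ranked by ARCE: true positives weighted
by 1/sqrt(MAF), divided by total cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .yield_calc import case_allele_freq

__all__ = [
    "PowerGrid",
    "DesignSpec",
    "DesignResult",
    "family_grid_from_simulation",
    "case_control_grid",
    "build_power_grid",
    "evaluate_design",
    "design_search",
]


@dataclass
class PowerGrid:
    """Per-(MAF, RR)-bin design inputs.

    ``carriage_per_unit``: expected number of sampling units (families /
    case-control pairs) in which a variant of the bin is observed among
    sequenced members, per unit sampled.  ``ncp_per_unit``: score-test
    non-centrality contributed per unit.  ``n_causal`` / ``n_null``: variant
    counts of the simulated pool in the bin (empty bins carry NaN inputs
    and are excluded from sums).
    """

    maf_edges: np.ndarray
    rr_edges: np.ndarray
    n_causal: np.ndarray
    n_null: np.ndarray
    carriage_per_unit: np.ndarray
    ncp_per_unit: np.ndarray
    unit: str = "family"

    @property
    def maf_mid(self) -> np.ndarray:
        return np.sqrt(self.maf_edges[:-1] * self.maf_edges[1:])

    def total_variants(self) -> float:
        return float(np.nansum(self.n_causal) + np.nansum(self.n_null))


def default_maf_bins() -> np.ndarray:
    return np.geomspace(1e-4, 0.5, 8)


def default_rr_bins() -> np.ndarray:
    return np.concatenate([[1.0], np.geomspace(1.1, 20.0, 6)])


def build_power_grid(
    maf, rr, causal, carriage, statistic, n_units,
    maf_bins=None, rr_bins=None, unit="family",
) -> PowerGrid:
    """Bin per-variant simulation output into a :class:`PowerGrid`.

    ``carriage`` is the number of units in which each variant was seen
    among sequenced members; ``statistic`` the per-variant score statistic
    (mean ~ 1 + NCP under the alternative, so the per-unit NCP is
    (mean - 1) / n_units, floored at 0).  Empty bins get NaN inputs.
    """
    maf_bins = default_maf_bins() if maf_bins is None else np.asarray(maf_bins)
    rr_bins = default_rr_bins() if rr_bins is None else np.asarray(rr_bins)
    maf = np.asarray(maf, dtype=float)
    rr = np.asarray(rr, dtype=float)
    causal = np.asarray(causal, dtype=bool)
    mi = np.clip(np.digitize(maf, maf_bins) - 1, 0, maf_bins.size - 2)
    ri = np.clip(np.digitize(rr, rr_bins) - 1, 0, rr_bins.size - 2)
    ri[~causal] = 0
    shape = (maf_bins.size - 1, rr_bins.size - 1)
    n_c = np.zeros(shape)
    n_n = np.zeros(shape)
    carr = np.zeros(shape)
    ncp = np.zeros(shape)
    cnt = np.zeros(shape)
    np.add.at(n_c, (mi[causal], ri[causal]), 1)
    np.add.at(n_n, (mi[~causal], ri[~causal]), 1)
    np.add.at(carr, (mi, ri), np.asarray(carriage, dtype=float))
    np.add.at(ncp, (mi, ri), np.asarray(statistic, dtype=float))
    np.add.at(cnt, (mi, ri), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        carr = np.where(cnt > 0, carr / cnt, np.nan) / n_units
        ncp = np.maximum(np.where(cnt > 0, ncp / cnt, np.nan) - 1.0, 0.0) / n_units
    return PowerGrid(maf_bins, rr_bins, n_c, n_n, carr, ncp, unit)


def family_grid_from_simulation(
    dataset, model, variants=None, maf_bins=None, rr_bins=None,
    score_mode="within",
) -> PowerGrid:
    """Tabulate a gene-dropped family dataset into a power grid.

    Carriage counts families in which the variant appears among *sequenced*
    members; the NCP input is the kinship score statistic.
    """
    from .famprior import family_score

    pop = dataset.pop
    if variants is None:
        variants = np.arange(pop.n_site)
    variants = np.asarray(variants)
    maf = pop.maf[variants]
    rr = np.exp(model.log_rr[variants])
    causal = model.causal[variants]
    carriage = np.empty(variants.size)
    statistic = np.empty(variants.size)
    for k, v in enumerate(variants):
        G = dataset.genotypes(v)
        seen = (np.where(dataset.sequenced, G, 0) > 0).any(axis=1)
        carriage[k] = seen.sum()
        s = family_score(dataset, v, mode=score_mode)
        statistic[k] = s.statistic if s.informative else 1.0
    return build_power_grid(
        maf, rr, causal, carriage, statistic, dataset.n_fam,
        maf_bins, rr_bins, unit="family",
    )


def case_control_grid(
    maf_bins=None, rr_bins=None, n_causal=None, n_null=None,
) -> PowerGrid:
    """Closed-form grid for case-control sampling (unit = one case plus one
    control): carriage is the expected allele count per pair and the NCP
    the usual 2x2 allelic chi-square non-centrality per pair."""
    maf_bins = default_maf_bins() if maf_bins is None else np.asarray(maf_bins)
    rr_bins = default_rr_bins() if rr_bins is None else np.asarray(rr_bins)
    qm = np.sqrt(maf_bins[:-1] * maf_bins[1:])
    rm = np.sqrt(rr_bins[:-1] * rr_bins[1:])
    rm[0] = 1.0
    shape = (qm.size, rm.size)
    carr = np.zeros(shape)
    ncp = np.zeros(shape)
    for i, q in enumerate(qm):
        for j, r in enumerate(rm):
            q1 = case_allele_freq(q, r)
            carr[i, j] = 2 * q1 + 2 * q  # copies per (case, control) pair
            var = q1 * (1 - q1) / 2.0 + q * (1 - q) / 2.0
            ncp[i, j] = (q1 - q) ** 2 / var if var > 0 else 0.0
    n_c = np.zeros(shape) if n_causal is None else np.asarray(n_causal, float)
    n_n = np.zeros(shape) if n_null is None else np.asarray(n_null, float)
    return PowerGrid(maf_bins, rr_bins, n_c, n_n, carr, ncp, unit="pair")


# ---------------------------------------------------------------------------
# Design evaluation
# ---------------------------------------------------------------------------


@dataclass
class DesignSpec:
    """A candidate two-stage design with its cost structure."""

    design_type: str = "family"  # or "case-control"
    total_units: int = 1000
    stage1_prop: float = 0.3
    c_min: int = 2
    threshold: float = 3.0  # score cutoff (family) or p-value (case-control)
    seq_per_family: int = 3
    members_per_family: int = 22
    cost_enroll: float = 1000.0  # per family, or per *subject* for cc
    cost_seq: float = 5000.0
    cost_genotype: float = 0.05
    genome_total: float = 20_000_000.0
    genome_causal: float = 1000.0
    alpha2: float = 0.05
    novel_ref_n: int = 1000
    novel_max_copies: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.stage1_prop <= 1):
            raise ValueError("stage1_prop must lie in (0, 1]")
        if self.c_min < 1:
            raise ValueError("c_min must be >= 1")
        if min(self.cost_enroll, self.cost_seq, self.cost_genotype) < 0:
            raise ValueError("costs must be non-negative")


@dataclass
class DesignResult:
    """Evaluated design: yields, power, cost, and ARCE."""

    spec: DesignSpec
    prop_causal_discovered: float
    n_prioritized: float
    n_prioritized_causal: float
    power_all: float
    power_novel: float
    expected_true_positives: float
    total_cost: float
    arce: float

    def row(self) -> dict:
        s = self.spec
        return {
            "design": s.design_type,
            "total_units": s.total_units,
            "stage1_prop": s.stage1_prop,
            "c_min": s.c_min,
            "threshold": s.threshold,
            "pct_causal_discovered": 100 * self.prop_causal_discovered,
            "n_prioritized": self.n_prioritized,
            "power_all_pct": 100 * self.power_all,
            "power_novel_pct": 100 * self.power_novel,
            "cost_millions": self.total_cost / 1e6,
            "arce_x1000": 1000 * self.arce,
        }


def evaluate_design(grid: PowerGrid, spec: DesignSpec) -> DesignResult:
    """Analytic two-stage evaluation on the binned grid.

    Per bin: P(discovery) = Poisson tail of the rescaled carriage at
    ``c_min``; P(prioritize) = non-central chi-square tail of the rescaled
    stage-1 NCP at the threshold; stage-2 power = non-central chi-square
    tail at the Bonferroni-corrected critical value, the correction
    spanning the expected (genome-scaled) prioritized count.  Overall power
    is the product, summed over causal bins; the novel-variant path
    additionally applies the reference-panel at-most-``novel_max_copies``
    filter.
    """
    n1 = spec.total_units * spec.stage1_prop
    n2 = spec.total_units - n1
    ok = np.isfinite(grid.carriage_per_unit) & np.isfinite(grid.ncp_per_unit)
    if not np.any(ok):
        raise ValueError("empty power grid")
    carr = np.where(ok, grid.carriage_per_unit, 0.0)
    ncp1 = np.where(ok, grid.ncp_per_unit, 0.0) * n1
    ncp2 = np.where(ok, grid.ncp_per_unit, 0.0) * n2

    p_disc = stats.poisson.sf(spec.c_min - 1, carr * n1)
    if spec.design_type == "family":
        crit1 = spec.threshold
    else:
        crit1 = stats.chi2.isf(min(max(spec.threshold, 1e-300), 1.0), 1)
    p_prio = _ncx2_sf(crit1, ncp1)

    n_c = np.where(np.isfinite(grid.n_causal), grid.n_causal, 0.0)
    n_n = np.where(np.isfinite(grid.n_null), grid.n_null, 0.0)
    causal_scale = spec.genome_causal / max(n_c.sum(), 1.0)
    null_scale = spec.genome_total / max(n_n.sum(), 1.0)

    pq = p_disc * p_prio
    m_causal = float(np.sum(n_c * pq)) * causal_scale
    m_null = float(np.sum(n_n * pq)) * null_scale
    m = m_causal + m_null

    p_novel = stats.poisson.cdf(
        spec.novel_max_copies, 2.0 * spec.novel_ref_n * grid.maf_mid
    )[:, None]

    if n2 <= 0 or m <= 0:
        p_rep = np.zeros_like(pq)
    else:
        crit2 = stats.chi2.isf(min(spec.alpha2 / m, 1.0), 1)
        p_rep = _ncx2_sf(crit2, ncp2)

    full = pq * p_rep
    tot_causal = max(n_c.sum(), 1e-300)
    power_all = float(np.sum(n_c * full)) / tot_causal
    tot_novel = max(float(np.sum(n_c * p_novel)), 1e-300)
    power_novel = float(np.sum(n_c * full * p_novel)) / tot_novel
    prop_disc = float(np.sum(n_c * p_disc)) / tot_causal
    tp = float(np.sum(n_c * full)) * causal_scale
    with np.errstate(divide="ignore"):
        w = 1.0 / np.sqrt(grid.maf_mid)[:, None]
    tp_weighted = float(np.sum(n_c * full * w)) * causal_scale

    # cost model (itemized; stage-2 genotyping covers every member)
    if spec.design_type == "family":
        enroll = spec.total_units * spec.cost_enroll
        seq = n1 * spec.seq_per_family * spec.cost_seq
        geno = n2 * spec.members_per_family * m * spec.cost_genotype
    else:
        enroll = spec.total_units * 2 * spec.cost_enroll
        seq = n1 * 2 * spec.cost_seq
        geno = n2 * 2 * m * spec.cost_genotype
    cost = enroll + seq + geno
    arce = tp_weighted / cost if cost > 0 else 0.0
    return DesignResult(
        spec, prop_disc, m, m_causal, power_all, power_novel, tp, cost, arce
    )


def _ncx2_sf(crit, lam):
    lam = np.asarray(lam, dtype=float)
    out = np.empty_like(lam)
    central = lam <= 0
    out[central] = stats.chi2.sf(crit, 1)
    if np.any(~central):
        out[~central] = stats.ncx2.sf(crit, 1, lam[~central])
    return out


def design_search(grid: PowerGrid, design_space, base_spec=None) -> pd.DataFrame:
    """Evaluate every design in a finite space and rank by ARCE.

    ``design_space`` is an iterable of keyword dicts overriding fields of
    ``base_spec`` (a :class:`DesignSpec`).  Returns a DataFrame of result
    rows sorted by descending ARCE.
    """
    base = base_spec or DesignSpec()
    rows = []
    specs = list(design_space)
    if not specs:
        raise ValueError("empty design space")
    for kw in specs:
        res = evaluate_design(grid, replace(base, **kw))
        rows.append(res.row())
    df = pd.DataFrame(rows).sort_values("arce_x1000", ascending=False)
    return df.reset_index(drop=True)
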