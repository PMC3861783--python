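"""Pedigree simulation: gene dropping through a fixed multiplex family.

The working pedigree has 4 generations with two offspring per couple and a
spouse marrying in for every non-terminal child: 22 members in 7 nuclear
families (8 founders, 14 non-founders).  Founders draw two haplotypes at
random from the population pool; each non-founder inherits one complete
haplotype from each parent by a fair coin (no recombination within the
region).  Disease is Bernoulli with logistic risk expit(intercept + genetic
log RR); families reaching a minimum number of affected members are
retained until the target count is ascertained.

An 11-member sub-pedigree (one grandparental couple, two sibships of 3 and
2, mutual first cousins) is provided for exhaustive-enumeration work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .disease_models import VariantEffectModel, haplotype_scores
from .hapsim import HaplotypePopulation

__all__ = [
    "Pedigree",
    "FamilyDataset",
    "standard_pedigree",
    "standard_subpedigree",
    "kinship",
    "relationship",
    "gene_drop",
    "gene_drop_ascertain",
    "parse_design_code",
    "select_members",
]


@dataclass
class Pedigree:
    """Member table: parent indices (-1 for founders) and generation."""

    father: np.ndarray
    mother: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        self.father = np.asarray(self.father, dtype=int)
        self.mother = np.asarray(self.mother, dtype=int)
        self.generation = np.asarray(self.generation, dtype=int)
        for i in range(self.n):
            if (self.father[i] == -1) != (self.mother[i] == -1):
                raise ValueError("members must have two parents or none")
            if max(self.father[i], self.mother[i]) >= i:
                raise ValueError("parents must precede children")

    @property
    def n(self) -> int:
        return self.father.size

    @property
    def founder(self) -> np.ndarray:
        return self.father == -1

    @property
    def n_nuclear_families(self) -> int:
        return len({(f, m) for f, m in zip(self.father, self.mother) if f >= 0})

    def children_of(self, i: int, j: int) -> list[int]:
        return [
            k
            for k in range(self.n)
            if {self.father[k], self.mother[k]} == {i, j}
        ]

    def to_ped_rows(self, family_id: str = "F1"):
        """PLINK PED-style rows (1-based ids, 0 = missing parent)."""
        rows = []
        for i in range(self.n):
            sex = 1 if (self.father[i] == -1 and i % 2 == 0) or (
                self.father[i] >= 0 and i % 2 == 1
            ) else 2
            rows.append(
                (family_id, i + 1, self.father[i] + 1, self.mother[i] + 1, sex)
            )
        return rows


def standard_pedigree() -> Pedigree:
    """The fixed 22-member, 4-generation, 7-nuclear-family structure.

    Members 0-1: founding couple.  Each generation's two children (of each
    couple) marry founders; terminal (4th generation) children do not.
    """
    father = [-1, -1, 0, -1, 0, -1, 2, 2, 4, 4, -1, -1, -1, -1,
              6, 6, 7, 7, 8, 8, 9, 9]
    mother = [-1, -1, 1, -1, 1, -1, 3, 3, 5, 5, -1, -1, -1, -1,
              10, 10, 11, 11, 12, 12, 13, 13]
    gen = [1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 3, 3, 3, 3,
           4, 4, 4, 4, 4, 4, 4, 4]
    # spouse map for generation-3 couples: (6,10), (7,11), (8,12), (9,13)
    return Pedigree(np.array(father), np.array(mother), np.array(gen))


def standard_subpedigree() -> Pedigree:
    """11-member sub-pedigree: grandparental couple, two married-in spouses,
    and two grandchild sibships (3 + 2) who are mutual first cousins."""
    father = [-1, -1, 0, -1, 0, -1, 2, 2, 2, 4, 4]
    mother = [-1, -1, 1, -1, 1, -1, 3, 3, 3, 5, 5]
    gen = [1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 3]
    return Pedigree(np.array(father), np.array(mother), np.array(gen))


def kinship(ped: Pedigree) -> np.ndarray:
    """Kinship matrix by the standard recursive algorithm.

    phi(i,i) = 1/2 (1 + phi(f_i, m_i)); for j < i,
    phi(i,j) = 1/2 (phi(f_i, j) + phi(m_i, j)); founders are unrelated and
    non-inbred.  Requires parents to precede children (validated by the
    Pedigree constructor; cyclic parentage cannot be represented).
    """
    n = ped.n
    K = np.zeros((n, n))
    for i in range(n):
        f, m = ped.father[i], ped.mother[i]
        K[i, i] = 0.5 if f == -1 else 0.5 * (1 + K[f, m])
        for j in range(i):
            K[i, j] = K[j, i] = (
                0.0 if f == -1 else 0.5 * (K[f, j] + K[m, j])
            )
    return K


def _ancestors(ped, i):
    out = {}
    stack = [(i, 0)]
    while stack:
        k, d = stack.pop()
        out[k] = min(out.get(k, 99), d)
        if ped.father[k] >= 0:
            stack.append((ped.father[k], d + 1))
            stack.append((ped.mother[k], d + 1))
    return out


def relationship(ped: Pedigree, i: int, j: int) -> str:
    """Classify the relationship between two members on this structure.

    Returns one of 'self', 'spouse', 'sib', 'parent', 'grandparent',
    'uncle', 'cousin', 'cousin1r' (first cousin once removed), or 'other'.
    Direction-free: 'parent' covers parent-offspring either way.
    """
    if i == j:
        return "self"
    fi, mi = ped.father[i], ped.mother[i]
    fj, mj = ped.father[j], ped.mother[j]
    if fi >= 0 and {fi, mi} == {fj, mj}:
        return "sib"
    if j in (fi, mi) or i in (fj, mj):
        return "parent"
    anc_i = _ancestors(ped, i)
    anc_j = _ancestors(ped, j)
    if j in anc_i and anc_i[j] == 2:
        return "grandparent"
    if i in anc_j and anc_j[i] == 2:
        return "grandparent"
    common = [k for k in anc_i if k in anc_j and anc_i[k] > 0 and anc_j[k] > 0]
    if common:
        d = sorted({(anc_i[k], anc_j[k]) for k in common})
        dmin = d[0]
        pair = tuple(sorted(dmin))
        if pair == (1, 2):
            return "uncle"
        if pair == (2, 2):
            return "cousin"
        if pair == (2, 3):
            return "cousin1r"
    if ped.children_of(i, j):
        return "spouse"
    return "other"


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


@dataclass
class FamilyDataset:
    """Ascertained pedigrees with haplotype assignments and phenotypes.

    ``hap`` holds population haplotype row indices, shape (n_fam, n_member,
    2); genotypes for any variant derive from the population matrix.
    ``sequenced`` masks the members whose genotypes are observed.
    """

    pedigree: Pedigree
    pop: HaplotypePopulation
    hap: np.ndarray
    y: np.ndarray
    sequenced: np.ndarray
    K: np.ndarray = field(default=None)
    n_attempted: int = 0

    def __post_init__(self) -> None:
        if self.K is None:
            self.K = kinship(self.pedigree)

    @property
    def n_fam(self) -> int:
        return self.hap.shape[0]

    def genotypes(self, variant: int) -> np.ndarray:
        """(n_fam, n_member) allele counts for one variant."""
        col = self.pop.haplotypes[:, variant].astype(np.int8)
        return col[self.hap[:, :, 0]] + col[self.hap[:, :, 1]]

    def carrier_families(self, variant: int) -> np.ndarray:
        return np.flatnonzero(self.genotypes(variant).sum(axis=1) > 0)


def gene_drop(
    ped: Pedigree, pop: HaplotypePopulation, n_fam: int, rng
) -> np.ndarray:
    """Vectorized founder draws plus Mendelian transmission (whole
    haplotypes, no recombination).  Returns (n_fam, n_member, 2) indices."""
    hap = np.empty((n_fam, ped.n, 2), dtype=np.int32)
    rows = np.arange(n_fam)
    for i in range(ped.n):
        if ped.father[i] == -1:
            hap[:, i, 0] = rng.integers(0, pop.n_hap, n_fam)
            hap[:, i, 1] = rng.integers(0, pop.n_hap, n_fam)
        else:
            hap[:, i, 0] = hap[rows, ped.father[i], rng.integers(0, 2, n_fam)]
            hap[:, i, 1] = hap[rows, ped.mother[i], rng.integers(0, 2, n_fam)]
    return hap


def gene_drop_ascertain(
    pop: HaplotypePopulation,
    model: VariantEffectModel,
    intercept: float,
    min_cases: int = 4,
    n_families: int = 1000,
    seed: int | None = None,
    pedigree: Pedigree | None = None,
    max_attempts: int = 20_000_000,
    batch: int = 20_000,
) -> FamilyDataset:
    """Rejection-sample families until ``n_families`` have >= ``min_cases``
    affected members.

    The intercept should be pre-calibrated to the target population
    prevalence (see :func:`seqdesign.disease_models.calibrate_intercept`).
    Raises if the ascertainment probability is too small to reach the
    target within ``max_attempts`` attempted families.
    """
    ped = pedigree or standard_pedigree()
    rng = np.random.default_rng(seed)
    scores = haplotype_scores(pop, model)
    keep_h, keep_y = [], []
    accepted = 0
    attempted = 0
    while accepted < n_families:
        if attempted >= max_attempts:
            raise RuntimeError(
                f"ascertained only {accepted}/{n_families} families after "
                f"{attempted} attempts; ascertainment probability too small"
            )
        m = min(batch, max_attempts - attempted)
        hap = gene_drop(ped, pop, m, rng)
        s = scores[hap[:, :, 0]] + scores[hap[:, :, 1]]
        y = (rng.random((m, ped.n)) < expit(intercept + s)).astype(np.int8)
        ok = np.flatnonzero(y.sum(axis=1) >= min_cases)[: n_families - accepted]
        keep_h.append(hap[ok])
        keep_y.append(y[ok])
        accepted += ok.size
        attempted += m
    hap = np.concatenate(keep_h)
    y = np.concatenate(keep_y)
    seqd = np.zeros((n_families, ped.n), dtype=bool)
    return FamilyDataset(ped, pop, hap, y, seqd, n_attempted=attempted)


# ---------------------------------------------------------------------------
# Sequencing-subset selection
# ---------------------------------------------------------------------------

_REL_CODE = {
    "S": "sib",
    "C": "cousin",
    "2": "cousin1r",
    "U": "uncle",
    "G": "grandparent",
    "P": "parent",
}


def parse_design_code(code: str):
    """Parse a member-selection code into (relationship, affected) specs.

    Each character denotes one sequenced member; upper case = affected,
    lower case = unaffected.  The first character is the anchor (its letter
    conventionally repeats the second member's relationship); every later
    character gives that member's relationship to the anchor: S sib, C
    first cousin, 2 first cousin once removed, U uncle/aunt, G grandparent,
    P parent.  E.g. ``"SSC"`` = an affected sib pair plus an affected first
    cousin of the anchor; ``"CCs"`` = an affected first-cousin pair plus an
    unaffected sib of the anchor.
    """
    if not code:
        raise ValueError("empty design code")
    specs = []
    for k, ch in enumerate(code):
        up = ch.upper()
        if up not in _REL_CODE:
            raise ValueError(f"unknown design code letter {ch!r}")
        rel = "self" if k == 0 else _REL_CODE[up]
        specs.append((rel, ch.isupper() or not ch.isalpha()))
    return specs


def select_members(
    ped: Pedigree,
    y: np.ndarray,
    design_code: str,
    seed: int | None = None,
) -> np.ndarray:
    """Flag a member subset matching a relationship/affection pattern.

    Returns a boolean sequenced mask (all False when the pattern cannot be
    matched in this family's phenotype configuration).  Ties among eligible
    assignments are broken by a seeded uniform choice.
    """
    specs = parse_design_code(design_code)
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    solutions: list[tuple[int, ...]] = []

    def extend(chosen: list[int]):
        k = len(chosen)
        if k == len(specs):
            solutions.append(tuple(chosen))
            return
        rel, aff = specs[k]
        for cand in range(ped.n):
            if cand in chosen:
                continue
            if bool(y[cand]) != aff:
                continue
            if k > 0 and relationship(ped, chosen[0], cand) != rel:
                continue
            extend(chosen + [cand])

    extend([])
    mask = np.zeros(ped.n, dtype=bool)
    if not solutions:
        return mask
    # canonical order for determinism, then a seeded pick among solutions
    solutions = sorted(set(tuple(sorted(s)) for s in solutions))
    pick = solutions[rng.integers(0, len(solutions))]
    mask[list(pick)] = True
    return mask
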