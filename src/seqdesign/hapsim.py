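"""Haplotype population simulation and I/O.

All downstream simulators (case-control cohorts, multilevel pathway models,
pedigree gene dropping) draw diplotypes from a single pool of phased binary
haplotypes over a contiguous region.  The pool can be simulated under a
calibrated human demographic model (African + European lineage with out-of-
Africa and population-specific bottlenecks followed by recent expansion,
which produces the heavy excess of very rare variants characteristic of
human resequencing data), under a simple constant-size coalescent, or read
from standard ms-format output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import msprime

__all__ = [
    "HaplotypePopulation",
    "SpectrumSummary",
    "calibrated_human_demography",
    "simulate_population",
    "read_ms",
    "write_ms",
    "maf_spectrum",
]


@dataclass
class HaplotypePopulation:
    """A phased haplotype pool: binary allele matrix plus site coordinates.

    Attributes
    ----------
    haplotypes : (n_hap, n_site) uint8 array
        0 = ancestral, 1 = derived allele.
    positions : (n_site,) float array
        Site coordinates in base pairs, 0-based within ``region_length``,
        non-decreasing (strictly increasing unless duplicate positions were
        deliberately retained on import).
    region_length : float
        Length of the simulated/declared region in base pairs.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    region_length: float

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.positions.shape != (self.haplotypes.shape[1],):
            raise ValueError("positions length must match number of sites")
        if np.any((self.haplotypes != 0) & (self.haplotypes != 1)):
            raise ValueError("haplotype matrix entries must be 0/1")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_site(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def derived_freq(self) -> np.ndarray:
        """Per-site derived allele frequency (column mean)."""
        return self.haplotypes.mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency in (0, 0.5]."""
        p = self.derived_freq
        return np.minimum(p, 1.0 - p)

    def drop_monomorphic(self) -> "HaplotypePopulation":
        p = self.derived_freq
        keep = (p > 0) & (p < 1)
        return HaplotypePopulation(
            self.haplotypes[:, keep], self.positions[keep], self.region_length
        )


@dataclass
class SpectrumSummary:
    """Counts of variants below each MAF cutoff (strict inequality)."""

    thresholds: np.ndarray
    counts: np.ndarray
    total: int

    def fractions(self) -> np.ndarray:
        return self.counts / max(self.total, 1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("maf_threshold\tcount\tfraction\n")
            for t, c in zip(self.thresholds, self.counts):
                fh.write(f"{t:g}\t{c}\t{c / max(self.total, 1):.6g}\n")
            fh.write(f"total\t{self.total}\t1\n")


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

#: cosi "bestfit" parameters (generations ago / diploid sizes) for the
#: African + European lineage; bottlenecks are specified by an inbreeding
#: coefficient F and realized as instantaneous bottlenecks of strength
#: -2N log(1-F) equivalent generations.
_CAL = dict(
    n_present=100_000,
    afr_agric_time=200,
    afr_agric_size=24_000,
    eur_agric_time=350,
    eur_agric_size=7_700,
    mig_rate=3.2e-5,
    mig_stop_time=1996,
    afr_bottleneck=(1997, 0.008),
    eur_bottleneck=(1999, 0.02),
    ooa_bottleneck=(3499, 0.085),
    ooa_split_time=3500,
    afr_ancient_time=17_000,
    afr_ancient_size=12_500,
    mutation_rate=1.5e-8,
    recombination_rate=1.0e-8,
)


def calibrated_human_demography() -> msprime.Demography:
    """Two-deme calibrated human demography (African + European lineage).

    Recent expansion to 100,000, agricultural-era sizes, population-specific
    bottlenecks, symmetric Africa-Europe migration while both demes exist,
    and an out-of-Africa bottleneck at the split.  A mass migration (rather
    than a population split event) merges Europe into Africa so that both
    demes remain active during the migration epoch.
    """
    c = _CAL
    d = msprime.Demography()
    d.add_population(name="AFR", initial_size=c["n_present"])
    d.add_population(name="EUR", initial_size=c["n_present"])
    d.set_symmetric_migration_rate(["AFR", "EUR"], c["mig_rate"])
    d.add_population_parameters_change(
        time=c["afr_agric_time"], population="AFR", initial_size=c["afr_agric_size"]
    )
    d.add_population_parameters_change(
        time=c["eur_agric_time"], population="EUR", initial_size=c["eur_agric_size"]
    )
    d.add_symmetric_migration_rate_change(
        time=c["mig_stop_time"], populations=["AFR", "EUR"], rate=0
    )

    def _bneck(time, pop, size, F):
        d.add_instantaneous_bottleneck(
            time=time, population=pop, strength=-2.0 * size * np.log1p(-F)
        )

    _bneck(c["afr_bottleneck"][0], "AFR", c["afr_agric_size"], c["afr_bottleneck"][1])
    _bneck(c["eur_bottleneck"][0], "EUR", c["eur_agric_size"], c["eur_bottleneck"][1])
    _bneck(c["ooa_bottleneck"][0], "EUR", c["eur_agric_size"], c["ooa_bottleneck"][1])
    d.add_mass_migration(
        time=c["ooa_split_time"], source="EUR", dest="AFR", proportion=1.0
    )
    d.add_population_parameters_change(
        time=c["afr_ancient_time"], population="AFR", initial_size=c["afr_ancient_size"]
    )
    d.sort_events()
    return d


def simulate_population(
    demography: str = "calibrated_human",
    n_hap: int = 10_000,
    region_length_bp: float = 250_000,
    seed: int | None = None,
    *,
    Ne: float = 10_000,
    mutation_rate: float | None = None,
    recombination_rate: float | None = None,
) -> HaplotypePopulation:
    """Simulate a haplotype pool under a named demographic model.

    Parameters
    ----------
    demography
        ``"calibrated_human"`` (default; European haplotype sample under the
        calibrated two-deme model) or ``"constant"`` (single deme of diploid
        size ``Ne``).
    n_hap
        Number of sampled haplotypes (haploid sample size).
    region_length_bp
        Region length in base pairs.
    seed
        Random seed; identical seed and configuration reproduce the output
        exactly.

    Raises
    ------
    ValueError
        Unknown demography name, or no segregating sites in the realization
        (advises a larger region or mutation rate).
    """
    if n_hap < 2:
        raise ValueError("n_hap must be >= 2")
    if region_length_bp <= 0:
        raise ValueError("region_length_bp must be positive")
    seed = None if seed is None else int(seed) % (2**31 - 2) + 1

    # population sizes are diploid; sample diploid individuals and keep
    # n_hap haplotypes
    n_ind = (n_hap + 1) // 2
    if demography == "calibrated_human":
        dem = calibrated_human_demography()
        samples = {"EUR": n_ind}
        mu = _CAL["mutation_rate"] if mutation_rate is None else mutation_rate
        rho = _CAL["recombination_rate"] if recombination_rate is None else recombination_rate
    elif demography == "constant":
        dem = msprime.Demography.isolated_model([Ne])
        samples = n_ind
        mu = 1.5e-8 if mutation_rate is None else mutation_rate
        rho = 1.0e-8 if recombination_rate is None else recombination_rate
    else:
        raise ValueError(
            f"unknown demography {demography!r}; expected 'calibrated_human' or 'constant'"
        )

    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=region_length_bp,
        recombination_rate=rho,
        ploidy=2,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=mu, random_seed=seed, model=msprime.BinaryMutationModel()
    )
    if mts.num_sites == 0:
        raise ValueError(
            "no segregating sites simulated; increase the region length or "
            "the mutation rate"
        )
    G = mts.genotype_matrix().T.astype(np.uint8)[:n_hap]  # haplotypes x sites
    pos = np.array([s.position for s in mts.sites()], dtype=float)
    pop = HaplotypePopulation(G, pos, float(region_length_bp)).drop_monomorphic()
    if pop.n_site == 0:
        raise ValueError(
            "no segregating sites after monomorphic filtering; increase the "
            "region length or the mutation rate"
        )
    return pop


# ---------------------------------------------------------------------------
# ms-format I/O
# ---------------------------------------------------------------------------


def write_ms(pop: HaplotypePopulation, path) -> None:
    """Write a population as a single-replicate ms-format file.

    Positions are written as fractions of the region length with enough
    digits that a read/write round trip preserves the allele matrix exactly.
    """
    with open(path, "w") as fh:
        fh.write(f"ms {pop.n_hap} 1\nseqdesign\n\n//\n")
        fh.write(f"segsites: {pop.n_site}\n")
        frac = pop.positions / pop.region_length
        fh.write("positions: " + " ".join(f"{x:.10f}" for x in frac) + "\n")
        for row in pop.haplotypes:
            fh.write("".join("1" if a else "0" for a in row) + "\n")


def read_ms(
    path,
    region_length_bp: float = 1.0,
    duplicate_positions: str = "keep",
) -> HaplotypePopulation:
    """Read the first replicate of an ms-format file.

    Parameters
    ----------
    region_length_bp
        Declared region length; ms positions (fractions in [0,1]) are
        rescaled to base pairs.
    duplicate_positions
        ``"keep"`` retains colliding positions in column order (ms output can
        collide after rescaling of an infinite-sites model); ``"reject"``
        raises.
    """
    if duplicate_positions not in ("keep", "reject"):
        raise ValueError("duplicate_positions must be 'keep' or 'reject'")
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.startswith("//"))
    except StopIteration:
        raise ValueError("malformed ms file: no replicate marker '//'") from None
    body = lines[start + 1 :]
    if not body or not body[0].startswith("segsites:"):
        raise ValueError("malformed ms file: missing 'segsites:' header")
    segsites = int(body[0].split()[1])
    if segsites == 0:
        raise ValueError("ms file contains no segregating sites")
    if len(body) < 2 or not body[1].startswith("positions:"):
        raise ValueError("malformed ms file: missing 'positions:' header")
    pos = np.array([float(x) for x in body[1].split()[1:]], dtype=float)
    if pos.size != segsites:
        raise ValueError("malformed ms file: positions count != segsites")
    rows = []
    for k, ln in enumerate(body[2:]):
        ln = ln.strip()
        if not ln:
            break
        if len(ln) != segsites or set(ln) - {"0", "1"}:
            raise ValueError(
                f"malformed ms file: bad haplotype row at line {start + 3 + k + 1}"
            )
        rows.append(np.frombuffer(ln.encode(), dtype=np.uint8) - ord("0"))
    if not rows:
        raise ValueError("malformed ms file: no haplotype rows")
    pos_bp = pos * region_length_bp
    if duplicate_positions == "reject" and np.any(np.diff(pos_bp) <= 0):
        raise ValueError("duplicate positions in ms file")
    return HaplotypePopulation(np.array(rows), pos_bp, float(region_length_bp))


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------


def maf_spectrum(
    pop: HaplotypePopulation, thresholds: Sequence[float]
) -> SpectrumSummary:
    """Count variants with MAF strictly below each cutoff.

    ``thresholds`` must be sorted ascending, each in (0, 0.5].
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.size == 0 or np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be non-empty and sorted ascending")
    if np.any(thr <= 0) or np.any(thr > 0.5):
        raise ValueError("thresholds must lie in (0, 0.5]")
    maf = pop.maf
    counts = np.array([int(np.sum(maf < t)) for t in thr])
    return SpectrumSummary(thr, counts, int(maf.size))


def watterson_expected_segsites(n_hap: int, theta_per_bp: float, length_bp: float):
    """Closed-form Watterson expectation and SD of the segregating-site count.

    E[S] = theta L sum_{i<n} 1/i ;  Var[S] = E[S] + (theta L)^2 sum 1/i^2,
    with theta = 4 N mu per bp on the diploid time scale.
    """
    i = np.arange(1, n_hap)
    tl = theta_per_bp * length_bp
    mean = tl * np.sum(1.0 / i)
    var = mean + tl**2 * np.sum(1.0 / i**2)
    return mean, np.sqrt(var)
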