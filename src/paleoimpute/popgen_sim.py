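"""Synthetic phased reference panels and target individuals.

This module builds the population-genetic scaffolding for the workbench: a
phased biallelic SNP panel with linkage disequilibrium and population
structure, held-out "ancient" diploid targets, admixed individuals with
recorded ancestry tracts, and diploid reference cohorts for PCA.

Linkage disequilibrium is produced by founder-mosaic copying: each panel
haplotype is a mosaic of a small number of population founder haplotypes,
with switch probability per inter-site interval 1 - exp(-dcM * s).  This
yields realistic LD decay without a coalescent simulator.  Population
divergence follows the Balding-Nichols model: per-population allele
frequencies are Beta draws around an ancestral frequency with variance
controlled by Fst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeneticMap",
    "SitePanel",
    "Individual",
    "simulate_panel",
    "sample_individual",
    "simulate_admixed",
    "cohort_genotypes",
]

# ordered (ref, alt) nucleotide pairs
TRANSITION_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
TRANSVERSION_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
]


@dataclass
class GeneticMap:
    """Physical -> genetic coordinates at panel sites.

    positions are 1-based base pairs, strictly increasing; cm is the
    cumulative genetic position in centimorgan, non-decreasing.
    """

    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.positions.shape != self.cm.shape:
            raise ValueError("positions and cm must have the same length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.cm) and np.any(np.diff(self.cm) < 0):
            raise ValueError("cm must be non-decreasing")

    @classmethod
    def uniform(cls, positions: np.ndarray, cm_per_mb: float = 1.0) -> "GeneticMap":
        """Uniform recombination map (default 1 cM/Mb)."""
        positions = np.asarray(positions, dtype=np.int64)
        return cls(positions=positions, cm=positions * (cm_per_mb / 1e6))


@dataclass
class SitePanel:
    """Phased biallelic haplotype reference panel on one linear chromosome.

    hap is an (H, M) matrix over {0, 1} with 0 = reference allele; every
    site is polymorphic in the panel and positions are strictly increasing.
    """

    chrom: str
    positions: np.ndarray          # (M,) 1-based bp
    ref_base: np.ndarray           # (M,) single characters
    alt_base: np.ndarray
    hap: np.ndarray                # (H, M) uint8 in {0,1}
    pop_of_hap: np.ndarray         # (H,) population labels
    map: GeneticMap
    genome_length: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_base = np.asarray(self.ref_base, dtype="<U1")
        self.alt_base = np.asarray(self.alt_base, dtype="<U1")
        self.hap = np.asarray(self.hap, dtype=np.uint8)
        self.pop_of_hap = np.asarray(self.pop_of_hap)
        H, M = self.hap.shape
        if H % 2:
            raise ValueError("panel must contain an even number of haplotypes")
        if len(self.positions) != M:
            raise ValueError("positions length must match haplotype matrix")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.positions[-1] > self.genome_length:
            raise ValueError("positions exceed genome_length")
        if np.any(self.ref_base == self.alt_base):
            raise ValueError("ref and alt base must differ at every site")
        ac = self.hap.sum(axis=0)
        if np.any(ac == 0) or np.any(ac == H):
            raise ValueError("every site must be polymorphic in the panel")

    @property
    def n_hap(self) -> int:
        return self.hap.shape[0]

    @property
    def n_sites(self) -> int:
        return self.hap.shape[1]

    @property
    def pops(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_of_hap:
            seen.setdefault(str(p), None)
        return list(seen)

    def alt_freq(self, pop: str | None = None) -> np.ndarray:
        """Per-site alternate-allele frequency, optionally within one population."""
        if pop is None:
            return self.hap.mean(axis=0)
        sel = self.pop_of_hap == pop
        if not sel.any():
            raise KeyError(f"unknown population label: {pop}")
        return self.hap[sel].mean(axis=0)

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def hap_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(self.pop_of_hap == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population label: {pop}")
        return idx

    def is_transition(self) -> np.ndarray:
        """Boolean per site: ref/alt is A<->G or C<->T."""
        pairs = np.char.add(self.ref_base, self.alt_base)
        return np.isin(pairs, ["AG", "GA", "CT", "TC"])


@dataclass
class Individual:
    """A diploid individual over the panel's sites.

    truth_tracts, when present, records the simulated ancestry ground truth
    as (start_cm, end_cm, ancestry_label, hap_index) intervals that tile
    [0, total cM] per haplotype.
    """

    hap1: np.ndarray
    hap2: np.ndarray
    pop: str
    truth_tracts: list[tuple[float, float, str, int]] | None = None

    def __post_init__(self) -> None:
        self.hap1 = np.asarray(self.hap1, dtype=np.uint8)
        self.hap2 = np.asarray(self.hap2, dtype=np.uint8)
        if self.hap1.shape != self.hap2.shape:
            raise ValueError("haplotypes must have equal length")

    @property
    def genotype(self) -> np.ndarray:
        return (self.hap1 + self.hap2).astype(np.int8)


def _neutral_frequencies(rng: np.random.Generator, n: int, maf_min: float) -> np.ndarray:
    # spectrum proportional to 1/f on [maf_min, 1 - maf_min], by inverse CDF
    u = rng.random(n)
    lo, hi = maf_min, 1.0 - maf_min
    return lo * (hi / lo) ** u


def _mosaic_haplotype(
    rng: np.random.Generator,
    founders: np.ndarray,
    p_switch: np.ndarray,
) -> np.ndarray:
    """One haplotype as a Markov mosaic over founder rows."""
    n_f, m = founders.shape
    switch = np.empty(m, dtype=bool)
    switch[0] = True
    switch[1:] = rng.random(m - 1) < p_switch
    seg_id = np.cumsum(switch) - 1
    founder_of_seg = rng.integers(0, n_f, size=seg_id[-1] + 1)
    return founders[founder_of_seg[seg_id], np.arange(m)]


def simulate_panel(
    n_pops: int,
    haps_per_pop: int,
    n_sites: int,
    genome_length: int,
    fst: float = 0.0,
    ts_fraction: float = 0.687,
    maf_min: float = 0.01,
    seed: int = 0,
    n_founders: int = 16,
    switch_scale: float = 3.0,
    cm_per_mb: float = 1.0,
    chrom: str = "1",
) -> SitePanel:
    """Simulate a phased biallelic reference panel with LD and structure.

    Ancestral allele frequencies follow a neutral-like 1/f spectrum
    truncated at ``maf_min``; population frequencies are Balding-Nichols
    draws with divergence ``fst`` (fst=0 collapses to a panmictic panel).
    Haplotypes are founder mosaics with switch probability
    1 - exp(-dcM * switch_scale) per interval, which creates LD.  Ref/alt
    nucleotides are transition pairs (A<->G, C<->T) with probability
    ``ts_fraction``; the C/T and G/A identity of a site is what couples it
    to the deamination model downstream.

    Deterministic given ``seed``.
    """
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    if haps_per_pop % 2:
        raise ValueError("haps_per_pop must be even")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if maf_min >= 0.5:
        raise ValueError("maf_min must be < 0.5")

    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(genome_length, size=n_sites, replace=False)) + 1
    gmap = GeneticMap.uniform(positions, cm_per_mb=cm_per_mb)
    p_switch = 1.0 - np.exp(-np.diff(gmap.cm) * switch_scale)

    p_anc = _neutral_frequencies(rng, n_sites, maf_min)
    H = n_pops * haps_per_pop
    hap = np.empty((H, n_sites), dtype=np.uint8)
    pop_labels = [f"pop{i}" for i in range(n_pops)]
    pop_of_hap = np.repeat(pop_labels, haps_per_pop)

    # the finite founder pool itself contributes ~ (1-F)/n_founders of
    # between-population variance, so the Balding-Nichols parameter is
    # deflated to make the REALIZED divergence match the requested fst;
    # with fst=0 all populations share one founder pool (panmixia).
    shared_founders = (rng.random((n_founders, n_sites)) < p_anc).astype(np.uint8)
    if fst > 0.0:
        fst_bn = max((fst - 1.0 / n_founders) / (1.0 - 1.0 / n_founders), 1e-6)
    for i in range(n_pops):
        if fst > 0.0:
            a = p_anc * (1.0 - fst_bn) / fst_bn
            b = (1.0 - p_anc) * (1.0 - fst_bn) / fst_bn
            p_pop = np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)
            founders = (rng.random((n_founders, n_sites)) < p_pop).astype(np.uint8)
        else:
            founders = shared_founders
        for j in range(haps_per_pop):
            hap[i * haps_per_pop + j] = _mosaic_haplotype(rng, founders, p_switch)

    _enforce_min_maf(rng, hap, maf_min)

    is_ts = rng.random(n_sites) < ts_fraction
    ref = np.empty(n_sites, dtype="<U1")
    alt = np.empty(n_sites, dtype="<U1")
    ts_idx = rng.integers(0, len(TRANSITION_PAIRS), size=n_sites)
    tv_idx = rng.integers(0, len(TRANSVERSION_PAIRS), size=n_sites)
    for j in range(n_sites):
        r, a = TRANSITION_PAIRS[ts_idx[j]] if is_ts[j] else TRANSVERSION_PAIRS[tv_idx[j]]
        ref[j], alt[j] = r, a

    return SitePanel(
        chrom=chrom,
        positions=positions,
        ref_base=ref,
        alt_base=alt,
        hap=hap,
        pop_of_hap=pop_of_hap,
        map=gmap,
        genome_length=int(genome_length),
    )


def _enforce_min_maf(rng: np.random.Generator, hap: np.ndarray, maf_min: float) -> None:
    """Flip alleles at under-polymorphic sites until panel MAF >= maf_min.

    Mirrors the panel-construction filter of real imputation panels
    (singletons and monomorphic sites excluded) without dropping sites, so
    the site universe stays fixed.  In-place; deterministic given rng.
    """
    H = hap.shape[0]
    min_count = max(1, math.ceil(maf_min * H))
    ac = hap.sum(axis=0).astype(np.int64)
    for j in np.flatnonzero(ac < min_count):
        carriers = np.flatnonzero(hap[:, j] == 0)
        flip = rng.choice(carriers, size=min_count - ac[j], replace=False)
        hap[flip, j] = 1
    ac = hap.sum(axis=0).astype(np.int64)
    for j in np.flatnonzero(ac > H - min_count):
        carriers = np.flatnonzero(hap[:, j] == 1)
        flip = rng.choice(carriers, size=ac[j] - (H - min_count), replace=False)
        hap[flip, j] = 0


def sample_individual(
    panel: SitePanel,
    pop: str,
    copy_error: float = 0.0,
    seed: int = 0,
    switch_rate: float = 1.0,
) -> Individual:
    """Draw a diploid individual as a haplotype-copying mosaic of one population.

    Each haplotype is a Li-Stephens-style mosaic of the panel haplotypes of
    ``pop`` with per-interval switch probability 1 - exp(-dcM * switch_rate)
    and independent per-site allele flip probability ``copy_error``.  With
    switch_rate=0 and copy_error=0 the individual is an exact panel
    haplotype pair.
    """
    rng = np.random.default_rng(seed)
    pool = panel.hap[panel.hap_indices(pop)]
    p_switch = 1.0 - np.exp(-np.diff(panel.map.cm) * switch_rate)
    haps = []
    for _ in range(2):
        h = _mosaic_haplotype(rng, pool, p_switch).astype(np.uint8)
        if copy_error > 0.0:
            flip = rng.random(panel.n_sites) < copy_error
            h = np.where(flip, 1 - h, h).astype(np.uint8)
        haps.append(h)
    return Individual(hap1=haps[0], hap2=haps[1], pop=pop)


def simulate_admixed(
    panel: SitePanel,
    pop_a: str,
    pop_b: str,
    alpha: float,
    generations: int,
    seed: int = 0,
) -> Individual:
    """Simulate an admixed diploid with recombination-scaled ancestry tracts.

    Per haplotype, crossover breakpoints form a Poisson process of rate
    ``generations`` per Morgan along the genetic map; each inter-breakpoint
    segment draws ancestry pop_b with probability ``alpha`` and copies its
    alleles from one random haplotype of that population.  The segment
    process (breakpoints plus per-segment ancestry draws) is recorded
    verbatim in ``truth_tracts``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    cm = panel.map.cm
    total_cm = float(cm[-1])
    rate_per_cm = generations / 100.0
    pools = {p: panel.hap[panel.hap_indices(p)] for p in (pop_a, pop_b)}

    haps = []
    tracts: list[tuple[float, float, str, int]] = []
    for hap_index in range(2):
        breaks = [0.0]
        while True:
            nxt = breaks[-1] + rng.exponential(1.0 / rate_per_cm)
            if nxt >= total_cm:
                break
            breaks.append(nxt)
        breaks.append(total_cm)
        h = np.empty(panel.n_sites, dtype=np.uint8)
        for lo, hi in zip(breaks[:-1], breaks[1:]):
            anc = pop_b if rng.random() < alpha else pop_a
            src = pools[anc][rng.integers(0, len(pools[anc]))]
            # segments are [lo, hi); the final segment also takes cm == total_cm
            sel = (cm >= lo) & ((cm < hi) | (hi == total_cm))
            h[sel] = src[sel]
            tracts.append((lo, hi, anc, hap_index))
        haps.append(h)
    return Individual(hap1=haps[0], hap2=haps[1], pop=f"admixed({pop_a},{pop_b})",
                      truth_tracts=tracts)


def cohort_genotypes(
    panel: SitePanel,
    n_per_pop: int,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Pair disjoint panel haplotypes into a diploid reference cohort.

    Returns an (N, M) genotype matrix over {0,1,2} and the population label
    of each individual.  Used as the PCA reference cohort.
    """
    rng = np.random.default_rng(seed)
    genos = []
    labels = []
    for pop in panel.pops:
        idx = panel.hap_indices(pop)
        if 2 * n_per_pop > idx.size:
            raise ValueError(f"not enough haplotypes in {pop} for {n_per_pop} individuals")
        chosen = rng.choice(idx, size=2 * n_per_pop, replace=False)
        for k in range(n_per_pop):
            g = panel.hap[chosen[2 * k]] + panel.hap[chosen[2 * k + 1]]
            genos.append(g.astype(np.int8))
            labels.append(pop)
    return np.asarray(genos), labels
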