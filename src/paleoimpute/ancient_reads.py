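"""Ancient sequencing-fragment simulation and damage profiling.

Fragments carry base observations only at panel SNP sites (no read mapping,
no full sequences).  The deamination channel follows the standard
end-overhang model of post-mortem damage: the probability that a cytosine
reads as thymine at 1-based distance d from a fragment end is

    delta(d) = udg_factor * [deam_ds + (deam_ss - deam_ds) * (1 - overhang_p)**(d-1)]

For double-strand libraries on + strand fragments, reference C reads T with
delta5(d5) and reference G reads A with delta3(d3); on - strand fragments
the roles swap (the fragment's 5' terminus is its rightmost reference
coordinate).  Single-strand libraries deaminate C at both ends.  After the
damage channel, a uniform sequencing-error channel is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .popgen_sim import Individual, SitePanel

__all__ = [
    "DamageModelParams",
    "Fragment",
    "ReadSet",
    "DamageProfile",
    "params_for_pmd",
    "simulate_reads",
    "downsample_reads",
    "trim_reads",
    "estimate_damage_profile",
    "fit_damage_model",
]

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
A, C, G, T = 0, 1, 2, 3

MIN_FRAG_LEN = 30
MAX_FRAG_LEN = 150


@dataclass(frozen=True)
class DamageModelParams:
    """Parameters of the post-mortem deamination channel.

    nick_freq is accepted for configuration compatibility with standard
    aDNA read simulators but is unused by the simplified channel: nicks are
    irrelevant at SNP-site resolution (a warning is issued at simulation
    time when it is non-zero).  ``deam_ss`` is the single-strand overhang
    deamination probability (the quantity swept in damage experiments);
    ``deam_ds`` the residual double-strand rate; ``overhang_p`` the
    geometric parameter of overhang length; ``udg_factor`` scales the whole
    channel to model UDG treatment (1 = untreated, 0 = fully repaired).
    """

    nick_freq: float = 0.024
    overhang_p: float = 0.36
    deam_ds: float = 0.0097
    deam_ss: float = 0.0
    seq_error: float = 0.001
    udg_factor: float = 1.0
    library: str = "double_strand"

    def __post_init__(self) -> None:
        for name in ("nick_freq", "overhang_p", "deam_ds", "deam_ss",
                     "seq_error", "udg_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.library not in ("double_strand", "single_strand"):
            raise ValueError("library must be 'double_strand' or 'single_strand'")
        if 0.0 < self.deam_ss < self.deam_ds:
            warnings.warn("deam_ss < deam_ds is unusual for ancient libraries",
                          stacklevel=3)

    def delta(self, d: np.ndarray) -> np.ndarray:
        """Deamination probability at 1-based distance d from a fragment end."""
        d = np.asarray(d, dtype=float)
        return self.udg_factor * (
            self.deam_ds
            + (self.deam_ss - self.deam_ds) * (1.0 - self.overhang_p) ** (d - 1.0)
        )

    def delta5_at_1(self) -> float:
        """Model-implied C->T rate at the 5' first position (headline PMD rate)."""
        return float(self.delta(np.array([1.0]))[0])


def params_for_pmd(pmd: float, **kwargs) -> DamageModelParams:
    """Damage parameters calibrated so the model-implied delta5(1) equals ``pmd``.

    At d=1 the closed form reduces to udg_factor * deam_ss, so deam_ss is
    solved directly; deam_ds is lowered when it would exceed the target.
    """
    base = DamageModelParams(**kwargs)
    if pmd > 0 and base.udg_factor <= 0:
        raise ValueError("cannot reach a positive PMD rate with udg_factor 0")
    ss = pmd / base.udg_factor if base.udg_factor > 0 else 0.0
    return replace(base, deam_ss=ss, deam_ds=min(base.deam_ds, ss))


@dataclass
class Fragment:
    """A single sequencing fragment (materialized view for small inputs)."""

    start: int
    end: int
    strand: str                       # '+' or '-'
    source: str                       # 'endogenous' or 'contaminant'
    obs: list[tuple[int, str, int]]   # (site_index, observed_base, qual)


@dataclass
class ReadSet:
    """Simulated fragments with per-site base observations (columnar storage).

    Fragment-level arrays are indexed by fragment id; observation-level
    arrays are parallel, with ``obs_frag`` linking each observation back to
    its fragment and ``obs_pos`` carrying the 1-based bp coordinate of the
    observed site.  ``realized_coverage`` is total site observations
    divided by the number of panel sites.
    """

    n_sites: int
    frag_start: np.ndarray   # (F,) int64, 1-based inclusive
    frag_end: np.ndarray     # (F,)
    frag_strand: np.ndarray  # (F,) uint8: 0='+', 1='-'
    frag_source: np.ndarray  # (F,) uint8: 0=endogenous, 1=contaminant
    obs_frag: np.ndarray     # (N,) int64 fragment index
    obs_site: np.ndarray     # (N,) int64 site index into the panel
    obs_pos: np.ndarray      # (N,) int64 site bp coordinate
    obs_base: np.ndarray     # (N,) uint8 code into BASES
    obs_qual: np.ndarray     # (N,) int16 phred

    def __post_init__(self) -> None:
        n = len(self.obs_frag)
        for a in (self.obs_site, self.obs_pos, self.obs_base, self.obs_qual):
            if len(a) != n:
                raise ValueError("observation arrays must be parallel")

    @property
    def n_fragments(self) -> int:
        return len(self.frag_start)

    @property
    def n_obs(self) -> int:
        return len(self.obs_site)

    @property
    def realized_coverage(self) -> float:
        return self.n_obs / self.n_sites

    def depth(self) -> np.ndarray:
        """Per-site observation count."""
        return np.bincount(self.obs_site, minlength=self.n_sites)

    def end_distances(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-observation 1-based distances to the fragment's 5' / 3' termini.

        For + strand fragments the 5' terminus is ``start``; for - strand
        fragments it is ``end`` (reference coordinates).
        """
        start = self.frag_start[self.obs_frag]
        end = self.frag_end[self.obs_frag]
        left = self.obs_pos - start + 1
        right = end - self.obs_pos + 1
        minus = self.frag_strand[self.obs_frag] == 1
        d5 = np.where(minus, right, left)
        d3 = np.where(minus, left, right)
        return d5, d3

    def select_fragments(self, keep: np.ndarray) -> "ReadSet":
        """Subset to the fragments flagged in the boolean mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        new_id = np.full(self.n_fragments, -1, dtype=np.int64)
        new_id[keep] = np.arange(int(keep.sum()))
        obs_keep = keep[self.obs_frag]
        return ReadSet(
            n_sites=self.n_sites,
            frag_start=self.frag_start[keep],
            frag_end=self.frag_end[keep],
            frag_strand=self.frag_strand[keep],
            frag_source=self.frag_source[keep],
            obs_frag=new_id[self.obs_frag[obs_keep]],
            obs_site=self.obs_site[obs_keep],
            obs_pos=self.obs_pos[obs_keep],
            obs_base=self.obs_base[obs_keep],
            obs_qual=self.obs_qual[obs_keep],
        )

    def select_obs(self, keep: np.ndarray) -> "ReadSet":
        """Keep the flagged observations; drop fragments left with none."""
        keep = np.asarray(keep, dtype=bool)
        frag_has_obs = np.zeros(self.n_fragments, dtype=bool)
        frag_has_obs[self.obs_frag[keep]] = True
        new_id = np.full(self.n_fragments, -1, dtype=np.int64)
        new_id[frag_has_obs] = np.arange(int(frag_has_obs.sum()))
        return ReadSet(
            n_sites=self.n_sites,
            frag_start=self.frag_start[frag_has_obs],
            frag_end=self.frag_end[frag_has_obs],
            frag_strand=self.frag_strand[frag_has_obs],
            frag_source=self.frag_source[frag_has_obs],
            obs_frag=new_id[self.obs_frag[keep]],
            obs_site=self.obs_site[keep],
            obs_pos=self.obs_pos[keep],
            obs_base=self.obs_base[keep],
            obs_qual=self.obs_qual[keep],
        )

    def fragments(self) -> list[Fragment]:
        """Materialize Fragment views (small inputs / display only)."""
        out = [
            Fragment(
                start=int(self.frag_start[f]),
                end=int(self.frag_end[f]),
                strand="-" if self.frag_strand[f] else "+",
                source="contaminant" if self.frag_source[f] else "endogenous",
                obs=[],
            )
            for f in range(self.n_fragments)
        ]
        for k in np.argsort(self.obs_frag, kind="stable"):
            out[int(self.obs_frag[k])].obs.append(
                (int(self.obs_site[k]), BASES[self.obs_base[k]], int(self.obs_qual[k]))
            )
        return out

    def to_tsv(self, path, chrom: str = "1") -> None:
        """Write one row per site observation (plain-text fragment exchange format)."""
        df = pd.DataFrame(
            {
                "frag": self.obs_frag,
                "chrom": chrom,
                "start": self.frag_start[self.obs_frag],
                "end": self.frag_end[self.obs_frag],
                "strand": np.where(self.frag_strand[self.obs_frag] == 1, "-", "+"),
                "source": np.where(
                    self.frag_source[self.obs_frag] == 1, "contaminant", "endogenous"
                ),
                "site_pos": self.obs_pos,
                "obs_base": np.array(list(BASES))[self.obs_base],
                "qual": self.obs_qual,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, panel: SitePanel) -> "ReadSet":
        df = pd.read_csv(path, sep="\t")
        if len(df) == 0:
            return cls.empty(panel.n_sites)
        frag_col = df["frag"].to_numpy(np.int64)
        frag_ids, frag_first, obs_frag = np.unique(
            frag_col, return_index=True, return_inverse=True
        )
        site = np.searchsorted(panel.positions, df["site_pos"].to_numpy(np.int64))
        bad = (site >= panel.n_sites) | (
            panel.positions[np.clip(site, 0, panel.n_sites - 1)]
            != df["site_pos"].to_numpy(np.int64)
        )
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"row {row + 2}: position {df['site_pos'].iloc[row]} is not a panel site"
            )
        return cls(
            n_sites=panel.n_sites,
            frag_start=df["start"].to_numpy(np.int64)[frag_first],
            frag_end=df["end"].to_numpy(np.int64)[frag_first],
            frag_strand=(df["strand"].to_numpy() == "-")[frag_first].astype(np.uint8),
            frag_source=(df["source"].to_numpy() == "contaminant")[frag_first].astype(np.uint8),
            obs_frag=obs_frag.astype(np.int64),
            obs_site=site.astype(np.int64),
            obs_pos=df["site_pos"].to_numpy(np.int64),
            obs_base=np.array([BASE_CODE[b] for b in df["obs_base"]], dtype=np.uint8),
            obs_qual=df["qual"].to_numpy(np.int16),
        )

    @classmethod
    def empty(cls, n_sites: int) -> "ReadSet":
        z = np.zeros(0, dtype=np.int64)
        return cls(
            n_sites=n_sites,
            frag_start=z, frag_end=z.copy(),
            frag_strand=np.zeros(0, dtype=np.uint8),
            frag_source=np.zeros(0, dtype=np.uint8),
            obs_frag=z.copy(), obs_site=z.copy(), obs_pos=z.copy(),
            obs_base=np.zeros(0, dtype=np.uint8),
            obs_qual=np.zeros(0, dtype=np.int16),
        )


@dataclass
class DamageProfile:
    """Empirical end-deamination rates by distance from the fragment ends.

    ``d5_ct[d-1]`` is the C->T mismatch rate at 1-based distance d from the
    5' end (pooled over strands in reference orientation: + strand ref-C
    observed T, - strand ref-G observed A); ``d3_ga`` the G->A rate from
    the 3' end.  Cells with zero denominator are NaN, not zero.  The
    headline PMD statistic is the 5' first-position rate.
    """

    d5_ct: np.ndarray
    d3_ga: np.ndarray
    n5: np.ndarray
    n3: np.ndarray

    @property
    def k_max(self) -> int:
        return len(self.d5_ct)

    @property
    def pmd_headline(self) -> float:
        return float(self.d5_ct[0])

    def to_tsv(self, path) -> None:
        rows = []
        for d in range(self.k_max):
            rows.append(("5p", d + 1, "C>T", self.d5_ct[d], self.n5[d]))
            rows.append(("3p", d + 1, "G>A", self.d3_ga[d], self.n3[d]))
        pd.DataFrame(
            rows, columns=["end", "distance", "substitution", "rate", "n"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DamageProfile":
        df = pd.read_csv(path, sep="\t")
        five = df[df["end"] == "5p"].sort_values("distance")
        three = df[df["end"] == "3p"].sort_values("distance")
        return cls(
            d5_ct=five["rate"].to_numpy(float),
            d3_ga=three["rate"].to_numpy(float),
            n5=five["n"].to_numpy(np.int64),
            n3=three["n"].to_numpy(np.int64),
        )


def _truncated_lognormal(frag_mean: float, frag_sd_log: float):
    return stats.lognorm(s=frag_sd_log, scale=frag_mean)


def _truncated_lognormal_lengths(
    rng: np.random.Generator, n: int, frag_mean: float, frag_sd_log: float
) -> np.ndarray:
    dist = _truncated_lognormal(frag_mean, frag_sd_log)
    lo, hi = dist.cdf(MIN_FRAG_LEN), dist.cdf(MAX_FRAG_LEN)
    u = rng.random(n) * (hi - lo) + lo
    return np.clip(np.round(dist.ppf(u)), MIN_FRAG_LEN, MAX_FRAG_LEN).astype(np.int64)


def _expected_fragment_length(frag_mean: float, frag_sd_log: float) -> float:
    dist = _truncated_lognormal(frag_mean, frag_sd_log)
    grid = np.arange(MIN_FRAG_LEN, MAX_FRAG_LEN + 1, dtype=float)
    w = dist.pdf(grid)
    return float((grid * w).sum() / w.sum())


def flip_probabilities(
    rs: ReadSet,
    damage: "DamageModelParams | DamageProfile",
    library: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation probability that a C reads T (p_ct) and a G reads A (p_ga).

    Encodes the strand convention: double-strand libraries deaminate C near
    the 5' terminus and G near the 3' terminus (reference orientation);
    single-strand libraries deaminate C at both ends (appearing as G->A on
    - strand fragments).  Accepts either model parameters (closed form) or
    an empirical profile (clamped table lookup).
    """
    d5, d3 = rs.end_distances()
    if isinstance(damage, DamageProfile):
        lib = library or "double_strand"
        delta5 = _profile_lookup(damage.d5_ct, d5)
        delta3 = _profile_lookup(damage.d3_ga, d3)
    else:
        lib = library or damage.library
        delta5 = damage.delta(d5)
        delta3 = damage.delta(d3)
    minus = rs.frag_strand[rs.obs_frag] == 1
    if lib == "single_strand":
        both = 1.0 - (1.0 - delta5) * (1.0 - delta3)
        p_ct = np.where(minus, 0.0, both)
        p_ga = np.where(minus, both, 0.0)
    else:
        p_ct = np.where(minus, delta3, delta5)
        p_ga = np.where(minus, delta5, delta3)
    return p_ct, p_ga


def _profile_lookup(curve: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Empirical-profile value at distance d, clamped to the profiled range.

    NaN cells (zero denominator) fall back to the nearest shallower finite
    cell, or 0 when none exists.
    """
    filled = np.array(curve, dtype=float)
    last = 0.0
    for i in range(len(filled)):
        if np.isfinite(filled[i]):
            last = filled[i]
        else:
            filled[i] = last
    idx = np.clip(np.asarray(d, dtype=np.int64) - 1, 0, len(filled) - 1)
    return filled[idx]


def simulate_reads(
    ind: Individual,
    panel: SitePanel,
    coverage: float,
    damage: DamageModelParams,
    seed: int = 0,
    frag_mean: float = 60.0,
    frag_sd_log: float = 0.35,
) -> ReadSet:
    """Simulate ancient fragments from a diploid individual.

    Fragment count is round(coverage * genome_length / E[length]); starts
    are uniform, lengths truncated lognormal on [30, 150], strand and
    haplotype of origin fair coin flips per fragment.  At each covered
    panel site the true allele base passes through the deamination channel
    and then a uniform sequencing-error channel (probability seq_error,
    uniform over the three other bases); base quality is the phred of
    seq_error.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if damage.nick_freq > 0:
        warnings.warn(
            "nick_freq accepted for config compatibility but unused: nicks are "
            "irrelevant at SNP-site resolution in this simplified channel",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    L = panel.genome_length
    e_len = _expected_fragment_length(frag_mean, frag_sd_log)
    n_frags = int(round(coverage * L / e_len))
    if n_frags == 0:
        warnings.warn("requested coverage yields zero fragments; returning empty ReadSet",
                      stacklevel=2)
        return ReadSet.empty(panel.n_sites)

    lengths = _truncated_lognormal_lengths(rng, n_frags, frag_mean, frag_sd_log)
    start = rng.integers(1, np.maximum(L - lengths + 1, 1) + 1)
    end = start + lengths - 1
    strand = rng.integers(0, 2, size=n_frags).astype(np.uint8)
    hap_of_frag = rng.integers(0, 2, size=n_frags)

    lo = np.searchsorted(panel.positions, start, side="left")
    hi = np.searchsorted(panel.positions, end, side="right")
    counts = hi - lo
    covered = counts > 0
    start, end, strand, hap_of_frag, lo, counts = (
        a[covered] for a in (start, end, strand, hap_of_frag, lo, counts)
    )
    n_frags = len(start)
    total = int(counts.sum())
    if total == 0:
        warnings.warn("no fragment covers any panel site; returning empty ReadSet",
                      stacklevel=2)
        return ReadSet.empty(panel.n_sites)

    obs_frag = np.repeat(np.arange(n_frags), counts)
    flat_base = np.repeat(np.cumsum(counts) - counts, counts)
    obs_site = np.repeat(lo, counts) + (np.arange(total) - flat_base)

    allele = np.where(
        hap_of_frag[obs_frag] == 0, ind.hap1[obs_site], ind.hap2[obs_site]
    )
    ref_code = np.frombuffer("".join(panel.ref_base).encode(), dtype=np.uint8)
    alt_code = np.frombuffer("".join(panel.alt_base).encode(), dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.uint8)
    for b, i in BASE_CODE.items():
        code_of[ord(b)] = i
    ref_code = code_of[ref_code]
    alt_code = code_of[alt_code]
    true_base = np.where(allele == 0, ref_code[obs_site], alt_code[obs_site]).astype(np.uint8)

    rs = ReadSet(
        n_sites=panel.n_sites,
        frag_start=start, frag_end=end, frag_strand=strand,
        frag_source=np.zeros(n_frags, dtype=np.uint8),
        obs_frag=obs_frag, obs_site=obs_site,
        obs_pos=panel.positions[obs_site],
        obs_base=true_base,
        obs_qual=np.full(total, _phred(damage.seq_error), dtype=np.int16),
    )
    p_ct, p_ga = flip_probabilities(rs, damage)
    u = rng.random(total)
    base = rs.obs_base.copy()
    base[(base == C) & (u < p_ct)] = T
    base[(base == G) & (u < p_ga)] = A
    if damage.seq_error > 0:
        err = rng.random(total) < damage.seq_error
        shift = rng.integers(1, 4, size=total).astype(np.uint8)
        base = np.where(err, (base + shift) % 4, base).astype(np.uint8)
    rs.obs_base = base
    return rs


def _phred(p: float) -> int:
    if p <= 0:
        return 93
    return int(round(-10.0 * np.log10(p)))


def downsample_reads(rs: ReadSet, target_coverage: float, seed: int = 0) -> ReadSet:
    """Keep fragments independently with probability target/realized coverage."""
    cur = rs.realized_coverage
    if target_coverage > cur:
        raise ValueError(f"target coverage {target_coverage} exceeds current {cur:.4f}")
    if target_coverage == cur:
        return rs
    rng = np.random.default_rng(seed)
    keep = rng.random(rs.n_fragments) < (target_coverage / cur)
    return rs.select_fragments(keep)


def trim_reads(rs: ReadSet, k: int) -> ReadSet:
    """Drop site observations within k bp of either fragment end.

    Mirrors pre-genotyping read trimming against end-deamination: an
    observation is removed when min(distance to either physical end) <= k,
    with 1-based distances, so k=0 is the identity.  Fragments left with no
    observation are dropped; realized coverage is non-increasing in k.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0 or rs.n_obs == 0:
        return rs
    start = rs.frag_start[rs.obs_frag]
    end = rs.frag_end[rs.obs_frag]
    d_min = np.minimum(rs.obs_pos - start + 1, end - rs.obs_pos + 1)
    return rs.select_obs(d_min > k)


def estimate_damage_profile(
    rs: ReadSet,
    panel: SitePanel,
    k_max: int = 25,
    library: str = "double_strand",
) -> DamageProfile:
    """Empirical end-deamination profile against the panel reference base.

    Uses the panel ref_base as the truth proxy, as read-level damage tools
    do against the reference genome.  Sites whose alternate allele equals
    the damage product of the reference base (ref C / alt T and ref G /
    alt A) are excluded from the tallies, since a true alternate allele
    there is indistinguishable from deamination; at the remaining sites the
    only residual inflation is sequencing error.  Pooling is strand-aware in
    read orientation: the 5' C->T cell at distance d counts + strand ref-C
    sites (observed T) together with - strand ref-G sites (observed A).
    In ``single_strand`` mode the 3' cells also tally C->T (the
    single-strand chemistry deaminates C at both ends).
    """
    if rs.n_obs == 0:
        raise ValueError("cannot estimate a damage profile from an empty ReadSet")
    d5, d3 = rs.end_distances()
    minus = rs.frag_strand[rs.obs_frag] == 1
    ref = np.array([BASE_CODE[b] for b in panel.ref_base], dtype=np.uint8)[rs.obs_site]
    alt = np.array([BASE_CODE[b] for b in panel.alt_base], dtype=np.uint8)[rs.obs_site]

    # Damage-ambiguous sites — where the alternate allele IS the damage
    # product of the reference base (ref C / alt T, ref G / alt A) — are
    # excluded from the tallies: there a true alternate allele is
    # read-level indistinguishable from deamination and would inflate the
    # rate by the site's alt frequency.
    ct_ambig = (ref == C) & (alt == T)
    ga_ambig = (ref == G) & (alt == A)

    # read-orientation "C" sites: ref C on + strand, ref G on - strand.
    # The denominator is further conditioned on the observation reading the
    # reference base or its damage product (C or T in read orientation):
    # other bases indicate the alternate allele, which cannot deaminate and
    # would otherwise dilute the rate by the site's alt dosage.
    is_c_read = np.where(minus, (ref == G) & ~ga_ambig, (ref == C) & ~ct_ambig)
    hit_ct = np.where(minus, rs.obs_base == A, rs.obs_base == T)
    src_ct = np.where(minus, rs.obs_base == G, rs.obs_base == C)
    if library == "single_strand":
        is_g_read, hit_ga, src_ga = is_c_read, hit_ct, src_ct
    else:
        is_g_read = np.where(minus, (ref == C) & ~ct_ambig, (ref == G) & ~ga_ambig)
        hit_ga = np.where(minus, rs.obs_base == T, rs.obs_base == A)
        src_ga = np.where(minus, rs.obs_base == C, rs.obs_base == G)

    def tally(dist, mask, hit, src):
        sel = mask & (dist >= 1) & (dist <= k_max) & (hit | src)
        n = np.bincount(dist[sel] - 1, minlength=k_max)
        h = np.bincount(dist[sel & hit] - 1, minlength=k_max)
        with np.errstate(invalid="ignore"):
            rate = np.where(n > 0, h / np.maximum(n, 1), np.nan)
        return rate, n

    d5_ct, n5 = tally(d5, is_c_read, hit_ct, src_ct)
    d3_ga, n3 = tally(d3, is_g_read, hit_ga, src_ga)
    return DamageProfile(d5_ct=d5_ct, d3_ga=d3_ga, n5=n5, n3=n3)


def fit_damage_model(
    profile: DamageProfile,
    seq_error: float = 0.001,
    library: str = "double_strand",
) -> DamageModelParams:
    """Least-squares fit of the closed-form deamination curve to a profile.

    Fits (deam_ds, deam_ss, overhang_p) to the 5' C->T curve weighted by
    cell counts, the parametric analogue of how damage-aware callers smooth
    their empirical damage estimates before genotyping.
    """
    d = np.arange(1, profile.k_max + 1, dtype=float)
    y = profile.d5_ct
    w = profile.n5.astype(float)
    ok = np.isfinite(y) & (w > 0)
    if ok.sum() < 3:
        raise ValueError("too few informative profile cells to fit the damage model")

    def curve(d, ds, ss, p):
        return ds + (ss - ds) * (1.0 - p) ** (d - 1.0)

    y0 = float(y[ok][0])
    popt, _ = optimize.curve_fit(
        curve, d[ok], y[ok], p0=[min(0.01, y0), max(y0, 1e-3), 0.36],
        sigma=1.0 / np.sqrt(w[ok]),
        bounds=([0.0, 0.0, 1e-3], [1.0, 1.0, 1.0]),
        maxfev=10000,
    )
    ds, ss, p = (float(v) for v in popt)
    return DamageModelParams(
        nick_freq=0.0, overhang_p=p, deam_ds=min(ds, ss), deam_ss=ss,
        seq_error=seq_error, udg_factor=1.0, library=library,
    )
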