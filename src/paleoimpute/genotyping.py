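"""Genotype likelihoods and high-coverage genotype calling.

Two per-read emission models are provided.  The naive model treats every
mismatch as sequencing error: P(b|a) = 1 - e if b = a else e/3.  The
damage-aware model first passes the allele base through the deamination
channel (C->T / G->A per the strand convention of the read simulator, with
probability delta at the observation's end distance) and then through the
error channel, so a T observed at a damage-prone position discounts rather
than penalizes the C allele.  With delta = 0 the two models agree exactly.

Genotype likelihood per site: L(g) = prod_reads [(1-g/2) P(b|ref) + (g/2) P(b|alt)].
Sites without reads carry the flat triple (1,1,1) and are never omitted
from the site universe (low-coverage imputation requires likelihoods at
every panel position, covered or not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancient_reads import (
    BASE_CODE,
    DamageModelParams,
    DamageProfile,
    ReadSet,
    flip_probabilities,
    trim_reads,
)
from .popgen_sim import SitePanel

__all__ = [
    "GenotypeLikelihoods",
    "CallFilters",
    "GenotypeCalls",
    "genotype_likelihoods",
    "call_genotypes_highcov",
    "concordant_intersection",
    "partition_by_agreement",
    "transition_fraction",
]

MISSING = -1


@dataclass
class GenotypeLikelihoods:
    """Per-site biallelic genotype likelihood triples (the VCF PL payload).

    ``lin`` is the linear triple normalized to max 1; ``pl`` the
    phred-scaled triple with min 0.  Depth-0 sites carry the flat (1,1,1)
    triple.
    """

    lin: np.ndarray      # (M, 3) float
    depth: np.ndarray    # (M,) int
    model: str           # 'naive' or 'damage_aware'

    def __post_init__(self) -> None:
        self.lin = np.asarray(self.lin, dtype=np.float64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.lin.shape != (len(self.depth), 3):
            raise ValueError("lin must be (M, 3)")
        if not np.all(np.isfinite(self.lin)) or np.any(self.lin < 0):
            raise ValueError("linear likelihoods must be finite and non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.depth)

    @property
    def pl(self) -> np.ndarray:
        """Phred-scaled triple, min 0 per site."""
        with np.errstate(divide="ignore"):
            pl = -10.0 * np.log10(np.maximum(self.lin, 1e-300))
        return pl - pl.min(axis=1, keepdims=True)

    @classmethod
    def from_loglik(cls, loglik: np.ndarray, depth: np.ndarray, model: str
                    ) -> "GenotypeLikelihoods":
        ll = np.asarray(loglik, dtype=np.float64)
        lin = np.exp(ll - ll.max(axis=1, keepdims=True))
        lin[np.asarray(depth) == 0] = 1.0
        return cls(lin=lin, depth=depth, model=model)

    @classmethod
    def from_pl(cls, pl: np.ndarray, depth: np.ndarray, model: str = "naive"
                ) -> "GenotypeLikelihoods":
        pl = np.asarray(pl, dtype=np.float64)
        return cls.from_loglik(-pl * (np.log(10.0) / 10.0), depth, model)


@dataclass(frozen=True)
class CallFilters:
    """Quality-control cascade for high-coverage genotype calling.

    The depth floor is max(min_depth_abs, min_depth_frac * mean depth); the
    ceiling max_depth_frac * mean depth.  Site quality is emulated as the
    phred gap between the best and second-best genotype likelihood, and
    sites below ``min_qual`` are set missing, as are masked sites.
    ``trim_k`` bases are removed from each read end before calling
    (standard for non-UDG libraries).
    """

    trim_k: int = 10
    min_depth_abs: int = 8
    min_depth_frac: float = 1.0 / 3.0
    max_depth_frac: float = 2.0
    min_qual: float = 30.0
    site_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.trim_k, self.min_depth_abs, self.min_depth_frac,
               self.max_depth_frac, self.min_qual) < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class GenotypeCalls:
    """Hard genotype calls with a per-site filter flag.

    gt is in {0, 1, 2} with -1 for missing; flagged (filtered) sites are
    always missing.
    """

    gt: np.ndarray         # (M,) int8, -1 missing
    filtered: np.ndarray   # (M,) bool
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.filtered = np.asarray(self.filtered, dtype=bool)
        if np.any((self.gt == MISSING) != self.filtered):
            raise ValueError("flagged sites must be missing and vice versa")

    @property
    def n_sites(self) -> int:
        return len(self.gt)

    @property
    def missing(self) -> np.ndarray:
        return self.gt == MISSING

    @classmethod
    def from_gt(cls, gt: np.ndarray, depth: np.ndarray | None = None) -> "GenotypeCalls":
        gt = np.asarray(gt, dtype=np.int8)
        return cls(gt=gt, filtered=gt == MISSING, depth=depth)


def genotype_likelihoods(
    rs: ReadSet,
    panel: SitePanel,
    model: str = "naive",
    damage: DamageModelParams | DamageProfile | None = None,
    seq_error: float = 0.001,
) -> GenotypeLikelihoods:
    """Per-site genotype likelihood triples from a ReadSet.

    model='naive' uses the pure sequencing-error emission;
    model='damage_aware' additionally marginalizes the deamination channel
    (delta from ``damage``, either closed-form parameters or an empirical
    profile) at each observation's end distance.
    """
    if model not in ("naive", "damage_aware"):
        raise ValueError("model must be 'naive' or 'damage_aware'")
    if model == "damage_aware" and damage is None:
        raise ValueError("damage model/profile required when model='damage_aware'")

    M = panel.n_sites
    depth = rs.depth()
    if rs.n_obs == 0:
        return GenotypeLikelihoods(lin=np.ones((M, 3)), depth=depth, model=model)

    ref = np.array([BASE_CODE[b] for b in panel.ref_base], dtype=np.uint8)[rs.obs_site]
    alt = np.array([BASE_CODE[b] for b in panel.alt_base], dtype=np.uint8)[rs.obs_site]
    e = seq_error

    def err_channel(b_eq_x: np.ndarray) -> np.ndarray:
        return np.where(b_eq_x, 1.0 - e, e / 3.0)

    if model == "naive":
        p_ref = err_channel(rs.obs_base == ref)
        p_alt = err_channel(rs.obs_base == alt)
    else:
        p_ct, p_ga = flip_probabilities(rs, damage)
        p_ref = _emission_with_damage(rs.obs_base, ref, p_ct, p_ga, e)
        p_alt = _emission_with_damage(rs.obs_base, alt, p_ct, p_ga, e)

    p_ref = np.maximum(p_ref, 1e-300)
    p_alt = np.maximum(p_alt, 1e-300)
    p_het = 0.5 * (p_ref + p_alt)
    loglik = np.column_stack([
        np.bincount(rs.obs_site, weights=np.log(p), minlength=M)
        for p in (p_ref, p_het, p_alt)
    ])
    return GenotypeLikelihoods.from_loglik(loglik, depth, model)


def _emission_with_damage(
    obs: np.ndarray, allele: np.ndarray, p_ct: np.ndarray, p_ga: np.ndarray, e: float
) -> np.ndarray:
    """P(b | allele) marginalized over the deamination channel.

    The allele base deaminates to its damage product t (C->T with p_ct,
    G->A with p_ga, identity otherwise), then the uniform error channel
    applies: P(b|a) = (1-p) err(b|a) + p err(b|t).
    """
    from .ancient_reads import A, C, G, T

    p = np.where(allele == C, p_ct, np.where(allele == G, p_ga, 0.0))
    t = np.where(allele == C, T, np.where(allele == G, A, allele)).astype(np.uint8)
    e_a = np.where(obs == allele, 1.0 - e, e / 3.0)
    e_t = np.where(obs == t, 1.0 - e, e / 3.0)
    return (1.0 - p) * e_a + p * e_t


def call_genotypes_highcov(
    rs: ReadSet,
    panel: SitePanel,
    model: str = "naive",
    filters: CallFilters = CallFilters(),
    damage: DamageModelParams | DamageProfile | None = None,
    seq_error: float = 0.001,
) -> GenotypeCalls:
    """Call and filter hard genotypes from high-coverage reads.

    Reads are end-trimmed by ``filters.trim_k`` first; the call is the
    argmax-likelihood genotype (ties break toward the lower genotype index
    and fail the quality filter since their phred gap is 0).  A site is set
    missing when its depth falls outside the depth window, its phred gap
    between best and second-best genotype is below ``min_qual``, or it is
    masked.
    """
    trimmed = trim_reads(rs, filters.trim_k)
    gl = genotype_likelihoods(trimmed, panel, model=model, damage=damage,
                              seq_error=seq_error)
    depth = gl.depth
    mean_depth = float(depth.mean()) if len(depth) else 0.0

    pl = gl.pl
    order = np.sort(pl, axis=1)
    qual = order[:, 1] - order[:, 0]   # phred gap best vs second best
    gt = np.argmax(gl.lin, axis=1).astype(np.int8)  # argmax ties -> lower index

    min_depth = max(filters.min_depth_abs, filters.min_depth_frac * mean_depth)
    bad = (
        (depth < min_depth)
        | (depth > filters.max_depth_frac * mean_depth)
        | (qual < filters.min_qual)
    )
    if filters.site_mask is not None:
        bad |= np.asarray(filters.site_mask, dtype=bool)
    gt[bad] = MISSING
    return GenotypeCalls(gt=gt, filtered=bad, depth=depth)


def concordant_intersection(a: GenotypeCalls, b: GenotypeCalls) -> GenotypeCalls:
    """Keep sites where both call sets are non-missing and agree; else missing.

    This is the "validation concordant" construction: the intersection of
    two independently produced genotype sets, retained only where they
    agree, used as the ground-truth proxy when no true genotypes exist.
    """
    if a.n_sites != b.n_sites:
        raise ValueError("call sets must share the same site universe")
    keep = (~a.missing) & (~b.missing) & (a.gt == b.gt)
    gt = np.where(keep, a.gt, MISSING).astype(np.int8)
    depth = None
    if a.depth is not None and b.depth is not None:
        depth = np.minimum(a.depth, b.depth)
    return GenotypeCalls(gt=gt, filtered=~keep, depth=depth)


def partition_by_agreement(
    a_best: np.ndarray, b_best: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Split a shared site universe by best-guess genotype agreement.

    Returns (concordant site indices, discordant site indices,
    discordance rate).  Inputs are best-guess genotype vectors of two
    imputed datasets over the same sites.
    """
    a_best = np.asarray(a_best)
    b_best = np.asarray(b_best)
    if a_best.shape != b_best.shape:
        raise ValueError("best-guess vectors must share the same site universe")
    agree = a_best == b_best
    concordant = np.flatnonzero(agree)
    discordant = np.flatnonzero(~agree)
    total = len(a_best)
    rate = len(discordant) / total if total else float("nan")
    return concordant, discordant, rate


def transition_fraction(sites: np.ndarray, panel: SitePanel) -> float:
    """Fraction of the listed sites whose ref/alt pair is a transition (A<->G, C<->T)."""
    sites = np.asarray(sites, dtype=np.int64)
    if len(sites) == 0:
        raise ValueError("transition_fraction requires a non-empty site list")
    return float(panel.is_transition()[sites].mean())
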