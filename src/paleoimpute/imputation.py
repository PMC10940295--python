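"""Diploid Li-Stephens haplotype-copying imputation from genotype likelihoods.

The hidden state at site m is an ordered pair (k1, k2) of reference-panel
haplotypes.  Per-haplotype transitions follow the usual copying process

    t(j -> k) = (1 - r_m) 1[j = k] + r_m / H,
    r_m = 1 - exp(-ne_scale * dcM_m / H)   (clamped),

and the pair transition factorizes as t * t, which lets the forward and
backward recursions run in O(M H^2) via row/column marginals instead of
O(M H^4).  The emission marginalizes the genotype likelihood triple over
the genotype implied by the copied alleles, each copied allele flipping
independently with the mismatch probability lambda (copy error):

    e_m(k1, k2) = sum_g L_m(g) P(g | a_{k1,m}, a_{k2,m}, lambda).

Posterior-probability triples (GP), dosages and best-guess genotypes come
from the forward-backward state posterior.  ``brute_force_posterior`` is an
independent exact oracle over the unfactorized transition matrix for tiny
instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .genotyping import GenotypeLikelihoods
from .popgen_sim import SitePanel

__all__ = ["HMMParams", "ImputedGenotypes", "impute_gl", "impute_gl_windowed",
           "brute_force_posterior"]


@dataclass(frozen=True)
class HMMParams:
    """Tunable constants of the copying HMM.

    ne_scale folds the effective-population-size recombination scaling into
    one constant: the default 20.0 gives a per-haplotype switch probability
    of about 1e-2 over 0.1 cM with a 200-haplotype panel.  copy_error is
    the per-site allele mismatch probability lambda (must be in (0, 0.5));
    min_switch/max_switch clamp the per-interval switch probability.
    """

    ne_scale: float = 20.0
    # lambda bounds the attainable posterior at (1 - lambda)^2, so it must sit
    # well below 1 - max posterior threshold used downstream (0.9999)
    copy_error: float = 1e-5
    min_switch: float = 1e-7
    max_switch: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.copy_error < 0.5:
            raise ValueError("copy_error must be in (0, 0.5)")
        if not 0.0 <= self.min_switch <= self.max_switch <= 1.0:
            raise ValueError("switch clamps must satisfy 0 <= min <= max <= 1")

    def switch_prob(self, dcm: np.ndarray, n_hap: int) -> np.ndarray:
        r = 1.0 - np.exp(-self.ne_scale * np.asarray(dcm, dtype=float) / n_hap)
        return np.clip(r, self.min_switch, self.max_switch)


@dataclass
class ImputedGenotypes:
    """Imputation output: per-site genotype posterior triples and summaries."""

    gp: np.ndarray        # (M, 3), rows sum to 1
    model: str = "LS-diploid"

    def __post_init__(self) -> None:
        self.gp = np.asarray(self.gp, dtype=np.float64)
        if self.gp.ndim != 2 or self.gp.shape[1] != 3:
            raise ValueError("gp must be (M, 3)")
        if np.any(np.abs(self.gp.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("GP triples must sum to 1")

    @property
    def n_sites(self) -> int:
        return self.gp.shape[0]

    @property
    def dosage(self) -> np.ndarray:
        return self.gp[:, 1] + 2.0 * self.gp[:, 2]

    @property
    def best_guess(self) -> np.ndarray:
        return np.argmax(self.gp, axis=1).astype(np.int8)

    @property
    def max_gp(self) -> np.ndarray:
        return self.gp.max(axis=1)


def _emission_tables(gl: GenotypeLikelihoods, lam: float) -> np.ndarray:
    """Per-site 2x2 emission over copied allele pairs: (M, a1, a2).

    P(g | a1, a2, lambda) with each copied allele flipping independently
    with probability lambda, contracted against the likelihood triple.
    """
    q = np.array([lam, 1.0 - lam])  # P(transmitted allele = 1 | copied a)
    # genotype distribution per (a1, a2): shape (2, 2, 3)
    pg = np.empty((2, 2, 3))
    for a1 in range(2):
        for a2 in range(2):
            q1, q2 = q[a1], q[a2]
            pg[a1, a2] = [(1 - q1) * (1 - q2), q1 * (1 - q2) + (1 - q1) * q2, q1 * q2]
    lin = gl.lin / gl.lin.sum(axis=1, keepdims=True)
    return np.einsum("mg,abg->mab", lin, pg)


def _transition_apply(F: np.ndarray, r: float) -> np.ndarray:
    """Apply the factorized pair transition to a state matrix F (H x H).

    Per axis: G = (1 - r) F + (r / H) * marginal, done for both haplotypes.
    """
    H = F.shape[0]
    G = (1.0 - r) * F + (r / H) * F.sum(axis=0, keepdims=True)
    return (1.0 - r) * G + (r / H) * G.sum(axis=1, keepdims=True)


@numba.njit(cache=True)
def _forward_backward_core(hap, em, r, pg):  # pragma: no cover - exercised via impute_gl
    """Scaled forward-backward over ordered haplotype pairs.

    hap: (H, M) uint8 panel alleles; em: (M, 2, 2) emission by copied
    allele pair; r: (M-1,) switch probabilities; pg: (2, 2, 3) genotype
    distribution per copied pair.  Returns (M, 3) unnormalized genotype
    posteriors.  The transition is applied through its row/column
    marginals, keeping the recursion O(M H^2).
    """
    H, M = hap.shape
    fwd = np.empty((M, H, H))
    F = np.empty((H, H))
    G = np.empty((H, H))
    s = 0.0
    for i in range(H):
        ai = hap[i, 0]
        for j in range(H):
            v = em[0, ai, hap[j, 0]]
            F[i, j] = v
            s += v
    for i in range(H):
        for j in range(H):
            F[i, j] /= s
            fwd[0, i, j] = F[i, j]

    col = np.empty(H)
    row = np.empty(H)
    for m in range(1, M):
        rm = r[m - 1]
        keep = 1.0 - rm
        jump = rm / H
        # axis-0 marginal (sum over k1) then axis-1, fused with emission
        for j in range(H):
            c = 0.0
            for i in range(H):
                c += F[i, j]
            col[j] = c
        for i in range(H):
            for j in range(H):
                G[i, j] = keep * F[i, j] + jump * col[j]
        for i in range(H):
            c = 0.0
            for j in range(H):
                c += G[i, j]
            row[i] = c
        s = 0.0
        for i in range(H):
            ai = hap[i, m]
            for j in range(H):
                v = (keep * G[i, j] + jump * row[i]) * em[m, ai, hap[j, m]]
                F[i, j] = v
                s += v
        for i in range(H):
            for j in range(H):
                F[i, j] /= s
                fwd[m, i, j] = F[i, j]

    gp = np.zeros((M, 3))
    B = np.ones((H, H))
    w = np.zeros((2, 2))
    for m in range(M - 1, -1, -1):
        w[:] = 0.0
        tot = 0.0
        for i in range(H):
            ai = hap[i, m]
            for j in range(H):
                g = fwd[m, i, j] * B[i, j]
                w[ai, hap[j, m]] += g
                tot += g
        for a1 in range(2):
            for a2 in range(2):
                wa = w[a1, a2] / tot
                for g in range(3):
                    gp[m, g] += wa * pg[a1, a2, g]
        if m > 0:
            rm = r[m - 1]
            keep = 1.0 - rm
            jump = rm / H
            s = 0.0
            for i in range(H):
                ai = hap[i, m]
                for j in range(H):
                    v = em[m, ai, hap[j, m]] * B[i, j]
                    G[i, j] = v
            for j in range(H):
                c = 0.0
                for i in range(H):
                    c += G[i, j]
                col[j] = c
            for i in range(H):
                for j in range(H):
                    G[i, j] = keep * G[i, j] + jump * col[j]
            for i in range(H):
                c = 0.0
                for j in range(H):
                    c += G[i, j]
                row[i] = c
            s = 0.0
            for i in range(H):
                for j in range(H):
                    v = keep * G[i, j] + jump * row[i]
                    B[i, j] = v
                    s += v
            for i in range(H):
                for j in range(H):
                    B[i, j] /= s
    return gp


def impute_gl(
    gl: GenotypeLikelihoods,
    panel: SitePanel,
    params: HMMParams = HMMParams(),
) -> ImputedGenotypes:
    """Impute genotype posteriors by diploid haplotype copying.

    ``gl`` must cover every panel site (uncovered sites carry flat
    triples); the forward-backward recursion is O(M H^2) using the
    factorized transition.
    """
    if gl.n_sites != panel.n_sites:
        raise ValueError("GL site universe must match the panel")
    if not np.all(np.isfinite(gl.lin)):
        raise ValueError("non-finite genotype likelihoods")
    H, M = panel.n_hap, panel.n_sites
    r = params.switch_prob(np.diff(panel.map.cm), H)
    em = _emission_tables(gl, params.copy_error)  # (M, 2, 2)
    pg = _pair_genotype_table(params.copy_error)  # (2, 2, 3)
    gp = _forward_backward_core(np.ascontiguousarray(panel.hap), em, r, pg)
    if not np.all(np.isfinite(gp)):
        raise FloatingPointError("forward-backward underflow")
    return ImputedGenotypes(gp=gp / gp.sum(axis=1, keepdims=True))


def _pair_genotype_table(lam: float) -> np.ndarray:
    q = np.array([lam, 1.0 - lam])
    pg = np.empty((2, 2, 3))
    for a1 in range(2):
        for a2 in range(2):
            q1, q2 = q[a1], q[a2]
            pg[a1, a2] = [(1 - q1) * (1 - q2), q1 * (1 - q2) + (1 - q1) * q2, q1 * q2]
    return pg


def impute_gl_windowed(
    gl: GenotypeLikelihoods,
    panel: SitePanel,
    params: HMMParams = HMMParams(),
    window_cm: float = 2.0,
    buffer_cm: float = 0.2,
) -> ImputedGenotypes:
    """Windowed imputation with buffered overlap-ligation.

    The chromosome is cut into consecutive cM windows, each imputed with a
    flanking buffer; buffer sites are resolved by keeping, per site, the
    window whose posterior is most confident (max-GP).  Single-window
    imputation (``impute_gl``) is the default everywhere; this mode exists
    for long chromosomes.
    """
    cm = panel.map.cm
    edges = np.arange(cm[0], cm[-1] + window_cm, window_cm)
    gp = np.zeros((panel.n_sites, 3))
    conf = np.full(panel.n_sites, -1.0)
    for lo_cm in edges:
        hi_cm = lo_cm + window_cm
        core = (cm >= lo_cm) & (cm < hi_cm)
        if not core.any():
            continue
        ext = (cm >= lo_cm - buffer_cm) & (cm < hi_cm + buffer_cm)
        idx = np.flatnonzero(ext)
        sub_panel = SitePanel(
            chrom=panel.chrom,
            positions=panel.positions[idx],
            ref_base=panel.ref_base[idx],
            alt_base=panel.alt_base[idx],
            hap=panel.hap[:, idx],
            pop_of_hap=panel.pop_of_hap,
            map=type(panel.map)(positions=panel.positions[idx], cm=cm[idx]),
            genome_length=panel.genome_length,
        )
        sub_gl = GenotypeLikelihoods(lin=gl.lin[idx], depth=gl.depth[idx], model=gl.model)
        res = impute_gl(sub_gl, sub_panel, params)
        better = res.max_gp > conf[idx]
        gp[idx[better]] = res.gp[better]
        conf[idx[better]] = res.max_gp[better]
    return ImputedGenotypes(gp=gp / gp.sum(axis=1, keepdims=True))


def brute_force_posterior(
    gl: GenotypeLikelihoods,
    panel: SitePanel,
    params: HMMParams = HMMParams(),
) -> ImputedGenotypes:
    """Exact genotype posterior via the unfactorized pair transition matrix.

    Test oracle only: builds the full H^2 x H^2 transition as a Kronecker
    product and runs explicit forward-backward over it, so it shares no
    code path with the factorized recursion.  Enforced to H <= 6, M <= 8.
    """
    H, M = panel.n_hap, panel.n_sites
    if H > 6 or M > 8:
        raise ValueError("brute-force oracle restricted to H <= 6, M <= 8")
    if gl.n_sites != M:
        raise ValueError("GL site universe must match the panel")

    r = params.switch_prob(np.diff(panel.map.cm), H)
    pg = _pair_genotype_table(params.copy_error)
    lin = gl.lin / gl.lin.sum(axis=1, keepdims=True)

    # emission vector over the H^2 ordered pairs at each site
    def emission(m: int) -> np.ndarray:
        a = panel.hap[:, m].astype(np.intp)
        e = np.einsum("g,abg->ab", lin[m], pg[np.ix_(a, a)].reshape(H, H, 3))
        return e.reshape(H * H)

    fwd = np.empty((M, H * H))
    bwd = np.empty((M, H * H))
    fwd[0] = emission(0) / (H * H)
    fwd[0] /= fwd[0].sum()
    for m in range(1, M):
        t_hap = (1.0 - r[m - 1]) * np.eye(H) + r[m - 1] / H
        t_pair = np.kron(t_hap, t_hap)
        f = (fwd[m - 1] @ t_pair) * emission(m)
        fwd[m] = f / f.sum()
    bwd[M - 1] = 1.0
    for m in range(M - 2, -1, -1):
        t_hap = (1.0 - r[m]) * np.eye(H) + r[m] / H
        t_pair = np.kron(t_hap, t_hap)
        b = t_pair @ (emission(m + 1) * bwd[m + 1])
        bwd[m] = b / b.sum()

    gp = np.empty((M, 3))
    for m in range(M):
        gamma = (fwd[m] * bwd[m]).reshape(H, H)
        gamma /= gamma.sum()
        a = panel.hap[:, m].astype(np.intp)
        Z = np.zeros((H, 2))
        Z[np.arange(H), a] = 1.0
        w = Z.T @ gamma @ Z
        trip = np.einsum("ab,abg->g", w, pg)
        gp[m] = trip / trip.sum()
    return ImputedGenotypes(gp=gp)
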