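"""Imputation-accuracy statistics and population-genetic diagnostics.

Covers non-reference discordance (NRD) with its depth/posterior filters,
MAF-stratified squared Pearson correlation, heterozygosity, PCA with
least-squares projection of partially missing samples and
eigenvalue-weighted PC distances, and a diploid ancestry HMM for
local-ancestry tract analysis.

NRD classifies each assessed site by its validation (truth) genotype into
error or match counters and excludes correct homozygous-reference calls:

    NRD = (eRR + eRA + eAA) / (eRR + eRA + eAA + mRA + mAA)

which weights errors at alternate-allele sites, the informative minority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotyping import MISSING, GenotypeCalls
from .imputation import ImputedGenotypes
from .popgen_sim import GeneticMap

__all__ = [
    "ConcordanceTable",
    "ConcordanceFilter",
    "PCAModel",
    "AncestryTract",
    "concordance_table",
    "r2_by_maf",
    "het_fraction",
    "pca_fit",
    "pca_project",
    "weighted_pc_distance",
    "infer_ancestry_tracts",
    "tract_summary",
]

DEFAULT_MAF_BINS = (0.0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5)


@dataclass
class ConcordanceTable:
    """The six NRD counters, classified by the validation genotype.

    eXY counts assessed sites whose validation genotype is XY but whose
    imputed best guess differs; mXY counts agreements.  NRD excludes mRR
    (correct homozygous-reference calls, the uninformative majority).
    """

    eRR: int = 0
    eRA: int = 0
    eAA: int = 0
    mRR: int = 0
    mRA: int = 0
    mAA: int = 0

    def __post_init__(self) -> None:
        if min(self.eRR, self.eRA, self.eAA, self.mRR, self.mRA, self.mAA) < 0:
            raise ValueError("counters must be non-negative")

    @property
    def n_assessed(self) -> int:
        return self.eRR + self.eRA + self.eAA + self.mRR + self.mRA + self.mAA

    @property
    def nrd(self) -> float:
        err = self.eRR + self.eRA + self.eAA
        den = err + self.mRA + self.mAA
        return err / den if den else float("nan")

    def to_tsv(self, path) -> None:
        row = dict(self.__dict__)
        row["n_assessed"] = self.n_assessed
        row["nrd"] = self.nrd
        pd.DataFrame([row]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConcordanceFilter:
    """Which sites enter the concordance assessment.

    min_validation_depth gates the validation (high-coverage truth) side;
    min_gp gates the imputed side on its posterior confidence; site_subset
    optionally restricts to a site-index list.
    """

    min_validation_depth: int = 8
    min_gp: float = 0.9999
    site_subset: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.min_validation_depth < 0 or not 0.0 <= self.min_gp <= 1.0:
            raise ValueError("concordance filter thresholds out of range")


def concordance_table(
    imputed: ImputedGenotypes,
    validation: GenotypeCalls,
    validation_depth: np.ndarray | None = None,
    filt: ConcordanceFilter = ConcordanceFilter(),
) -> ConcordanceTable:
    """Tally imputation errors and matches against a validation call set.

    A site is assessed iff the validation call is non-missing, validation
    depth >= min_validation_depth, imputed max-GP >= min_gp, and (when
    given) the site is in ``site_subset``.  Each assessed site increments
    exactly one of the six counters.
    """
    if imputed.n_sites != validation.n_sites:
        raise ValueError("imputed and validation site universes differ")
    if validation_depth is None:
        validation_depth = validation.depth
    assessed = ~validation.missing
    if validation_depth is not None:
        assessed &= np.asarray(validation_depth) >= filt.min_validation_depth
    assessed &= imputed.max_gp >= filt.min_gp
    if filt.site_subset is not None:
        in_subset = np.zeros(imputed.n_sites, dtype=bool)
        in_subset[np.asarray(filt.site_subset, dtype=np.int64)] = True
        assessed &= in_subset

    truth = validation.gt[assessed]
    guess = imputed.best_guess[assessed]
    match = truth == guess
    t = ConcordanceTable(
        eRR=int(np.sum((truth == 0) & ~match)),
        eRA=int(np.sum((truth == 1) & ~match)),
        eAA=int(np.sum((truth == 2) & ~match)),
        mRR=int(np.sum((truth == 0) & match)),
        mRA=int(np.sum((truth == 1) & match)),
        mAA=int(np.sum((truth == 2) & match)),
    )
    return t


def r2_by_maf(
    dosage: np.ndarray,
    validation: GenotypeCalls,
    maf: np.ndarray,
    bins: tuple[float, ...] = DEFAULT_MAF_BINS,
) -> pd.DataFrame:
    """Squared Pearson correlation of dosage vs truth within MAF bins.

    Sites with missing validation are excluded; bins with fewer than two
    assessed sites or zero variance on either side report NaN.
    """
    dosage = np.asarray(dosage, dtype=float)
    maf = np.asarray(maf, dtype=float)
    ok = ~validation.missing
    edges = np.asarray(bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = ok & (maf >= lo) & (maf < hi)
        n = int(sel.sum())
        r2 = float("nan")
        if n >= 2:
            x, y = dosage[sel], validation.gt[sel].astype(float)
            if x.std() > 0 and y.std() > 0:
                r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append({"maf_lo": lo, "maf_hi": hi, "n": n, "r2": r2})
    return pd.DataFrame(rows)


def het_fraction(gt: np.ndarray | GenotypeCalls) -> float:
    """Fraction of heterozygous genotypes among non-missing sites."""
    if isinstance(gt, GenotypeCalls):
        gt = gt.gt
    gt = np.asarray(gt)
    ok = gt != MISSING
    if not ok.any():
        raise ValueError("all sites missing")
    return float(np.mean(gt[ok] == 1))


@dataclass
class PCAModel:
    """PCA of a diploid reference cohort with frequency-normalized genotypes.

    Genotypes are centred by 2p and scaled by sqrt(2p(1-p)); fixed sites
    are dropped (recorded in ``kept_sites``).  ``loadings`` has orthonormal
    columns (one per component) over kept sites, eigenvalues are
    non-increasing, and ``scores`` holds the cohort coordinates.
    """

    mean: np.ndarray        # (M_kept,) 2p per kept site
    scale: np.ndarray       # (M_kept,) sqrt(2p(1-p))
    kept_sites: np.ndarray  # indices into the original site universe
    loadings: np.ndarray    # (M_kept, K)
    eigenvalues: np.ndarray # (K,)
    scores: np.ndarray      # (N, K)
    labels: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_tsv(self, loadings_path, eigenvalues_path) -> None:
        pd.DataFrame(self.loadings).assign(site=self.kept_sites).to_csv(
            loadings_path, sep="\t", index=False
        )
        pd.DataFrame({"eigenvalue": self.eigenvalues}).to_csv(
            eigenvalues_path, sep="\t", index=False
        )


def pca_fit(genotypes: np.ndarray, labels: list[str] | None, K: int) -> PCAModel:
    """Fit a K-component PCA on a diploid cohort genotype matrix (N x M).

    Uses the allele-frequency normalization standard in population
    genetics: centre 2p, scale sqrt(2p(1-p)); monomorphic sites are
    dropped.  Missingness is not supported on the fit side (the reference
    cohort is complete by construction); partially missing samples are
    handled at projection time.
    """
    X = np.asarray(genotypes, dtype=float)
    n, m = X.shape
    p = X.mean(axis=0) / 2.0
    kept = np.flatnonzero((p > 0.0) & (p < 1.0))
    if K > min(n, len(kept)):
        raise ValueError(f"K={K} exceeds the rank available ({min(n, len(kept))})")
    mean = 2.0 * p[kept]
    scale = np.sqrt(mean * (1.0 - p[kept]))
    Z = (X[:, kept] - mean) / scale
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    return PCAModel(
        mean=mean,
        scale=scale,
        kept_sites=kept,
        loadings=Vt[:K].T,
        eigenvalues=(s[:K] ** 2) / n,
        scores=U[:, :K] * s[:K],
        labels=labels,
    )


def pca_project(model: PCAModel, genotypes: np.ndarray) -> np.ndarray:
    """Project a genotype vector with missingness onto fitted components.

    Solves the least-squares problem restricted to the non-missing entries
    (the classical missing-data projection used for ancient samples): the
    normalized observed entries are regressed on the corresponding loading
    rows.  With no missingness this reproduces a cohort member's score
    vector exactly.
    """
    g = np.asarray(genotypes, dtype=float)[model.kept_sites]
    ok = np.isfinite(g) & (g >= 0)  # NaN or negative genotypes mark missing sites
    if int(ok.sum()) < model.n_components:
        raise ValueError("fewer non-missing sites than components")
    z = (g[ok] - model.mean[ok]) / model.scale[ok]
    coords, *_ = np.linalg.lstsq(model.loadings[ok], z, rcond=None)
    return coords


def weighted_pc_distance(
    a: np.ndarray,
    b: np.ndarray,
    eigenvalues: np.ndarray,
    K: int = 10,
    mode: str = "eigenvalue",
) -> float:
    """Eigenvalue-weighted Euclidean distance over the first K PCs.

    sqrt(sum_k w_k (a_k - b_k)^2) with w the first K eigenvalues (or their
    square roots with mode='sqrt') normalized to sum 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)
    if min(len(a), len(b), len(lam)) < K:
        raise ValueError(f"need at least K={K} components")
    w = lam[:K] if mode == "eigenvalue" else np.sqrt(lam[:K])
    w = w / w.sum()
    return float(np.sqrt(np.sum(w * (a[:K] - b[:K]) ** 2)))


@dataclass
class AncestryTract:
    """A contiguous run of diploid ancestry states containing one ancestry."""

    start_cm: float
    end_cm: float
    ancestry: str
    posterior_support: float = 1.0

    def __post_init__(self) -> None:
        if self.end_cm <= self.start_cm:
            raise ValueError("tract must have positive length")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


def infer_ancestry_tracts(
    gt: np.ndarray,
    pop_freqs: dict[str, np.ndarray],
    generations: int,
    alpha_prior: dict[str, float],
    gmap: GeneticMap,
    target_ancestry: str | None = None,
) -> list[AncestryTract]:
    """Viterbi local-ancestry tracts from best-guess genotypes.

    Hidden state = ordered pair of source populations; emission is the
    genotype distribution from independent Bernoulli allele draws at each
    population's frequency; each haplotype slot switches over an interval
    with probability 1 - exp(-generations * dMorgan) into the stationary
    ancestry mixture ``alpha_prior``.  Maximal runs of states containing
    the target (minority) ancestry are reported as tracts whose cM bounds
    extend to the midpoints between flanking sites, so tracts tile cleanly.
    """
    pops = list(pop_freqs)
    if not 2 <= len(pops) <= 3:
        raise ValueError("two or three reference populations required")
    gt = np.asarray(gt)
    M = len(gt)
    for p, f in pop_freqs.items():
        if len(f) != M:
            raise ValueError(f"frequency vector for {p} misaligned with sites")
    pi = np.array([alpha_prior[p] for p in pops], dtype=float)
    pi = pi / pi.sum()
    if target_ancestry is None:
        target_ancestry = pops[int(np.argmin(pi))]

    P = len(pops)
    states = [(i, j) for i in range(P) for j in range(P)]
    S = len(states)
    F = np.stack([np.clip(pop_freqs[p], 1e-4, 1 - 1e-4) for p in pops])  # (P, M)

    # log emission (S, M): P(g | f_i, f_j)
    log_em = np.zeros((S, M))
    valid = gt != MISSING
    for s, (i, j) in enumerate(states):
        fi, fj = F[i], F[j]
        pg = np.stack([
            (1 - fi) * (1 - fj),
            fi * (1 - fj) + (1 - fi) * fj,
            fi * fj,
        ])
        e = np.where(valid, pg[np.clip(gt, 0, 2), np.arange(M)], 1.0)
        log_em[s] = np.log(np.maximum(e, 1e-300))

    dcm = np.diff(gmap.cm)
    s_int = 1.0 - np.exp(-generations * dcm / 100.0)

    # Viterbi over ordered pairs with factorized per-haplotype transitions
    log_pi_pair = np.array([np.log(pi[i] * pi[j]) for i, j in states])
    delta = log_pi_pair + log_em[:, 0]
    back = np.zeros((M, S), dtype=np.int64)
    for m in range(1, M):
        sw = s_int[m - 1]
        t_hap = (1.0 - sw) * np.eye(P) + sw * pi[None, :]
        log_t = np.log(np.maximum(
            np.array([[t_hap[a[0], b[0]] * t_hap[a[1], b[1]] for b in states]
                      for a in states]), 1e-300))
        cand = delta[:, None] + log_t
        back[m] = np.argmax(cand, axis=0)
        delta = cand[back[m], np.arange(S)] + log_em[:, m]
    path = np.empty(M, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for m in range(M - 1, 0, -1):
        path[m - 1] = back[m, path[m]]

    t_idx = pops.index(target_ancestry)
    has_target = np.array([t_idx in states[s] for s in path])
    return _runs_to_tracts(has_target, gmap, target_ancestry)


def _runs_to_tracts(mask: np.ndarray, gmap: GeneticMap, label: str) -> list[AncestryTract]:
    cm = gmap.cm
    M = len(cm)
    bounds = np.empty(M + 1)
    bounds[0] = cm[0]
    bounds[-1] = cm[-1]
    bounds[1:-1] = 0.5 * (cm[:-1] + cm[1:])
    tracts: list[AncestryTract] = []
    m = 0
    while m < M:
        if mask[m]:
            j = m
            while j + 1 < M and mask[j + 1]:
                j += 1
            lo, hi = float(bounds[m]), float(bounds[j + 1])
            if hi > lo:
                tracts.append(AncestryTract(start_cm=lo, end_cm=hi, ancestry=label))
            m = j + 1
        else:
            m += 1
    return tracts


def tracts_to_tsv(tracts: list[AncestryTract], path) -> None:
    """Write a tract list as TSV (start_cm, end_cm, ancestry, posterior_support)."""
    pd.DataFrame(
        [(t.start_cm, t.end_cm, t.ancestry, t.posterior_support) for t in tracts],
        columns=["start_cm", "end_cm", "ancestry", "posterior_support"],
    ).to_csv(path, sep="\t", index=False)


def tract_summary(tracts: list[AncestryTract], total_cm: float) -> dict[str, float]:
    """Summary statistics of a tract list: dosage, count, median length, short fraction."""
    if not tracts:
        return {"ancestry_fraction": 0.0, "tract_count": 0,
                "median_length_cm": 0.0, "frac_sub_1cm": 0.0}
    lengths = np.array([t.length_cm for t in tracts])
    return {
        "ancestry_fraction": float(lengths.sum() / total_cm),
        "tract_count": int(len(tracts)),
        "median_length_cm": float(np.median(lengths)),
        "frac_sub_1cm": float(np.mean(lengths < 1.0)),
    }
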