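"""End-to-end experiment orchestration.

Two headline experiments are wired here:

* the PMD experiment — sweep the single-strand deamination probability,
  build validation calls from 30x reads under both emission models, impute
  the 1x genotype likelihoods three ways (naive, damage-aware, trim-5 then
  naive), and record NRD, inter-model discordance, and the transition
  fraction of concordantly vs discordantly imputed sites;

* the contamination experiment — mix contaminant fragments into an
  uncontaminated 1x target at each grid rate, impute naively, and record
  NRD against the clean 30x validation, heterozygosity of the imputed
  best-guess genotypes, the eigenvalue-weighted PC drift from the
  validation projection, the hemizygous contamination-rate estimate, and
  (optionally) local-ancestry tract summaries with a dosage-matched true
  admixture control.

Results are tidy long tables (one metric per row) stamped with the config
hash; the master seed fans out deterministically to per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import vcfio
from .ancient_reads import (
    DamageModelParams,
    downsample_reads,
    estimate_damage_profile,
    fit_damage_model,
    params_for_pmd,
    simulate_reads,
    trim_reads,
)
from .contamination import contaminate_reads, estimate_contamination_hemizygous
from .evaluation import (
    ConcordanceFilter,
    concordance_table,
    het_fraction,
    infer_ancestry_tracts,
    pca_fit,
    pca_project,
    r2_by_maf,
    tract_summary,
    weighted_pc_distance,
)
from .genotyping import (
    MISSING,
    CallFilters,
    call_genotypes_highcov,
    concordant_intersection,
    genotype_likelihoods,
    partition_by_agreement,
    transition_fraction,
)
from .imputation import HMMParams, impute_gl
from .popgen_sim import Individual, sample_individual, simulate_admixed, simulate_panel

__all__ = ["ExperimentConfig", "run_pmd_experiment", "run_contamination_experiment",
           "read_vcf", "write_vcf"]

log = logging.getLogger("paleoimpute")


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for both experiments (desk scale by default).

    Defaults describe one 5 Mb chromosome with 5,000 panel SNPs and 200
    panel haplotypes in two populations, a 30x validation / 1x target
    coverage pair, a deamination sweep from 0 to 50% terminal C->T, and a
    contamination grid spanning 0-90%.
    """

    # panel
    n_pops: int = 2
    haps_per_pop: int = 100
    n_sites: int = 5000
    genome_length: int = 5_000_000
    fst: float = 0.15
    ts_fraction: float = 0.687
    maf_min: float = 0.01
    # uniform 1 cM/Mb by default; tract analyses override this to 20 cM/Mb
    # so the desk chromosome spans ~1 Morgan, the scale at which admixture
    # tracts are resolvable (at 1 cM/Mb a 5 Mb chromosome is only 5 cM)
    cm_per_mb: float = 1.0
    # target individual
    target_pop: str = "pop0"
    copy_error: float = 0.005
    # coverage
    coverage_high: float = 30.0
    coverage_low: float = 1.0
    # damage
    deam_sweep: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    trim_values: tuple[int, ...] = (0, 5, 10)
    contam_pmd: float = 0.1
    seq_error: float = 0.001
    # contamination
    contamination_grid: tuple[float, ...] = (
        0.0, 0.01, 0.02, 0.03, 0.05, 0.1, 0.15, 0.2, 0.25, 0.5, 0.75, 0.9
    )
    contaminant_kind: str = "diverged"   # 'close' (same pop) or 'diverged'
    pool_coverage: float = 2.0
    hemi_fraction: float = 0.4           # trailing site fraction treated as haploid
    tract_c_values: tuple[float, ...] = (0.25,)
    admix_generations: int = 8
    # models
    hmm: HMMParams = HMMParams()
    call_filters: CallFilters = CallFilters()
    concordance: ConcordanceFilter = ConcordanceFilter()
    pca_components: int = 10
    pca_per_pop: int = 20
    # run shape
    replicates: int = 10
    master_seed: int = 0

    def validate(self) -> None:
        if self.contaminant_kind not in ("close", "diverged"):
            raise ValueError("contaminant_kind must be 'close' or 'diverged'")
        if not all(0.0 <= c <= 1.0 for c in self.contamination_grid):
            raise ValueError("contamination grid values must be in [0, 1]")
        if not all(0.0 <= d <= 1.0 for d in self.deam_sweep):
            raise ValueError("deamination sweep values must be in [0, 1]")
        if self.coverage_low > self.coverage_high:
            raise ValueError("low coverage must not exceed high coverage")
        if not 0.0 < self.hemi_fraction <= 1.0:
            raise ValueError("hemi_fraction must be in (0, 1]")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path) -> "ExperimentConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = dict(raw)
        if "hmm" in kwargs:
            kwargs["hmm"] = HMMParams(**kwargs["hmm"])
        if "call_filters" in kwargs:
            kwargs["call_filters"] = CallFilters(**kwargs["call_filters"])
        if "concordance" in kwargs:
            kwargs["concordance"] = ConcordanceFilter(**kwargs["concordance"])
        for key in ("deam_sweep", "trim_values", "contamination_grid", "tract_c_values"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def child_seed(master: int, *path: int | str) -> int:
    """Deterministic per-stage seed derived from the master seed and a path."""
    tokens = [int(master)] + [
        int.from_bytes(hashlib.sha256(str(p).encode()).digest()[:4], "big")
        for p in path
    ]
    return int(np.random.SeedSequence(tokens).generate_state(1)[0] % (2**31))


def _build_panel(cfg: ExperimentConfig, seed: int):
    return simulate_panel(
        n_pops=cfg.n_pops,
        haps_per_pop=cfg.haps_per_pop,
        n_sites=cfg.n_sites,
        genome_length=cfg.genome_length,
        fst=cfg.fst,
        ts_fraction=cfg.ts_fraction,
        maf_min=cfg.maf_min,
        cm_per_mb=cfg.cm_per_mb,
        seed=seed,
    )


def _damage(cfg: ExperimentConfig, pmd: float) -> DamageModelParams:
    # nick_freq set to 0 explicitly: the channel ignores nicks and the
    # experiments should not spam the config-compatibility warning
    return params_for_pmd(pmd, nick_freq=0.0, seq_error=cfg.seq_error)


def _fitted_damage(reads, panel, cfg: ExperimentConfig):
    """Empirical damage model re-estimated from the reads being genotyped.

    Mirrors how damage-aware callers first profile the library and then
    smooth the profile into a parametric curve; falls back to the raw
    profile when the curve fit is under-determined (e.g. zero damage).
    """
    profile = estimate_damage_profile(reads, panel, k_max=20)
    try:
        return fit_damage_model(profile, seq_error=cfg.seq_error)
    except (ValueError, RuntimeError):
        return profile


def _validation_calls(reads30, panel, cfg: ExperimentConfig, dmg):
    """The 'validation concordant' construction from high-coverage reads.

    Two independent call sets — a conventional caller with 10 bp end
    trimming, and a damage-aware caller using the library's own estimated
    damage curve without trimming — intersected to concordant sites.
    """
    naive = call_genotypes_highcov(
        reads30, panel, model="naive", filters=cfg.call_filters,
        seq_error=cfg.seq_error,
    )
    aware = call_genotypes_highcov(
        reads30, panel, model="damage_aware",
        filters=replace(cfg.call_filters, trim_k=0),
        damage=dmg, seq_error=cfg.seq_error,
    )
    return concordant_intersection(naive, aware)


def run_pmd_experiment(cfg: ExperimentConfig = ExperimentConfig()) -> pd.DataFrame:
    """Sweep terminal deamination and measure its effect on imputation.

    Per replicate and sweep value: simulate 30x reads from a held-out
    target under that damage level, downsample to 1x, build the concordant
    validation from the 30x reads, compute 1x genotype likelihoods three
    ways (naive; damage-aware with the damage curve re-estimated from the
    1x reads; 5 bp end-trim then naive), impute each, and record NRD,
    inter-model discordance, and transition fractions.
    """
    cfg.validate()
    rows: list[dict] = []
    chash = cfg.config_hash()
    for rep in range(cfg.replicates):
        panel = _build_panel(cfg, child_seed(cfg.master_seed, "pmd", rep, "panel"))
        target = sample_individual(
            panel, cfg.target_pop, copy_error=cfg.copy_error,
            seed=child_seed(cfg.master_seed, "pmd", rep, "target"),
        )
        maf = panel.maf()
        for pmd in cfg.deam_sweep:
            damage = _damage(cfg, pmd)
            reads30 = simulate_reads(
                target, panel, cfg.coverage_high, damage,
                seed=child_seed(cfg.master_seed, "pmd", rep, pmd, "reads"),
            )
            reads1 = downsample_reads(
                reads30, cfg.coverage_low,
                seed=child_seed(cfg.master_seed, "pmd", rep, pmd, "ds"),
            )
            # the damage curve is re-estimated from the library's reads; the
            # full readset stands in for the off-SNP genomic positions a
            # read-level profiler would use, which SNP-only fragments lack
            dmg = _fitted_damage(reads30, panel, cfg)
            validation = _validation_calls(reads30, panel, cfg, dmg)

            gl_sets = {
                "naive": genotype_likelihoods(
                    reads1, panel, model="naive", seq_error=cfg.seq_error),
                "damage_aware": genotype_likelihoods(
                    reads1, panel, model="damage_aware",
                    damage=dmg, seq_error=cfg.seq_error),
                "trim5_naive": genotype_likelihoods(
                    trim_reads(reads1, 5), panel, model="naive",
                    seq_error=cfg.seq_error),
            }
            imputed = {name: impute_gl(gl, panel, cfg.hmm)
                       for name, gl in gl_sets.items()}

            def emit(metric, value, condition=pmd, model=""):
                rows.append({
                    "experiment": "pmd", "replicate": rep, "condition": condition,
                    "model": model, "metric": metric, "value": value,
                    "config_hash": chash,
                })

            all_sites = ConcordanceFilter(
                min_validation_depth=cfg.concordance.min_validation_depth,
                min_gp=0.0)
            for name, imp in imputed.items():
                tab = concordance_table(imp, validation, filt=cfg.concordance)
                emit("nrd", tab.nrd, model=name)
                emit("n_assessed", tab.n_assessed, model=name)
                # the publication-grade GP filter keeps only sites where
                # confident models agree; the unfiltered rate is the one
                # that resolves differences between emission models at
                # desk scale
                tab_all = concordance_table(imp, validation, filt=all_sites)
                emit("nrd_all", tab_all.nrd, model=name)
                r2 = r2_by_maf(imp.dosage, validation, maf)
                for _, b in r2.iterrows():
                    emit(f"r2_maf_{b.maf_lo:g}_{b.maf_hi:g}", b.r2, model=name)
            conc, disc, rate = partition_by_agreement(
                imputed["naive"].best_guess, imputed["damage_aware"].best_guess)
            emit("discordance_rate", rate)
            emit("n_discordant", len(disc))
            if len(disc):
                emit("ts_fraction_discordant", transition_fraction(disc, panel))
            if len(conc):
                emit("ts_fraction_concordant", transition_fraction(conc, panel))
        log.info("pmd experiment: replicate %d/%d done", rep + 1, cfg.replicates)
    return pd.DataFrame(rows)


def run_contamination_experiment(
    cfg: ExperimentConfig = ExperimentConfig(),
    metrics: tuple[str, ...] = ("nrd", "het", "pca", "c_hat", "tracts"),
) -> pd.DataFrame:
    """Sweep the contamination rate and measure how imputation degrades.

    Per replicate: build a clean 1x target (downsampled from the 30x
    validation reads) and a contaminant fragment pool from a second
    individual; at each grid rate, mix, compute naive genotype
    likelihoods, impute, and record the requested metric families.
    """
    cfg.validate()
    rows: list[dict] = []
    chash = cfg.config_hash()
    contam_pop = "pop0" if cfg.contaminant_kind == "close" else f"pop{cfg.n_pops - 1}"
    no_damage = DamageModelParams(nick_freq=0.0, deam_ds=0.0, deam_ss=0.0,
                                  seq_error=cfg.seq_error)
    damage = _damage(cfg, cfg.contam_pmd)

    for rep in range(cfg.replicates):
        sd = lambda *p: child_seed(cfg.master_seed, "contam", rep, *p)
        panel = _build_panel(cfg, sd("panel"))
        target = sample_individual(panel, cfg.target_pop,
                                   copy_error=cfg.copy_error, seed=sd("target"))
        contaminant = sample_individual(panel, contam_pop,
                                        copy_error=cfg.copy_error, seed=sd("cont"))
        reads30 = simulate_reads(target, panel, cfg.coverage_high, damage,
                                 seed=sd("reads30"))
        reads1 = downsample_reads(reads30, cfg.coverage_low, seed=sd("ds"))
        pool = simulate_reads(contaminant, panel, cfg.pool_coverage, no_damage,
                              seed=sd("pool"))
        validation = None
        if "nrd" in metrics or "pca" in metrics:
            validation = call_genotypes_highcov(
                reads30, panel, model="naive", filters=cfg.call_filters,
                seq_error=cfg.seq_error)
        maf = panel.maf()
        f_target = panel.alt_freq(cfg.target_pop)
        f_contam = panel.alt_freq(contam_pop)

        if "pca" in metrics:
            from .popgen_sim import cohort_genotypes

            G, labels = cohort_genotypes(panel, cfg.pca_per_pop, seed=sd("cohort"))
            pca = pca_fit(G, labels, K=cfg.pca_components)
            val_geno = np.where(validation.missing, np.nan,
                                validation.gt.astype(float))
            ref_coord = pca_project(pca, val_geno)

        if "c_hat" in metrics:
            hemi_lo = int(cfg.n_sites * (1.0 - cfg.hemi_fraction))
            hemi_ind = Individual(hap1=target.hap1, hap2=target.hap1,
                                  pop=cfg.target_pop)
            hemi_reads = simulate_reads(hemi_ind, panel, cfg.coverage_low,
                                        no_damage, seed=sd("hemi"))

        for c in cfg.contamination_grid:
            mixed, report = contaminate_reads(reads1, pool, c, seed=sd(c, "mix"))
            gl = genotype_likelihoods(mixed, panel, model="naive",
                                      seq_error=cfg.seq_error)
            imp = impute_gl(gl, panel, cfg.hmm)

            def emit(metric, value, condition=c):
                rows.append({
                    "experiment": "contamination", "replicate": rep,
                    "condition": condition, "model": cfg.contaminant_kind,
                    "metric": metric, "value": value, "config_hash": chash,
                })

            emit("rate_realized", report.rate_realized)
            if "nrd" in metrics:
                tab = concordance_table(imp, validation, filt=cfg.concordance)
                emit("nrd", tab.nrd)
                emit("n_assessed", tab.n_assessed)
                tab_all = concordance_table(
                    imp, validation,
                    filt=ConcordanceFilter(
                        min_validation_depth=cfg.concordance.min_validation_depth,
                        min_gp=0.0))
                emit("nrd_all", tab_all.nrd)
            if "het" in metrics:
                emit("het_fraction", het_fraction(imp.best_guess))
            if "pca" in metrics:
                coord = pca_project(pca, imp.best_guess.astype(float))
                emit("pc_distance",
                     weighted_pc_distance(coord, ref_coord, pca.eigenvalues,
                                          K=cfg.pca_components))
            if "c_hat" in metrics:
                hemi_mixed, _ = contaminate_reads(hemi_reads, pool, c,
                                                  seed=sd(c, "hemimix"))
                est = estimate_contamination_hemizygous(
                    hemi_mixed, panel, region=(hemi_lo, cfg.n_sites),
                    contaminant_freqs=f_contam, endogenous_prior=f_target,
                    seq_error=cfg.seq_error)
                emit("c_hat", est.c_hat)
            if "tracts" in metrics and c in cfg.tract_c_values:
                total_cm = float(panel.map.cm[-1])
                tracts = infer_ancestry_tracts(
                    imp.best_guess,
                    pop_freqs={cfg.target_pop: f_target, contam_pop: f_contam},
                    generations=cfg.admix_generations,
                    alpha_prior={cfg.target_pop: 0.75, contam_pop: 0.25},
                    gmap=panel.map, target_ancestry=contam_pop)
                summ = tract_summary(tracts, total_cm)
                for k, v in summ.items():
                    emit(f"tract_{k}", v)
                # matched true-admixture control: tract analysis reports the
                # genome fraction where >=1 haplotype is minority, which for
                # admixture proportion a is 1-(1-a)^2; invert to match
                f = max(min(summ["ancestry_fraction"], 0.99), 0.05)
                alpha = 1.0 - np.sqrt(1.0 - f)
                adm = simulate_admixed(panel, cfg.target_pop, contam_pop,
                                       alpha=alpha,
                                       generations=cfg.admix_generations,
                                       seed=sd(c, "admix"))
                adm_reads = downsample_reads(
                    simulate_reads(adm, panel, cfg.coverage_high, damage,
                                   seed=sd(c, "admixreads")),
                    cfg.coverage_low, seed=sd(c, "admixds"))
                adm_gl = genotype_likelihoods(adm_reads, panel, model="naive",
                                              seq_error=cfg.seq_error)
                adm_imp = impute_gl(adm_gl, panel, cfg.hmm)
                adm_tracts = infer_ancestry_tracts(
                    adm_imp.best_guess,
                    pop_freqs={cfg.target_pop: f_target, contam_pop: f_contam},
                    generations=cfg.admix_generations,
                    alpha_prior={cfg.target_pop: 1 - alpha, contam_pop: alpha},
                    gmap=panel.map, target_ancestry=contam_pop)
                for k, v in tract_summary(adm_tracts, total_cm).items():
                    emit(f"admixed_tract_{k}", v)
        log.info("contamination experiment: replicate %d/%d done",
                 rep + 1, cfg.replicates)
    return pd.DataFrame(rows)


def random_site_subset(n_sites: int, fraction: float = 0.4, seed: int = 0) -> np.ndarray:
    """A random site-index subset, the placeholder for capture-array panels.

    Restricting evaluation to a site subset emulates analyses limited to
    capture-assay positions; which ascertainment would meaningfully mirror
    a real capture design is left to the user, so the default is a plain
    uniform draw of 40% of the sites.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    k = max(1, int(round(fraction * n_sites)))
    return np.sort(rng.choice(n_sites, size=k, replace=False))


def write_vcf(path, payload, panel, kind: str, **kwargs) -> None:
    """Dispatch VCF export by payload kind: panel, gl, calls or imputed."""
    writers = {
        "panel": lambda: vcfio.write_panel_vcf(payload, path, **kwargs),
        "gl": lambda: vcfio.write_gl_vcf(payload, panel, path, **kwargs),
        "calls": lambda: vcfio.write_calls_vcf(payload, panel, path, **kwargs),
        "imputed": lambda: vcfio.write_imputed_vcf(payload, panel, path, **kwargs),
    }
    if kind not in writers:
        raise ValueError(f"unknown payload kind: {kind}")
    writers[kind]()


def read_vcf(path, kind: str, **kwargs):
    """Dispatch VCF import by payload kind: panel, gl, calls or imputed."""
    readers = {
        "panel": lambda: vcfio.read_panel_vcf(path, **kwargs),
        "gl": lambda: vcfio.read_gl_vcf(path),
        "calls": lambda: vcfio.read_calls_vcf(path),
        "imputed": lambda: vcfio.read_imputed_vcf(path),
    }
    if kind not in readers:
        raise ValueError(f"unknown payload kind: {kind}")
    return readers[kind]()
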