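# Methods

`paleoimpute` is a self-contained workbench for studying two failure modes
of low-coverage genotype imputation in ancient DNA: post-mortem damage
(PMD) and present-day contamination. Everything is simulated; no external
data is read. This note documents the models, the defaults and why they
were chosen, and what the synthetic setting does and does not show about
real data.

## Reference panel and targets (`popgen_sim`)

The panel is a phased biallelic SNP matrix over one linear chromosome.
Ancestral allele frequencies follow a neutral-like 1/f spectrum truncated
at `maf_min` (default 0.01, mirroring the exclusion of singletons from
real imputation panels). Population divergence is Balding–Nichols:
per-population frequencies are Beta draws around the ancestral frequency
with variance governed by Fst. Haplotypes are mosaics of `n_founders`
(default 16) founder haplotypes per population, switching founders per
inter-site interval with probability `1 − exp(−ΔcM · s)`, `s = 3`/cM.
This produces monotone LD decay without a coalescent simulator. Because a
finite founder pool itself contributes ≈ 1/n_founders of between-population
variance, the Balding–Nichols parameter is deflated so the *realized* Fst
(Hudson estimator) matches the request; with `fst = 0` all populations
share one founder pool and the panel is exactly panmictic. The realized
divergence cannot fall below ≈ 1/n_founders for `fst > 0`, so requests in
(0, 0.06) overshoot — the workbench uses 0.1–0.2.

Nucleotide assignment: transition pairs (A↔G, C↔T) with probability
`ts_fraction` (default 0.687, the transition share typical of human SNP
panels), transversions uniform over the remaining eight ordered pairs.
The C/T–G/A identity of a site is what couples it to the damage model.

Targets are Li–Stephens-style mosaics of one population's panel
haplotypes with per-site copy error (default 0.005), so the held-out
individual is imputable but never a verbatim panel row. Admixed
individuals place crossovers as a Poisson process of `generations` per
Morgan; each segment draws its ancestry Bernoulli(α) and copies one
random haplotype of that population. `truth_tracts` records the raw
segment process (no merging of same-ancestry neighbours), so the expected
mean recorded segment length is 1/generations Morgan up to edge
truncation.

The genetic map is uniform `cm_per_mb` (default 1 cM/Mb, the genome-wide
human average); arbitrary maps are accepted. Coordinates are 1-based,
intervals closed, matching VCF conventions.

## Ancient reads and the deamination channel (`ancient_reads`)

Fragments carry base observations only at panel SNP sites; there is no
read mapping and no full sequence. Fragment lengths are lognormal
(log-mean log 60 bp, σ 0.35) truncated to [30, 150] bp — a typical aDNA
insert distribution; starts are uniform; strand and haplotype of origin
are fair coins per fragment.

Deamination follows the standard end-overhang closed form

    δ(d) = udg_factor · [deam_ds + (deam_ss − deam_ds) · (1 − overhang_p)^(d−1)]

with d the 1-based distance from a fragment end. Defaults
`overhang_p = 0.36`, `deam_ds = 0.0097` follow the parameterisation used
by standard aDNA read simulators; `deam_ss` is the swept quantity and
equals the headline "PMD rate" δ5(1) when `udg_factor = 1`. UDG treatment
is modelled purely as the multiplicative `udg_factor`. The nick frequency
accepted in the parameter block is unused — nicks do not matter at
SNP-site resolution — and a warning says so.

Strand convention (reference orientation): on + strand fragments,
reference C reads T with δ5(d5) and reference G reads A with δ3(d3); on −
strand fragments the roles swap, the fragment's 5′ terminus being its
rightmost reference coordinate. Single-strand libraries deaminate C at
both ends. After damage, a uniform sequencing-error channel (default
0.001) applies; base qualities are constant at phred(seq_error) —
per-base quality strings are out of scope.

The damage-profile estimator tallies C→T (5′) and G→A (3′) mismatch
rates against the panel reference base, pooling strands in read
orientation. Two refinements keep it unbiased on an all-SNP panel, where
a read-level profiler's usual background (monomorphic reference
positions) does not exist: sites whose alternate allele *is* the damage
product (ref C/alt T, ref G/alt A) are excluded, and the denominator is
conditioned on observations reading the reference base or its damage
product, so true alternate alleles neither inflate nor dilute the rate.
Cells with zero denominator report NaN, never zero. `fit_damage_model`
least-squares-fits the closed form to a profile (weighted by cell
counts), the parametric smoothing a damage-aware caller applies before
genotyping.

Trimming removes observations within k bp of either physical fragment
end (strand-symmetric, as read trimmers behave); downsampling keeps
fragments i.i.d. with probability target/realized coverage.

## Contamination (`contamination`)

Mixing is an exact read-replacement: round(c·n) uniformly chosen
endogenous fragments are removed and the same number of pool fragments
added, conserving the fragment count. The hemizygous estimator treats a
designated site-index range as haploid (the male-X analogue; no sex
chromosome machinery) and maximises, on a grid over [0, 0.5] in steps of
0.005, the likelihood in which each read is a (1−c)/c mixture of the
unknown haploid consensus (marginalised under a frequency prior) and a
contaminant population of known allele frequencies. Estimates above 40%
are flagged as outside the validated range: like its real-data
counterparts, the one-consensus likelihood loses power and underestimates
at high rates (the grid itself caps at 50%). The estimator ignores
damage; when run on damaged reads the C→T excess registers as a small
positive bias, visible in the workbench output at c = 0.

## Genotype likelihoods and calling (`genotyping`)

Per-site likelihoods are `L(g) = Π_reads [(1−g/2)·P(b|ref) + (g/2)·P(b|alt)]`.
The naive emission is pure sequencing error, `P(b|a) = 1−e` if `b = a`
else `e/3`. The damage-aware emission first passes the allele through the
deamination channel at the observation's end distances (closed form or
empirical profile) and then through the error channel; at δ = 0 the two
models agree exactly. Sites without reads carry the flat triple (1,1,1)
and are always written to output — low-coverage imputation requires a
likelihood at every panel position.

High-coverage calling trims reads (default 10 bp, the standard
precaution for non-UDG libraries), takes the argmax genotype, and sets a
site missing when depth < max(8, mean/3), depth > 2·mean, the phred gap
between best and second-best genotype is below 30 (the workbench's
emulation of a caller QUAL, which is not reproducible verbatim), or the
site is masked. Ties break toward the lower genotype index and are
removed by the zero phred gap. The "validation concordant" set intersects
a conventional trimmed call set with an untrimmed damage-aware call set
and keeps sites where both agree — the ground-truth proxy used when, as
with real ancient genomes, no truth exists.

## Imputation (`imputation`)

A diploid Li–Stephens HMM: hidden state = ordered pair of panel
haplotypes, per-haplotype transition `t(j→k) = (1−r)·1[j=k] + r/H` with
`r_m = 1 − exp(−ne_scale·ΔcM/H)` clamped to [1e-7, 0.5], emission = the
likelihood triple contracted against the genotype implied by the copied
alleles with independent per-allele mismatch λ. Forward–backward runs in
O(M·H²) through the row/column-marginal factorization of the pair
transition (compiled with numba). A brute-force oracle over the explicit
H²×H² transition matrix (H ≤ 6, M ≤ 8) shares no code with the factorized
recursion and agrees with it to 1e-9.

Defaults: `ne_scale = 20` (switch probability ≈ 1e-2 over 0.1 cM with a
200-haplotype panel) and `λ = 1e-5`. λ bounds the attainable posterior at
(1−λ)², so it must sit well below the complement of the strictest
downstream posterior filter (0.9999); 1e-4 would cap GP at 0.9998 and
silently empty every assessed-site set. These constants are declared and
config-overridable; they are not claimed to match any external tool
numerically. Windowed imputation with buffered overlap-ligation exists
for long chromosomes but is off by default at desk scale.

## Evaluation (`evaluation`)

Non-reference discordance classifies each assessed site by its validation
genotype, `NRD = (eRR+eRA+eAA)/(eRR+eRA+eAA+mRA+mAA)`, excluding correct
homozygous-reference calls. Assessment requires validation depth ≥ 8
(the depth filter is applied to the truth side, where it gates
trustworthiness; the opposite reading is switchable) and imputed max-GP ≥
0.9999. PCA uses the population-genetics normalization (centre 2p, scale
√(2p(1−p)), drop fixed sites); partially missing samples are projected by
least squares on the non-missing loading rows, which reproduces a cohort
member's scores exactly at full data. Weighted PC distances apply the
first-K eigenvalues, normalized to sum 1, to squared per-PC differences
(square-root weighting available; the choice is recorded in output
metadata). MAF bins default to {0, .005, .01, .02, .05, .1, .2, .5}.

Local ancestry is a genotype-level Viterbi HMM over ordered population
pairs: emissions from independent Bernoulli draws at each population's
frequencies, per-haplotype switching into the stationary ancestry mixture
at rate `generations` per Morgan. Tracts are maximal runs of states
containing the minority ancestry, with bounds extended to inter-site
midpoints. Two consequences matter for interpretation: the reported
"ancestry fraction" is the genome share where *at least one* haplotype
slot is minority (≈ 1−(1−α)² for true admixture at proportion α — the
workbench inverts this when building dosage-matched admixture controls),
and resolving sub-centimorgan tracts requires tens of sites per cM, so
tract analyses use a dense panel on a 20 cM/Mb map (a ~1 Morgan desk
chromosome) while NRD/PCA analyses use the standard 1 cM/Mb map, where
the same physical chromosome carries much stronger LD per site.

## The experiments (`workbench`)

Desk scale is 5,000 SNPs on 5 Mb, 200 panel haplotypes in two populations
(Fst 0.15), 30× validation / 1× target coverage, 10 replicates; each
experiment finishes in minutes on one CPU. The PMD experiment sweeps
δ5(1) over {0, .1, .2, .3, .4, .5}; the damage curve used by the
damage-aware genotyper is re-estimated from the library's own reads (the
full pre-downsampling readset stands in for the off-SNP genomic positions
a real profiler would use, which SNP-only fragments lack) and smoothed by
the closed-form fit. The contamination experiment mixes a diverged- or
same-population individual's fragments into the 1× target over a grid
spanning 0–90% (the "close"/"diverged" pair emulating a same-continent
vs. African-level divergence contrast), imputes naively, and reports NRD,
imputed heterozygosity, eigenvalue-weighted PC drift from the validation
projection, the hemizygous contamination estimate, and tract summaries
with a dosage-matched admixed control per tract rate.

Both experiments report NRD twice: under the publication-grade filters
(`nrd`) and over all assessed-depth sites with no GP filter (`nrd_all`).
At desk scale the GP ≥ 0.9999 subset is, by construction, dominated by
sites where confident models agree — the filter absorbs most of the
difference between emission models — so model comparisons (naive vs
damage-aware vs trim-then-naive) are read from `nrd_all`, while headline
degradation curves are visible in both. This selection effect is much
weaker at biobank panel sizes, where posteriors are overconfident enough
for damaged sites to pass the filter while wrong.

Reproducibility: the master seed fans out to per-stage children through
SHA-256 of the stage path, so any stage can be re-run in isolation;
identical config + seed gives byte-identical result tables, stamped with
the config hash.

## Problem sizes used by the test suite

The packaged tests run the experiments at sizes chosen so the whole suite
completes in a few minutes on one CPU while keeping 10 replicates
everywhere a mean is compared: the contamination and damage sweeps use
100 panel haplotypes and 1,500 SNPs on 3 Mb; the tract comparison uses
4,000 SNPs on 2.5 Mb under the 20 cM/Mb map; damage-profile recovery uses
a deliberately dense 12,000-SNP, 200 kb panel (per-distance profile cells
need hundreds of eligible observations, which SNP density, not coverage,
controls); the contamination-rate estimator uses 2,500 haploid sites at
1×. The acceptance script runs the full 200-haplotype, 5,000-SNP
configuration.

## What the synthetic setting does not show

The generator has no indels, no multiallelics, no mapping or reference
bias, no base-quality variation, no microbial background, and panel LD
comes from founder mosaics rather than coalescent genealogies. Absolute
error rates therefore transfer to real data only in order of magnitude;
the monotone relationships (NRD vs damage, NRD vs contamination, PC
drift, het peak near 50% contamination, short-tract enrichment under
contamination) are the transferable content. Tract lengths are
diploid-state runs, not haplotype-level tracts, so they are comparable
within the workbench but not numerically to phased local-ancestry
output.
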