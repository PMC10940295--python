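# paleoimpute

A self-contained synthetic workbench for studying how **post-mortem
damage (PMD)** and **present-day contamination** affect low-coverage
genotype imputation of ancient genomes.

Low-coverage ancient genomes are routinely imputed from genotype
likelihoods (GLs) against a phased reference panel. Two aDNA-specific
artefacts threaten this: cytosine deamination concentrates C→T (and
complementary G→A) substitutions at fragment ends, corrupting the GLs;
and contaminant reads from a second individual inject a third and fourth
haplotype into the copying model. `paleoimpute` simulates the whole
pipeline — panel, ancient fragments, damage, contamination, genotype
likelihoods, imputation, evaluation — so both effects can be measured
under fully known ground truth, at a scale that runs in minutes on one
CPU.

The pieces, each usable on its own:

- **`popgen_sim`** — phased biallelic reference panels with LD
  (founder-mosaic copying) and population structure (Balding–Nichols,
  parameterised by Fst); held-out diploid targets; admixed individuals
  with recorded crossover tracts; diploid PCA cohorts.
- **`ancient_reads`** — fragment simulation with the end-overhang
  deamination model δ(d) = udg·[ds + (ss−ds)(1−p)^(d−1)], downsampling,
  end-trimming, and empirical damage-profile estimation with a
  closed-form fit.
- **`contamination`** — exact read-replacement mixing and a
  hemizygous-region maximum-likelihood contamination-rate estimator
  (grid search, validated up to 40%).
- **`genotyping`** — naive and damage-aware genotype-likelihood
  emissions, a filtered high-coverage caller, concordant-intersection
  validation sets, transition-fraction statistics.
- **`imputation`** — a diploid Li–Stephens haplotype-copying HMM with
  GL emissions, O(M·H²) forward–backward (numba-compiled), posterior
  triples (GP), dosages and best-guess genotypes, plus an exhaustive
  brute-force oracle for testing.
- **`evaluation`** — non-reference discordance (NRD) with
  depth/posterior filters, MAF-stratified r², heterozygosity, PCA with
  least-squares projection of partially missing samples,
  eigenvalue-weighted PC distances, and a diploid local-ancestry HMM
  with tract summaries.
- **`workbench`** — the two end-to-end experiments, VCF 4.2 / TSV I/O,
  and a `paleoimpute` command-line interface.

The central evaluation statistic is non-reference discordance,

    NRD = (eRR + eRA + eAA) / (eRR + eRA + eAA + mRA + mAA),

the imputation error rate that excludes correctly imputed
homozygous-reference sites (`e`/`m` = errors/matches classified by the
validation genotype; R/A = reference/alternate allele).

## Worked example

```python
import paleoimpute as pi

# a two-population panel: 200 haplotypes, 1,500 SNPs on 3 Mb, Fst 0.15
panel = pi.simulate_panel(n_pops=2, haps_per_pop=100, n_sites=1500,
                          genome_length=3_000_000, fst=0.15, seed=1)
target = pi.sample_individual(panel, "pop0", copy_error=0.005, seed=2)

# heavily damaged library: 40% C->T at the 5' first position
damage = pi.params_for_pmd(0.40, seq_error=0.001)
reads30 = pi.simulate_reads(target, panel, coverage=30, damage=damage, seed=3)
reads1 = pi.downsample_reads(reads30, 1.0, seed=4)

profile = pi.estimate_damage_profile(reads30, panel)
print(f"estimated PMD rate: {profile.pmd_headline:.3f}")

validation = pi.call_genotypes_highcov(reads30, panel, model="naive")
gl = pi.genotype_likelihoods(reads1, panel, model="naive", seq_error=0.001)
imputed = pi.impute_gl(gl, panel)
table = pi.concordance_table(imputed, validation)
print(f"NRD at 1x, {table.n_assessed} assessed sites: {table.nrd:.4f}")
```

Output (seeds as above):

```
estimated PMD rate: 0.340
NRD at 1x, 1151 assessed sites: 0.0387
```

The profile estimator reads the heavy terminal deamination off the
fragments alone (0.34 against a simulated 0.40 at this panel density;
per-cell counts, not the estimator, limit the precision here), and the
imputed 1× genome disagrees with the high-coverage validation at about
4% of the confidently imputed non-reference sites — the damage-inflated baseline that the
damage-aware emission model and end-trimming are then measured against
(see `run_pmd_experiment`). The contamination experiment
(`run_contamination_experiment`) mixes contaminant fragments into the 1×
target over a 0–90% grid and tracks NRD, imputed heterozygosity (which
peaks near 50% contamination), PCA drift toward the contaminant, the
estimated contamination rate, and ancestry-tract signatures against a
dosage-matched true-admixture control.

The same pipeline is scriptable from the shell:

```sh
paleoimpute simulate-panel panel.vcf panel.map.tsv
paleoimpute simulate-reads --coverage 1 --pmd 0.4 panel.vcf panel.map.tsv reads.tsv
paleoimpute call-gl --model damage_aware panel.vcf reads.tsv gl.vcf
paleoimpute impute panel.vcf panel.map.tsv gl.vcf imputed.vcf
```

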