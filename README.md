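# heteropatry

An individual-based, forward-in-time simulator of sympatric speciation driven
by selection against mutations accumulating on conditionally silenced
niche-preference alleles — plus the statistics used to analyse such runs.

## The problem

How can one interbreeding population split into two reproductively isolated
species without geographic separation? The classical route needs disruptive
selection against intermediate phenotypes. This package implements an
alternative mechanism in which the ecological trait is *perception*: each
diploid "exploiter" carries a 13-locus chromosome pair encoding a
2-input / 3-hidden / 1-output perceptron that decides, from a two-channel
resource signal, which of four niches to use. Codominant expression (the
expressed weight is the mean of the two alleles) lets epistatic "super-alleles"
evolve that are silenced in some genotype combinations; silenced alleles
accumulate harmful mutations that surface in recombinant offspring, which
selects for mating on the preferred resource (heteropatry) via a single
unlinked mating gene (allele *a* assortative, *r* random, *a* dominant). Once
the population mates assortatively, silenced alleles diverge freely —
a Bateson–Dobzhansky–Muller incompatibility — and two pre- and post-zygotically
isolated specialist lineages result.

## The model in brief

For signal (s₁, s₂) the expressed perceptron responds

    ξⱼ = s₁w₁ⱼ + s₂w₂ⱼ − b_hj,   θⱼ = σ(ωξⱼ),
    ψ  = σ(ω(Σⱼ θⱼ w_out,j − b_o)),      ω = 4,

giving a response array Ψ = (ψ₁..ψ₄) over the four niches
(N = [250, 0.01, 250, 0.01]; signals on the diagonal of signal space).
Reproductive output is allocated as eₖ = φψₖ²/Σψ (φ = 3) and fitness
discounts each niche by crowding,

    fᵢ = Σₖ eₖᵢ / (1 + (Eₖ / (εNₖ))^a),    ε = 1.5,  a = 2.5,

with Eₖ the population's total output on niche k. Random maters pair across
the whole population; assortative maters pair within niche pools joined in
proportion to their rounded Ψ. Each pair leaves round(f₁+f₂) recruits built
from parental gametes with crossover (10⁻⁴/locus), point mutation
(0.01/allele, uniform(−10,10) perturbations clamped to ±20) and mating-gene
mutation (5·10⁻⁴) under a three-phase schedule: mating-gene mutation off
until generation 20,000, all mutations off from 80,000, end at 100,000.

The analysis battery covers unfit-phenotype fractions, likelihood-ratio
(maximum-likelihood χ²) tests on 2×2 tables, a single-mutant robustness
assay (K = P(P−1) resampled mutants per genotype pool), PCA + k-means
clustering of haplotype/genotype matrices, running-average trajectory
smoothing, and polymorphism classification of snapshots.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

A scaled run with shortened phases (mating-gene mutation from generation
2,000, mutations stopped at 6,000, end at 8,000):

```python
import heteropatry as hp

config = hp.SimulationConfig(
    generations=8000, mating_mutation_start=2000, mutation_stop=6000, seed=0,
)
result = hp.run(config)

for gen in (0, 1999, 4000, 6000, 8000):
    rec = next(r for r in result.records if r.generation == gen)
    print(f"gen {gen:5d}  size {rec.size:3d}  freq(a) {rec.freq_a:.3f}  "
          f"pref-heterozygotes {rec.n_het_pref:3d}  unfit {rec.n_unfit:3d}")

summary = hp.polymorphism_summary(result.final_population, config.environment())
print("outcome:", summary.outcome)
print("genotype counts:", summary.genotype_counts)
print("modal phenotype classes:", summary.modal_classes)
```

prints

```
gen     0  size 500  freq(a) 0.000  pref-heterozygotes 500  unfit 274
gen  1999  size 334  freq(a) 0.000  pref-heterozygotes 332  unfit  86
gen  4000  size 351  freq(a) 0.957  pref-heterozygotes 350  unfit  12
gen  6000  size 259  freq(a) 0.975  pref-heterozygotes 257  unfit  12
gen  8000  size 314  freq(a) 1.000  pref-heterozygotes   0  unfit   0
outcome: non_type_polymorphism
genotype counts: {'AA': 212, 'AB': 0, 'BB': 102}
modal phenotype classes: {'AA': (0, 0, 1, 0), 'BB': (1, 0, 0, 0)}
```

Read bottom-up, that is the whole storyline: a founding population of 500
random perceptrons (274 of them unfit) evolves discrimination under enforced
random mating; once mating-gene mutation is allowed at generation 2,000 the
assortative allele sweeps to fixation (freq(a) 0 → 0.957 → 1.0); and after
mutations stop, selection strips out every remaining preference heterozygote,
leaving two reproductively isolated homozygote lineages — 212 niche-III
specialists [0,0,1,0] and 102 niche-I specialists [1,0,0,0] — with zero
unfit phenotypes.

## Command line

```bash
heteropatry run --outdir runs/demo --seed 0 --generations 8000
heteropatry stats --outdir runs/demo --window 1000:2000 --window 3000:4000
heteropatry robustness --outdir runs/demo
heteropatry pca --snapshot runs/demo/snapshot_008000.tsv --clusters 2
heteropatry trajectories --outdir runs/demo --plot runs/demo/traj.png
heteropatry replicate --n 10 --outdir runs/batch --generations 20000
```

Runs write a per-generation TSV log, periodic full-genome snapshot TSVs, the
config YAML and a JSON manifest; everything is reproducible from
(config, seed).

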