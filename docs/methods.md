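# Methods

`heteropatry` is an individual-based, forward-in-time simulator of a diploid,
sexually reproducing population of "exploiters" whose niche preference is a
perceptual decision made by a genetically encoded perceptron, together with
the statistics used to analyse such runs. This note documents the model, the
choices made where the design was genuinely open, and what the synthetic
dynamics do and do not show.

## The model

### Environment

Four resources k = 1..4 with carrying capacities N = [250, 0.01, 250, 0.01]:
two suitable niches (I, III) and two unsuitable ones (II, IV; the 0.01 is a
guard against division by zero, and any N below the suitability threshold of
1 marks the niche unsuitable). Each resource emits a two-channel signal
(s_k1, s_k2) ∈ [0,1]²; the default set
[(0.2,0.8), (0.4,0.6), (0.6,0.4), (0.8,0.2)] lines the four resources up on
the anti-diagonal of signal space, the hardest arrangement to discriminate
with ratio cues.

### Genotype → phenotype

Each individual carries two preference haplotypes of 13 real-valued alleles
(locus order w11, w21, bh1, w12, w22, bh2, w13, w23, bh3, wout1, wout2,
wout3, bo) and two mating alleles from {r, a}. Alleles are codominant: the
expressed weight at a locus is the mean of the two allelic values; expression
is recomputed from the haplotypes on demand, never cached. The expressed
weights parameterise a 2-input / 3-hidden / 1-output perceptron. For signal
(s1, s2), hidden node j has activity ξ_j = s1·w1j + s2·w2j − bhj and output
θ_j = σ(ω ξ_j); the output node has activity ξ_out = Σ_j θ_j·woutj − bo and
response ψ = σ(ω ξ_out), with σ the logistic function and ω = 4. The
response array Ψ = (ψ1..ψ4) holds the preference strengths for the four
niches; rounding component-wise (ties up) gives one of 16 binary phenotype
classes, e.g. [1,0,0,0] (niche-I specialist), [1,0,1,0] (discriminating
generalist), [1,1,1,1] (non-discriminating generalist). The four weights
touching hidden node j form a "super-gene"; its haplotype-specific values
are the units in which regulatory interactions (silencing, modification)
emerge.

Design choices here: the exact sigmoid is not dictated by the model's
qualitative contract ("negative activity → output near 0"), so the standard
logistic σ(ωx) is used; ties at ψ = 0.5 round up (any fixed rule works —
a measure-zero event for continuous weights); biases enter negatively, as an
inhibitory input of weight b from a constant −1 node.

### Reproductive output and fitness

Output allocation: e_k = φ·ψ_k²/Σ_l ψ_l with φ = 3 (e ≡ 0 when Ψ = 0). The
squared numerator makes output depend on the absolute response as well as
the share of the response going to niche k: every all-or-none binary Ψ
allocates exactly φ in total, while graded responses lose output, which
selects for bimodal (0/1) preferences. Fitness discounts each niche's
contribution by a Hill-type competition term,

    f_i = Σ_k e_k,i / (1 + (E_k / (ε N_k))^a),

with E_k = Σ_i e_k,i the total load on niche k (the individual's own output
included), ε = 1.5 the half-saturation coefficient (a niche's contribution
is exactly halved when E_k = ε N_k) and a = 2.5 the abruptness of the onset
of density dependence. Both formulas are isolated behind
`reproductive_output` and `fitness` so alternates can be swapped in.

### Mating

Five pools: p0 (random maters: genotype rr under a-dominance) and p1..p4,
one per niche. Assortative maters (ra, aa) join one of p1..p4 sampled in
proportion to their binary phenotype class (a [1,0,1,0] individual joins p1
or p3 with probability ½ each); an assortative individual whose class is
all-zero has nowhere to congregate and skips mating that generation. Pairs
form by drawing the first member uniformly from the unmated population and
its partner uniformly from the first member's pool — or from the whole
unmated population when the first member is in p0. Assortative individuals
therefore never choose a random mater but can be chosen by one; a
`p0_partner_scope="pool"` switch confines p0 to itself for comparison.
Mated individuals leave the pool; generations do not overlap.

### Recruits, mutation, recombination

Each pair contributes round(f1 + f2) recruits (see "Offspring accounting"
below). Every recruit receives from each parent one preference gamete —
copied from a uniformly chosen parental haplotype, switching template with
probability 10⁻⁴ at each locus (crossover with preserved linkage; ≈1 gamete
with a crossover per generation at a census of 400) — and one mating allele,
copied from a uniformly chosen parental chromosome. Point mutations hit each
preference allele with probability 0.01 (≈100 mutated gametes per
generation at census 400), adding a uniform(−10, 10) perturbation, clamped
to [−20, 20]; mating alleles flip r↔a with probability 5·10⁻⁴ when mating
mutation is enabled.

### Phase schedule

Runs start from 500 individuals with all 26 preference alleles uniform on
(−1, 1) — non-discriminating phenotypes — and mating genotype rr. Random
mating is enforced for the first 20,000 generations by disabling mating-gene
mutation (the pool logic is never overridden); mating-gene mutation is
enabled from generation 20,000 and all mutations stop at 80,000, with runs
ending at 100,000. Crossover is retained after the mutation stop
(recombination is not mutation); `crossover_after_stop=False` disables it
too. A single seeded `numpy.random.Generator` drives the run with a fixed
per-generation draw order (pool sampling → pairing → gamete blocks), so
(config, seed) reproduces a run bit-exactly.

### Offspring accounting

The natural reading of "recruits per pair = nearest integer of the pair's
mean fitness" is dynamically inconsistent with the rest of the model: with
φ = 3 a pair can at best leave round(3) = 3 recruits, a founding population
of non-discriminating generalists has pair-mean fitness ≤ 1.5 and cannot
replace itself, and the all-specialist equilibrium census it implies (~190)
is far below the ~370–400 implied by the sampled statistics. Empirically
that rule extinguishes the population within ten generations. The package
therefore accounts recruits as round(f1 + f2) per pair (`pair_fecundity=
"sum"`, the default). This variant lets the stated founding population
persist, equilibrates near a census of 280–350, and — unlike the
`"per_parent"` variant (2·round(mean), also available) — cannot drive a
homogeneous specialist lineage through its round-to-zero fitness threshold
in a single doubling, a failure mode observed in testing. The printed rule
remains available as `pair_fecundity="mean"`.

## Analysis battery

* **Unfit phenotypes**: classes preferring ≥1 unsuitable niche.
* **ML chi-square**: likelihood-ratio G = 2·Σ O ln(O/E) on 2×2 tables, p
  from χ²(1); no multiple-testing correction is applied.
* **Robustness assay**: from a genotype pool of size P, K = P(P−1) mutants
  are drawn with replacement; each receives one simulation-style
  perturbation at one random allele. The expected unfit count after
  mutation is round(mutant unfit fraction × P), and the increase is
  reported as a percentage of the pool's original unfit count (0 → 0
  counts as a 0% increase). Default sampling windows are generations
  15,000–20,000 (random mating) and 27,000–32,000 (assortative mating),
  every 1,000 generations.
* **PCA + clustering**: principal-component scores of haplotype (13-dim) or
  genotype (26-dim, storage-order concatenation) rows, partitioned by
  k-means on the scores; the cluster count is a user parameter, with a
  silhouette-selected k ∈ 2..6 as the default heuristic (the original
  analysis was visual). Genotype rows keep haplotype storage order, so a
  heterozygote appears as mirror clusters AB and BA.
* **Polymorphism classification** (`polymorphism_summary`): a snapshot is
  called a two-haplotype polymorphism when the pooled haplotypes separate
  into two k-means clusters with silhouette ≥ 0.6 and both homozygote
  genotypes hold ≥ 2% of the population; it is of the "type" kind when the
  heterozygote's modal phenotype class equals that of exactly one
  homozygote. The thresholds are structural-detection choices, fixed before
  any end-to-end evaluation.
* **Trajectory smoothing**: centred running mean (window 80, emitted every
  20 generations) of phenotype-class counts, dropping classes that never
  exceed 80 individuals.

## Scaled problem sizes

Full runs (100,000 generations) take hours; the package's own evaluation
uses scaled designs chosen to exercise every phase: polymorphism surveys run
10 replicates to generation 20,000 (the end of the enforced-random-mating
phase, where the original outcome census was taken); the reduced end-to-end
check runs population 250 to generation 5,000; phased dynamics use the
shortened schedule 2,000 / 6,000 / 8,000. At these scales a replicate takes
tens of seconds to a few minutes on one core.

## What the synthetic dynamics show — and what they do not

The simulator reproduces, from first principles, the qualitative programme:
specialist phenotypes and a two-haplotype polymorphism emerge under random
mating (6/10 replicates at generation 20,000, of which 3 are "type" cases
with the heterozygote phenotypically identical to one homozygote and 3 have
both homozygotes sharing a phenotype; the remaining 4 fix the [1,0,1,0]
discriminating generalist); the assortative allele invades to fixation in
most replicates once allowed; and heterozygotes disappear after mutations
stop. The relative frequencies of these outcome classes are sensitive to
unprinted details — above all the exact sigmoid and the offspring
accounting — so they should be read as the model's qualitative repertoire,
not calibrated probabilities. The monomorphic discriminating-generalist
attractor is somewhat stickier here than in the original report, plausibly
because all binary phenotype classes earn identical total output, leaving
the outcome to mutation accessibility and drift.

These are synthetic populations: discrete non-overlapping generations, no
spatial structure, no sexes, no cost of specialisation or of assortative
mating, and an idealised one-locus mating gene. Passing tests demonstrate
internal consistency of the model and its statistics, not predictions about
any natural population.

## Numerical notes

* ψ is mathematically confined to (0, 1) but saturates to exactly 0.0/1.0
  in float64 for |activation| ≳ 37; downstream code treats the closed
  interval as valid.
* Offspring counts round half up (floor(x + 0.5)), as do phenotype classes
  at ψ = 0.5 and the robustness assay's expected counts.
* Snapshots serialise floats with 17 significant digits and round-trip
  bit-exactly.
* Degenerate inputs: an empty mating pool leaves its would-be first member
  unmated; a generation with zero recruits terminates the run with an
  "extinct" record; Ψ = 0 allocates zero output rather than 0/0.
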