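# Methods

## Trait model

`argtrait` simulates additive quantitative traits on an ancestral
recombination graph (ARG) held as a succinct tree sequence. The model is
the standard GWAS architecture transplanted to the ARG setting:

1. **Causal sites.** A trait is associated with a set of causal sites.
   By default one site is chosen uniformly at random; the user may ask
   for `num_causal` random sites or supply an explicit table. Random
   selection draws uniformly *without replacement from sites carrying at
   least one mutation*: a mutation-free site can never generate genetic
   variance, so including it would silently produce degenerate traits.
2. **Causal alleles.** At each causal site one derived allele is causal,
   chosen uniformly among the distinct derived states of the site's
   mutations, excluding the ancestral state. The ancestral allele is
   never causal in this implementation (a deliberate restriction — an
   "effect of the ancestral allele" is a re-parameterisation of the
   derived-allele effect plus an intercept); mutations whose derived
   state equals the ancestral state (pure back mutations) are likewise
   not candidates.
3. **Effect sizes.** Raw effects are drawn i.i.d. across sites from one
   of five univariate families — `normal(mean, var)`, location–scale
   `t(mean, var, df)` (draws are `mean + sqrt(var)·T(df)`, so `var` is
   the squared scale, keeping the parameter names meaningful across
   families), degenerate `fixed(value)`, `exponential(scale)` and
   `gamma(shape, scale)` — or from a multivariate normal that assigns
   each site one correlated vector of effects across `k` pleiotropic
   traits. Exponential and gamma are non-negative by default;
   `negative_allowed=True` flips each draw's sign independently with
   probability ½.
4. **Frequency dependence.** Optionally each raw effect is multiplied by
   `(2p(1−p))^(α/2)`, where `p` is the causal-allele frequency among
   haploid **sample nodes** (not individuals — consistent with the
   node-level definition of genetic value) and α tunes the strength of
   the rare-variant effect (α < 0: rare alleles get larger effects).
   α = 0 is the identity by definition, applied without evaluating the
   formula, so it is exact for any p including 0 and 1. For α ≠ 0 a
   frequency outside (0, 1) is an error: the scaling is undefined there.
   For multivariate models the same multiplier applies to every trait's
   component at a site (a single shared causal allele per site).
5. **Genetic values.** At each causal site, every node of the local tree
   whose decoded allele equals the causal allele has genetic value
   `beta_scaled`; node values sum over causal sites, and an individual's
   genetic value is the sum over its nodes (arbitrary ploidy is
   supported, diploid being the usual case).
6. **Phenotypes.** `Y = G + E` per individual and trait, with
   `E ~ Normal(0, V_G(1−h²)/h²)`. `V_G` is the **unbiased (n−1) sample
   variance** of the genetic values over exactly the individuals that
   receive phenotypes — a documented choice; the alternative (population
   variance, denominator n) differs by O(1/n). `h² = 1` is allowed and
   yields `E ≡ 0`; `h² = 0` is rejected rather than read as infinite
   noise, as is `V_G = 0` with `h² < 1` (there is no genetic variance to
   anchor the heritability).

## Allele decoding and back mutations

Sites are decoded **one at a time** by a local-tree traversal: the
marginal tree covering the site's position is walked in preorder, each
node inheriting its parent's state unless it carries a mutation at the
site, in which case the mutation's derived state takes over for the node
and (unless overridden again) its subtree. This handles back mutations
(restoring the ancestral state below an earlier mutation) and recurrent
mutations naturally, and is the package's central efficiency property:
memory and time scale with the number of *causal* sites, never with the
total number of variant sites, and no genotype matrix is ever formed.
The inner loop is JIT-compiled with numba (with a pure-Python fallback).

Tie-break when several mutations at one site sit on the same node: the
most recent one (smallest time-before-present) wins; among unknown times
the last-listed row wins. In a validly sorted mutation table the two
rules coincide, because younger mutations sort later within a site.
Nodes isolated at the site's position (no edges there) take the ancestral
state unless they carry a mutation themselves.

Individuals are the phenotype-bearing unit. Nodes attached to the null
individual (−1) — typically ancestral nodes, but possibly also sample
nodes — contribute to allele frequencies but to no individual's genetic
value. Conversely, every individual owning at least one node receives a
phenotype, whether or not its nodes are samples; this covers ARGs
embedded in multigenerational pedigrees where internal nodes belong to
real individuals.

## Randomness and reproducibility

All sampling flows through `numpy.random.Generator`. The one-call
pipeline splits its master seed into two independent child streams
(effect simulation, environmental noise) via `SeedSequence.spawn`, and
the noise stage splits further into one stream per trait, so adding a
trait never perturbs another trait's noise and identical seeds reproduce
identical tables bit for bit. Within effect simulation the stream is
consumed in a documented order — site selection, then allele choice in
position order, then effect draws — so explicit and random causal-site
modes are interchangeable.

## Numerical choices

- Genome intervals are half-open `[left, right)`, positions 0-based
  reals (the tree-sequence convention).
- Covariance matrices are validated by symmetric eigendecomposition with
  tolerance 1e−8 on the smallest eigenvalue.
- Genetic-value accumulation is ordered (sites in position order, then
  nodes), fixing floating-point associativity; doubling every beta
  doubles every genetic value exactly.
- CSV output prints floats with 17 significant digits (`%.17g`) and the
  plain-text table reader parses with round-trip precision, so dump →
  load is an exact identity and CLI outputs are byte-stable and
  diffable. Output rows are deterministically ordered by
  (position, trait_id) and (individual_id, trait_id).

## Synthetic data

`argtrait.fixtures` generates all test data programmatically:

- `fig1_fixture()` reconstructs the package's worked example: three
  diploid individuals over six sample nodes, one site with ancestral
  state A, a mutation to T on internal node *i* and a back mutation to A
  on sample node *e* below it. The caption-level facts pin the fixture
  only partially; the committed topology places two cherries (c,d) and
  (e,f) under *i*, so after the back mutation exactly three of the six
  sample nodes carry T (frequency 0.5) and the individual genetic values
  under a fixed β = 0.05 are (0, 0.10, 0.05).
- `random_arg(FixtureSpec(...))` builds a random ARG from an internal
  Kingman-style coalescent sampler: each interval between recombination
  breakpoints receives an independent binary tree over the same sample
  nodes, and each site gets one guaranteed non-silent mutation plus,
  with probability 0.4, a stacked mutation at or below it (producing
  back/recurrent mutations and same-node mutation pairs) and, with
  probability 0.2, an independent extra mutation. The sampler is
  deliberately minimal — it emulates tree shape, mutation layering and
  the table invariants, not demography, selection, linkage realism or
  correlated marginal trees (adjacent intervals are independent, unlike
  real ARGs). Passing tests therefore demonstrate correctness of the
  trait machinery on arbitrary valid ARGs, not realism of any population
  model; realistic inputs should come from a coalescent simulator.

## Problem sizes in the test suite

The oracle-equivalence suite cross-checks the tree-traversal genetic
values against an independent full genotype-matrix decode on 100 random
ARGs of up to 50 samples and 20 sites at 1e−12 relative tolerance.
Heritability calibration is checked at n = 10,000 individuals (noise
variance within 5% of its target) and via 200 phenotype replicates on a
fixed ARG of 2,000 diploid individuals with 20 causal sites, where the
mean of Var(G)/Var(Y) must recover h² = 0.5 within ±0.03; replicates
redraw causal sites, effects and noise on one genealogy, which isolates
the trait machinery from coalescent variance across genealogies.

## Known limitations

- Additive model only: no dominance, epistasis, gene–environment
  interaction or liability thresholding.
- Environmental noise is normal and independent across individuals; no
  shared-environment or family effects.
- Effect-size families are the six built-ins; arbitrary user
  distributions are supported only indirectly, by supplying explicit
  effect sizes in the causal-site table.
- The ancestral allele cannot be designated causal (see above).
- `random_arg` is a test-surface generator, not a population-genetics
  simulator.
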