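# argtrait

Quantitative trait simulation directly on ancestral recombination graphs
(ARGs).

Population-genetic simulators (msprime, SLiM, stdpopsim) and modern ARG
inference methods produce genealogies in the succinct tree-sequence
encoding rather than genotype matrices. GWAS method development needs
ground-truth phenotypes on top of those genealogies, but exporting the
genotype matrix first is slow, loses ancestral detail and is infeasible at
biobank scale. `argtrait` simulates additive quantitative traits for the
individuals of an ARG without ever decoding the full variation data: only
the causal sites are decoded, each by a single local-tree traversal.

## Model

Each trait has one or more causal sites. At causal site *j* with causal
allele *a<sub>j</sub>*, a raw effect size *β<sub>j</sub>* is drawn from a
user-chosen distribution (normal, t, fixed, exponential, gamma, or
multivariate normal across pleiotropic traits) and optionally scaled for
frequency dependence:

> β̃<sub>j</sub> = β<sub>j</sub> · (2 p<sub>j</sub> (1 − p<sub>j</sub>))<sup>α/2</sup>

where *p<sub>j</sub>* is the causal-allele frequency among haploid sample
nodes and *α* ≤ 0 gives rare alleles larger effects (*α* = 0, the default,
disables scaling). Every node of the local tree at site *j* that inherits
*a<sub>j</sub>* — back and recurrent mutations are honoured, so a lineage
that mutates back to the ancestral state carries nothing — receives
genetic value β̃<sub>j</sub>; an individual's genetic value *G* is the sum
over its nodes (two for a diploid) and over causal sites. Phenotypes are

> Y = G + E,  E ~ Normal(0, V<sub>G</sub> (1 − h²) / h²)

with *V<sub>G</sub>* the sample variance of the individual genetic values
and *h²* the narrow-sense heritability, so a fraction *h²* of phenotypic
variance is genetic in expectation.

## Worked example

```python
import argtrait
from argtrait.fixtures import FixtureSpec, random_arg

arg = random_arg(FixtureSpec(n_individuals=5, ploidy=2, n_sites=10, seed=7))
model = argtrait.trait_model("normal", mean=0, var=1)
result = argtrait.sim_phenotype(arg, model, num_causal=3, alpha=-0.5,
                                h2=0.8, random_seed=42)
print(result.effects)
print(result.phenotypes)
```

```text
 site_id  position causal_allele  trait_id  beta_raw  allele_freq  beta_scaled
       3     0.141             C         0 -1.084246          0.2    -1.441585
       5     0.466             G         0  1.464221          0.1     2.247960
       8     0.849             T         0  0.290727          0.1     0.446342

 individual_id  trait_id  genetic_value  environmental_noise  phenotype
             0         0      -1.441585             0.354085  -1.087500
             1         0       0.000000            -1.062070  -1.062070
             2         0       0.446342            -0.039701   0.406641
             3         0      -1.441585             0.160900  -1.280685
             4         0       2.247960             0.708874   2.956833
```

Three of the ten sites were chosen as causal. Each effect row shows the
raw draw `beta_raw`, the causal-allele frequency among the ten haploid
sample genomes, and the α-scaled effect actually applied — with
α = −0.5 the two rare alleles (p = 0.1) are boosted more than the common
one. In the phenotype table, individual 1 carries no causal allele
(genetic value 0) yet still has a nonzero phenotype from environmental
noise, and every row satisfies `phenotype = genetic_value +
environmental_noise` exactly.

The same pipeline is available stepwise (`sim_trait` → `genetic_values` →
`sim_env`) for users who want to supply their own causal sites or effect
sizes as a CSV/DataFrame, and from the shell:

```sh
argtrait --trees example.trees --model normal --mean 0 --var 1 \
         --num-causal 100 --h2 0.5 --seed 1 --out run1
# writes run1.effects.csv and run1.phenotypes.csv
```

ARGs load from standard `.trees` files or from a plain-text five-table
dump (`argtrait.fixtures.export_tables` / `argtrait.load_arg`), so test
data can live in version control as TSV.

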