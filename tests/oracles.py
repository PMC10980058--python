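"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the package's own decoding path: allele states
are obtained by walking each node up to its local root, and genetic values
by decoding the full genotype matrix with tskit's variant decoder and
taking a matrix product.
"""

import math

import numpy as np


def walk_allele_state(ts, site_id, node):
    """Allele of ``node`` at ``site_id`` by walking the path to the root.

    The nearest mutated ancestor (inclusive of the node itself) determines
    the state; on a node with several mutations the youngest (smallest
    time; among unknown times the last-listed) wins.
    """
    site = ts.site(site_id)
    winner = {}
    best = {}
    for row, mut in enumerate(site.mutations):
        t = mut.time
        key = (math.inf if math.isnan(t) else -t, row)
        if mut.node not in best or key > best[mut.node]:
            best[mut.node] = key
            winner[mut.node] = mut.derived_state
    tree = ts.at(site.position)
    u = node
    while u != -1:
        if u in winner:
            return winner[u]
        u = tree.parent(u)
    return site.ancestral_state


def genotype_matrix_values(ts, effects):
    """Per-individual genetic values via full genotype-matrix decode.

    Decodes every variant with tskit, multiplies carrier indicators by the
    scaled effect sizes, and folds haplotypes into individuals.
    """
    num_traits = int(effects["trait_id"].max()) + 1 if len(effects) else 1
    values = np.zeros((ts.num_individuals, num_traits))
    samples = ts.samples()
    node_individual = ts.nodes_individual
    for var in ts.variants():
        rows = effects[effects["site_id"] == var.site.id]
        for row in rows.itertuples():
            if row.causal_allele not in var.alleles:
                continue
            allele_index = var.alleles.index(row.causal_allele)
            for u in samples[var.genotypes == allele_index]:
                ind = node_individual[u]
                if ind >= 0:
                    values[ind, int(row.trait_id)] += row.beta_scaled
    return values


def individuals_with_nodes(ts):
    return np.unique(ts.nodes_individual[ts.nodes_individual >= 0])
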