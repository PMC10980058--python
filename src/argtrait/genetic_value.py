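"""Per-node genetic values and additive aggregation to individuals.

At each causal site, every node of the local tree whose decoded allele is
the causal allele has genetic value ``beta_scaled``; a node's total genetic
value sums these contributions over causal sites, and an individual's
genetic value is the sum over its nodes (two for a diploid).  This is the
``genetic_values`` stage.

The computation is a per-causal-site subtree traversal — causal states are
pushed down from each mutation's node, honouring overriding mutations
below — and never materialises a genotype matrix, so cost scales with the
number of causal sites, not the number of variant sites.

Sample nodes attached to the null individual (−1) count towards allele
frequencies but are NOT attached to any row of the output: only
individuals owning at least one node receive genetic values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tskit

from . import arg_core

__all__ = ["node_genetic_values", "aggregate_by_individual", "genetic_values"]


def _effect_sites(effects):
    """Unique causal sites in position order, with their per-trait betas."""
    required = {"site_id", "causal_allele", "trait_id", "beta_scaled"}
    missing = required - set(effects.columns)
    if missing:
        raise ValueError(f"effect table missing columns: {sorted(missing)}")
    order = effects.sort_values(["position", "trait_id"]) if "position" in effects else effects
    return order.groupby("site_id", sort=True)


def _node_value_matrix(ts, effects, num_traits):
    """(num_nodes, num_traits) matrix of per-node genetic values.

    Each unique causal site is decoded exactly once; contributions are
    accumulated in site order then node order so the result is
    deterministic.
    """
    values = np.zeros((ts.num_nodes, num_traits))
    if len(effects) == 0:
        return values
    tree = tskit.Tree(ts)
    for site_id, group in _effect_sites(effects):
        site_id = int(site_id)
        if not 0 <= site_id < ts.num_sites:
            raise ValueError(f"effect table references unknown site {site_id}")
        tree.seek(ts.site(site_id).position)
        alleles, states = arg_core.site_allele_states(ts, site_id, tree=tree)
        for allele, allele_group in group.groupby("causal_allele", sort=False):
            if allele not in alleles:
                continue  # causal allele carried by no node at this position
            carrier = states == alleles.index(allele)
            for row in allele_group.itertuples():
                values[carrier, int(row.trait_id)] += row.beta_scaled
    return values


def node_genetic_values(ts, effects, trait_id=0):
    """Genetic value of every node for one trait.

    Returns an array of length ``ts.num_nodes``; nodes carrying no causal
    allele have value 0.
    """
    sub = effects[effects["trait_id"] == trait_id]
    n_traits = int(trait_id) + 1
    return _node_value_matrix(ts, sub, n_traits)[:, int(trait_id)]


def aggregate_by_individual(ts, node_values):
    """Sum node genetic values within individuals.

    ``node_values`` is an array over nodes (or a mapping node -> value).
    Nodes with individual −1 are ignored; every individual owning at least
    one node appears, with value 0 if none of its nodes carry a causal
    allele.
    """
    if isinstance(node_values, dict):
        arr = np.zeros(ts.num_nodes)
        for node, v in node_values.items():
            arr[node] = v
        node_values = arr
    node_values = np.asarray(node_values, dtype=float)
    ind = ts.nodes_individual
    owned = ind != tskit.NULL
    totals = np.bincount(ind[owned], weights=node_values[owned], minlength=ts.num_individuals)
    has_nodes = np.bincount(ind[owned], minlength=ts.num_individuals) > 0
    ids = np.flatnonzero(has_nodes)
    return pd.DataFrame({"individual_id": ids, "genetic_value": totals[ids]})


def genetic_values(ts, effects):
    """Per-individual genetic values for every trait in ``effects``.

    Returns a DataFrame with columns ``individual_id, trait_id,
    genetic_value``, one row per (individual x trait), sorted by
    (individual_id, trait_id).
    """
    trait_ids = sorted(effects["trait_id"].unique()) if len(effects) else [0]
    num_traits = int(max(trait_ids)) + 1 if trait_ids else 1
    matrix = _node_value_matrix(ts, effects, num_traits)
    frames = []
    for t in trait_ids:
        df = aggregate_by_individual(ts, matrix[:, int(t)])
        df.insert(1, "trait_id", int(t))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["individual_id", "trait_id"], ignore_index=True)
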