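"""Core handling of ARGs in succinct tree-sequence form.

An ancestral recombination graph (ARG) is represented as a
:class:`tskit.TreeSequence`: node, edge, site, mutation and individual
tables encoding the ensemble of correlated local trees along a recombining
genome.  This module loads and validates ARGs, reconstructs the marginal
tree at a genome position, and decodes per-node allele states at single
sites with full back/recurrent-mutation semantics.

Decoding is deliberately *per site*: the allele state of every node in the
local tree is obtained by pushing states down the tree from each mutation,
letting mutations on lower (younger) nodes override those above them.  Only
the sites a caller asks about are ever decoded, so memory use is independent
of the total number of variant sites.

Genome intervals are half-open ``[left, right)`` and positions are 0-based,
following the standard tree-sequence convention.
"""

from __future__ import annotations

import math
import os
import pathlib

import numpy as np
import pandas as pd
import tskit

__all__ = [
    "load_arg",
    "local_tree_at",
    "allele_state",
    "allele_frequency",
    "site_allele_states",
    "read_tables_dir",
    "write_tables_dir",
    "TABLE_FILE_NAMES",
]

#: Files making up a plain-text table dump: five tables plus a one-line
#: metadata file carrying the sequence length.
TABLE_FILE_NAMES = (
    "nodes.tsv",
    "edges.tsv",
    "sites.tsv",
    "mutations.tsv",
    "individuals.tsv",
    "metadata.tsv",
)

try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _propagate_py(preorder, parent, mut_allele, state, visited):
    # Push allele states down the local tree in preorder.  A node takes its
    # own (winning) mutation if it has one, else it inherits from its parent;
    # roots inherit the ancestral state (index 0).
    for u in preorder:
        p = parent[u]
        if mut_allele[u] >= 0:
            state[u] = mut_allele[u]
        elif p >= 0:
            state[u] = state[p]
        else:
            state[u] = 0
        visited[u] = True
    # Nodes isolated at this position (not reachable from any root) carry
    # their own mutation if any, else the ancestral state.
    for u in range(state.shape[0]):
        if not visited[u] and mut_allele[u] >= 0:
            state[u] = mut_allele[u]


if _HAVE_NUMBA:
    _propagate = numba.njit(_propagate_py)
else:  # pragma: no cover
    _propagate = _propagate_py


def _winning_mutation_alleles(ts, site, num_nodes):
    """Map each mutated node to the allele index that wins on that node.

    When several mutations at one site sit on the same node, the latest
    (most recent, i.e. smallest time-before-present) wins; among unknown
    times the last-listed row wins.  In a validly sorted mutation table
    these two rules agree: younger mutations come later.

    Returns ``(alleles, mut_allele)`` where ``alleles`` lists the ancestral
    state first followed by distinct derived states in order of first
    appearance, and ``mut_allele[u]`` is the winning allele index on node
    ``u`` (−1 where no mutation).
    """
    alleles = [site.ancestral_state]
    index_of = {site.ancestral_state: 0}
    mut_allele = np.full(num_nodes, -1, dtype=np.int32)
    best_key = {}
    for row, mut in enumerate(site.mutations):
        state = mut.derived_state
        if state not in index_of:
            index_of[state] = len(alleles)
            alleles.append(state)
        t = mut.time
        # smaller time-before-present = more recent; unknown times defer
        # to listing order (they cannot mix with known times at one site)
        key = (math.inf if (t is None or math.isnan(t)) else -t, row)
        if mut.node not in best_key or key > best_key[mut.node]:
            best_key[mut.node] = key
            mut_allele[mut.node] = index_of[state]
    return alleles, mut_allele


def site_allele_states(ts, site_id, *, tree=None):
    """Decode the allele state of every node at one site.

    Parameters
    ----------
    ts : tskit.TreeSequence
        The ARG.
    site_id : int
        Site to decode.
    tree : tskit.Tree, optional
        A tree already positioned over the site, to avoid a fresh seek.

    Returns
    -------
    alleles : list of str
        Distinct allele strings at the site; ``alleles[0]`` is the
        ancestral state.
    states : numpy.ndarray
        Integer array of length ``ts.num_nodes``; ``alleles[states[u]]`` is
        the allele carried by node ``u``.
    """
    site = ts.site(site_id)
    if tree is None:
        tree = ts.at(site.position)
    alleles, mut_allele = _winning_mutation_alleles(ts, site, ts.num_nodes)
    states = np.zeros(ts.num_nodes, dtype=np.int32)
    visited = np.zeros(ts.num_nodes, dtype=np.bool_)
    _propagate(tree.preorder(), tree.parent_array, mut_allele, states, visited)
    return alleles, states


def allele_state(ts, site_id, node):
    """Return the allele carried by ``node`` at ``site_id``.

    The allele is the derived state of the nearest mutation at the site on
    the path from the node up to its local root (including the node
    itself), or the ancestral state when no such mutation exists.
    """
    if not 0 <= node < ts.num_nodes:
        raise ValueError(f"node {node} does not exist")
    alleles, states = site_allele_states(ts, site_id)
    return alleles[states[node]]


def allele_frequency(ts, site_id, allele):
    """Frequency of ``allele`` at ``site_id`` among sample nodes.

    The denominator counts haploid sample nodes, not individuals.
    """
    if ts.num_samples == 0:
        raise ValueError("ARG has no sample nodes")
    alleles, states = site_allele_states(ts, site_id)
    sample_states = states[ts.samples()]
    try:
        idx = alleles.index(allele)
    except ValueError:
        return 0.0
    return float(np.count_nonzero(sample_states == idx)) / ts.num_samples


def local_tree_at(ts, position):
    """Parent mapping of the marginal tree covering ``position``.

    Returns a dict ``{node_id: parent_id or None}`` over all nodes; roots
    and nodes isolated at this position map to ``None``.
    """
    if not 0 <= position < ts.sequence_length:
        raise ValueError(
            f"position {position} outside [0, {ts.sequence_length})"
        )
    tree = ts.at(position)
    parent = tree.parent_array
    return {
        u: (int(parent[u]) if parent[u] != tskit.NULL else None)
        for u in range(ts.num_nodes)
    }


def _validate(ts):
    if ts.num_samples == 0:
        raise ValueError("ARG has no sample nodes")
    if ts.num_individuals == 0:
        raise ValueError(
            "ARG has no individuals; phenotypes are defined per individual"
        )
    return ts


def load_arg(source):
    """Load and validate an ARG.

    ``source`` may be a :class:`tskit.TreeSequence`, a
    :class:`tskit.TableCollection`, a path to a tree-sequence file, or a
    path to a directory holding the plain-text table dump written by
    :func:`write_tables_dir`.

    Raises ``ValueError`` (or a tskit error) on structural violations —
    dangling references, unsorted edges, zero individuals.
    """
    if isinstance(source, tskit.TreeSequence):
        return _validate(source)
    if isinstance(source, tskit.TableCollection):
        return _validate(source.tree_sequence())
    path = pathlib.Path(source)
    if path.is_dir():
        return _validate(read_tables_dir(path))
    if not path.exists():
        raise FileNotFoundError(f"no such ARG file: {path}")
    return _validate(tskit.load(path))


# -- plain-text table dump -------------------------------------------------
#
# One TSV per table with a documented header row, so an ARG can live in a
# repository as text.  Floats are printed with 17 significant digits and
# round-trip exactly.  Within a site, mutations must be listed with
# ancestral mutations before their descendants (tree-sequence sort order);
# mutation parents are recomputed on load.

_FLOAT_FMT = "%.17g"


def write_tables_dir(ts, directory):
    """Write ``ts`` as a plain-text five-table dump plus metadata file."""
    directory = pathlib.Path(directory)
    os.makedirs(directory, exist_ok=True)
    t = ts.tables

    nodes = pd.DataFrame(
        {
            "id": np.arange(len(t.nodes)),
            "is_sample": (t.nodes.flags & tskit.NODE_IS_SAMPLE).astype(bool).astype(int),
            "time": t.nodes.time,
            "individual": t.nodes.individual,
        }
    )
    edges = pd.DataFrame(
        {
            "left": t.edges.left,
            "right": t.edges.right,
            "parent": t.edges.parent,
            "child": t.edges.child,
        }
    )
    sites = pd.DataFrame(
        {
            "id": np.arange(len(t.sites)),
            "position": t.sites.position,
            "ancestral_state": [s.ancestral_state for s in ts.sites()],
        }
    )
    mutations = pd.DataFrame(
        {
            "id": np.arange(len(t.mutations)),
            "site": t.mutations.site,
            "node": t.mutations.node,
            "time": t.mutations.time,
            "derived_state": [m.derived_state for m in ts.mutations()],
            "parent": t.mutations.parent,
        }
    )
    # unknown mutation times serialise as empty fields
    mutations.loc[np.isnan(mutations["time"]), "time"] = np.nan
    individuals = pd.DataFrame({"id": np.arange(ts.num_individuals)})
    metadata = pd.DataFrame(
        {"key": ["sequence_length"], "value": [_FLOAT_FMT % ts.sequence_length]}
    )

    for name, df in [
        ("nodes", nodes),
        ("edges", edges),
        ("sites", sites),
        ("mutations", mutations),
        ("individuals", individuals),
        ("metadata", metadata),
    ]:
        df.to_csv(
            directory / f"{name}.tsv",
            sep="\t",
            index=False,
            float_format=_FLOAT_FMT,
            na_rep="",
        )


def read_tables_dir(directory):
    """Read a plain-text table dump into a validated tree sequence."""
    directory = pathlib.Path(directory)
    for name in TABLE_FILE_NAMES:
        if not (directory / name).exists():
            raise FileNotFoundError(f"table dump incomplete: missing {name}")

    def read(name, **kw):
        # round_trip: floats printed with 17 significant digits must parse
        # back to the identical double
        return pd.read_csv(
            directory / name, sep="\t", float_precision="round_trip", **kw
        )

    meta = read("metadata.tsv", dtype=str).set_index("key")["value"]
    sequence_length = float(meta["sequence_length"])

    tc = tskit.TableCollection(sequence_length=sequence_length)

    individuals = read("individuals.tsv")
    for _ in range(len(individuals)):
        tc.individuals.add_row()

    nodes = read("nodes.tsv")
    if not np.array_equal(nodes["id"].to_numpy(), np.arange(len(nodes))):
        raise ValueError("nodes.tsv ids must be 0..n-1 in order")
    for row in nodes.itertuples():
        tc.nodes.add_row(
            flags=tskit.NODE_IS_SAMPLE if row.is_sample else 0,
            time=float(row.time),
            individual=int(row.individual),
        )

    for row in read("edges.tsv").itertuples():
        tc.edges.add_row(
            left=float(row.left),
            right=float(row.right),
            parent=int(row.parent),
            child=int(row.child),
        )

    sites = read("sites.tsv", dtype={"ancestral_state": str})
    if not np.array_equal(sites["id"].to_numpy(), np.arange(len(sites))):
        raise ValueError("sites.tsv ids must be 0..n-1 in order")
    for row in sites.itertuples():
        tc.sites.add_row(
            position=float(row.position), ancestral_state=row.ancestral_state
        )

    mutations = read("mutations.tsv", dtype={"derived_state": str})
    for row in mutations.itertuples():
        t = float(row.time) if not pd.isna(row.time) else tskit.UNKNOWN_TIME
        tc.mutations.add_row(
            site=int(row.site),
            node=int(row.node),
            derived_state=row.derived_state,
            time=t,
        )

    tc.sort()
    tc.build_index()
    tc.compute_mutation_parents()
    return tc.tree_sequence()
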