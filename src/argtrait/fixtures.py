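"""Programmatic generation of small ARGs for examples and tests.

Provides a hand-built worked example — one site with ancestral state A, a
mutation to T on an internal node and a back mutation to A on a sample
node below it, over three diploid individuals — plus a minimal random
coalescent generator so the whole package is testable without downloading
or simulating anything externally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tskit

from . import arg_core

__all__ = ["fig1_fixture", "FIG1_NODES", "FixtureSpec", "random_arg", "export_tables"]

_ALPHABET = ("A", "C", "G", "T")

#: Sample-node letters of the worked example mapped to node ids; ``i`` is
#: the internal node carrying the causal T mutation.
FIG1_NODES = {"a": 0, "b": 1, "c": 2, "d": 3, "e": 4, "f": 5, "i": 8}


def fig1_fixture():
    """The worked diploid example with a back mutation.

    Three diploid individuals: 0 owns sample nodes (a, b), 1 owns (c, d),
    2 owns (e, f).  Committed topology (times in parentheses)::

                  10 (3.0)
                 /        \\
            9 (1.0)      8 = i (2.0)
            /  \\         /        \\
           a    b     6 (1.0)    7 (1.0)
                      /  \\       /  \\
                     c    d     e    f

    One site at position 0.5 with ancestral state A; a mutation to T on
    internal node ``i`` and a back mutation to A on sample node ``e``.
    After the back mutation the T carriers among samples are c, d and f
    (three of six sample nodes), and with a fixed effect size of 0.05
    every T-carrying node has genetic value 0.05 while ``e`` has 0.
    Internal nodes belong to the null individual (−1).
    """
    tc = tskit.TableCollection(sequence_length=1.0)
    for _ in range(3):
        tc.individuals.add_row()
    for node in "abcdef":
        tc.nodes.add_row(
            flags=tskit.NODE_IS_SAMPLE, time=0.0, individual=FIG1_NODES[node] // 2
        )
    for time in (1.0, 1.0, 2.0, 1.0, 3.0):  # nodes 6, 7, 8=i, 9, 10
        tc.nodes.add_row(time=time)
    for parent, child in [
        (6, 2), (6, 3),   # c, d
        (7, 4), (7, 5),   # e, f
        (8, 6), (8, 7),   # i joins the two cherries
        (9, 0), (9, 1),   # a, b
        (10, 8), (10, 9),
    ]:
        tc.edges.add_row(left=0.0, right=1.0, parent=parent, child=child)
    tc.sites.add_row(position=0.5, ancestral_state="A")
    tc.mutations.add_row(site=0, node=8, derived_state="T", time=2.5)
    tc.mutations.add_row(site=0, node=4, derived_state="A", time=0.5, parent=0)
    tc.sort()
    tc.build_index()
    tc.compute_mutation_parents()
    return tc.tree_sequence()


@dataclass
class FixtureSpec:
    """Parameters of a random test ARG (sequence length is 1.0)."""

    n_individuals: int
    ploidy: int = 2
    n_sites: int = 5
    recombination_breakpoints: tuple = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if any(not 0 < b < 1 for b in self.recombination_breakpoints):
            raise ValueError("breakpoints must lie strictly inside (0, 1)")


def _coalesce(tc, samples, left, right, rng, t_start=0.0):
    """Kingman-style merge of ``samples`` over [left, right).

    Returns the parent mapping of the resulting tree (fresh internal nodes
    are appended to ``tc.nodes``).
    """
    lineages = list(samples)
    parent = {}
    t = t_start
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        new = tc.nodes.add_row(time=t)
        for child in (a, b):
            tc.edges.add_row(left=left, right=right, parent=new, child=child)
            parent[child] = new
        lineages = [x for x in lineages if x not in (a, b)] + [new]
    return parent


def _subtree(parent, root):
    children = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    out, stack = [], [root]
    while stack:
        u = stack.pop()
        out.append(u)
        stack.extend(children.get(u, ()))
    return out


def random_arg(spec):
    """Generate a random ARG from a :class:`FixtureSpec`.

    Each genome interval between recombination breakpoints gets an
    independent binary coalescent tree over the same sample nodes, and
    each site receives one to three mutations: always one non-silent
    mutation, optionally a stacked mutation below it (a potential back or
    recurrent mutation) and/or an independent mutation elsewhere in the
    tree.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_individuals * spec.ploidy
    tc = tskit.TableCollection(sequence_length=1.0)
    for _ in range(spec.n_individuals):
        tc.individuals.add_row()
    samples = [
        tc.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0, individual=i // spec.ploidy)
        for i in range(n_samples)
    ]

    bounds = [0.0, *sorted(spec.recombination_breakpoints), 1.0]
    intervals = list(zip(bounds[:-1], bounds[1:]))
    parents = [
        _coalesce(tc, samples, left, right, rng) for left, right in intervals
    ]

    def branch_time(node, upper=None):
        # a time strictly inside the branch above `node`
        lo = tc.nodes[node].time
        hi = tc.nodes[parent[node]].time if upper is None else upper
        return rng.uniform(lo, hi)

    positions = np.sort(
        rng.choice(np.arange(1, 1000) / 1000.0, size=spec.n_sites, replace=False)
    )
    for pos in positions:
        idx = next(i for i, (l, r) in enumerate(intervals) if l <= pos < r)
        parent = parents[idx]
        nodes_here = list(parent)  # every non-root node of this local tree
        ancestral = _ALPHABET[rng.integers(4)]
        site = tc.sites.add_row(position=pos, ancestral_state=ancestral)

        first = nodes_here[rng.integers(len(nodes_here))]
        t_first = branch_time(first)
        derived = str(rng.choice([a for a in _ALPHABET if a != ancestral]))
        tc.mutations.add_row(site=site, node=first, derived_state=derived, time=t_first)
        if rng.random() < 0.4:
            # stacked mutation at or below the first one: a potential back
            # mutation (to the ancestral state) or recurrent mutation
            below = _subtree(parent, first)
            stacked = below[rng.integers(len(below))]
            t = branch_time(stacked, upper=t_first if stacked == first else None)
            tc.mutations.add_row(
                site=site,
                node=stacked,
                derived_state=_ALPHABET[rng.integers(4)],
                time=t,
            )
        if rng.random() < 0.2:
            other = nodes_here[rng.integers(len(nodes_here))]
            t = branch_time(other, upper=t_first if other == first else None)
            tc.mutations.add_row(
                site=site, node=other, derived_state=_ALPHABET[rng.integers(4)], time=t
            )

    tc.sort()
    tc.build_index()
    tc.compute_mutation_parents()
    return tc.tree_sequence()


def export_tables(ts, directory):
    """Write ``ts`` as the plain-text table dump readable by ``load_arg``."""
    arg_core.write_tables_dir(ts, directory)
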