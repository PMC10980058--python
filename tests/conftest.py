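import numpy as np
import pytest
import tskit

from argtrait.fixtures import FixtureSpec, fig1_fixture, random_arg


@pytest.fixture(scope="session")
def fig1():
    return fig1_fixture()


@pytest.fixture
def fixed_model():
    import argtrait

    return argtrait.trait_model("fixed", value=0.05)


def make_random_arg(seed, max_individuals=25, max_sites=20, with_recomb=None):
    """A small random ARG, its shape drawn deterministically from seed."""
    rng = np.random.default_rng(seed)
    if with_recomb is None:
        with_recomb = seed % 3 == 0
    spec = FixtureSpec(
        n_individuals=int(rng.integers(2, max_individuals + 1)),
        ploidy=2,
        n_sites=int(rng.integers(1, max_sites + 1)),
        recombination_breakpoints=(0.5,) if with_recomb else (),
        seed=seed,
    )
    return random_arg(spec)


def single_node_arg():
    """Degenerate ARG: one sample node, one individual, no edges."""
    tc = tskit.TableCollection(sequence_length=1.0)
    tc.individuals.add_row()
    tc.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0, individual=0)
    return tc.tree_sequence()


def two_tree_arg():
    """Hand-built two-tree ARG with a recombination breakpoint at 0.5.

    Samples 0..3 (two diploids).  Left tree: (0,(1,(2,3))); right tree:
    (((0,1),2),3) with distinct internal nodes, so the parent maps at
    positions 0.4 and 0.6 differ.
    """
    tc = tskit.TableCollection(sequence_length=1.0)
    for _ in range(2):
        tc.individuals.add_row()
    for i in range(4):
        tc.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0, individual=i // 2)
    for t in (1.0, 2.0, 3.0, 1.5, 2.5, 3.5):  # nodes 4..9
        tc.nodes.add_row(time=t)
    left_edges = [(4, 2), (4, 3), (5, 1), (5, 4), (6, 0), (6, 5)]
    right_edges = [(7, 0), (7, 1), (8, 7), (8, 2), (9, 8), (9, 3)]
    for p, c in left_edges:
        tc.edges.add_row(left=0.0, right=0.5, parent=p, child=c)
    for p, c in right_edges:
        tc.edges.add_row(left=0.5, right=1.0, parent=p, child=c)
    tc.sort()
    return tc.tree_sequence()


def stacked_chain_arg():
    """Single lineage with three stacked mutations A->T->G->T at one site.

    Chain 3 -> 2 -> 1 -> 0 where only node 0 is a sample; mutations sit on
    nodes 2 (T), 1 (G) and 0 (T), so the sample below all three carries T.
    """
    tc = tskit.TableCollection(sequence_length=1.0)
    tc.individuals.add_row()
    tc.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0, individual=0)
    for t in (1.0, 2.0, 3.0):
        tc.nodes.add_row(time=t)
    # a second sample keeps the ancestral state observable
    other = tc.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0.0, individual=0)
    tc.edges.add_row(left=0.0, right=1.0, parent=1, child=0)
    tc.edges.add_row(left=0.0, right=1.0, parent=2, child=1)
    tc.edges.add_row(left=0.0, right=1.0, parent=3, child=2)
    tc.edges.add_row(left=0.0, right=1.0, parent=3, child=other)
    tc.sites.add_row(position=0.5, ancestral_state="A")
    tc.mutations.add_row(site=0, node=2, derived_state="T", time=2.5)
    tc.mutations.add_row(site=0, node=1, derived_state="G", time=1.5)
    tc.mutations.add_row(site=0, node=0, derived_state="T", time=0.5)
    tc.sort()
    tc.build_index()
    tc.compute_mutation_parents()
    return tc.tree_sequence()
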