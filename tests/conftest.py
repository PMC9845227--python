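"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's pruning/message-passing
code paths: they enumerate every joint assignment of states to nodes
and sum (or minimize) directly, so they stay valid checks of the fast
implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from paleoasr import MkModel, Node, Tree, code_alternate, code_preferred, make_study_fixture
from paleoasr.coding import ALL_STATES, CharacterCoding


# ---------------------------------------------------------------------------
# Random tree / coding generators (seeded)
# ---------------------------------------------------------------------------

def random_tree(rng: np.random.Generator, n_tips: int, min_len=0.1, max_len=3.0) -> Tree:
    """Random rooted topology (with occasional polytomies) + random lengths."""
    tips = [Node(label=f"T{i}", length=float(rng.uniform(min_len, max_len)))
            for i in range(n_tips)]
    pool = tips[:]
    while len(pool) > 1:
        k = 3 if (len(pool) >= 3 and rng.uniform() < 0.2) else 2
        parent = Node(length=float(rng.uniform(min_len, max_len)))
        for _ in range(k):
            parent.add_child(pool.pop(int(rng.integers(len(pool)))))
        pool.append(parent)
    root = pool[0]
    root.length = None
    return Tree(root)


def random_coding(rng: np.random.Generator, tree: Tree, k: int = 3,
                  max_ambiguous: int = 2) -> CharacterCoding:
    """Singleton states at most tips; up to ``max_ambiguous`` ambiguous tips."""
    labels = tree.leaf_labels()
    states = {}
    ambiguous_slots = rng.choice(len(labels), size=min(max_ambiguous, len(labels)),
                                 replace=False)
    for i, lab in enumerate(labels):
        if i in ambiguous_slots and rng.uniform() < 0.7:
            if rng.uniform() < 0.5:
                states[lab] = ALL_STATES
            else:
                pair = rng.choice(k, size=2, replace=False)
                states[lab] = frozenset(int(s) for s in pair)
        else:
            states[lab] = frozenset({int(rng.integers(k))})
    return CharacterCoding(states)


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracles
# ---------------------------------------------------------------------------

def enumerate_loglik(tree: Tree, coding: CharacterCoding, model: MkModel) -> float:
    """Σ over all joint node-state assignments of prior × Π branch probs."""
    nodes = list(tree.postorder())
    allowed = [sorted(coding[n.label]) if n.is_leaf else list(range(model.k))
               for n in nodes]
    prior = model.prior_vector()
    P = {n.id: model.transition_matrix(n.length) for n in nodes if n.parent is not None}
    idx = {n.id: i for i, n in enumerate(nodes)}
    total = 0.0
    for assign in itertools.product(*allowed):
        p = prior[assign[idx[tree.root.id]]]
        for n in nodes:
            if n.parent is not None:
                p *= P[n.id][assign[idx[n.parent.id]], assign[idx[n.id]]]
        total += p
    return math.log(total)


def enumerate_marginals(tree: Tree, coding: CharacterCoding, model: MkModel):
    """Exact per-node posteriors by brute-force joint enumeration."""
    nodes = list(tree.postorder())
    allowed = [sorted(coding[n.label]) if n.is_leaf else list(range(model.k))
               for n in nodes]
    prior = model.prior_vector()
    P = {n.id: model.transition_matrix(n.length) for n in nodes if n.parent is not None}
    idx = {n.id: i for i, n in enumerate(nodes)}
    post = {n.id: np.zeros(model.k) for n in nodes}
    for assign in itertools.product(*allowed):
        p = prior[assign[idx[tree.root.id]]]
        for n in nodes:
            if n.parent is not None:
                p *= P[n.id][assign[idx[n.parent.id]], assign[idx[n.id]]]
        for n in nodes:
            post[n.id][assign[idx[n.id]]] += p
    return {nid: v / v.sum() for nid, v in post.items()}


def enumerate_sankoff(tree: Tree, coding: CharacterCoding, k: int = 3):
    """Minimum changes and per-node MPR sets by enumerating labelings."""
    nodes = list(tree.postorder())
    allowed = [sorted(coding[n.label]) if n.is_leaf else list(range(k)) for n in nodes]
    idx = {n.id: i for i, n in enumerate(nodes)}
    best = math.inf
    mpr = {n.id: set() for n in nodes}
    for assign in itertools.product(*allowed):
        cost = sum(
            1
            for n in nodes
            if n.parent is not None and assign[idx[n.id]] != assign[idx[n.parent.id]]
        )
        if cost < best:
            best = cost
            mpr = {n.id: {assign[idx[n.id]]} for n in nodes}
        elif cost == best:
            for n in nodes:
                mpr[n.id].add(assign[idx[n.id]])
    return int(best), {nid: frozenset(s) for nid, s in mpr.items()}


# ---------------------------------------------------------------------------
# Study fixture (expensive pieces shared across the session)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def study_fixture():
    return make_study_fixture()


@pytest.fixture(scope="session")
def fixture_trees(study_fixture):
    from paleoasr import parse_newick, timescale_tree, unit_branch_lengths

    supertree = parse_newick(study_fixture.supertree_newick)
    return {
        "supertree": supertree,
        "timescaled": timescale_tree(supertree, study_fixture.ranges),
        "unit": unit_branch_lengths(supertree),
    }


@pytest.fixture(scope="session")
def fixture_codings(study_fixture):
    return {
        "preferred": code_preferred(study_fixture.evidence),
        "alternate": code_alternate(study_fixture.evidence),
    }
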