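"""Naive reference implementations by exhaustive enumeration.

Everything here recomputes quantities that the main code obtains by pruning
(dynamic programming) through direct summation over all internal-node state
assignments: the full joint tensor over internal states is materialised and
then summed, with no message passing.  Exponential in the number of internal
nodes, so usable only on small trees — which is exactly their purpose:
independent validation of the pruning and marginal-reconstruction code, and
exact null expectations for the convergence scan on tiny configurations.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping

import numpy as np

from .phylo_model import SubstitutionModel
from .seqio import Msa, PhyloTree


def _joint_internal_tensor(
    tree: PhyloTree,
    column: Mapping[str, str],
    model: SubstitutionModel,
) -> tuple[np.ndarray, dict[int, int]]:
    """Unnormalised joint over internal-node states given the tip pattern.

    Axis ``axis_of[node.index]`` of the returned tensor indexes the state of
    that internal node; the tensor entry is
    pi(root) * prod(branch transition factors) * prod(tip factors).
    """
    internals = [n for n in tree.nodes if not n.is_leaf]
    axis_of = {n.index: i for i, n in enumerate(internals)}
    k, m = model.n_states, len(internals)

    def expand1(vec: np.ndarray, ax: int) -> np.ndarray:
        shape = [1] * m
        shape[ax] = k
        return vec.reshape(shape)

    def expand2(mat: np.ndarray, ax_row: int, ax_col: int) -> np.ndarray:
        if ax_row > ax_col:
            return expand2(mat.T, ax_col, ax_row)
        shape = [1] * m
        shape[ax_row] = k
        shape[ax_col] = k
        return mat.reshape(shape)

    joint = expand1(model.pi, axis_of[tree.root.index]).astype(float).copy()
    joint = np.broadcast_to(joint, [k] * m).copy()
    for node in tree.nodes:
        if node is tree.root:
            continue
        P = model.transition_matrix(node.length)
        pax = axis_of[node.parent.index]
        if node.is_leaf:
            # tip marginalised: message to the parent, indexed by parent state
            joint *= expand1(P @ model.encode(column[node.name]), pax)
        else:
            joint *= expand2(P, pax, axis_of[node.index])
    return joint, axis_of


def enumerate_site_likelihood(
    tree: PhyloTree,
    column: Mapping[str, str],
    model: SubstitutionModel,
) -> float:
    """Site likelihood as an explicit sum over internal-node assignments."""
    joint, _ = _joint_internal_tensor(tree, column, model)
    return float(joint.sum())


def enumerate_posteriors(
    tree: PhyloTree,
    column: Mapping[str, str],
    model: SubstitutionModel,
) -> dict[int, np.ndarray]:
    """Exact marginal posterior per internal node, from the joint tensor."""
    joint, axis_of = _joint_internal_tensor(tree, column, model)
    total = joint.sum()
    out = {}
    for idx, ax in axis_of.items():
        other = tuple(a for a in range(joint.ndim) if a != ax)
        out[idx] = joint.sum(axis=other) / total
    return out


def pattern_probabilities(
    tree: PhyloTree,
    model: SubstitutionModel,
) -> Iterable[tuple[dict[str, str], float]]:
    """All tip patterns with their probabilities (exhaustive; tiny trees only)."""
    labels = tree.leaf_labels
    for combo in product(model.alphabet, repeat=len(labels)):
        column = dict(zip(labels, combo))
        yield column, enumerate_site_likelihood(tree, column, model)


def exact_expected_convergent_sites(
    tree: PhyloTree,
    model: SubstitutionModel,
    foreground: Iterable[str],
    n_sites: int,
    **scan_kwargs,
) -> float:
    """Exact per-alignment expectation of the convergence-scan site count.

    Sums, over every possible tip pattern, the pattern probability times the
    number of records the scan emits for that single-column alignment (the
    reconstruction is deterministic given the pattern); multiplying by
    ``n_sites`` uses the independence of sites under the simulator.
    """
    from .convergence import scan_identical
    from .phylo_model import marginal_asr

    fg = list(foreground)
    expected = 0.0
    for column, prob in pattern_probabilities(tree, model):
        if prob == 0.0:
            continue
        msa = Msa([(label, column[label]) for label in tree.leaf_labels])
        asr = marginal_asr(tree, msa, model)
        records = scan_identical(tree, asr, msa, fg, **scan_kwargs)
        if records:
            expected += prob * len(records)
    return expected * n_sites
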