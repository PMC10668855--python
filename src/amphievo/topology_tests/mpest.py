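"""Rooted-triplet pseudo-likelihood species-tree estimation (MP-EST style).

For every taxon triplet, the frequencies of the three rooted topologies
across gene trees are scored by a multinomial whose concordant-topology
probability is 1 - (2/3)exp(-t), t being the internal path length (in
coalescent units) separating the triplet's two coalescences on the species
tree. Internal branch lengths are optimized numerically; branch lengths are
capped (default 10) because a fully concordant triplet pushes t to
infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

T_CAP = 10.0


def _pair_mrca_depths(tree) -> dict[frozenset, tuple[int, int]]:
    """For each leaf pair: (mrca postorder id, mrca depth in edges)."""
    depth = {}
    for node in tree.preorder():
        depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1
    below: dict[int, set] = {}
    out = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.name}
            continue
        sets = [below[id(c)] for c in node.children]
        for sa, sb in combinations(sets, 2):
            for a in sa:
                for b in sb:
                    out[frozenset((a, b))] = (id(node), depth[id(node)])
        below[id(node)] = set().union(*sets)
    return out


def triplet_topology(tree, triple: tuple[str, str, str]) -> frozenset | None:
    """The cherry pair of a rooted triplet: the pair with the deepest MRCA."""
    pm = _pair_mrca_depths(tree)
    a, b, c = triple
    pairs = [frozenset((a, b)), frozenset((a, c)), frozenset((b, c))]
    depths = [pm[p][1] for p in pairs]
    best = max(depths)
    winners = [p for p, d in zip(pairs, depths) if d == best]
    if len(winners) != 1:
        return None  # unresolved
    return winners[0]


def triplet_counts(gene_trees: list, taxa: list[str] | None = None):
    """Counts of each cherry pair per triplet across rooted gene trees."""
    if taxa is None:
        taxa = sorted(gene_trees[0].leaf_names())
    counts: dict[tuple, dict[frozenset, int]] = {}
    for triple in combinations(sorted(taxa), 3):
        counts[triple] = {
            frozenset((triple[0], triple[1])): 0,
            frozenset((triple[0], triple[2])): 0,
            frozenset((triple[1], triple[2])): 0,
        }
    for gt in gene_trees:
        if len(gt.root.children) != 2:
            raise ValueError("gene trees must be rooted (supply an outgroup)")
        pm = _pair_mrca_depths(gt)
        present = set(gt.leaf_names())
        for triple in counts:
            if not set(triple) <= present:
                continue
            pairs = list(counts[triple])
            depths = [pm[p][1] for p in pairs]
            best = max(depths)
            winners = [p for p, d in zip(pairs, depths) if d == best]
            if len(winners) == 1:
                counts[triple][winners[0]] += 1
    return counts


@dataclass
class MpestResult:
    pseudo_loglik: float
    branch_lengths: dict[frozenset, float]  # keyed by the clade below the branch
    species_tree: object
    capped: list[frozenset]


def _internal_branches(tree):
    return [
        n
        for n in tree.postorder()
        if n.parent is not None and not n.is_leaf
    ]


def _triplet_paths(tree, taxa):
    """Map each triplet to (cherry pair, indices of internal branches whose
    lengths sum to the separating path t)."""
    internals = _internal_branches(tree)
    node_to_idx = {id(n): i for i, n in enumerate(internals)}
    pm = _pair_mrca_depths(tree)
    nodes_by_id = {id(n): n for n in tree.postorder()}
    out = {}
    for triple in combinations(sorted(taxa), 3):
        a, b, c = triple
        pairs = [frozenset((a, b)), frozenset((a, c)), frozenset((b, c))]
        depths = [pm[p][1] for p in pairs]
        best = max(depths)
        winners = [p for p, d in zip(pairs, depths) if d == best]
        if len(winners) != 1:
            raise ValueError("species topology must be fully resolved")
        cherry = winners[0]
        deep_id = pm[cherry][0]
        # triple MRCA: the common MRCA of the two non-cherry pairs
        other = [p for p in pairs if p is not cherry][0]
        top_id = pm[other][0]
        # walk from the deep MRCA up to the triple MRCA collecting internal branches
        node = nodes_by_id[deep_id]
        idxs = []
        while id(node) != top_id:
            if id(node) in node_to_idx:
                idxs.append(node_to_idx[id(node)])
            node = node.parent
        out[triple] = (cherry, idxs)
    return out


def mpest_fit(gene_trees: list, species_topology, t_cap: float = T_CAP) -> MpestResult:
    """Maximum pseudo-likelihood internal branch lengths for a fixed rooted
    species topology, from rooted gene-tree triplet frequencies."""
    taxa = sorted(species_topology.leaf_names())
    counts = triplet_counts(gene_trees, taxa)
    tree = species_topology.copy()
    internals = _internal_branches(tree)
    paths = _triplet_paths(tree, taxa)

    triples = list(paths)
    n_conc = np.array([counts[t][paths[t][0]] for t in triples], dtype=float)
    n_disc = np.array(
        [sum(counts[t].values()) - counts[t][paths[t][0]] for t in triples], dtype=float
    )
    # design matrix: t_triple = A @ branch_lengths
    A = np.zeros((len(triples), len(internals)))
    for i, t in enumerate(triples):
        for j in paths[t][1]:
            A[i, j] = 1.0

    def nll(x):
        t = A @ x
        e = np.exp(-t)
        p_conc = np.clip(1 - (2.0 / 3.0) * e, 1e-12, 1.0)
        p_disc = np.clip(e / 3.0, 1e-12, 1.0)
        return -float(np.sum(n_conc * np.log(p_conc) + n_disc * np.log(p_disc)))

    x0 = np.full(len(internals), 0.5)
    res = minimize(
        nll, x0, method="L-BFGS-B",
        bounds=[(1e-6, t_cap)] * len(internals),
        options={"maxiter": 500, "ftol": 1e-12},
    )
    lengths = {}
    capped = []
    for node, val in zip(internals, res.x):
        key = frozenset(tree.leafset_below(node))
        lengths[key] = float(val)
        node.length = float(val)
        if val >= t_cap - 1e-6:
            capped.append(key)
    return MpestResult(
        pseudo_loglik=-res.fun,
        branch_lengths=lengths,
        species_tree=tree,
        capped=capped,
    )


def triplet_probability(t: float) -> tuple[float, float]:
    """(concordant, each-discordant) rooted-triplet probabilities at internal
    branch length t coalescent units."""
    e = np.exp(-t)
    return 1 - (2.0 / 3.0) * e, e / 3.0
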