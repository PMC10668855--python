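"""Genes-as-characters supertree estimation by step-matrix (Sankoff) parsimony.

Each gene tree contributes a single multistate character: every taxon's
state is its own tip, and the step matrix is the matrix of nodal
(edge-count) distances between tips in that gene tree. Candidate species
topologies are scored by Sankoff dynamic programming summed over genes, all
characters weighted equally. Search is exhaustive for small taxon sets and
NNI hill-climbing from a majority-rule start otherwise; ties are broken by
lexicographic Newick order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from amphievo.core.tree import Node, Tree, enumerate_unrooted_topologies

_INF = 1e18


def nodal_distance_matrix(tree: Tree, taxa: list[str]) -> np.ndarray:
    """Pairwise edge-count distances between tips, on the unrooted shape
    (a degree-2 root is suppressed)."""
    n = len(taxa)
    dist = np.zeros((n, n))
    depth = {}
    for node in tree.preorder():
        depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1
    leaves = {leaf.name: leaf for leaf in tree.leaves()}
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            b = taxa[j]
            na, nb = leaves[a], leaves[b]
            # walk up to common ancestor
            pa, pb = na, nb
            seen = set()
            while pa is not None:
                seen.add(id(pa))
                pa = pa.parent
            anc = nb
            while id(anc) not in seen:
                anc = anc.parent
            d = (depth[id(na)] - depth[id(anc)]) + (depth[id(nb)] - depth[id(anc)])
            if anc is tree.root and len(tree.root.children) == 2:
                d -= 1
            dist[i, j] = dist[j, i] = d
    return dist


def sankoff_score(topology: Tree, step: np.ndarray, taxa: list[str]) -> float:
    """Minimum total cost of one step-matrix character on a topology."""
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    cost: dict[int, np.ndarray] = {}
    for node in topology.postorder():
        if node.is_leaf:
            v = np.full(n, _INF)
            v[index[node.name]] = 0.0
            cost[node.index] = v
        else:
            acc = np.zeros(n)
            for child in node.children:
                acc = acc + np.min(step + cost[child.index][None, :], axis=1)
            cost[node.index] = acc
    return float(cost[topology.root.index].min())


@dataclass
class GACResult:
    tree: Tree
    score: float
    bootstrap_support: dict[frozenset, float] | None = None


def _score_topology(topology: Tree, steps: list[np.ndarray], taxa: list[str]) -> float:
    return sum(sankoff_score(topology, s, taxa) for s in steps)


def _nni_neighbors(tree: Tree) -> list[Tree]:
    """NNI rearrangements around internal edges of a (rooted representation
    of an) unrooted tree."""
    out = []
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        parent = node.parent
        siblings = [c for c in parent.children if c is not node]
        if not siblings:
            continue
        sib = siblings[0]
        for child in list(node.children):
            out.append(_swap_subtrees(tree, child, sib))
    return [t for t in out if t is not None]


def _swap_subtrees(tree: Tree, a: Node, b: Node) -> Tree | None:
    if a.parent is None or b.parent is None:
        return None
    t = tree.copy()
    # locate the copies by the path of child indices from the root
    def path(node: Node):
        p = []
        while node.parent is not None:
            p.append(node.parent.children.index(node))
            node = node.parent
        return list(reversed(p))

    def follow(root: Node, p):
        for i in p:
            root = root.children[i]
        return root

    ca, cb = follow(t.root, path(a)), follow(t.root, path(b))
    pa, pb = ca.parent, cb.parent
    ia, ib = pa.children.index(ca), pb.children.index(cb)
    pa.children[ia], pb.children[ib] = cb, ca
    ca.parent, cb.parent = pb, pa
    return Tree(t.root)


def majority_rule_start(gene_trees: list[Tree], taxa: list[str]) -> Tree:
    """Greedy consensus: most frequent compatible bipartitions, resolved
    arbitrarily to a binary tree by sequential grouping."""
    from collections import Counter

    counts: Counter = Counter()
    for gt in gene_trees:
        for bip in gt.bipartitions():
            counts[bip] += 1
    chosen: list[frozenset] = []

    def compatible(b, existing):
        full = set(taxa)
        for e in existing:
            for x, y in ((b, e), (b, full - e)):
                if not (x <= y or y <= x or not (x & y)):
                    return False
        return True

    for bip, _ in counts.most_common():
        if compatible(bip, chosen):
            chosen.append(bip)
    # build from compatible clusters greedily (rooted at taxa[0] side)
    root = Node()
    nodes = {frozenset([t]): Node(t, 1.0) for t in taxa}
    clusters = sorted(chosen, key=len)
    for cl in clusters:
        members = [c for c in list(nodes) if c <= cl]
        # keep only maximal disjoint members
        members = [m for m in members if not any(m < other for other in members)]
        if len(members) < 2:
            continue
        parent = Node(None, 1.0)
        for m in members:
            parent.add_child(nodes.pop(m))
        nodes[cl] = parent
    for node in nodes.values():
        root.add_child(node)
    return Tree(root)


def gac_supertree(
    gene_trees: list[Tree],
    search: str = "auto",
    n_bootstrap: int = 0,
    seed: int = 0,
) -> GACResult:
    """Estimate a species tree from gene trees by GAC step-matrix parsimony."""
    taxon_sets = [set(t.leaf_names()) for t in gene_trees]
    shared = sorted(set.intersection(*taxon_sets)) if taxon_sets else []
    if len(shared) < 3:
        raise ValueError("fewer than 3 taxa shared across gene trees")
    steps = [nodal_distance_matrix(t, shared) for t in gene_trees]

    def best_tree(step_list) -> tuple[Tree, float]:
        if search == "exhaustive" or (search == "auto" and len(shared) <= 7):
            candidates = enumerate_unrooted_topologies(shared)
            scored = [
                (_score_topology(c, step_list, shared), c.to_newick(lengths=False), c)
                for c in candidates
            ]
            scored.sort(key=lambda x: (x[0], x[1]))
            return scored[0][2], scored[0][0]
        current = majority_rule_start(gene_trees, shared)
        cur_score = _score_topology(current, step_list, shared)
        improved = True
        while improved:
            improved = False
            neighbors = _nni_neighbors(current)
            scored = [
                (_score_topology(nb, step_list, shared), nb.to_newick(lengths=False), nb)
                for nb in neighbors
            ]
            scored.sort(key=lambda x: (x[0], x[1]))
            if scored and scored[0][0] < cur_score - 1e-9:
                cur_score, _, current = scored[0]
                improved = True
        return current, cur_score

    tree, score = best_tree(steps)
    support = None
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        target = tree.bipartitions()
        hits = {b: 0 for b in target}
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(steps), size=len(steps))
            bt, _ = best_tree([steps[i] for i in idx])
            found = bt.bipartitions()
            for b in target:
                if b in found:
                    hits[b] += 1
        support = {b: hits[b] / n_bootstrap for b in target}
    return GACResult(tree=tree, score=score, bootstrap_support=support)
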