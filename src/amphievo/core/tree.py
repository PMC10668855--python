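"""Rooted trees with branch lengths and per-branch class labels.

Newick parsing is delegated to dendropy; the internal structure is a plain
parent/child node graph convenient for pruning algorithms. Branch attributes
(length, class label, omega) live on the child node of the branch.
"""

from __future__ import annotations

import itertools

import dendropy


class Node:
    __slots__ = ("name", "length", "children", "parent", "cls", "index")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.cls: str | None = None  # branch-class label (branch above node)
        self.index: int = -1

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name or self.index}>"


class Tree:
    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    # ------------------------------------------------------------- structure
    def _reindex(self):
        """Assign postorder indices: leaves first is NOT guaranteed; the
        root always gets the last index."""
        for i, node in enumerate(self.postorder()):
            node.index = i

    def postorder(self) -> list[Node]:
        out, stack = [], [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen:
                out.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        return out

    def preorder(self) -> list[Node]:
        return list(reversed(self.postorder()))

    def nodes(self) -> list[Node]:
        return self.postorder()

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[Node]:
        """All non-root nodes; each carries its parent branch."""
        return [n for n in self.postorder() if n.parent is not None]

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def mrca(self, names: list[str]) -> Node:
        targets = set(names)
        below: dict[Node, set] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name} if node.name in targets else set()
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if below[node] == targets:
                return node
        raise ValueError(f"taxa {sorted(targets)} not all present")

    def leafset_below(self, node: Node) -> frozenset:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def total_length(self) -> float:
        return sum(n.length for n in self.branches())

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.cls = node.cls
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root))

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions (as the smaller-side frozenset,
        canonicalized against the full leaf set)."""
        all_leaves = frozenset(self.leaf_names())
        out = set()
        for node in self.postorder():
            if node.parent is None or node.is_leaf:
                continue
            side = self.leafset_below(node)
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
        return out

    def unrooted_copy(self) -> "Tree":
        """Copy with a degree-2 root collapsed to a multifurcation.

        Reversible-model likelihoods depend only on the unrooted tree; a
        bifurcating root splits one edge into two separately parameterized
        halves (a likelihood ridge, and spurious freedom when the halves
        carry different branch classes), so fits should collapse it. The
        merged edge keeps the minority class of the two halves (the
        foreground/stem label in practice); ties go to the first child.
        2-taxon trees are returned unchanged.
        """
        t = self.copy()
        root = t.root
        if len(root.children) != 2:
            return t
        u, v = root.children
        if u.is_leaf and v.is_leaf:
            return t
        absorb, other = (u, v) if not u.is_leaf else (v, u)
        other.length += absorb.length
        if other.cls != absorb.cls:
            from collections import Counter

            counts = Counter(b.cls for b in t.branches())
            first = u.cls  # tie-break: class of the first-listed child
            other.cls = min(
                (absorb.cls, other.cls),
                key=lambda c: (counts.get(c, 0), c != first),
            )
        new_root = Node(absorb.name, 0.0)
        for child in list(absorb.children):
            new_root.add_child(child)
        new_root.add_child(other)
        return Tree(new_root)

    # ----------------------------------------------------------------- labels
    def set_branch_classes(
        self,
        class_map: dict[str, list[str]],
        default: str = "background",
        include_stem: bool = True,
    ) -> None:
        """Label branches by clade membership.

        ``class_map`` maps a class label to the leaf names of a clade; every
        branch inside the clade (and its stem, if ``include_stem``) receives
        the label. Unlisted branches get ``default``.
        """
        for node in self.branches():
            node.cls = default
        for label, taxa in class_map.items():
            missing = set(taxa) - set(self.leaf_names())
            if missing:
                raise ValueError(f"class {label!r}: unknown taxa {sorted(missing)}")
            if len(taxa) == 1:
                self.find(taxa[0]).cls = label
                continue
            top = self.mrca(list(taxa))
            stack = list(top.children)
            while stack:
                n = stack.pop()
                n.cls = label
                stack.extend(n.children)
            if include_stem and top.parent is not None:
                top.cls = label

    # --------------------------------------------------------------------- IO
    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                base = node.name or ""
            else:
                base = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    base += node.name
            if lengths and node.parent is not None:
                base += f":{node.length:.10g}"
            return base

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(label, dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dt.seed_node))

    def __repr__(self):  # pragma: no cover
        return f"<Tree {self.to_newick(lengths=False)}>"


# ------------------------------------------------------------------ builders
def star_tree(names: list[str], length: float = 0.1) -> Tree:
    root = Node()
    for name in names:
        root.add_child(Node(name, length))
    return Tree(root)


def enumerate_unrooted_topologies(taxa: list[str]) -> list[Tree]:
    """All distinct unrooted binary topologies, represented as trees rooted
    at the first taxon's incident node. Feasible for <= 8 taxa."""
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")

    def build(current: list[tuple], remaining: list[str]):
        if not remaining:
            yield current
            return
        taxon = remaining[0]
        for i in range(len(current)):
            augmented = current[:i] + [(current[i], taxon)] + current[i + 1 :]
            yield from build(augmented, remaining[1:])

    def edges(struct):
        """Flatten nested tuples into an explicit node structure."""
        def make(obj) -> Node:
            if isinstance(obj, str):
                return Node(obj, 1.0)
            node = Node(None, 1.0)
            node.add_child(make(obj[0]))
            node.add_child(make(obj[1]))
            return node
        return make(struct)

    # unrooted tree on 3 taxa = single internal node; grow by edge insertion
    # represented as a "rooted at trifurcation" structure
    first = [taxa[0], taxa[1], taxa[2]]

    def grow(structs, remaining):
        if not remaining:
            yield structs
            return
        taxon = remaining[0]
        # attach to any edge: edges correspond to any element position in the
        # nested-tuple forest, recursively
        def positions(obj, path):
            yield path
            if not isinstance(obj, str):
                yield from positions(obj[0], path + (0,))
                yield from positions(obj[1], path + (1,))

        for i, top in enumerate(structs):
            for path in positions(top, ()):
                new_top = _attach(top, path, taxon)
                yield from grow(structs[:i] + [new_top] + structs[i + 1 :], remaining[1:])

    def _attach(obj, path, taxon):
        if not path:
            return (obj, taxon)
        a, b = obj
        if path[0] == 0:
            return (_attach(a, path[1:], taxon), b)
        return (a, _attach(b, path[1:], taxon))

    out = []
    for structs in grow(first, taxa[3:]):
        root = Node()
        for s in structs:
            root.add_child(edges(s))
        out.append(Tree(root))
    return out


def random_resolved_tree(taxa: list[str], rng, branch_length: float = 0.1) -> Tree:
    """A random rooted binary topology via sequential random joins."""
    nodes = [Node(t, branch_length) for t in taxa]
    order = rng.permutation(len(nodes))
    pool = [nodes[i] for i in order]
    while len(pool) > 1:
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        parent = Node(None, branch_length)
        parent.add_child(a)
        parent.add_child(b)
        pool = [n for k, n in enumerate(pool) if k not in (i, j)] + [parent]
    pool[0].length = 0.0
    return Tree(pool[0])
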