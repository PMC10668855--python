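"""Sequence and gene-tree simulators.

Codon alignments evolve under the GY94-type matrix of
:mod:`amphievo.codon_selection`; protein alignments under the bundled JTT
model with discrete-gamma site rates; gene trees under the multispecies
coalescent. All generators are pure functions of their inputs and a seed:
the root seed spawns one child stream per gene by counter, so reduced runs
reproduce prefixes of larger ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from amphievo.core import codes
from amphievo.core.alignment import Alignment
from amphievo.core.models import discrete_gamma, empirical_aa_model
from amphievo.core.pruning import simulate_states
from amphievo.core.tree import Node, Tree
from amphievo.codon_selection.model import codon_model, uniform_codon_frequencies


@dataclass
class PlantedChange:
    """A deterministic substitution planted at a site on named branches."""

    site: int  # 0-based column
    branches: list[str]  # node names; the change applies to the subtree below
    ancestral: str
    derived: str


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 1
    n_sites: int = 300  # codons or residues
    kappa: float = 2.0
    pi: np.ndarray | None = None  # 61 codon frequencies
    omega: dict[str, float] | float = 0.2  # per branch class
    alpha: float = 1.0
    k: int = 4
    missing_fraction: float = 0.0
    bias_taxa: list[str] = field(default_factory=list)
    gc_shift: float = 0.0
    planted: list[PlantedChange] = field(default_factory=list)

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing fraction must be in [0, 1)")
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float)
            if abs(self.pi.sum() - 1.0) > 1e-12:
                raise ValueError("pi must sum to 1 within 1e-12")


def gene_seeds(root_seed: int, n_genes: int) -> list[np.random.Generator]:
    """Per-gene derived streams (counter-indexed children of the root seed)."""
    ss = np.random.SeedSequence(root_seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_genes)]


def _branch_omega(tree: Tree, omega) -> dict[int, float]:
    out = {}
    for b in tree.branches():
        if isinstance(omega, dict):
            if b.cls not in omega:
                raise ValueError(
                    f"branch above {b.name or f'node{b.index}'} has class "
                    f"{b.cls!r} with no omega defined"
                )
            out[b.index] = float(omega[b.cls])
        else:
            out[b.index] = float(omega)
    return out


def simulate_codon_alignment(tree: Tree, cfg: SimConfig, rng=None) -> Alignment:
    """Evolve sense codons from a root draw along the tree."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    pi = cfg.pi if cfg.pi is not None else uniform_codon_frequencies()
    omegas = _branch_omega(tree, cfg.omega)
    models = {w: codon_model(cfg.kappa, w, pi) for w in set(omegas.values())}
    pmats = {
        b.index: models[omegas[b.index]].transition_matrix(b.length)
        for b in tree.branches()
    }
    states = simulate_states(tree, pmats, pi, cfg.n_sites, rng)
    taxa = tree.leaf_names()
    rows = []
    for leaf in tree.leaves():
        seq = "".join(codes.SENSE_CODONS[s] for s in states[leaf.index])
        rows.append(list(seq))
    return Alignment(taxa, np.array(rows, dtype="<U1"), "CODON61")


def simulate_protein_alignment(tree: Tree, cfg: SimConfig, rng=None) -> Alignment:
    """JTT+Gamma(k) amino-acid simulation with optional planted changes.

    Site rates are drawn from the k discrete gamma categories; planted
    parallel substitutions overwrite their column deterministically: every
    taxon gets the ancestral residue, and leaves below each named branch get
    the derived residue.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    model = empirical_aa_model()
    cat_rates = discrete_gamma(cfg.alpha, cfg.k)
    site_cats = rng.integers(0, cfg.k, size=cfg.n_sites)
    # simulate per category and interleave
    taxa = tree.leaf_names()
    out = np.empty((len(taxa), cfg.n_sites), dtype=np.int64)
    leaf_order = {leaf.name: i for i, leaf in enumerate(tree.leaves())}
    for c in range(cfg.k):
        cols = np.nonzero(site_cats == c)[0]
        if cols.size == 0:
            continue
        pmats = {
            b.index: model.transition_matrix(b.length * cat_rates[c])
            for b in tree.branches()
        }
        states = simulate_states(tree, pmats, model.pi, cols.size, rng)
        for leaf in tree.leaves():
            out[leaf_order[leaf.name], cols] = states[leaf.index]
    chars = np.array(list(codes.AA_ALPHABET), dtype="<U1")
    rows = chars[out]
    aln = Alignment(taxa, rows, "AA20")
    for change in cfg.planted:
        if change.ancestral == change.derived:
            raise ValueError(
                f"planted change at site {change.site}: derived residue equals ancestral"
            )
        aln.sites[:, change.site] = change.ancestral
        for branch_name in change.branches:
            node = tree.find(branch_name)
            for name in tree.leafset_below(node) if not node.is_leaf else [node.name]:
                aln.sites[aln.taxa.index(name), change.site] = change.derived
    return aln


def simulate_gene_trees(species_tree: Tree, n_genes: int, seed: int = 0) -> list[Tree]:
    """Gene trees under the multispecies coalescent.

    Species-tree branch lengths are in coalescent units; within each branch,
    lineage pairs coalesce at rate C(k,2). Remaining lineages coalesce above
    the root.
    """
    for b in species_tree.branches():
        if b.length < 0:
            raise ValueError("negative branch length in species tree")
    rngs = gene_seeds(seed, n_genes)
    return [_one_msc_tree(species_tree, rng) for rng in rngs]


def _one_msc_tree(sp: Tree, rng: np.random.Generator) -> Tree:
    # lineages[node.index] = list of (gene-tree Node, height)
    lineages: dict[int, list[tuple[Node, float]]] = {}
    heights = {}
    # species node heights (root = max depth); compute via depths
    depth = {}
    for node in sp.preorder():
        depth[node.index] = 0.0 if node.parent is None else depth[node.parent.index] + node.length
    max_depth = max(depth[leaf.index] for leaf in sp.leaves())

    def coalesce(pool, t_start, t_end, rng):
        t = t_start
        while len(pool) > 1:
            k = len(pool)
            rate = k * (k - 1) / 2.0
            t_next = t + rng.exponential(1.0 / rate)
            if t_next > t_end:
                return pool
            i, j = rng.choice(k, size=2, replace=False)
            a, b = pool[i], pool[j]
            parent = Node(None)
            parent.add_child(a[0])
            parent.add_child(b[0])
            a[0].length = t_next - a[1]
            b[0].length = t_next - b[1]
            pool = [p for x, p in enumerate(pool) if x not in (i, j)]
            pool.append((parent, t_next))
            t = t_next
        return pool

    for node in sp.postorder():
        if node.is_leaf:
            pool = [(Node(node.name), max_depth - depth[node.index])]
        else:
            pool = []
            for c in node.children:
                pool.extend(lineages[c.index])
        height_here = max_depth - depth[node.index]
        if node.parent is None:
            pool = coalesce(pool, height_here, np.inf, rng)
        else:
            height_top = max_depth - depth[node.parent.index]
            pool = coalesce(pool, height_here, height_top, rng)
        lineages[node.index] = pool

    root_node, root_h = lineages[sp.root.index][0]
    root_node.length = 0.0
    return Tree(root_node)


def corrupt_alignment(
    aln: Alignment,
    missing_frac: float = 0.0,
    bias_taxa: list[str] | None = None,
    gc_shift: float = 0.0,
    seed: int = 0,
) -> Alignment:
    """Inject missing data and taxon-specific GC bias.

    Missing cells are drawn without replacement so the realized proportion
    equals the target up to rounding. GC shift resamples synonymous third
    positions of the bias taxa with G/C weights inflated by (1 + gc_shift).
    """
    if not (0 <= missing_frac < 1):
        raise ValueError("missing_frac must be in [0, 1)")
    bias_taxa = bias_taxa or []
    unknown = set(bias_taxa) - set(aln.taxa)
    if unknown:
        raise ValueError(f"bias taxa not in alignment: {sorted(unknown)}")
    if missing_frac == 0 and (not bias_taxa or gc_shift == 0):
        return Alignment(list(aln.taxa), aln.sites.copy(), aln.alphabet)
    rng = np.random.default_rng(seed)
    sites = aln.sites.copy()

    if gc_shift and bias_taxa and aln.alphabet == "CODON61":
        for taxon in bias_taxa:
            row = aln.taxa.index(taxon)
            for c in range(aln.n_sites // 3):
                codon = "".join(sites[row, 3 * c : 3 * c + 3]).upper()
                if any(ch in aln.missing for ch in codon):
                    continue
                prefix = codon[:2]
                choices = [
                    b
                    for b in codes.NUCS
                    if prefix + b in codes.CODON_INDEX
                    and codes.CODON_TO_AA[prefix + b] == codes.CODON_TO_AA.get(codon)
                ]
                if len(choices) < 2:
                    continue
                weights = np.array(
                    [1.0 + gc_shift if b in "GC" else 1.0 for b in choices]
                )
                weights /= weights.sum()
                sites[row, 3 * c + 2] = rng.choice(choices, p=weights)

    if missing_frac > 0:
        n_cells = sites.size
        n_missing = int(round(missing_frac * n_cells))
        if aln.alphabet == "CODON61":
            # knock out whole codons to avoid frameshifted stop artifacts
            n_codon_cells = aln.n_taxa * (aln.n_sites // 3)
            n_missing_codons = int(round(missing_frac * n_codon_cells))
            flat = rng.choice(n_codon_cells, size=n_missing_codons, replace=False)
            rows, cods = np.divmod(flat, aln.n_sites // 3)
            for r, cc in zip(rows, cods):
                sites[r, 3 * cc : 3 * cc + 3] = "-"
        else:
            flat = rng.choice(n_cells, size=n_missing, replace=False)
            rows, cols = np.divmod(flat, aln.n_sites)
            sites[rows, cols] = "-"
    return Alignment(list(aln.taxa), sites, aln.alphabet)
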