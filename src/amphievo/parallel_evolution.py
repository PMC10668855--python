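"""Ancestral reconstruction and parallel/common substitution analysis.

Workflow: reconstruct marginal ancestral amino acids on a rooted tree,
collect derived changes shared by every member of a focal group (emitted on
the group's stem branch), classify two-lineage coincidences as parallel
(same ancestral residue, same derived residue) or common (different derived
residues), and compute the chance probability of the observed number of
parallel substitutions under a Poisson null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from amphievo.core import codes
from amphievo.core.alignment import Alignment
from amphievo.core.models import discrete_gamma, empirical_aa_model
from amphievo.core.pruning import leaf_state_matrix, marginal_posteriors
from amphievo.core.tree import Tree

logger = logging.getLogger(__name__)


@dataclass
class ChangeRecord:
    site: int  # 1-based alignment coordinate
    branch: str
    ancestral: str
    derived: str
    posterior: float

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived residues must differ")
        if not (0 < self.posterior <= 1):
            raise ValueError("posterior must be in (0, 1]")


@dataclass
class ParallelCall:
    site: int
    lineages: tuple[str, str]
    kind: str  # "parallel" | "common"
    ancestral: str
    derived_a: str
    derived_b: str
    p_chance: float | None = None


@dataclass
class AncestralReconstruction:
    """Posterior state distributions at internal nodes.

    ``posterior[node_index]`` is a (20, n_sites) matrix; MAP states and
    their posteriors are precomputed. Ties in the MAP state are broken
    lexicographically by one-letter code (tie counts logged).
    """

    tree: Tree
    posterior: dict[int, np.ndarray]
    map_states: dict[int, np.ndarray]
    map_posterior: dict[int, np.ndarray]
    site_logliks: np.ndarray


def ancestral_reconstruct(
    aln: Alignment,
    tree: Tree,
    alpha: float = 1.0,
    k: int = 4,
    model=None,
) -> AncestralReconstruction:
    """Marginal ancestral posteriors under an empirical AA model + Gamma(k)."""
    if aln.alphabet != "AA20":
        raise ValueError("amino-acid alignment required")
    if len(tree.root.children) != 2:
        raise ValueError("rooted tree required (root must be bifurcating)")
    model = model or empirical_aa_model()
    work = tree.copy()
    sub = aln.subset_taxa(work.leaf_names())
    states = sub.state_indices()
    leaf_states = leaf_state_matrix(work, sub.taxa, states)
    rates = discrete_gamma(alpha, k)
    weights = np.full(k, 1.0 / k)

    per_cat = []
    site_ll_cat = []
    for r in rates:
        pmats = {b.index: model.transition_matrix(b.length * r) for b in work.branches()}
        post, site_ll = marginal_posteriors(work, leaf_states, pmats, model.pi)
        per_cat.append(post)
        site_ll_cat.append(site_ll)
    site_ll_cat = np.stack(site_ll_cat)  # (k, L)
    from scipy.special import logsumexp

    total_ll = logsumexp(site_ll_cat + np.log(weights)[:, None], axis=0)
    cat_weight = np.exp(site_ll_cat + np.log(weights)[:, None] - total_ll)  # (k, L)

    posterior: dict[int, np.ndarray] = {}
    map_states: dict[int, np.ndarray] = {}
    map_post: dict[int, np.ndarray] = {}
    n_ties = 0
    for node in work.postorder():
        if node.is_leaf:
            continue
        mix = np.zeros_like(per_cat[0][node.index])
        for c in range(k):
            mix += cat_weight[c][None, :] * per_cat[c][node.index]
        posterior[node.index] = mix
        # lexicographic tie-break: argmax returns the lowest index, and the
        # state alphabet is alphabetical
        best = np.argmax(mix, axis=0)
        ties = (np.isclose(mix, mix.max(axis=0), atol=1e-12).sum(axis=0) > 1).sum()
        n_ties += int(ties)
        map_states[node.index] = best
        map_post[node.index] = mix[best, np.arange(mix.shape[1])]
    if n_ties:
        logger.info("MAP-state ties at %d node-site combinations", n_ties)
    return AncestralReconstruction(
        tree=work,
        posterior=posterior,
        map_states=map_states,
        map_posterior=map_post,
        site_logliks=total_ll,
    )


def group_shared_changes(
    aln: Alignment,
    recon: AncestralReconstruction,
    group: list[str],
    posterior_threshold: float = 0.7,
) -> list[ChangeRecord]:
    """Derived changes shared by every member of a monophyletic group.

    A site qualifies when all group members carry the same residue X, and
    the reconstruction at the parent of the group MRCA is Y != X with
    posterior >= threshold. Sites where any member is missing are skipped.
    """
    tree = recon.tree
    mrca = tree.mrca(group)
    if frozenset(tree.leafset_below(mrca)) != frozenset(group):
        raise ValueError("group is not monophyletic on the tree")
    if mrca.parent is None:
        raise ValueError("group MRCA is the root; no stem branch exists")
    parent = mrca.parent
    rows = {t: aln.taxa.index(t) for t in group}
    out = []
    for site in range(aln.n_sites):
        residues = {str(aln.sites[r, site]).upper() for r in rows.values()}
        if len(residues) != 1:
            continue
        x = next(iter(residues))
        if x not in codes.AA_INDEX:
            continue  # missing in at least one member
        anc_idx = int(recon.map_states[parent.index][site])
        anc_post = float(recon.map_posterior[parent.index][site])
        y = codes.AA_ALPHABET[anc_idx]
        if y == x or anc_post < posterior_threshold:
            continue
        out.append(
            ChangeRecord(
                site=site + 1,
                branch=mrca.name or f"stem:{','.join(sorted(group))}",
                ancestral=y,
                derived=x,
                posterior=anc_post,
            )
        )
    return out


def branch_map_changes(recon: AncestralReconstruction, aln: Alignment) -> dict[int, set[int]]:
    """Sites with a MAP-state substitution per branch (internal comparisons
    use MAP states; leaves their observed residues)."""
    tree = recon.tree
    idx = {t: i for i, t in enumerate(aln.taxa)}
    changes: dict[int, set[int]] = {}
    for node in tree.branches():
        parent_states = recon.map_states[node.parent.index]
        if node.is_leaf:
            row = aln.sites[idx[node.name]]
            child_states = np.array(
                [codes.AA_INDEX.get(str(ch).upper(), -1) for ch in row]
            )
        else:
            child_states = recon.map_states[node.index]
        diff = np.nonzero((child_states != parent_states) & (child_states >= 0))[0]
        changes[node.index] = set((diff + 1).tolist())
    return changes


def classify_pairwise_changes(
    changes_a: list[ChangeRecord],
    changes_b: list[ChangeRecord],
    lineages: tuple[str, str] = ("A", "B"),
) -> list[ParallelCall]:
    """Classify coincident sites as parallel or common.

    Parallel: same ancestral residue and same derived residue on both
    lineages. Common: same site, different derived residues. Coincidences
    with the same derived residue but different ancestral residues are
    excluded (logged), per the stated definitions.
    """
    by_site_a = {c.site: c for c in changes_a}
    out = []
    for cb in changes_b:
        ca = by_site_a.get(cb.site)
        if ca is None:
            continue
        if ca.derived == cb.derived:
            if ca.ancestral == cb.ancestral:
                out.append(
                    ParallelCall(
                        site=cb.site,
                        lineages=lineages,
                        kind="parallel",
                        ancestral=ca.ancestral,
                        derived_a=ca.derived,
                        derived_b=cb.derived,
                    )
                )
            else:
                logger.info(
                    "site %d: same derived residue but different ancestors; excluded",
                    cb.site,
                )
        else:
            out.append(
                ParallelCall(
                    site=cb.site,
                    lineages=lineages,
                    kind="common",
                    ancestral=ca.ancestral if ca.ancestral == cb.ancestral else
                    f"{ca.ancestral}/{cb.ancestral}",
                    derived_a=ca.derived,
                    derived_b=cb.derived,
                )
            )
    return out


def _one_step_same_derived_probability(model, ancestral_dist: np.ndarray) -> float:
    """E_a[ sum_x p(x|a)^2 ] with p(x|a) the conditional one-step
    substitution distribution of the model."""
    Q = model.Q.copy()
    np.fill_diagonal(Q, 0.0)
    rowsum = Q.sum(axis=1, keepdims=True)
    cond = Q / rowsum
    same = (cond**2).sum(axis=1)
    return float(ancestral_dist @ same)


def parallel_null_probability(
    n_a: int,
    n_b: int,
    n_sites: int,
    observed_parallel: int,
    model: str = "jtt",
    ancestral_dist: np.ndarray | None = None,
) -> tuple[float, float]:
    """Expected chance parallels and Poisson upper-tail p-value.

    E = n_a * n_b / L * P(same derived residue), with the derived-residue
    distribution either the JTT one-step conditional ("jtt") or uniform over
    the 19 alternatives ("equal"). p = P(X >= observed | Poisson(E)).
    """
    if min(n_a, n_b, observed_parallel) < 0 or n_sites <= 0:
        raise ValueError("counts must be non-negative and n_sites positive")
    if model == "equal":
        p_same = 1.0 / 19.0
    elif model == "jtt":
        aa = empirical_aa_model()
        dist = aa.pi if ancestral_dist is None else np.asarray(ancestral_dist)
        p_same = _one_step_same_derived_probability(aa, dist)
    else:
        raise ValueError(f"unknown null model {model!r}")
    expected = n_a * n_b / n_sites * p_same
    if expected == 0:
        if observed_parallel > 0:
            logger.warning("expected 0 parallels but observed %d", observed_parallel)
            return 0.0, 0.0
        return 0.0, 1.0
    p = float(poisson.sf(observed_parallel - 1, expected))
    return float(expected), p
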