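import numpy as np
import pytest

from amphievo.core import codes
from amphievo.core.alignment import Alignment
from amphievo.core.models import empirical_aa_model
from amphievo.core.tree import Tree
from amphievo.parallel_evolution import (
    ChangeRecord,
    ancestral_reconstruct,
    classify_pairwise_changes,
    group_shared_changes,
    parallel_null_probability,
)
from amphievo.synthetic_data import SimConfig, simulate_protein_alignment
from amphievo.synthetic_data.simulate import PlantedChange


@pytest.fixture
def salamander_tree():
    return Tree.from_newick(
        "(((sal1:0.1,sal2:0.1)salStem:0.2,frog:0.3):0.2,(anole:0.35,human:0.35):0.15);"
    )


class TestAncestralReconstruct:
    def test_invariant_column_high_posterior(self, salamander_tree):
        aln = Alignment(
            ["sal1", "sal2", "frog", "anole", "human"],
            np.array([list("AAAA")] * 5),
            "AA20",
        )
        recon = ancestral_reconstruct(aln, salamander_tree, alpha=1.0)
        a_idx = codes.AA_INDEX["A"]
        for node_idx, states in recon.map_states.items():
            assert (states == a_idx).all()
            assert (recon.map_posterior[node_idx] > 0.99).all()

    def test_unrooted_tree_rejected(self):
        tree = Tree.from_newick("(a:1,b:1,c:1);")
        aln = Alignment(["a", "b", "c"], np.array([list("AA")] * 3), "AA20")
        with pytest.raises(ValueError, match="rooted"):
            ancestral_reconstruct(aln, tree)

    def test_four_taxon_enumeration_oracle(self):
        """Marginal posterior at one internal node vs brute force over the
        two internal states (single rate category)."""
        tree = Tree.from_newick("((a:0.2,b:0.3):0.15,(c:0.25,d:0.2):0.1);")
        model = empirical_aa_model()
        rng = np.random.default_rng(0)
        sites = rng.choice(list(codes.AA_ALPHABET), size=(4, 6))
        aln = Alignment(["a", "b", "c", "d"], sites, "AA20")
        recon = ancestral_reconstruct(aln, tree, alpha=1.0, k=1, model=model)
        node_ab = tree.mrca(["a", "b"])
        work = recon.tree
        wab = work.mrca(["a", "b"])
        states = aln.state_indices()
        P = {b.index: model.transition_matrix(b.length) for b in work.branches()}
        root = work.root
        wcd = work.mrca(["c", "d"])
        Pa = P[work.find("a").index]
        Pb = P[work.find("b").index]
        Pc = P[work.find("c").index]
        Pd = P[work.find("d").index]
        Pab = P[wab.index]
        Pcd = P[wcd.index]
        for site in range(6):
            sa, sb, sc, sd = states[:, site]
            post = np.zeros(20)
            for u in range(20):  # state at ab node
                tot = 0.0
                for r in range(20):  # root state
                    for v in range(20):  # cd node
                        tot += (
                            model.pi[r]
                            * Pab[r, u]
                            * Pcd[r, v]
                            * Pc[v, sc]
                            * Pd[v, sd]
                        )
                post[u] = tot * Pa[u, sa] * Pb[u, sb]
            post /= post.sum()
            got = recon.posterior[wab.index][:, site]
            assert np.abs(got - post).max() < 1e-8

    def test_simulation_accuracy(self):
        tree = Tree.from_newick(
            "(((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1):0.1,(e:0.15,f:0.15):0.15);"
        )
        from amphievo.core.models import discrete_gamma
        from amphievo.core.pruning import simulate_states

        model = empirical_aa_model()
        rng = np.random.default_rng(1)
        pm = {b.index: model.transition_matrix(b.length) for b in tree.branches()}
        states = simulate_states(tree, pm, model.pi, 500, rng)
        leaves = tree.leaves()
        aln = Alignment(
            [l.name for l in leaves],
            np.array([[codes.AA_ALPHABET[s] for s in states[l.index]] for l in leaves]),
            "AA20",
        )
        recon = ancestral_reconstruct(aln, tree, alpha=1.0, k=1, model=model)
        correct = total = 0
        for node in recon.tree.postorder():
            if node.is_leaf:
                continue
            truth_node = states[node.index]
            correct += (recon.map_states[node.index] == truth_node).sum()
            total += 500
        assert correct / total >= 0.9


class TestGroupSharedChanges:
    def test_constant_alignment_empty(self, salamander_tree):
        aln = Alignment(
            ["sal1", "sal2", "frog", "anole", "human"],
            np.array([list("AAAA")] * 5),
            "AA20",
        )
        recon = ancestral_reconstruct(aln, salamander_tree)
        assert group_shared_changes(aln, recon, ["sal1", "sal2"]) == []

    def test_planted_stem_substitution_recovered(self, salamander_tree):
        cfg = SimConfig(
            seed=3,
            n_sites=200,
            alpha=2.0,
            planted=[
                PlantedChange(site=189, branches=["salStem"], ancestral="V", derived="L")
            ],
        )
        aln = simulate_protein_alignment(salamander_tree, cfg)
        recon = ancestral_reconstruct(aln, salamander_tree, alpha=2.0)
        changes = group_shared_changes(aln, recon, ["sal1", "sal2"])
        hits = [c for c in changes if c.site == 190]
        assert len(hits) == 1
        assert hits[0].ancestral == "V" and hits[0].derived == "L"

    def test_partial_group_not_reported(self, salamander_tree):
        cfg = SimConfig(seed=4, n_sites=50, alpha=2.0)
        aln = simulate_protein_alignment(salamander_tree, cfg)
        # force a column where one salamander is derived, the other ancestral
        aln.sites[:, 10] = "V"
        aln.sites[aln.taxa.index("sal1"), 10] = "L"
        recon = ancestral_reconstruct(aln, salamander_tree, alpha=2.0)
        assert all(c.site != 11 for c in group_shared_changes(aln, recon, ["sal1", "sal2"]))

    def test_missing_member_site_skipped(self, salamander_tree):
        cfg = SimConfig(seed=5, n_sites=50, alpha=2.0)
        aln = simulate_protein_alignment(salamander_tree, cfg)
        aln.sites[:, 5] = "V"
        aln.sites[aln.taxa.index("sal1"), 5] = "L"
        aln.sites[aln.taxa.index("sal2"), 5] = "-"
        recon = ancestral_reconstruct(aln, salamander_tree, alpha=2.0)
        assert all(c.site != 6 for c in group_shared_changes(aln, recon, ["sal1", "sal2"]))

    def test_non_monophyletic_group_rejected(self, salamander_tree):
        aln = Alignment(
            ["sal1", "sal2", "frog", "anole", "human"],
            np.array([list("AAAA")] * 5),
            "AA20",
        )
        recon = ancestral_reconstruct(aln, salamander_tree)
        with pytest.raises(ValueError, match="monophyletic"):
            group_shared_changes(aln, recon, ["sal1", "frog"])


class TestClassification:
    def _rec(self, site, anc, der):
        return ChangeRecord(site=site, branch="x", ancestral=anc, derived=der, posterior=0.95)

    def test_published_classifications(self):
        # OGFR V190L/V190L parallel; P231K vs P231R common;
        # PTGES2 E183A vs E183D common; SIRT1 K375R/K375R parallel
        sal = [
            self._rec(190, "V", "L"),
            self._rec(231, "P", "K"),
            self._rec(183, "E", "A"),
            self._rec(375, "K", "R"),
        ]
        other = [
            self._rec(190, "V", "L"),
            self._rec(231, "P", "R"),
            self._rec(183, "E", "D"),
            self._rec(375, "K", "R"),
        ]
        calls = {c.site: c.kind for c in classify_pairwise_changes(sal, other)}
        assert calls == {190: "parallel", 231: "common", 183: "common", 375: "parallel"}

    def test_different_ancestors_excluded_from_parallel(self):
        calls = classify_pairwise_changes(
            [self._rec(10, "V", "L")], [self._rec(10, "I", "L")]
        )
        assert calls == []

    def test_classification_total(self):
        # every coincidence is parallel, common, or excluded
        a = [self._rec(1, "A", "C"), self._rec(2, "A", "C"), self._rec(3, "G", "C")]
        b = [self._rec(1, "A", "C"), self._rec(2, "A", "D"), self._rec(3, "A", "C")]
        calls = classify_pairwise_changes(a, b)
        kinds = {c.site: c.kind for c in calls}
        assert kinds == {1: "parallel", 2: "common"}  # site 3 excluded


class TestNullProbability:
    def test_no_substitutions(self):
        e, p = parallel_null_probability(0, 5, 100, 0, model="equal")
        assert e == 0.0 and p == 1.0

    def test_equal_model_closed_form(self):
        e, p = parallel_null_probability(10, 10, 100, 0, model="equal")
        assert e == pytest.approx(10 * 10 / (100 * 19))

    def test_monte_carlo_oracle_equal(self):
        rng = np.random.default_rng(7)
        nA = nB = 10
        L = 100
        draws = 100_000
        sites_a = rng.integers(0, L, size=(draws, nA))
        sites_b = rng.integers(0, L, size=(draws, nB))
        res_a = rng.integers(0, 19, size=(draws, nA))
        res_b = rng.integers(0, 19, size=(draws, nB))
        same_site = sites_a[:, :, None] == sites_b[:, None, :]
        same_res = res_a[:, :, None] == res_b[:, None, :]
        mc = (same_site & same_res).sum() / draws
        e, _ = parallel_null_probability(nA, nB, L, 0, model="equal")
        assert e == pytest.approx(mc, rel=0.05)

    def test_poisson_tail_monotone(self):
        ps = [
            parallel_null_probability(10, 10, 100, k, model="jtt")[1] for k in range(5)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_jtt_same_probability_exceeds_equal(self):
        # empirical models concentrate one-step targets, so the chance of
        # matching derived residues is above 1/19
        e_jtt, _ = parallel_null_probability(10, 10, 100, 0, model="jtt")
        e_eq, _ = parallel_null_probability(10, 10, 100, 0, model="equal")
        assert e_jtt > e_eq


class TestRoundTrip:
    def test_planted_stem_changes_recovered(self, salamander_tree):
        recovered = 0
        n_rep = 6
        for rep in range(n_rep):
            cfg = SimConfig(
                seed=100 + rep,
                n_sites=300,
                alpha=2.0,
                planted=[
                    PlantedChange(
                        site=50, branches=["salStem"], ancestral="V", derived="L"
                    )
                ],
            )
            aln = simulate_protein_alignment(salamander_tree, cfg)
            recon = ancestral_reconstruct(aln, salamander_tree, alpha=2.0)
            changes = group_shared_changes(aln, recon, ["sal1", "sal2"])
            if any(c.site == 51 and c.derived == "L" for c in changes):
                recovered += 1
        assert recovered / n_rep >= 0.95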