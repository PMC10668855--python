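import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from amphievo.core import codes
from amphievo.core.alignment import Alignment
from amphievo.core.tree import Tree
from amphievo.codon_selection import (
    CodonModelParams,
    bh_adjust,
    build_codon_Q,
    codon_model,
    f3x4_frequencies,
    feg_scan,
    fit_branch_model,
    fourfold_rates,
    fourfold_sites,
    group_mean_dnds,
    psg_scan,
)
from amphievo.codon_selection.model import uniform_codon_frequencies
from amphievo.synthetic_data import SimConfig, simulate_codon_alignment


class TestCodonQ:
    def test_row_sums_zero(self):
        pi = uniform_codon_frequencies()
        Q, _ = build_codon_Q(2.0, 0.5, pi)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        Q, _ = build_codon_Q(3.0, 0.2, pi)
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-14

    def test_uniform_neutral_rates_equal(self):
        pi = uniform_codon_frequencies()
        Q, _ = build_codon_Q(1.0, 1.0, pi)
        off = Q[codes.PAIR_I, codes.PAIR_J]
        assert np.allclose(off, off[0])

    def test_multinucleotide_changes_zero(self):
        pi = uniform_codon_frequencies()
        Q, _ = build_codon_Q(2.0, 0.5, pi)
        single = set(zip(codes.PAIR_I.tolist(), codes.PAIR_J.tolist()))
        for i in range(0, 61, 7):
            for j in range(0, 61, 11):
                if i != j and (i, j) not in single:
                    assert Q[i, j] == 0.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CodonModelParams(kappa=-1.0, omega=0.5)
        with pytest.raises(ValueError):
            CodonModelParams(kappa=2.0, omega=-0.1)


class TestTwoTaxonOracle:
    def test_pairwise_closed_form(self):
        """2-taxon pruning likelihood equals sum_i pi_i P_ij(t_total)."""
        pi = uniform_codon_frequencies()
        m = codon_model(2.0, 0.5, pi)
        tree = Tree.from_newick("(A:0.15,B:0.1);")
        aln = simulate_codon_alignment(tree, SimConfig(seed=1, n_sites=20, omega=0.5))
        states = aln.state_indices()
        from amphievo.core.pruning import site_log_likelihoods, leaf_state_matrix

        pm = {b.index: m.transition_matrix(b.length) for b in tree.branches()}
        ll = site_log_likelihoods(
            tree, leaf_state_matrix(tree, aln.taxa, states), pm, pi
        )
        P = m.transition_matrix(0.25)  # reversibility: only the sum matters
        for s in range(20):
            i, j = states[0, s], states[1, s]
            assert ll[s] == pytest.approx(np.log(pi[i] * P[i, j]), rel=1e-8)


class TestLikelihoodInvariants:
    def test_taxon_order_invariance(self, small_codon_alignment, five_taxon_tree):
        from amphievo.codon_selection.fit import CodonLikelihood

        aln = small_codon_alignment
        shuffled = Alignment(aln.taxa[::-1], aln.sites[::-1].copy(), "CODON61")
        l1 = CodonLikelihood(aln, five_taxon_tree)
        l2 = CodonLikelihood(shuffled, five_taxon_tree)
        bl = np.full(len(l1.branches), 0.2)
        w = np.full(len(l1.branches), 0.5)
        assert np.allclose(
            l1.site_logliks(2.0, w, bl), l2.site_logliks(2.0, w, bl)
        )

    def test_rescaling_gauge(self):
        # scaling Q by c with branch length t/c leaves P unchanged
        pi = uniform_codon_frequencies()
        Q, rate = build_codon_Q(2.0, 0.5, pi)  # scaled to mean rate 1
        Q2, _ = build_codon_Q(2.0, 0.5, pi, scale=rate / 3.0)  # 3x faster gauge
        from amphievo.core.models import ReversibleModel

        m1 = ReversibleModel(Q, pi, normalize=False)
        m2 = ReversibleModel(Q2, pi, normalize=False)
        assert np.allclose(m1.transition_matrix(0.3), m2.transition_matrix(0.1))


class TestBranchFit:
    def test_identical_sequences_flagged(self):
        row = "ATGGCTGCAATT" * 10
        aln = Alignment(["A", "B", "C"], np.array([list(row)] * 3), "CODON61")
        tree = Tree.from_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        fit, rates = fit_branch_model(aln, tree, "one_ratio", n_restarts=0, maxiter=60)
        assert "degenerate_zero_length" in fit.flags
        assert rates.table["omega"].isna().all()

    def test_two_ratio_recovery(self, five_taxon_tree):
        tree = five_taxon_tree.copy()
        tree.set_branch_classes({"fg": ["A", "B"]}, default="bg")
        cfg = SimConfig(seed=3, n_sites=800, kappa=2.0, omega={"fg": 1.5, "bg": 0.2})
        aln = simulate_codon_alignment(tree, cfg)
        fit, _ = fit_branch_model(aln, tree, "two_ratio", fg_class="fg", n_restarts=0)
        assert fit.params["omega"]["fg"] == pytest.approx(1.5, rel=0.25)
        assert fit.params["omega"]["bg"] == pytest.approx(0.2, rel=0.25)

    def test_unknown_model(self, small_codon_alignment, five_taxon_tree):
        with pytest.raises(ValueError, match="unknown model"):
            fit_branch_model(small_codon_alignment, five_taxon_tree, "m8")


class TestFegScan:
    def test_bh_arithmetic(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_bh_monotone_vs_statsmodels_reference(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_elevated_foreground_detected(self, four_taxon_rooted):
        tree = four_taxon_rooted.copy()
        tree.set_branch_classes({"fg": ["A"]}, default="bg")
        genes = [
            simulate_codon_alignment(
                tree, SimConfig(seed=s, n_sites=400, omega={"fg": 1.2, "bg": 0.15})
            )
            for s in range(4)
        ]
        res = feg_scan(genes, tree, "fg", maxiter=120)
        assert (res.table["call"] == "FEG").sum() >= 3
        assert (res.table["loglik_alt"] >= res.table["loglik_null"] - 1e-6).all()


class TestPsgScan:
    def test_nesting_and_structure(self, four_taxon_rooted):
        tree = four_taxon_rooted.copy()
        tree.set_branch_classes({"fg": ["A"]}, default="bg")
        genes = [
            simulate_codon_alignment(tree, SimConfig(seed=s, n_sites=120, omega=0.3))
            for s in range(2)
        ]
        res = psg_scan(genes, tree, "fg", maxiter=80)
        t = res.table
        assert (t["loglik_alt"] >= t["loglik_null"] - 1e-6).all()
        assert (t["lrt"] >= 0).all()
        assert ((t["p"] >= 0) & (t["p"] <= 1)).all()
        assert (t["p_adj"] >= t["p"] - 1e-12).all()
        assert len(res.site_posteriors) == 2
        assert res.site_posteriors[0].shape == (120,)

    def test_planted_selected_sites_enriched(self):
        # 10% of sites evolve under omega2=10 on a foreground clade; planted
        # sites must be >= 3x enriched in the top posterior decile, pooled
        # over 3 genes (random expectation: 3 hits/gene)
        tree = Tree.from_newick("((A:0.5,B:0.5):0.25,(C:0.4,D:0.4):0.2);")
        tree.set_branch_classes({"fg": ["A", "B"]}, default="bg")
        n_sites, n_sel = 300, 30
        total_hits = 0
        for seed in (20, 40, 60):
            bg_aln = simulate_codon_alignment(
                tree,
                SimConfig(seed=seed, n_sites=n_sites - n_sel, omega={"fg": 0.2, "bg": 0.2}),
            )
            sel_aln = simulate_codon_alignment(
                tree,
                SimConfig(seed=seed + 1, n_sites=n_sel, omega={"fg": 10.0, "bg": 0.2}),
            )
            aln = Alignment(
                bg_aln.taxa, np.concatenate([bg_aln.sites, sel_aln.sites], axis=1), "CODON61"
            )
            res = psg_scan([aln], tree, "fg", maxiter=300)
            post = res.site_posteriors[0]
            top = np.argsort(post)[-n_sites // 10 :]
            total_hits += len(set(range(n_sites - n_sel, n_sites)) & set(top.tolist()))
        assert total_hits >= 3 * 3 * (n_sites // 10) * n_sel / n_sites  # 27


class TestGroupMeans:
    def _rates_df(self, rows):
        return pd.DataFrame(rows)

    def test_exclusion_rule(self):
        df = self._rates_df(
            [
                {"branch": "A", "leafset": "A", "cls": "t", "t": 1, "omega": 0.1, "dN": 0, "dS": 0},
                {"branch": "B", "leafset": "B", "cls": "t", "t": 1, "omega": 0.3, "dN": 0, "dS": 0},
                {"branch": "C", "leafset": "C", "cls": "t", "t": 1, "omega": 6.0, "dN": 0, "dS": 0},
            ]
        )
        out = group_mean_dnds(df, {"A": "g1", "B": "g1", "C": "g1"})
        assert out["means"]["g1"] == pytest.approx(0.2)

    def test_constant_omega(self):
        df = self._rates_df(
            [
                {"branch": t, "leafset": t, "cls": "t", "t": 1, "omega": 0.7, "dN": 0, "dS": 0}
                for t in "ABCD"
            ]
        )
        out = group_mean_dnds(df, {t: "g" for t in "ABCD"})
        assert out["means"]["g"] == pytest.approx(0.7)

    def test_empty_group_warns(self):
        df = self._rates_df(
            [{"branch": "A", "leafset": "A", "cls": "t", "t": 1, "omega": 9.0, "dN": 0, "dS": 0}]
        )
        with pytest.warns(UserWarning, match="surviving"):
            out = group_mean_dnds(df, {"A": "g"})
        assert np.isnan(out["means"]["g"])

    def test_unmapped_terminal_raises(self):
        df = self._rates_df(
            [{"branch": "A", "leafset": "A", "cls": "t", "t": 1, "omega": 0.3, "dN": 0, "dS": 0}]
        )
        with pytest.raises(ValueError, match="without a group"):
            group_mean_dnds(df, {"B": "g"})

    def test_elevated_group_detected_by_wilcoxon(self, four_taxon_rooted):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        frames = []
        for g in range(60):
            frames.append(
                pd.DataFrame(
                    [
                        {"branch": "A", "leafset": "A", "omega": rng.gamma(4, 0.1)},
                        {"branch": "B", "leafset": "B", "omega": rng.gamma(2, 0.1)},
                    ]
                ).assign(gene=g)
            )
        df = pd.concat(frames)
        out = group_mean_dnds(df, {"A": "fast", "B": "slow"})
        fast = out["values"].loc[out["values"]["group"] == "fast", "omega"]
        slow = out["values"].loc[out["values"]["group"] == "slow", "omega"]
        _, p = mannwhitneyu(fast, slow, alternative="greater")
        assert p < 0.05


class TestFourfold:
    def test_glycine_column_included(self):
        # all taxa Gly (GGx): third positions 4-fold degenerate
        rows = ["GGAGGC", "GGGGGT", "GGCGGA"]
        aln = Alignment(["a", "b", "c"], np.array([list(r) for r in rows]), "CODON61")
        sub = fourfold_sites(aln)
        assert sub.n_sites == 2
        assert sub.alphabet == "DNA4"

    def test_atg_column_excluded(self):
        rows = ["ATGGGA", "ATGGGC", "ATGGGT"]
        aln = Alignment(["a", "b", "c"], np.array([list(r) for r in rows]), "CODON61")
        sub = fourfold_sites(aln)
        assert sub.n_sites == 1  # only the Gly column

    def test_mixed_family_column_excluded(self):
        rows = ["GGA", "CCA", "GGA"]  # Gly vs Pro prefixes differ
        aln = Alignment(["a", "b", "c"], np.array([list(r) for r in rows]), "CODON61")
        assert fourfold_sites(aln).n_sites == 0

    def test_rates_correlate_with_ds_on_neutral_simulation(self, five_taxon_tree):
        # 4D rates should track dS from the free-ratio decomposition
        aln = simulate_codon_alignment(
            five_taxon_tree,
            SimConfig(seed=9, n_sites=3000, omega=1.0, kappa=2.0),
        )
        rates, fit, flags = fourfold_rates(aln, five_taxon_tree, maxiter=150)
        _, br = fit_branch_model(aln, five_taxon_tree, "one_ratio", n_restarts=0)
        merged = []
        for _, row in br.table.iterrows():
            key = frozenset(row["leafset"].split(","))
            if key in rates:
                merged.append((rates[key], row["dS"]))
        merged = np.array(merged)
        r = np.corrcoef(merged[:, 0], merged[:, 1])[0, 1]
        assert r >= 0.9
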