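import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from pia.model import (SubstitutionModel, build_rate_matrix,
                       gamma_category_rates, optimize_branch, pruning_loglik,
                       tip_partial)
from pia.simulate import evolve, random_tree
from pia.tree import Tree
from pia._wag import AA_ORDER


class Aln:
    def __init__(self, rows):
        self.rows = rows


def enumeration_loglik(tree, rows, model):
    """Sum the likelihood over every assignment of internal-node states.

    Exponential in internal nodes; the independent oracle for pruning.
    """
    internals = [n for n in tree.postorder() if not n.is_tip]
    tipmap = {n.name: n for n in tree.tips()}
    n_sites = len(next(iter(rows.values())))
    P = {n.index: model.transition_probs(n.length or 0.0)
         for n in tree.postorder() if n is not tree.root}
    idx = {a: i for i, a in enumerate(AA_ORDER)}
    total = 0.0
    for site in range(n_sites):
        site_l = 0.0
        for combo in itertools.product(range(20), repeat=len(internals)):
            state = {n.index: s for n, s in zip(internals, combo)}
            for name, n in tipmap.items():
                state[n.index] = idx[rows[name][site]]
            term = model.freqs[state[tree.root.index]]
            for n in tree.postorder():
                if n is not tree.root:
                    term *= P[n.index][state[n.parent.index], state[n.index]]
            site_l += term
        total += np.log(site_l)
    return total


class TestRateMatrix:
    def test_rows_sum_to_zero(self, wag):
        assert np.abs(wag.Q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self, wag):
        F = wag.freqs[:, None] * wag.Q
        assert np.abs(F - F.T).max() < 1e-12

    def test_unit_mean_rate(self, wag):
        assert -np.sum(wag.freqs * np.diag(wag.Q)) == pytest.approx(1.0, abs=1e-12)

    def test_asymmetric_exchangeabilities_rejected(self, wag):
        bad = wag.exchangeabilities.copy()
        bad[0, 1] += 1.0
        with pytest.raises(ValueError):
            SubstitutionModel("bad", bad, wag.freqs)


class TestTransitionProbs:
    def test_identity_at_zero(self, wag):
        assert np.abs(wag.transition_probs(0.0) - np.eye(20)).max() < 1e-10

    def test_stationary_limit(self, wag):
        P = wag.transition_probs(50.0)
        assert np.abs(P - wag.freqs[None, :]).max() < 1e-6

    def test_chapman_kolmogorov(self, wag):
        rng = np.random.default_rng(5)
        for _ in range(5):
            s, t = rng.uniform(0.01, 2.0, 2)
            lhs = wag.transition_probs(s) @ wag.transition_probs(t)
            assert np.abs(lhs - wag.transition_probs(s + t)).max() < 1e-8

    def test_negative_time_rejected(self, wag):
        with pytest.raises(ValueError):
            wag.transition_probs(-0.1)


class TestGammaRates:
    def test_single_category_is_unit(self):
        assert list(gamma_category_rates(0.7, 1)) == [1.0]

    def test_mean_is_one(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            rates = gamma_category_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-10)

    def test_large_alpha_limit(self):
        rates = gamma_category_rates(1e6, 4)
        assert np.abs(rates - 1.0).max() < 1e-2

    def test_matches_quadrature(self):
        alpha, k = 0.5, 4
        rates = gamma_category_rates(alpha, k)
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1 / alpha)
        for i in range(k):
            val, _ = quad(lambda x: x * gamma_dist.pdf(x, alpha, scale=1 / alpha),
                          edges[i], edges[i + 1] if np.isfinite(edges[i + 1]) else 50)
            assert rates[i] == pytest.approx(k * val, abs=1e-6)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            gamma_category_rates(0.0, 4)


class TestPruning:
    def test_two_zero_branches_give_stationary_logprob(self, wag):
        tree = Tree.from_newick("(A:0.0,B:0.0);")
        rows = {"A": "MKV", "B": "MKV"}
        idx = {a: i for i, a in enumerate(AA_ORDER)}
        expect = sum(np.log(wag.freqs[idx[c]]) for c in "MKV")
        assert pruning_loglik(tree, Aln(rows), wag) == pytest.approx(expect)

    def test_matches_enumeration_on_small_trees(self, wag):
        rng = np.random.default_rng(17)
        for seed in range(6):
            tree = random_tree(4, seed + 50)
            aln = evolve(tree, wag, 4, seed + 150)
            got = pruning_loglik(tree, aln, wag)
            want = enumeration_loglik(tree, aln.rows, wag)
            assert got == pytest.approx(want, abs=1e-8)

    def test_gamma_mixture_matches_manual_average(self, wag):
        tree = random_tree(4, 2)
        aln = evolve(tree, wag, 6, 3)
        gmodel = SubstitutionModel(n_gamma_cats=4, alpha=0.7)
        got = pruning_loglik(tree, aln, gmodel)
        # manual: average per-site likelihood over single-rate models
        rates = gamma_category_rates(0.7, 4)
        site_ls = []
        for r in rates:
            scaled = tree.copy()
            for n in scaled.postorder():
                if n is not scaled.root:
                    n.length = (n.length or 0.0) * r
            site_ls.append([enumeration_loglik_site(scaled, aln.rows, wag, s)
                            for s in range(6)])
        site_ls = np.exp(np.array(site_ls))  # (k, sites)
        want = float(np.sum(np.log(site_ls.mean(axis=0))))
        assert got == pytest.approx(want, abs=1e-8)

    def test_rerooting_invariance(self, wag):
        tree = random_tree(6, 9)
        aln = evolve(tree, wag, 30, 10)
        base = pruning_loglik(tree, aln, wag)
        for edge_id in sorted(tree.edges()):
            rt = tree.reroot_on_edge(edge_id, 0.3)
            assert abs(pruning_loglik(rt, aln, wag) - base) < 1e-9

    def test_duplicated_tip_at_zero_distance_is_free(self, wag):
        tree = Tree.from_newick("((A:0.1,B:0.2):0.1,C:0.3,D:0.15);")
        aln = evolve(tree, wag, 20, 4)
        base = pruning_loglik(tree, aln, wag)
        dup = Tree.from_newick(
            "(((A:0.0,A2:0.0):0.1,B:0.2):0.1,C:0.3,D:0.15);")
        rows = dict(aln.rows)
        rows["A2"] = rows["A"]
        assert pruning_loglik(dup, Aln(rows), wag) == pytest.approx(base, abs=1e-9)

    def test_missing_tip_row_rejected(self, wag):
        tree = Tree.from_newick("(A:0.1,B:0.2,C:0.1);")
        with pytest.raises(ValueError, match="C"):
            pruning_loglik(tree, Aln({"A": "M", "B": "M"}), wag)

    def test_gap_and_x_are_missing_data(self, wag):
        tree = Tree.from_newick("(A:0.1,B:0.2,C:0.1);")
        full = pruning_loglik(tree, Aln({"A": "M", "B": "-", "C": "X"}), wag)
        # B and C contribute nothing: equals single-tip stationary prob
        idx = AA_ORDER.index("M")
        assert full == pytest.approx(np.log(wag.freqs[idx]), abs=1e-9)


def enumeration_loglik_site(tree, rows, model, site):
    return enumeration_loglik(tree, {k: v[site] for k, v in rows.items()}, model)


class TestIndependentImplementation:
    def test_matches_phangorn(self, wag, tmp_path):
        """Cross-check the pruning likelihood against an unrelated
        implementation (R/phangorn) on a simulated case."""
        import subprocess
        from pia.seqs import write_fasta
        tree = random_tree(5, 42)
        aln = evolve(tree, wag, 40, 43)
        write_fasta(list(aln.rows.items()), tmp_path / "a.fasta")
        (tmp_path / "t.nwk").write_text(tree.to_newick() + "\n")
        ours = pruning_loglik(tree, aln, wag)
        script = (
            'suppressMessages(library(phangorn));'
            f'aln <- read.phyDat("{tmp_path}/a.fasta", format="fasta", type="AA");'
            f'tr <- read.tree("{tmp_path}/t.nwk");'
            'cat(sprintf("%.10f", pml(tr, aln, model="WAG")$logLik))')
        r = subprocess.run(["Rscript", "-e", script],
                           capture_output=True, text=True, timeout=120)
        assert r.returncode == 0, r.stderr
        assert ours == pytest.approx(float(r.stdout), abs=1e-4)


class TestOptimizeBranch:
    def test_recovers_simulated_length(self, wag):
        tree = Tree.from_newick("(A:0.3,B:0.0);")
        aln = evolve(tree, wag, 5000, 21)
        # grid-search oracle on the same likelihood surface
        grid = np.linspace(0.15, 0.5, 141)
        lls = []
        for g in grid:
            tree2 = Tree.from_newick(f"(A:{g},B:0.0);")
            lls.append(pruning_loglik(tree2, aln, wag))
        grid_best = grid[int(np.argmax(lls))]
        t3 = Tree.from_newick("(A:0.1,B:0.0);")
        edge = next(e for e, n in t3.edges().items() if n.name == "A")
        length, ll = optimize_branch(t3, edge, aln, wag)
        assert abs(length - 0.3) < 0.05
        assert abs(length - grid_best) < 0.005

    def test_idempotent_at_optimum(self, wag):
        tree = random_tree(4, 33)
        aln = evolve(tree, wag, 200, 34)
        edge = sorted(tree.edges())[0]
        l1, ll1 = optimize_branch(tree, edge, aln, wag)
        l2, ll2 = optimize_branch(tree, edge, aln, wag)
        assert abs(l2 - l1) < 1e-5
        assert ll2 >= ll1 - 1e-8

    def test_identical_tips_hit_lower_bound(self, wag):
        tree = Tree.from_newick("(A:0.2,B:0.1,C:0.1);")
        rows = {"A": "MKVLW" * 10, "B": "MKVLW" * 10, "C": "MKVLW" * 10}
        edge = next(e for e, n in tree.edges().items() if n.name == "A")
        length, _ = optimize_branch(tree, edge, aln=Aln(rows), model=wag)
        assert length < 1e-4

    def test_never_loses_likelihood(self, wag):
        tree = random_tree(5, 41)
        aln = evolve(tree, wag, 100, 42)
        start = pruning_loglik(tree, aln, wag)
        for edge in sorted(tree.edges()):
            _, ll = optimize_branch(tree, edge, aln, wag)
            assert ll >= start - 1e-9
            start = ll
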