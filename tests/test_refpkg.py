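import json

import numpy as np
import pytest

from pia.profilealn import Alignment
from pia.refpkg import (RefPkgError, dereplicate, prune_long_branches,
                        read_refpkg, reoptimize_branch_lengths, write_refpkg,
                        _ungapped_identity)
from pia.seqs import ProteinSequence
from pia.simulate import evolve, random_tree, simulate_refpkg
from pia.tree import Tree

P = ProteinSequence


class TestDereplicate:
    def test_exact_duplicates_keep_lexicographic(self):
        kept, log = dereplicate([P("B", "MKV"), P("A", "MKV")])
        assert [s.id for s in kept] == ["A"]
        assert log == {"B": "A"}

    def test_exact_substring_removed(self):
        kept, log = dereplicate([P("A", "MKVLW"), P("B", "KVL")])
        assert [s.id for s in kept] == ["A"]
        assert log == {"B": "A"}

    def test_unrelated_sequences_all_retained(self):
        rng = np.random.default_rng(3)
        seqs = [P(f"s{i}", "".join("ARNDCQEGHILKMFPSTWYV"[j]
                                   for j in rng.integers(0, 20, 40)))
                for i in range(10)]
        # all-pairs identity oracle: none should reach the 0.9 threshold
        for a in seqs:
            for b in seqs:
                if a.id < b.id:
                    assert _ungapped_identity(a.residues, b.residues) < 0.9
        kept, log = dereplicate(seqs, identity_threshold=0.9)
        assert len(kept) == 10 and not log

    def test_idempotent(self):
        seqs = [P("A", "MKVLW"), P("B", "KVL"), P("C", "WWWWW")]
        once, _ = dereplicate(seqs)
        twice, log2 = dereplicate(once)
        assert twice == once and not log2

    def test_identity_threshold_clustering(self):
        a = P("A", "MKVLWMKVLW")
        b = P("B", "MKVLWMKVLA")  # 9/10 identical
        kept, log = dereplicate([a, b], identity_threshold=0.9)
        assert [s.id for s in kept] == ["A"] and log == {"B": "A"}
        kept2, _ = dereplicate([a, b], identity_threshold=0.95)
        assert len(kept2) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dereplicate([])


class TestPruneLongBranches:
    def test_equal_lengths_untouched(self):
        t = Tree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,E:0.1);")
        out, _, log = prune_long_branches(t, None, factor=10)
        assert sorted(out.tip_names()) == sorted(t.tip_names()) and not log

    def test_single_outlier_removed(self):
        tips = ",".join(f"t{i}:0.1" for i in range(9))
        t = Tree.from_newick(f"({tips},bad:10.0);")
        out, _, log = prune_long_branches(t, None, factor=10)
        assert [r["tip"] for r in log] == ["bad"]
        assert "bad" not in out.tip_names()

    def test_ladder_matches_hand_simulation(self):
        # lengths 1,2,4,...,512: oracle = direct simulation of the rule
        lengths = [2.0 ** i for i in range(10)]
        tips = ",".join(f"t{i}:{l}" for i, l in enumerate(lengths))
        t = Tree.from_newick(f"({tips});")

        def hand(lengths, factor):
            import statistics
            cur = dict(enumerate(lengths))
            removed = []
            while len(cur) > 3:
                med = statistics.median(cur.values())
                over = [(l, i) for i, l in cur.items() if l > factor * med]
                if not over:
                    break
                l, i = max(over)
                removed.append(f"t{i}")
                del cur[i]
            return removed

        for factor in (1.5, 3, 10):
            out, _, log = prune_long_branches(t, None, factor=factor)
            assert [r["tip"] for r in log] == hand(lengths, factor)

    def test_never_below_three_tips(self):
        t = Tree.from_newick("(a:1,b:10,c:100,d:1000);")
        out, _, _ = prune_long_branches(t, None, factor=1.5)
        assert out.n_tips >= 3

    def test_alignment_rows_dropped_in_sync(self):
        tips = ",".join(f"t{i}:0.1" for i in range(5))
        t = Tree.from_newick(f"({tips},bad:50.0);")
        aln = Alignment({n: "MKV" for n in t.tip_names()})
        out, aln2, _ = prune_long_branches(t, aln, factor=10)
        assert set(aln2.rows) == set(out.tip_names())

    def test_small_tree_rejected(self):
        with pytest.raises(ValueError):
            prune_long_branches(Tree.from_newick("(a:1,b:1,c:1);"), None)


class TestReoptimize:
    # moderate lengths: relative error is ill-posed for near-zero branches
    SIX_TIP = ("((t1:0.12,t2:0.30):0.10,(t3:0.22,t4:0.08):0.15,"
               "(t5:0.25,t6:0.18):0.09);")

    def test_recovers_lengths_within_30pct(self, wag):
        tree = Tree.from_newick(self.SIX_TIP)
        aln = evolve(tree, wag, 2000, 72)
        start = tree.copy()
        for n in start.postorder():  # perturb the starting lengths
            if n is not start.root:
                n.length = 0.05
        out, ll, trace = reoptimize_branch_lengths(start, aln, wag, sweeps=4)
        true_by_id = {n.edge_id: n.length for n in tree.postorder()
                      if n is not tree.root}
        for n in out.postorder():
            if n is not out.root:
                truth = true_by_id[n.edge_id]
                assert abs(n.length - truth) / truth < 0.30, \
                    (n.edge_id, n.length, truth)
        assert trace == sorted(trace)  # monotone non-decreasing

    def test_idempotent_at_optimum(self, wag):
        tree = random_tree(4, 81)
        aln = evolve(tree, wag, 300, 82)
        opt, ll1, _ = reoptimize_branch_lengths(tree, aln, wag, sweeps=3)
        again, ll2, trace = reoptimize_branch_lengths(opt, aln, wag, sweeps=1)
        assert ll2 - ll1 < 1e-3
        assert ll2 >= ll1 - 1e-9


class TestPackageIO:
    def test_roundtrip(self, tmp_path, pkg8):
        d = write_refpkg(pkg8, tmp_path / "pkg")
        back = read_refpkg(d)
        assert back.family == pkg8.family
        assert back.ref_alignment.rows == pkg8.ref_alignment.rows
        assert back.tree.to_newick(edge_tags=True) == \
            pkg8.tree.to_newick(edge_tags=True)
        assert back.baits == pkg8.baits
        assert back.landmarks.entries == pkg8.landmarks.entries
        assert np.allclose(back.model.freqs, pkg8.model.freqs)

    def test_missing_file_named(self, tmp_path, pkg8):
        d = write_refpkg(pkg8, tmp_path / "pkg")
        (d / "ref.nwk").unlink()
        with pytest.raises(RefPkgError, match="tree"):
            read_refpkg(d)

    def test_checksum_mismatch_named(self, tmp_path, pkg8):
        d = write_refpkg(pkg8, tmp_path / "pkg")
        (d / "baits.faa").write_text(">x\nMKV\n")
        with pytest.raises(RefPkgError, match="checksum.*baits"):
            read_refpkg(d)

    def test_extra_alignment_row_rejected(self, tmp_path, pkg8):
        d = write_refpkg(pkg8, tmp_path / "pkg")
        with open(d / "ref.aln.faa", "a") as f:
            f.write(">intruder\n" + "M" * pkg8.ref_alignment.n_cols + "\n")
        man = json.loads((d / "manifest.json").read_text())
        import hashlib
        man["checksums"]["alignment"] = hashlib.md5(
            (d / "ref.aln.faa").read_bytes()).hexdigest()
        (d / "manifest.json").write_text(json.dumps(man))
        with pytest.raises(RefPkgError, match="mismatch"):
            read_refpkg(d)

    def test_simulated_packages_validate(self, wag):
        for seed in (1, 2, 3):
            pkg = simulate_refpkg("f", 6, 40, seed=seed, model=wag)
            assert pkg.validate() == []
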