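"""Homology search, NJ trees, bootstrap condensation, clade assignment."""

import functools

import numpy as np
import pytest

from snoevo.families import (
    Scoring,
    assign_by_clade,
    assign_by_homology,
    bootstrap_tree,
    condense_tree,
    karlin_lambda,
    local_align,
    nj_tree,
    node_support,
    progressive_align,
)
from snoevo.simulate import _evolve, default_root_snorna

from conftest import random_dna


def brute_force_local_score(q, s, scoring=Scoring()):
    """Independent local-alignment maximum via memoized path enumeration
    with an explicit affine-gap state (tiny inputs only)."""

    @functools.lru_cache(maxsize=None)
    def best_ending_at(i, j, state):
        # state: 0 = pair, 1 = gap in subject (consume q), 2 = gap in query
        opts = []
        if state == 0:
            sub = scoring.match if q[i] == s[j] else scoring.mismatch
            prev = [0.0]
            if i > 0 and j > 0:
                prev += [best_ending_at(i - 1, j - 1, st) for st in (0, 1, 2)]
            opts += [p + sub for p in prev]
        elif state == 1 and i > 0:
            opts.append(best_ending_at(i - 1, j, 0) + scoring.gap_open)
            opts.append(best_ending_at(i - 1, j, 1) + scoring.gap_extend)
        elif state == 2 and j > 0:
            opts.append(best_ending_at(i, j - 1, 0) + scoring.gap_open)
            opts.append(best_ending_at(i, j - 1, 2) + scoring.gap_extend)
        return max(opts) if opts else -1e9

    best = 0.0
    for i in range(len(q)):
        for j in range(len(s)):
            for st in (0, 1, 2):
                best = max(best, best_ending_at(i, j, st))
    return best


class TestLocalAlign:
    def test_identical_fifty_mers(self):
        seq = ("ACGT" * 13)[:50]
        hit = local_align(seq, seq)
        assert hit.score == 100.0
        assert hit.identity == 1.0
        assert hit.q_span == (0, 50)

    def test_minimal_single_match(self):
        hit = local_align("ACGT", "TTTT")
        assert hit.score == 2.0

    def test_evalue_decreases_with_score(self):
        long = ("ACGT" * 20)[:60]
        h1 = local_align(long, long)
        h2 = local_align(long[:20], long[:20])
        assert h1.score > h2.score and h1.evalue < h2.evalue

    def test_matches_exhaustive_enumeration_on_short_pairs(self, rng):
        for _ in range(25):
            q = random_dna(rng, int(rng.integers(3, 9)))
            s = random_dna(rng, int(rng.integers(3, 9)))
            assert local_align(q, s).score == pytest.approx(
                brute_force_local_score(q, s)
            )

    def test_karlin_lambda_solves_moment_equation(self):
        lam = karlin_lambda()
        lhs = 0.25 * np.exp(lam * 2.0) + 0.75 * np.exp(lam * -3.0)
        assert lhs == pytest.approx(1.0, abs=1e-10)


@pytest.fixture(scope="module")
def references():
    root, _ = default_root_snorna(seed=11)
    rng = np.random.default_rng(1)
    flat = np.full(len(root), 1.0)
    other = _evolve(root, 1.0, flat * 0.25, rng, 4.0)
    return [("hb52_a", root, "HBII-52"), ("hb52_b", root, "HBII-52"),
            ("hb85_a", other, "HBII-85")]


class TestAssignByHomology:

    def test_identical_candidate_assigned(self, references):
        cand = [("c1", references[0][1])]
        a = assign_by_homology(cand, references)[0]
        assert a.family == "HBII-52" and a.method == "homology"
        assert a.support <= 1e-3

    def test_random_sequences_unassigned(self, references):
        unassigned = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = assign_by_homology([("q", random_dna(rng, 80))],
                                   references)[0]
            unassigned += not a.assigned
        assert unassigned >= 99

    def test_tie_broken_lexicographically(self):
        seq = ("ACGTTGCA" * 10)[:60]
        refs = [("refB", seq, "famY"), ("refA", seq, "famX")]
        a = assign_by_homology([("c", seq)], refs)[0]
        assert a.family == "famX"  # refA wins the tie


class TestNJ:
    def test_additive_four_taxon_split_recovered(self):
        D = np.array([[0, 2, 7, 7], [2, 0, 7, 7],
                      [7, 7, 0, 2], [7, 7, 2, 0]], float)
        tree = nj_tree(["A", "B", "C", "D"], D)
        clades = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in tree.preorder_internal_node_iter()
        }
        assert frozenset({"A", "B"}) in clades or frozenset({"C", "D"}) in clades

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(["A", "B", "C"], D)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_ultrametric_matrix_reproduced_exactly(self):
        # ultrametric: ((A,B),(C,D)) with heights 1 and 3
        D = np.array([[0, 2, 6, 6], [2, 0, 6, 6],
                      [6, 6, 0, 2], [6, 6, 2, 0]], float)
        tree = nj_tree(["A", "B", "C", "D"], D)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        labels = ["A", "B", "C", "D"]
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(D[i, j])

    def test_random_additive_trees_recovered(self, rng):
        # NJ is consistent on additive matrices: the recovered tree's path
        # distances must reproduce the generating matrix exactly.
        import random as pyrandom

        import dendropy

        for rep in range(15):
            n = int(rng.integers(4, 11))
            taxa = [f"t{i}" for i in range(n)]
            ns = dendropy.TaxonNamespace(taxa)
            source = dendropy.simulate.treesim.star_tree(ns)
            source.resolve_polytomies(rng=pyrandom.Random(rep))
            for edge in source.preorder_edge_iter():
                if edge.tail_node is not None:
                    edge.length = float(rng.uniform(0.5, 2.0))
            pdm = source.phylogenetic_distance_matrix()
            D = np.zeros((n, n))
            tx = {t.label: t for t in ns}
            for i in range(n):
                for j in range(i + 1, n):
                    D[i, j] = D[j, i] = pdm.distance(tx[taxa[i]], tx[taxa[j]])
            recovered = nj_tree(taxa, D)
            rpdm = recovered.phylogenetic_distance_matrix()
            rtx = {t.label: t for t in recovered.taxon_namespace}
            for i in range(n):
                for j in range(i + 1, n):
                    assert rpdm.distance(
                        rtx[taxa[i]], rtx[taxa[j]]
                    ) == pytest.approx(D[i, j], abs=1e-9)

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            nj_tree(["A", "B", "C"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            nj_tree(["A", "B", "C"],
                    np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]]))


def _two_clade_alignment(rng, n_per_clade=5, depth_mut=25, tip_mut=2, L=60):
    base = random_dna(rng, L)

    def mutate(s, n):
        s = list(s)
        for i in rng.choice(len(s), n, replace=False):
            choices = [b for b in "ACGT" if b != s[i]]
            s[i] = choices[int(rng.integers(3))]
        return "".join(s)

    other = mutate(base, depth_mut)
    aln = [(f"A{i}", mutate(base, tip_mut)) for i in range(n_per_clade)]
    aln += [(f"B{i}", mutate(other, tip_mut)) for i in range(n_per_clade)]
    return aln


class TestBootstrap:
    def test_deep_split_has_high_support(self, rng):
        aln = _two_clade_alignment(rng)
        tree = bootstrap_tree(aln, n_reps=100, seed=0)
        split_support = None
        for node in tree.preorder_internal_node_iter():
            leaves = {l.taxon.label for l in node.leaf_iter()}
            if leaves in ({f"A{i}" for i in range(5)},
                          {f"B{i}" for i in range(5)}):
                split_support = node_support(node)
        assert split_support is not None and split_support >= 90

    def test_identical_sequences_no_crash(self):
        aln = [(f"s{i}", "ACGT" * 10) for i in range(5)]
        tree = bootstrap_tree(aln, n_reps=20, seed=0)
        assert len(tree.leaf_nodes()) == 5

    def test_same_seed_same_supports(self, rng):
        aln = _two_clade_alignment(rng)
        t1 = bootstrap_tree(aln, n_reps=50, seed=7)
        t2 = bootstrap_tree(aln, n_reps=50, seed=7)
        s1 = sorted(node_support(n) for n in t1.preorder_internal_node_iter()
                    if node_support(n) is not None)
        s2 = sorted(node_support(n) for n in t2.preorder_internal_node_iter()
                    if node_support(n) is not None)
        assert s1 == s2

    def test_short_alignment_flagged(self):
        aln = [(f"s{i}", "ACGTACGT") for i in range(4)]
        with pytest.warns(UserWarning, match="shorter"):
            tree = bootstrap_tree(aln, n_reps=5, seed=0)
        assert tree.short_alignment


class TestCondense:
    def _supported_tree(self, rng, sup):
        aln = _two_clade_alignment(rng)
        tree = bootstrap_tree(aln, n_reps=20, seed=1)
        for node in tree.preorder_internal_node_iter():
            if node is not tree.seed_node:
                node.support = sup
                node.label = str(sup)
        return tree

    def test_all_supported_unchanged(self, rng):
        tree = self._supported_tree(rng, 100)
        before = len(tree.internal_nodes())
        after = len(condense_tree(tree, 50).internal_nodes())
        assert before == after

    def test_all_weak_collapses_to_star(self, rng):
        tree = self._supported_tree(rng, 10)
        star = condense_tree(tree, 50)
        assert len(star.seed_node.child_nodes()) == len(star.leaf_nodes())

    def test_idempotent(self, rng):
        aln = _two_clade_alignment(rng)
        tree = bootstrap_tree(aln, n_reps=50, seed=2)
        once = condense_tree(tree, 50)
        twice = condense_tree(once, 50)
        assert (len(once.internal_nodes()) == len(twice.internal_nodes()))
        assert ({l.taxon.label for l in once.leaf_node_iter()}
                == {l.taxon.label for l in twice.leaf_node_iter()})


class TestAssignByClade:
    def test_candidate_in_pure_supported_clade(self, rng):
        aln = _two_clade_alignment(rng)
        tree = bootstrap_tree(aln, n_reps=100, seed=3)
        refs = {f"A{i}": "famA" for i in range(4)}
        refs |= {f"B{i}": "famB" for i in range(4)}
        out = {a.gene_id: a for a in
               assign_by_clade(tree, refs, ["A4", "B4"])}
        assert out["A4"].family == "famA"
        assert out["B4"].family == "famB"

    def test_star_tree_assigns_nothing(self, rng):
        aln = _two_clade_alignment(rng)
        tree = condense_tree(bootstrap_tree(aln, n_reps=20, seed=4), 101)
        refs = {f"A{i}": "famA" for i in range(5)}
        out = assign_by_clade(tree, refs)
        assert all(a.method == "none" for a in out)

    def test_agreement_with_homology_on_separated_families(self):
        total = agree = 0
        for trial in range(5):
            rng = np.random.default_rng(trial)
            rootA, _ = default_root_snorna(seed=trial)
            flat = np.full(len(rootA), 1.0)
            rootB = _evolve(rootA, 1.0, flat * 0.25, rng, 4.0)

            def fam(root, n, d=0.04):
                return [_evolve(root, 1.0, flat * d, rng, 4.0)
                        for _ in range(n)]

            refs = [(f"rA{i}", s, "famA") for i, s in enumerate(fam(rootA, 4))]
            refs += [(f"rB{i}", s, "famB") for i, s in enumerate(fam(rootB, 4))]
            cands = [(f"cA{i}", s) for i, s in enumerate(fam(rootA, 4))]
            cands += [(f"cB{i}", s) for i, s in enumerate(fam(rootB, 4))]
            hom = assign_by_homology(cands, refs)
            aln = [(r, s) for r, s, _ in refs] + cands
            tree = condense_tree(bootstrap_tree(aln, n_reps=50, seed=trial), 50)
            clade = assign_by_clade(tree, {r: f for r, _, f in refs},
                                    [c[0] for c in cands])
            for h, c in zip(hom, clade):
                total += 1
                agree += (h.assigned and c.assigned and h.family == c.family)
        assert agree / total >= 0.95


class TestProgressiveAlign:
    def test_identical_sequences_gapless(self):
        seqs = [("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGTACGT")]
        aln = progressive_align(seqs)
        assert all(row == "ACGTACGT" for _, row in aln)

    def test_single_internal_deletion_yields_one_gap_run(self):
        full = "ACGTTGCAACGGTTAC"
        deleted = full[:6] + full[9:]
        aln = dict(progressive_align([("x", full), ("y", deleted)]))
        gaps = aln["y"].strip("-")
        assert aln["x"] == full
        assert gaps.count("-") == 3
        runs = [r for r in gaps.split("A") if "-" in r]  # contiguous check
        assert "---" in aln["y"]

    def test_width_at_least_max_input_length(self, rng):
        seqs = [(f"s{i}", random_dna(rng, int(rng.integers(20, 40))))
                for i in range(4)]
        aln = progressive_align(seqs)
        width = len(aln[0][1])
        assert width >= max(len(s) for _, s in seqs)
        assert [n for n, _ in aln] == [n for n, _ in seqs]  # order preserved
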