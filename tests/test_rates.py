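"""K2P distances, group averages, bootstrap SE, partition and birth rates."""

import itertools
import math

import numpy as np
import pytest

from snoevo.rates import (
    between_group_distance,
    birth_rate,
    bootstrap_se,
    concatenate_by_name,
    flank_vs_gene,
    k2p_distance,
    partitioned_rates,
    rate_ratio,
)
from snoevo.simulate import _evolve

from conftest import random_dna


def k2p_closed_form(P, Q):
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))


class TestK2P:
    def test_identical_rows(self):
        r = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (r.P, r.Q, r.K) == (0.0, 0.0, 0.0) and r.defined

    def test_hand_case_ten_transitions_five_transversions(self):
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        r = k2p_distance(a, b)
        assert r.P == 0.10 and r.Q == 0.05
        assert r.K == pytest.approx(k2p_closed_form(0.10, 0.05), abs=1e-12)
        assert round(r.K, 4) == 0.1702

    def test_domain_boundary(self):
        # P=0.3, Q=0.2 -> defined; P=0.45, Q=0.2 -> saturated
        a = "A" * 100
        ok = "G" * 30 + "C" * 20 + "A" * 50
        assert k2p_distance(a, ok).defined
        bad = "G" * 45 + "C" * 20 + "A" * 35
        r = k2p_distance(a, bad)
        assert not r.defined and math.isnan(r.K)

    def test_gaps_and_n_excluded_pairwise(self):
        r = k2p_distance("ACGT-N", "ACGAAN")
        assert r.valid_sites == 4
        assert r.P == 0.0 and r.Q == 0.25  # T vs A is a transversion

    def test_zero_valid_sites_raises(self):
        with pytest.raises(ValueError):
            k2p_distance("--", "AC")

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = random_dna(rng, 50), random_dna(rng, 50)
            ra, rb = k2p_distance(a, b), k2p_distance(b, a)
            assert ra == rb


class TestBetweenGroup:
    def test_mean_of_pairs(self):
        x = "A" * 100
        y = "G" * 9 + "C" * 0 + "A" * 91   # P=.09 -> K
        z = "G" * 20 + "C" * 8 + "A" * 72
        gd = between_group_distance([x], [y, z])
        want = (k2p_distance(x, y).K + k2p_distance(x, z).K) / 2
        assert gd.K_mean == pytest.approx(want)
        assert gd.n_pairs == 2

    def test_saturated_pair_dropped_and_counted(self):
        x = "A" * 100
        y = "G" * 10 + "A" * 90
        sat = "G" * 45 + "C" * 20 + "A" * 35
        gd = between_group_distance([x], [y, sat])
        assert gd.n_pairs == 1 and gd.n_dropped == 1
        assert gd.K_mean == pytest.approx(k2p_distance(x, y).K)

    def test_matches_exhaustive_enumeration(self, rng):
        base = random_dna(rng, 80)

        def mutate(s, n):
            s = list(s)
            for i in rng.choice(len(s), n, replace=False):
                s[i] = "ACGT"[(("ACGT".index(s[i])) + 1) % 4]
            return "".join(s)

        A = [mutate(base, 4) for _ in range(5)]
        B = [mutate(base, 8) for _ in range(5)]
        gd = between_group_distance(A, B)
        ks = [k2p_distance(a, b).K for a, b in itertools.product(A, B)
              if k2p_distance(a, b).defined]
        assert gd.K_mean == pytest.approx(np.mean(ks))

    def test_symmetric_in_groups(self, rng):
        A = [random_dna(rng, 40) for _ in range(3)]
        B = [random_dna(rng, 40) for _ in range(3)]
        assert between_group_distance(A, B).K_mean == pytest.approx(
            between_group_distance(B, A).K_mean
        )


class TestBootstrapSE:
    def test_zero_divergence_zero_se(self):
        rows = ["ACGTACGTAC"] * 2
        assert bootstrap_se([rows[0]], [rows[1]], n_boot=50, seed=0) == 0.0

    def test_deterministic_under_seed(self, rng):
        a, b = random_dna(rng, 60), random_dna(rng, 60)
        s1 = bootstrap_se([a], [b], n_boot=100, seed=5)
        s2 = bootstrap_se([a], [b], n_boot=100, seed=5)
        assert s1 == s2

    def test_matches_delta_method_on_long_pair(self):
        # 1000-site pair near K=0.1: bootstrap SE within 20% of the
        # analytic (delta-method) variance of the K2P estimator.
        rng = np.random.default_rng(5)
        L = 1000
        anc = random_dna(rng, L)
        rates = np.full(L, 0.05)
        a = _evolve(anc, 1.0, rates, rng, 4.0)
        b = _evolve(anc, 1.0, rates, rng, 4.0)
        res = k2p_distance(a, b)
        P, Q, n = res.P, res.Q, res.valid_sites
        c1 = 1.0 / (1 - 2 * P - Q)
        c2 = 0.5 * (1.0 / (1 - 2 * P - Q) + 1.0 / (1 - 2 * Q))
        analytic = math.sqrt(
            (c1**2 * P + c2**2 * Q - (c1 * P + c2 * Q) ** 2) / n
        )
        boot = bootstrap_se([a], [b], n_boot=500, seed=1)
        assert abs(boot - analytic) / analytic < 0.2


class TestConcatenate:
    def test_lexicographic_order(self):
        assert concatenate_by_name([("b", "CC"), ("a", "AA")]) == "AACC"

    def test_single_record_identity(self):
        assert concatenate_by_name([("x", "ACGT")]) == "ACGT"

    def test_length_additivity(self, rng):
        recs = [(f"g{i}", random_dna(rng, int(rng.integers(5, 30))))
                for i in range(10)]
        assert len(concatenate_by_name(recs)) == sum(
            len(s) for _, s in recs
        )


class TestPartitionedRates:
    def test_single_class_equals_unrestricted(self, rng):
        a = random_dna(rng, 60)
        b = a[:5] + "".join("ACGT"[(("ACGT".index(c)) + 1) % 4]
                            for c in a[5:12]) + a[12:]
        labels = ["REST"] * 60
        pr = partitioned_rates([a], [b], labels, min_sites=1)
        assert pr["REST"] == pytest.approx(
            between_group_distance([a], [b]).K_mean
        )
        assert pr["BOX"] is None

    def test_label_permutation_equivariance(self, rng):
        width = 60
        a, b = random_dna(rng, width), random_dna(rng, width)
        labels = ["BOX"] * 20 + ["REST"] * 40
        pr1 = partitioned_rates([a], [b], labels, min_sites=1)
        perm = rng.permutation(width)
        labels2 = [labels[i] for i in perm]
        a2 = "".join(a[i] for i in perm)
        b2 = "".join(b[i] for i in perm)
        pr2 = partitioned_rates([a2], [b2], labels2, min_sites=1)
        for cls in ("BOX", "REST"):
            assert pr1[cls] == pytest.approx(pr2[cls])

    def test_width_mismatch_raises(self):
        with pytest.raises(ValueError):
            partitioned_rates(["ACGT"], ["ACGT"], ["REST"] * 3)

    def test_constrained_class_slower_in_simulation(self):
        # BOX multiplier 0.05 vs REST 1.0: ordering recovered in >= 19/20
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            L = 400
            anc = random_dna(rng, L)
            labels = ["BOX"] * 200 + ["REST"] * 200
            rates = np.where(np.arange(L) < 200, 0.05, 1.0) * 0.3
            a = _evolve(anc, 1.0, rates, rng, 4.0)
            b = _evolve(anc, 1.0, rates, rng, 4.0)
            pr = partitioned_rates([a], [b], labels)
            wins += pr["BOX"] < pr["REST"]
        assert wins >= 19


class TestFlankVsGene:
    def test_identical_flanks_divergent_genes(self):
        gene = [("h", "A" * 50), ("m", "G" * 10 + "A" * 40)]
        flank = [("h", "C" * 50), ("m", "C" * 50)]
        fc = flank_vs_gene(gene, flank, flank, ["h"], ["m"])
        assert fc.K_f == 0.0 and fc.K_sno > 0

    def test_symmetric_in_flank_exchange(self, rng):
        ids = ["a", "b"]

        def related_pair(n_mut):
            base = random_dna(rng, 40)
            other = list(base)
            for i in rng.choice(40, n_mut, replace=False):
                other[i] = "ACGT"[(("ACGT".index(other[i])) + 1) % 4]
            return [("a", base), ("b", "".join(other))]

        gene = related_pair(3)
        up = related_pair(5)
        down = related_pair(2)
        f1 = flank_vs_gene(gene, up, down, ["a"], ["b"])
        f2 = flank_vs_gene(gene, down, up, ["a"], ["b"])
        assert f1.K_f == pytest.approx(f2.K_f)

    def test_constrained_gene_slower_than_neutral_flank(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            anc_g = random_dna(rng, 300)
            anc_u = random_dna(rng, 500)
            anc_d = random_dna(rng, 500)

            def pair(anc, rate):
                r = np.full(len(anc), rate)
                return (_evolve(anc, 1.0, r, rng, 4.0),
                        _evolve(anc, 1.0, r, rng, 4.0))

            g = pair(anc_g, 0.3 * 0.15)
            u = pair(anc_u, 1.0 * 0.15)
            d = pair(anc_d, 1.0 * 0.15)
            fc = flank_vs_gene(
                [("h", g[0]), ("m", g[1])],
                [("h", u[0]), ("m", u[1])],
                [("h", d[0]), ("m", d[1])],
                ["h"], ["m"],
            )
            wins += fc.K_sno < fc.K_f
        assert wins >= 19

    def test_id_mismatch_raises(self):
        with pytest.raises(KeyError):
            flank_vs_gene([("a", "AC")], [("b", "AC")], [("a", "AC")],
                          ["a"], ["a"])


class TestBirthRate:
    def test_human_imprinted_cluster(self):
        br = birth_rate(47, 6.75, 2)
        assert round(br.rate, 2) == 6.96
        assert round(br.per_family_rate, 2) == 3.48

    def test_mouse_imprinted_cluster(self):
        br = birth_rate(154, 36.9, 2)
        assert round(br.rate, 2) == 4.17
        assert round(4.17 / 2, 3) == 2.085

    def test_zero_new_genes(self):
        assert birth_rate(0, 10.0, 3).rate == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            birth_rate(5, 0.0, 1)
        with pytest.raises(ValueError):
            birth_rate(5, 1.0, 0)

    def test_published_fold_ratios(self):
        assert rate_ratio(3.48, 0.0433) == 80.37
        assert rate_ratio(2.085, 0.0163) == 127.91

    def test_self_ratio_is_one(self):
        assert rate_ratio(1.234, 1.234) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            rate_ratio(1.0, 0.0)
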