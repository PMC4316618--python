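import io as _io
import math

import numpy as np
import pytest
import skbio

from rasprok import phylo
from rasprok.synthetic_data import _draw_bg, _random_ultrametric_tree, evolve_family


def _read(newick):
    return skbio.TreeNode.read(_io.StringIO(newick))


class TestDistances:
    def test_identical_pair_zero(self):
        dm = phylo.distances({"a": "MGDT", "b": "MGDT"})
        assert dm["a", "b"] == 0.0

    def test_poisson_correction_closed_form(self):
        # half the comparable columns differ -> d = -ln(1 - 0.5) = ln 2
        dm = phylo.distances({"a": "AAAA", "b": "AACC"})
        assert dm["a", "b"] == pytest.approx(math.log(2))

    def test_saturated_pair_capped(self):
        dm = phylo.distances({"a": "AAAAAAAAAA", "b": "CCCCCCCCCC"})
        assert dm["a", "b"] == pytest.approx(-math.log(0.05))

    def test_gap_columns_excluded_matches_brute_force(self):
        rng = np.random.default_rng(0)
        alpha = list("ACDG-")
        for _ in range(30):
            a = "".join(rng.choice(alpha, 60))
            b = "".join(rng.choice(alpha, 60))
            both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not both:
                continue
            p = sum(x != y for x, y in both) / len(both)
            expected = -math.log(1 - p) if p < 0.95 else -math.log(0.05)
            dm = phylo.distances({"a": a, "b": b})
            assert dm["a", "b"] == pytest.approx(expected)

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            phylo.distances({"a": "A--", "b": "-CC"})

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            phylo.distances({"a": "AA", "b": "AAA"})


def _additive_matrix(tree):
    dm = tree.tip_tip_distances()
    return skbio.DistanceMatrix(dm.data, list(dm.ids))


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        tree = _read("((a:1,b:2):0.7,(c:0.5,d:1.5):0.3);")
        nj_tree = phylo.neighbor_joining(_additive_matrix(tree))
        assert phylo.bipartitions(nj_tree) == phylo.bipartitions(tree)
        got = nj_tree.tip_tip_distances()
        want = tree.tip_tip_distances()
        for i in got.ids:
            for j in got.ids:
                assert got[i, j] == pytest.approx(want[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        dm = skbio.DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        tree = phylo.neighbor_joining(dm)
        # star resolution: la+lb=3, la+lc=4, lb+lc=5 -> la=1, lb=2, lc=3
        lengths = {t.name: t.length for t in tree.tips()}
        total = tree.tip_tip_distances()
        assert total["a", "b"] == pytest.approx(3)
        assert total["a", "c"] == pytest.approx(4)
        assert total["b", "c"] == pytest.approx(5)

    def test_input_order_invariance(self):
        tree = _read("((a:1,b:2):0.7,((c:0.5,e:2):0.4,d:1.5):0.3);")
        dm = _additive_matrix(tree)
        shuffled = dm.filter(["d", "a", "e", "b", "c"])
        t1 = phylo.neighbor_joining(dm)
        t2 = phylo.neighbor_joining(shuffled)
        assert phylo.bipartitions(t1) == phylo.bipartitions(t2)

    def test_fewer_than_three_taxa_rejected(self):
        dm = skbio.DistanceMatrix([[0, 1], [1, 0]], ["a", "b"])
        with pytest.raises(ValueError):
            phylo.neighbor_joining(dm)

    def test_random_additive_trees_recovered(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            tree = _random_ultrametric_tree([f"t{i}" for i in range(n)], 1.0, rng)
            nj_tree = phylo.neighbor_joining(_additive_matrix(tree))
            assert phylo.bipartitions(nj_tree) == phylo.bipartitions(tree)


class TestBootstrapConsensus:
    @pytest.fixture(scope="class")
    def two_clade_alignment(self):
        rng = np.random.default_rng(5)
        rootA = _draw_bg(rng, 120)
        rootB = phylo_mutate = None
        from rasprok.synthetic_data import _mutate

        rootB = _mutate(rootA, 1.0, np.ones(120, dtype=bool), rng)
        seqsA, _ = evolve_family(rootA, [f"a{i}" for i in range(6)], 0.1, rng)
        seqsB, _ = evolve_family(rootB, [f"b{i}" for i in range(6)], 0.1, rng)
        return {**seqsA, **seqsB}

    def test_fixed_seed_reproduces_byte_identical_summary(self, two_clade_alignment):
        s1 = phylo.bootstrap_consensus(two_clade_alignment, 25, seed=3)
        s2 = phylo.bootstrap_consensus(two_clade_alignment, 25, seed=3)
        assert s1 == s2

    def test_single_replicate_supports_all_one(self, two_clade_alignment):
        s = phylo.bootstrap_consensus(two_clade_alignment, 1, seed=1)
        assert s.supports
        assert all(sup == 1.0 for _, sup in s.supports)

    def test_identical_sequences_give_star(self):
        aln = {f"t{i}": "MGDTARVL" * 10 for i in range(6)}
        s = phylo.bootstrap_consensus(aln, 20, seed=0)
        assert s.supports == []
        tree = _read(s.consensus_newick)
        assert phylo.bipartitions(tree) == set()

    def test_planted_split_strongly_supported(self, two_clade_alignment):
        s = phylo.bootstrap_consensus(two_clade_alignment, 100, seed=2)
        split = tuple(sorted(f"a{i}" for i in range(6)))
        support = dict(s.supports).get(split, 0.0)
        assert support >= 0.95

    def test_replicate_count_recorded(self, two_clade_alignment):
        assert phylo.bootstrap_consensus(two_clade_alignment, 7, seed=0).n_replicates == 7


class TestCongruence:
    def _mirrored_pair(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        tg = _random_ultrametric_tree([f"g{i}" for i in range(n)], 1.0, rng)
        tb = tg.copy()
        for tip in tb.tips():
            tip.name = tip.name.replace("g", "b")
        pm = {f"g{i}": [f"b{i}"] for i in range(n)}
        return tg, tb, pm

    def test_identical_topologies_score_one(self):
        tg, tb, pm = self._mirrored_pair()
        assert phylo.congruence(tg, tb, pm).fraction == 1.0

    def test_rerooting_invariance(self):
        tg, tb, pm = self._mirrored_pair(n=10, seed=1)
        rerooted = tb.root_at(list(tb.non_tips())[2])
        assert phylo.congruence(tg, rerooted, pm).fraction == 1.0

    def test_shuffled_partner_map_near_null(self):
        rng = np.random.default_rng(3)
        tg, tb, pm = self._mirrored_pair(n=16, seed=2)
        gs = sorted(pm)
        null_fracs = []
        for _ in range(30):
            perm = [pm[g][0] for g in gs]
            rng.shuffle(perm)
            shuffled = dict(zip(gs, ([p] for p in perm)))
            null_fracs.append(phylo.congruence(tg, tb, shuffled).fraction)
        null_mean = float(np.mean(null_fracs))
        assert null_mean < 0.4  # far below the coevolved value of 1.0
        one_more = dict(zip(gs, ([p] for p in sorted(pm[g][0] for g in gs))))
        # any single shuffled map sits near the permutation null
        assert abs(null_fracs[0] - null_mean) <= 3 * (np.std(null_fracs) + 0.05)

    def test_two_partner_systems_can_satisfy_split_with_either(self):
        tg = _read("((g1,g2),(g3,g4));")
        # b1x sits with the g3/g4 partners, but b1y rescues the {g1,g2} split
        tb = _read("(((b1y,b2),(b3,b4)),b1x);")
        pm = {"g1": ["b1x", "b1y"], "g2": ["b2"], "g3": ["b3"], "g4": ["b4"]}
        rep = phylo.congruence(tg, tb, pm)
        assert rep.fraction == 1.0
        chosen = rep.chosen_partners.get("g1")
        assert chosen in (None, "b1x", "b1y")

    def test_empty_partner_map_rejected(self):
        tg, tb, _ = self._mirrored_pair()
        with pytest.raises(ValueError, match="empty"):
            phylo.congruence(tg, tb, {})

    def test_planted_coevolved_true_trees_fully_congruent(self, default_census):
        pm = {}
        for pid, r in default_census.manifest["proteins"].items():
            if r["family"] == "mgla" and r["coupled"]:
                pm[pid] = [f"{r['genome_id']}|{t}" for t in r["partner_locus_tags"]]
        for group in ("MglA-1", "MglA-2"):
            tg = _read(default_census.true_trees[group])
            tb = _read(default_census.true_trees[f"mglb_{group}"])
            sub = {g: v for g, v in pm.items() if g in {t.name for t in tg.tips()}}
            assert phylo.congruence(tg, tb, sub).fraction == 1.0
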