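import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import factorde as fd
from factorde.enrich import GeneSetCollection, _running_sum


def exact_hypergeom_tail(k, K, n, N):
    """Oracle: exact rational summation of binomial-coefficient ratios."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


class TestHypergeomTail:
    def test_k_zero_is_one(self):
        assert fd.hypergeom_tail(0, 5, 5, 20) == 1.0

    def test_full_overlap_universe(self):
        assert fd.hypergeom_tail(5, 20, 5, 20) == pytest.approx(1.0)

    def test_worked_example_matches_enumeration(self):
        assert fd.hypergeom_tail(3, 5, 5, 20) == pytest.approx(
            exact_hypergeom_tail(3, 5, 5, 20), rel=1e-12
        )

    def test_bounds_violations_rejected(self):
        with pytest.raises(ValueError):
            fd.hypergeom_tail(6, 5, 5, 20)
        with pytest.raises(ValueError):
            fd.hypergeom_tail(1, 25, 5, 20)
        with pytest.raises(ValueError):
            fd.hypergeom_tail(-1, 5, 5, 20)

    @given(st.integers(1, 18), st.data())
    def test_matches_exact_enumeration(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert fd.hypergeom_tail(k, K, n, N) == pytest.approx(
            exact_hypergeom_tail(k, K, n, N), rel=1e-10, abs=1e-300
        )


class TestOraTable:
    def _collection(self):
        coll = GeneSetCollection()
        coll.add("setA", [f"g{i}" for i in range(10)])
        coll.add("setB", [f"g{i}" for i in range(50, 70)])
        coll.add("outside", ["x1", "x2"])
        return coll

    def test_empty_selection_gives_unit_pvalues(self):
        universe = [f"g{i}" for i in range(100)]
        out = fd.ora_table([], universe, self._collection())
        assert (out["k"] == 0).all()
        assert (out["p_raw"] == 1.0).all()

    def test_disjoint_set_omitted(self):
        universe = [f"g{i}" for i in range(100)]
        out = fd.ora_table(["g1"], universe, self._collection())
        assert "outside" not in set(out["set"])
        assert len(out) == 2

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fd.ora_table(["zz"], [f"g{i}" for i in range(10)], self._collection())

    def test_bh_monotone_in_praw_rank(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        coll = GeneSetCollection()
        for s in range(15):
            coll.add(f"s{s}", list(rng.choice(universe, size=20, replace=False)))
        selected = list(rng.choice(universe, size=40, replace=False))
        out = fd.ora_table(selected, universe, coll)
        assert (np.diff(out["p_adj"]) >= -1e-12).all()
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()

    def test_planted_sets_outrank_background(self, design):
        """ORA ranks planted-enrichment sets above uniform sets."""
        wins = 0
        for seed in range(10):
            cfg = fd.SimulationConfig(n_probes=400, seed=seed)
            _, truth = fd.simulate_expression(design, cfg)
            coll = fd.plant_gene_sets(truth, 10, 25, 0.8, seed=seed + 100)
            selected = list(truth.loc[truth["true_class"] != "null", "probe_id"])
            out = fd.ora_table(selected, list(truth["probe_id"]), coll)
            ranks = {name: r for r, name in enumerate(out["set"])}
            planted = [r for n, r in ranks.items() if "planted" in n]
            background = [r for n, r in ranks.items() if "background" in n]
            if max(planted) < min(background):
                wins += 1
        assert wins >= 9


class TestPrerankedEs:
    def _ranked(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(scores, index=[f"g{i}" for i in range(n)])

    def test_unweighted_top_block_reaches_one(self):
        ranked = self._ranked(50)
        top = list(ranked.index[:10])
        assert fd.preranked_es(ranked, top, 0.0) == pytest.approx(1.0)

    def test_unweighted_invariant_to_monotone_transform(self):
        ranked = self._ranked(60, seed=1)
        gene_set = list(ranked.index[5:20:3])
        es1 = fd.preranked_es(ranked, gene_set, 0.0)
        transformed = pd.Series(np.exp(ranked.to_numpy() / 2), index=ranked.index)
        es2 = fd.preranked_es(transformed, gene_set, 0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_ten_gene_worked_fixture_matches_hand_loop(self):
        scores = [3.0, 2.5, 2.0, 1.0, 0.5, -0.5, -1.0, -2.0, -2.5, -3.0]
        genes = list("abcdefghij")
        ranked = pd.Series(scores, index=genes)
        gene_set = ["a", "c", "h"]
        # oracle: explicit running sum, weight 1
        hit_w = {g: abs(s) for g, s in zip(genes, scores) if g in gene_set}
        total = sum(hit_w.values())
        running, best = 0.0, 0.0
        for g, s in zip(genes, scores):
            if g in gene_set:
                running += abs(s) / total
            else:
                running -= 1.0 / (10 - 3)
            if abs(running) > abs(best):
                best = running
        assert fd.preranked_es(ranked, gene_set, 1.0) == pytest.approx(best, abs=1e-12)

    def test_reversing_ranking_negates_unweighted_es(self):
        ranked = self._ranked(40, seed=2)
        gene_set = list(ranked.index[:8])
        es = fd.preranked_es(ranked, gene_set, 0.0)
        reversed_ranked = ranked.iloc[::-1]
        es_rev = fd.preranked_es(reversed_ranked, gene_set, 0.0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    @given(st.integers(0, 1000))
    def test_es_always_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        k = int(rng.integers(1, n - 1))
        ranked = pd.Series(
            rng.normal(size=n), index=[f"g{i}" for i in range(n)]
        ).sort_values(ascending=False)
        gene_set = list(rng.choice(ranked.index, size=k, replace=False))
        es = fd.preranked_es(ranked, gene_set, rng.uniform(0, 2))
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_degenerate_sets_rejected(self):
        ranked = self._ranked(10)
        with pytest.raises(ValueError):
            fd.preranked_es(ranked, list(ranked.index), 1.0)
        with pytest.raises(ValueError):
            fd.preranked_es(ranked, ["nope"], 1.0)


class TestEsPermutationFdr:
    def _fixture(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 200
        ranked = pd.Series(
            np.sort(rng.normal(size=n))[::-1], index=[f"g{i}" for i in range(n)]
        )
        coll = GeneSetCollection()
        coll.add("top_loaded", [f"g{i}" for i in range(0, 30)])
        coll.add("random_set", list(rng.choice(ranked.index, 30, replace=False)))
        return ranked, coll

    def test_deterministic_given_seed(self):
        ranked, coll = self._fixture()
        a = fd.es_permutation_fdr(ranked, coll, n_perm=150, seed=3)
        b = fd.es_permutation_fdr(ranked, coll, n_perm=150, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_top_loaded_set_has_tiny_q(self):
        ranked, coll = self._fixture(seed=4)
        out = fd.es_permutation_fdr(ranked, coll, n_perm=1000, seed=5)
        row = out[out["set"] == "top_loaded"].iloc[0]
        assert row["q"] < 0.01
        assert row["ES"] > 0 and row["NES"] > 1

    def test_random_sets_get_broad_q(self):
        """Mean q of non-planted sets over seeded fixtures stays large."""
        rng = np.random.default_rng(6)
        n = 100
        ranked = pd.Series(
            np.sort(rng.normal(size=n))[::-1], index=[f"g{i}" for i in range(n)]
        )
        qs = []
        for seed in range(25):
            r2 = np.random.default_rng(seed)
            coll = GeneSetCollection()
            coll.add("rand", list(r2.choice(ranked.index, 15, replace=False)))
            out = fd.es_permutation_fdr(ranked, coll, n_perm=200, seed=seed)
            qs.append(float(out["q"].iloc[0]))
        assert np.mean(qs) >= 0.2

    def test_too_few_permutations_rejected(self):
        ranked, coll = self._fixture()
        with pytest.raises(ValueError):
            fd.es_permutation_fdr(ranked, coll, n_perm=50, seed=0)


class TestGmtRoundtrip:
    def test_write_read_preserves_sets(self, tmp_path):
        coll = GeneSetCollection()
        coll.add("s1", ["a", "b", "c"], description="first")
        coll.add("s2", ["d", "e"], description="second")
        path = tmp_path / "sets.gmt"
        coll.to_gmt(path)
        back = GeneSetCollection.from_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_empty_set_rejected_at_load(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("s1\tdesc\t\n")
        with pytest.raises(ValueError):
            GeneSetCollection.from_gmt(path)

    def test_duplicate_members_deduplicated(self):
        coll = GeneSetCollection()
        coll.add("s", ["a", "a", "b"])
        assert coll.sets["s"] == ["a", "b"]
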