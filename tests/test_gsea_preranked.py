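"""Pre-ranked GSEA: ranking, enrichment score, permutation null, FDR."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microjxn.gsea_preranked import (
    GeneSet,
    RankedList,
    enrichment_score,
    rank_by_correlation,
    read_gmt,
    run_preranked,
)


def brute_force_es(scores, hit_positions, weight=1.0, tie_tol=1e-9):
    """Independent oracle: literal walk over the ranked list accumulating the
    running sum, then first position whose |value| is within tie_tol of the max."""
    n = len(scores)
    hits = set(hit_positions)
    w = [abs(s) ** weight for s in scores]
    denom = sum(w[i] for i in hits)
    values = []
    run = 0.0
    for i in range(n):
        if i in hits:
            run += (w[i] / denom) if denom > 0 else 1.0 / len(hits)
        else:
            run -= 1.0 / (n - len(hits))
        values.append(run)
    peak = max(abs(v) for v in values)
    for v in values:
        if abs(v) >= peak - tie_tol:
            return v


class TestReadGmt:
    def test_parses_name_description_members(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET_A\tdesc\tg1\tg2\tg3\nSET_B\t\tg4\tg5\n")
        sets = read_gmt(p)
        assert sets[0].name == "SET_A" and sets[0].members == {"g1", "g2", "g3"}
        assert sets[1].members == {"g4", "g5"}

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("SET_A\tdesc\n")
        with pytest.raises(ValueError, match="3 tab-separated"):
            read_gmt(p)


class TestRankedList:
    def test_sorted_descending_with_lexicographic_ties(self):
        rl = RankedList(["b", "a", "c"], [0.5, 0.5, 0.9])
        assert rl.genes == ("c", "a", "b")

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            RankedList(["a", "a"], [1.0, 0.5])


class TestRankByCorrelation:
    def test_order_and_sign(self):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(40)]
        pheno = pd.Series(rng.uniform(size=40), index=samples)
        z = ((pheno - pheno.mean()) / pheno.std()).to_numpy()
        expr = pd.DataFrame(
            {
                "g_pos": 0.9 * z + 0.1 * rng.standard_normal(40),
                "g_zero": rng.standard_normal(40),
                "g_neg": -0.9 * z + 0.1 * rng.standard_normal(40),
            }
        ).T
        expr.columns = samples
        ranked = rank_by_correlation(expr, pheno)
        assert ranked.genes[0] == "g_pos" and ranked.genes[-1] == "g_neg"

    def test_constant_genes_dropped(self):
        samples = [f"S{i}" for i in range(20)]
        pheno = pd.Series(np.linspace(0, 1, 20), index=samples)
        expr = pd.DataFrame(
            [np.linspace(1, 2, 20), np.full(20, 7.0)], index=["g_ok", "g_const"], columns=samples
        )
        ranked = rank_by_correlation(expr, pheno)
        assert ranked.genes == ("g_ok",)


class TestEnrichmentScore:
    def test_single_member_at_rank_one_is_one(self):
        rl = RankedList([f"g{i}" for i in range(5)], [5.0, 4.0, 3.0, 2.0, 1.0])
        res = enrichment_score(rl, ["g0"])
        assert res.es == pytest.approx(1.0)
        assert res.peak_index == 0

    def test_single_member_at_last_rank_reaches_minus_one(self):
        # four misses of -1/4 each reach -1.0 before the final hit returns to 0
        rl = RankedList([f"g{i}" for i in range(5)], [5.0, 4.0, 3.0, 2.0, 1.0])
        res = enrichment_score(rl, ["g4"])
        assert res.es == pytest.approx(-1.0)
        assert res.running_sum[-1] == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_brute_force_oracle_small(self):
        """ES matches the independent oracle for all subsets at small N."""
        rng = np.random.default_rng(7)
        for n in (4, 6, 8):
            rl = RankedList([f"g{i:02d}" for i in range(n)], np.sort(rng.standard_normal(n))[::-1])
            for k in range(1, min(4, n)):
                for sub in combinations(range(n), k):
                    expected = brute_force_es(rl.scores, sub)
                    got = enrichment_score(rl, [rl.genes[i] for i in sub]).es
                    assert got == pytest.approx(expected, abs=1e-12), (n, sub)

    def test_all_zero_member_scores_fall_back_to_unweighted(self, caplog):
        rl = RankedList(["a", "b", "c", "d"], [1.0, 0.0, 0.0, -1.0])
        with caplog.at_level("WARNING"):
            res = enrichment_score(rl, ["b", "c"])
        assert "unweighted" in caplog.text
        assert -1.0 <= res.es <= 1.0

    def test_empty_intersection_rejected(self):
        rl = RankedList(["a", "b"], [1.0, 0.5])
        with pytest.raises(ValueError, match="no members"):
            enrichment_score(rl, ["zzz"])

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), k=st.integers(1, 6))
    def test_es_bounded_and_unweighted_reversal_negates(self, seed, k):
        rng = np.random.default_rng(seed)
        n = 20
        scores = rng.standard_normal(n)
        rl = RankedList([f"g{i:02d}" for i in range(n)], scores)
        members = list(rng.choice(rl.genes, size=k, replace=False))
        es = enrichment_score(rl, members, weight=0.0).es
        assert -1.0 <= es <= 1.0
        reversed_rl = RankedList(rl.genes, -rl.scores[::-1] + 0.0)
        es_rev = enrichment_score(reversed_rl, members, weight=0.0).es
        assert abs(es_rev) == pytest.approx(abs(es), abs=1e-9)


class TestRunPreranked:
    def _ranked(self, n=60, seed=3):
        rng = np.random.default_rng(seed)
        return RankedList([f"g{i:03d}" for i in range(n)], rng.standard_normal(n)), rng

    def test_seeded_rerun_is_identical(self):
        rl, rng = self._ranked()
        sets = [GeneSet("s", frozenset(rng.choice(rl.genes, 10, replace=False)))]
        t1 = run_preranked(rl, sets, n_perm=100, seed=5)
        t2 = run_preranked(rl, sets, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_size_bounds_filter_sets(self):
        rl, rng = self._ranked()
        sets = [
            GeneSet("small", frozenset(rl.genes[:2])),
            GeneSet("ok", frozenset(rl.genes[:10])),
            GeneSet("absent", frozenset(["zzz"])),
        ]
        table = run_preranked(rl, sets, n_perm=50, seed=0, min_size=5, max_size=20)
        assert list(table["set"]) == ["ok"]
        with pytest.raises(ValueError, match="size bounds"):
            run_preranked(rl, sets[:1], n_perm=50, seed=0, min_size=5)

    def test_nes_sign_matches_es_and_p_in_range(self):
        rl, rng = self._ranked(n=120)
        sets = [
            GeneSet(f"s{j}", frozenset(rng.choice(rl.genes, 12, replace=False)))
            for j in range(5)
        ]
        table = run_preranked(rl, sets, n_perm=200, seed=1)
        finite = table["nes"].notna()
        assert (np.sign(table.loc[finite, "nes"]) == np.sign(table.loc[finite, "es"])).all()
        assert table["nominal_p"].between(0, 1).all()
        assert table["fdr"].dropna().between(0, 1).all()

    def test_top_loaded_set_is_enriched(self):
        rl, _ = self._ranked(n=200, seed=8)
        top = GeneSet("top", frozenset(rl.genes[:15]))
        table = run_preranked(rl, [top], n_perm=500, seed=2)
        assert table.loc[0, "es"] > 0.5
        assert table.loc[0, "nominal_p"] <= 1 / 500

    def test_nominal_p_matches_exhaustive_enumeration(self):
        """6-gene list, 2-member set: the resampling null has 15 equally likely
        placements, so nominal p converges to the exhaustive same-sign fraction."""
        rl = RankedList(
            [f"g{i}" for i in range(6)], [2.5, 1.8, 0.9, -0.4, -1.1, -2.0]
        )
        members = ["g1", "g4"]
        es_obs = enrichment_score(rl, members).es
        null = [
            brute_force_es(rl.scores, sub) for sub in combinations(range(6), 2)
        ]
        same = [v for v in null if (v >= 0) == (es_obs >= 0)]
        exact = np.mean([abs(v) >= abs(es_obs) for v in same])
        table = run_preranked(
            rl, [GeneSet("s", frozenset(members))], n_perm=10000, seed=0, min_size=2
        )
        got = table.loc[0, "nominal_p"]
        # binomial sampling bound: 4 sigma on the same-sign subsample
        sd = np.sqrt(exact * (1 - exact) / (len(same) / len(null) * 10000))
        assert got == pytest.approx(exact, abs=max(4 * sd, 5e-3))

    def test_null_sets_give_unremarkable_p(self):
        rl, rng = self._ranked(n=150, seed=12)
        sets = [
            GeneSet(f"null{j}", frozenset(rng.choice(rl.genes, 10, replace=False)))
            for j in range(20)
        ]
        table = run_preranked(rl, sets, n_perm=200, seed=3)
        # on random sets nominal p should not pile up near zero
        assert (table["nominal_p"] < 0.05).sum() <= 4

    def test_bh_fdr_alternative(self):
        rl, rng = self._ranked(n=100)
        sets = [
            GeneSet(f"s{j}", frozenset(rng.choice(rl.genes, 10, replace=False)))
            for j in range(4)
        ]
        table = run_preranked(rl, sets, n_perm=100, seed=4, fdr_method="bh")
        assert (table["fdr"] >= table["nominal_p"] - 1e-12).all()
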