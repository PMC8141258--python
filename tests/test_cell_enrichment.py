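import numpy as np
import pytest

from th17translate.cell_enrichment import (
    MAX_RANK,
    RankedGeneList,
    rank_genes,
    score_all_cell_types,
    weight_at_rank,
    weighted_score,
    windowed_overlap,
)
from th17translate.io_formats import GeneSetCollection, ValidationError
from th17translate.synthetic_data import GeneratorConfig, gen_ranked_planting

from .conftest import make_deg


def make_ranked(n, prefix="R"):
    return RankedGeneList(
        genes=[f"{prefix}{i:05d}" for i in range(1, n + 1)],
        values=np.linspace(10, -10, n),
    )


def brute_force_score(ranked, markers):
    """Independent per-marker weight lookup: weight = 21 - ceil(rank/100)."""
    rank_of = {g: i + 1 for i, g in enumerate(ranked.genes)}
    total = 0
    for m in dict.fromkeys(markers):
        r = rank_of.get(m)
        if r is not None and r <= 2000:
            total += 21 - -(-r // 100)
    return total


class TestRankGenes:
    def test_descending_order(self):
        t = make_deg(["A", "B", "C"], [2.0, 3.0, 1.0])
        assert rank_genes(t).genes == ["B", "A", "C"]

    def test_tie_break_lexicographic(self):
        t = make_deg(["B", "A"], [1.0, 1.0])
        assert rank_genes(t).genes == ["A", "B"]

    def test_truncation(self):
        n = 5000
        t = make_deg([f"G{i:05d}" for i in range(n)], np.random.default_rng(0).normal(size=n))
        assert len(rank_genes(t, top_n=2000)) == 2000

    def test_absolute_ranking(self):
        t = make_deg(["A", "B", "C"], [-5.0, 3.0, 1.0])
        assert rank_genes(t, absolute=True).genes == ["A", "B", "C"]

    def test_bad_top_n(self):
        with pytest.raises(ValidationError):
            rank_genes(make_deg(["A"], [1.0]), top_n=0)


class TestWeightAtRank:
    @pytest.mark.parametrize(
        "rank,weight",
        [(1, 20), (100, 20), (101, 19), (150, 19), (200, 19), (201, 18),
         (1901, 1), (1999, 1), (2000, 1), (2001, 0), (5000, 0)],
    )
    def test_weight_table(self, rank, weight):
        assert weight_at_rank(rank) == weight


class TestWindowedOverlap:
    def test_markers_in_top_50(self):
        ranked = make_ranked(1000)
        markers = ranked.genes[:50]
        win = windowed_overlap(ranked, markers, window=200, step=100)
        assert win.iloc[0]["overlap"] == 50
        beyond = win[win["start"] > 50]
        assert (beyond["overlap"] == 0).all()

    def test_disjoint_markers_all_zero(self):
        win = windowed_overlap(make_ranked(500), ["NOT_THERE"], window=200)
        assert (win["overlap"] == 0).all()

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(5)
        ranked = make_ranked(800)
        markers = list(rng.choice(ranked.genes, size=60, replace=False))
        win = windowed_overlap(ranked, markers, window=200, step=100)
        mset = set(markers)
        for _, row in win.iterrows():
            segment = ranked.genes[int(row["start"]) - 1 : int(row["end"])]
            assert row["overlap"] == len(mset & set(segment))

    def test_window_larger_than_list_rejected(self):
        with pytest.raises(ValidationError):
            windowed_overlap(make_ranked(100), ["R00001"], window=200)

    def test_empty_markers_rejected(self):
        with pytest.raises(ValidationError):
            windowed_overlap(make_ranked(500), [])


class TestWeightedScore:
    def test_single_marker_boundaries(self):
        ranked = make_ranked(2500)
        for rank, expected in [(1, 20), (150, 19), (1999, 1), (2001, 0)]:
            es = weighted_score(ranked, [ranked.genes[rank - 1]])
            assert es.weighted_score == expected

    def test_k_markers_in_top_100(self):
        ranked = make_ranked(2000)
        for k in (1, 5, 30):
            es = weighted_score(ranked, ranked.genes[:k])
            assert es.weighted_score == 20 * k

    def test_scattered_markers_match_oracle(self):
        rng = np.random.default_rng(17)
        ranked = make_ranked(2500)
        markers = list(rng.choice(ranked.genes, size=30, replace=False))
        es = weighted_score(ranked, markers)
        assert es.weighted_score == brute_force_score(ranked, markers)

    def test_invariant_to_marker_order_and_duplicates(self):
        ranked = make_ranked(300)
        markers = ranked.genes[10:20]
        a = weighted_score(ranked, markers).weighted_score
        b = weighted_score(ranked, markers[::-1] + markers[:3]).weighted_score
        assert a == b

    def test_monotone_in_rank(self):
        # moving a marker to a better rank never decreases the score
        ranked = make_ranked(2000)
        scores = [weighted_score(ranked, [ranked.genes[r - 1]]).weighted_score for r in range(1, 2001, 97)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_score_bounded_by_20n(self):
        ranked = make_ranked(2000)
        es = weighted_score(ranked, ranked.genes[:40])
        assert es.weighted_score <= 20 * es.n_markers

    def test_random_ranking_expectation(self):
        # E[score] = n_markers * 100 * (20+...+1) / G for uniform placement
        rng = np.random.default_rng(23)
        G, n_markers = 4000, 25
        genes = [f"U{i:05d}" for i in range(G)]
        markers = genes[:n_markers]
        expected = n_markers * 100 * 210 / G
        total = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = list(rng.permutation(genes))
            ranked = RankedGeneList(genes=perm[:2000], values=np.arange(2000, 0, -1.0))
            total += weighted_score(ranked, markers).weighted_score
        assert total / n_perm == pytest.approx(expected, rel=0.05)

    def test_planted_ranks_score_exact_sum(self):
        cfg = GeneratorConfig(seed=31, planted_ranks=tuple(range(1, 21)) + (150, 1999, 2001))
        table, planted = gen_ranked_planting(cfg)
        ranked = rank_genes(table, top_n=2000)
        # planting really put each marker at its requested rank
        rank_of = ranked.rank_of()
        for marker, rank in planted.items():
            if rank <= 2000:
                assert rank_of[marker] == rank
        es = weighted_score(ranked, list(planted.index))
        assert es.weighted_score == sum(weight_at_rank(int(r)) for r in planted)


class TestScoreAllCellTypes:
    def test_planted_type_wins(self):
        ranked = make_ranked(2000)
        c = GeneSetCollection()
        c.add("TOP", ranked.genes[:20])
        c.add("ABSENT", ["X1", "X2", "X3"])
        out = score_all_cell_types(ranked, c)
        assert out.iloc[0]["cell_type"] == "TOP"
        assert out.iloc[0]["weighted_score"] == 400
        assert out.iloc[1]["weighted_score"] == 0

    def test_order_invariance(self):
        ranked = make_ranked(1000)
        c1, c2 = GeneSetCollection(), GeneSetCollection()
        c1.add("A", ranked.genes[:5]); c1.add("B", ranked.genes[500:510])
        c2.add("B", ranked.genes[500:510]); c2.add("A", ranked.genes[:5])
        out1 = score_all_cell_types(ranked, c1)
        out2 = score_all_cell_types(ranked, c2)
        assert out1["cell_type"].tolist() == out2["cell_type"].tolist()

    def test_normalized_column(self):
        ranked = make_ranked(2000)
        c = GeneSetCollection()
        c.add("T", ranked.genes[:10])
        out = score_all_cell_types(ranked, c)
        assert out.iloc[0]["normalized_score"] == pytest.approx(1.0)

    def test_planted_gd_tcell_attains_max_normalized(self):
        cfg = GeneratorConfig(seed=41, planted_ranks=tuple(range(1, 31)), planted_cell_type="GD_TCELL")
        table, planted = gen_ranked_planting(cfg)
        ranked = rank_genes(table)
        c = GeneSetCollection()
        c.add("GD_TCELL", list(planted.index))
        rng = np.random.default_rng(1)
        for i in range(3):
            c.add(f"OTHER{i}", list(rng.choice(table.genes, size=30, replace=False)))
        out = score_all_cell_types(ranked, c)
        best = out.sort_values("normalized_score", ascending=False).iloc[0]
        assert best["cell_type"] == "GD_TCELL"
        assert best["normalized_score"] == pytest.approx(1.0)
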