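"""Attention attribution: scores, rankings, Top-N, library selection."""

import numpy as np
import pytest

from gexmol.attention import (gene_scores, mean_rank_permutation_test,
                              ranking_table, select_by_gene_rank, top_n_hit,
                              top_n_null_expectation)
from gexmol.network import AttentionRecord


def random_record(rng, n_layers=2, n_heads=2, L=6, genes=8, n_tokens=5):
    w = rng.gamma(1.0, 1.0, size=(n_layers, n_heads, L, genes + 1))
    w /= w.sum(axis=-1, keepdims=True)
    return AttentionRecord(weights=w, n_tokens=n_tokens, gene_count=genes)


def test_scores_match_brute_force_triple_loop():
    rng = np.random.default_rng(0)
    rec = random_record(rng)
    ranking = gene_scores(rec)
    nl, nh, _, S = rec.weights.shape
    brute = np.zeros(S)
    count = 0
    for layer in range(nl):
        for head in range(nh):
            for pos in range(rec.n_tokens):
                brute += rec.weights[layer, head, pos]
                count += 1
    brute /= count
    assert np.allclose(ranking.scores, brute[1:], atol=1e-6)
    assert ranking.cell_score == pytest.approx(brute[0], abs=1e-6)


def test_scores_sum_to_one_minus_cell_score():
    rec = random_record(np.random.default_rng(1))
    ranking = gene_scores(rec)
    assert ranking.scores.sum() + ranking.cell_score == pytest.approx(1.0)


def test_uniform_attention_ranks_in_gene_list_order():
    genes = 6
    w = np.full((1, 1, 3, genes + 1), 1.0 / (genes + 1))
    rec = AttentionRecord(weights=w, n_tokens=3, gene_count=genes)
    ranking = gene_scores(rec)
    assert ranking.ranks.tolist() == [1, 2, 3, 4, 5, 6]  # ties -> list order


def test_concentrated_attention_puts_that_gene_first():
    genes = 5
    w = np.zeros((2, 1, 4, genes + 1))
    w[..., 3] = 1.0  # all mass on gene index 2 (conditioning column 3)
    rec = AttentionRecord(weights=w, n_tokens=4, gene_count=genes)
    ranking = gene_scores(rec)
    assert ranking.rank_of(2) == 1
    assert ranking.ranks.argmin() == 2


def test_ranks_are_a_permutation():
    rec = random_record(np.random.default_rng(2), genes=12)
    ranking = gene_scores(rec)
    assert sorted(ranking.ranks.tolist()) == list(range(1, 13))


def test_last_layer_reduction_differs_from_mean():
    rec = random_record(np.random.default_rng(3), n_layers=3)
    full = gene_scores(rec, reduction="mean")
    last = gene_scores(rec, reduction="last_layer")
    assert not np.allclose(full.scores, last.scores)


def test_top_n_hit_basic_cases():
    rec = random_record(np.random.default_rng(4), genes=10)
    ranking = gene_scores(rec)
    best = int(np.argmin(ranking.ranks))
    worst = int(np.argmax(ranking.ranks))
    assert top_n_hit(ranking, [best], 1) == 1
    assert top_n_hit(ranking, [worst], 9) == 0
    assert top_n_hit(ranking, [worst], 10) == 1
    with pytest.raises(ValueError):
        top_n_hit(ranking, [best], 0)
    with pytest.raises(ValueError):
        top_n_hit(ranking, [best], 11)


def test_top_n_monotone_in_n():
    rng = np.random.default_rng(5)
    rec = random_record(rng, genes=20)
    ranking = gene_scores(rec)
    interactors = [3, 17]
    hits = [top_n_hit(ranking, interactors, n) for n in range(1, 21)]
    assert all(a <= b for a, b in zip(hits, hits[1:]))


def test_top_n_null_expectation_matches_simulation():
    gene_count, k, n = 12, 2, 3
    expected = top_n_null_expectation(gene_count, k, n)
    rng = np.random.default_rng(6)
    hits = 0
    trials = 20000
    for _ in range(trials):
        top = rng.permutation(gene_count)[:n]
        hits += bool(set(top.tolist()) & {0, 1})
    assert hits / trials == pytest.approx(expected, abs=0.01)


def test_select_by_gene_rank_exact_subset():
    rng = np.random.default_rng(7)
    records = [random_record(rng, genes=9) for _ in range(5)]
    rankings = [gene_scores(r) for r in records]
    mols = [f"mol{i}" for i in range(5)]
    gene = 4
    cut = 5
    expected = [m for m, r in zip(mols, rankings) if r.rank_of(gene) <= cut]
    assert select_by_gene_rank(mols, rankings, gene, rank_cut=cut) == expected
    # rank_cut = gene_count keeps everything
    assert select_by_gene_rank(mols, rankings, gene, rank_cut=9) == mols
    with pytest.raises(ValueError, match="rank_cut"):
        select_by_gene_rank(mols, rankings, gene, rank_cut=0)
    with pytest.raises(KeyError):
        select_by_gene_rank(mols, rankings, 99, rank_cut=5)


def test_permutation_test_detects_planted_signal():
    """Rankings where sample i's planted gene is always rank 1 must beat
    the shuffled-pairing null decisively."""
    rng = np.random.default_rng(8)
    genes = 30
    rankings, planted = [], []
    for i in range(40):
        g = i % genes
        w = np.zeros((1, 1, 2, genes + 1))
        w[..., g + 1] = 0.9
        w[..., 0] = 0.1
        rec = AttentionRecord(weights=w, n_tokens=2, gene_count=genes)
        rankings.append(gene_scores(rec))
        planted.append(g)
    obs, p = mean_rank_permutation_test(rankings, planted,
                                        n_permutations=500, seed=0)
    assert obs == 1.0
    assert p < 0.05


def test_permutation_test_null_case_is_insignificant():
    rng = np.random.default_rng(9)
    rankings = [gene_scores(random_record(rng, genes=25)) for _ in range(30)]
    planted = rng.integers(0, 25, size=30)
    _, p = mean_rank_permutation_test(rankings, planted,
                                      n_permutations=500, seed=1)
    assert p > 0.05


def test_ranking_table_sorted_by_rank():
    rec = random_record(np.random.default_rng(10), genes=7)
    table = ranking_table(gene_scores(rec))
    assert table["rank"].tolist() == list(range(1, 8))
    assert table["score"].is_monotonic_decreasing


def test_interaction_table_loading_and_top_n_rate(tmp_path):
    path = tmp_path / "interactions.tsv"
    path.write_text("G0001\tCCO\nG0003\tCCO\nG0002\tCCN\n")
    from gexmol.attention import load_interactions, top_n_rate
    inter = load_interactions(path)
    assert inter == {"CCO": {"G0001", "G0003"}, "CCN": {"G0002"}}

    genes = [f"G{i:04d}" for i in range(6)]
    rankings = []
    for hot in (1, 5):  # first record favors G0001, second favors G0005
        w = np.zeros((1, 1, 2, 7))
        w[..., hot + 1] = 1.0
        rec = AttentionRecord(weights=w, n_tokens=2, gene_count=6)
        rankings.append(gene_scores(rec, genes=genes))
    rate = top_n_rate(rankings, inter, ["CCO", "CCN"], n=1)
    assert rate == 0.5  # CCO hits via G0001; CCN's G0002 is not top-1
    with pytest.raises(ValueError, match="no molecule"):
        top_n_rate(rankings, {}, ["CCO", "CCN"], n=1)
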