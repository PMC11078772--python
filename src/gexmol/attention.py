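"""Cross-attention attribution: per-gene scores, rankings, Top-N validation.

The per-gene score is the uniform mean, over decoder layers, attention
heads and non-PAD molecule positions, of the attention weight placed on
that gene's conditioning row.  Because each attention row is a probability
distribution over the 1 + gene_count conditioning positions, the gene
scores sum to 1 minus the cell-token score.  Alternative reductions
(last layer only, per-layer) are available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .network import AttentionRecord


@dataclass
class GeneAttentionRanking:
    """Scores and 1-based descending ranks for every gene.

    Ties resolve to gene-list order; the cell token is excluded.
    """

    scores: np.ndarray
    ranks: np.ndarray
    cell_score: float
    genes: list[str] | None = None

    def rank_of(self, gene) -> int:
        return int(self.ranks[self._gene_index(gene)])

    def top(self, n: int) -> np.ndarray:
        """Gene indices of the n best ranks, in rank order."""
        if not 1 <= n <= self.scores.size:
            raise ValueError(f"n must be in [1, {self.scores.size}]")
        return np.argsort(self.ranks, kind="stable")[:n]

    def _gene_index(self, gene) -> int:
        if isinstance(gene, (int, np.integer)):
            if not 0 <= gene < self.scores.size:
                raise KeyError(f"gene index {gene} out of range")
            return int(gene)
        if self.genes is None or gene not in self.genes:
            raise KeyError(f"unknown gene {gene!r}")
        return self.genes.index(gene)


def gene_scores(record: AttentionRecord, genes: list[str] | None = None,
                reduction: str = "mean") -> GeneAttentionRanking:
    """Reduce one attention record to a per-gene ranking."""
    w = record.weights[:, :, :record.n_tokens, :]
    if reduction == "mean":
        pooled = w.mean(axis=(0, 1, 2))
    elif reduction == "last_layer":
        pooled = w[-1].mean(axis=(0, 1))
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    scores = pooled[1:]
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, scores.size + 1)
    return GeneAttentionRanking(scores=scores, ranks=ranks,
                                cell_score=float(pooled[0]), genes=genes)


def top_n_hit(ranking: GeneAttentionRanking, interactors, n: int) -> int:
    """1 if any known interacting gene ranks within the top n, else 0."""
    if not 1 <= n <= ranking.scores.size:
        raise ValueError(f"n must be in [1, {ranking.scores.size}]")
    idx = {ranking._gene_index(g) for g in interactors}
    top = set(ranking.top(n).tolist())
    return int(bool(idx & top))


def top_n_null_expectation(gene_count: int, n_interactors: int,
                           n: int) -> float:
    """Expected Top-N hit rate when ranks are a uniform random permutation:
    1 - C(gene_count - k, n) / C(gene_count, n)."""
    if n_interactors == 0:
        return 0.0
    if gene_count - n_interactors < n:
        return 1.0
    return 1.0 - comb(gene_count - n_interactors, n) / comb(gene_count, n)


def select_by_gene_rank(molecules, rankings, gene, rank_cut: int = 200):
    """Molecules whose attention rank of ``gene`` is within ``rank_cut``.

    ``molecules`` and ``rankings`` are aligned sequences; order preserved.
    """
    rankings = list(rankings)
    molecules = list(molecules)
    if len(molecules) != len(rankings):
        raise ValueError("molecules and rankings must align")
    if rankings and not 1 <= rank_cut:
        raise ValueError("rank_cut must be >= 1")
    if not rankings:
        return []
    if rank_cut < 1 or rank_cut > rankings[0].scores.size:
        raise ValueError(
            f"rank_cut must be in [1, {rankings[0].scores.size}]")
    return [m for m, r in zip(molecules, rankings)
            if r.rank_of(gene) <= rank_cut]


def mean_rank_permutation_test(rankings, planted_genes,
                               n_permutations: int = 1000, seed: int = 0
                               ) -> tuple[float, float]:
    """Is the planted gene ranked better (lower) than under shuffled pairing?

    ``planted_genes[i]`` is the informative gene of sample i.  The null
    re-pairs rankings with planted genes by permutation; the one-sided
    p-value is the fraction of permuted mean ranks at or below the observed
    one (add-one corrected).
    """
    rankings = list(rankings)
    planted = np.asarray([r._gene_index(g)
                          for r, g in zip(rankings, planted_genes)])
    if len(rankings) != planted.size or not rankings:
        raise ValueError("rankings and planted_genes must align (non-empty)")
    rank_matrix = np.stack([r.ranks for r in rankings])  # (n, G)
    n = len(rankings)
    observed = float(rank_matrix[np.arange(n), planted].mean())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        null = rank_matrix[np.arange(n), planted[perm]].mean()
        if null <= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return observed, p


def load_interactions(path) -> dict:
    """Two-column TSV (gene id, molecule SMILES/id) -> molecule -> gene set."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "molecule"], dtype=str)
    out: dict = {}
    for gene, mol in zip(df["gene"], df["molecule"]):
        out.setdefault(mol, set()).add(gene)
    return out


def top_n_rate(rankings, interactions: dict, molecules, n: int) -> float:
    """Mean Top-N hit over aligned (ranking, molecule) pairs; molecules
    without any known interactor are skipped."""
    hits, used = 0, 0
    for ranking, mol in zip(rankings, molecules):
        genes = interactions.get(mol)
        if not genes:
            continue
        known = [g for g in genes
                 if ranking.genes is None or g in ranking.genes]
        if not known:
            continue
        hits += top_n_hit(ranking, known, n)
        used += 1
    if used == 0:
        raise ValueError("no molecule has a known interactor")
    return hits / used


def ranking_table(ranking: GeneAttentionRanking) -> "pd.DataFrame":
    import pandas as pd
    genes = ranking.genes or [f"G{i:04d}" for i in range(ranking.scores.size)]
    df = pd.DataFrame({"gene": genes, "score": ranking.scores,
                       "rank": ranking.ranks})
    return df.sort_values("rank").reset_index(drop=True)
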