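# gexmol

De novo molecule generation conditioned on gene-expression change.

`gexmol` addresses phenotype-based drug design: instead of asking for a
molecule that binds a known target, it asks for molecules associated with a
*transcriptional phenotype* — the vector of expression differences between a
diseased (or perturbed) cell line and its matched control. It is aimed at
computational chemists and bioinformaticians who have L1000-style landmark
gene readouts and want candidate structures plus a per-gene account of what
the generator attended to.

## The model

A record couples a cell line *C* and expression differences
*E = (e₁, …, e₉₇₈)* (one decimal place) with the perturbing molecule *M*.
The conditioning matrix is

```
G₀ = FNN(Linear(Concat(v_c, v_e)))          v_c = Linear(one-hot(C))
                                            v_e = Linear(f_emb(E))
```

where `f_emb` encodes each signed decimal eᵢ numerically. Four schemes are
implemented; the best-performing **tenfold-binary** encoding writes
`[sign bit ‖ 9-bit binary of |eᵢ|·10]`, e.g. `7.3 → 1 001001001` and
`−14.4 → 0 010010000`. Keeping the 978 genes as distinct rows of G₀ is what
later allows per-gene attribution.

Molecules are strings in a robust self-referencing token alphabet
(SELFIES-style, implemented in `gexmol.codec`): *every* token sequence
decodes to a valid structure, so generation validity is 100% by
construction. A transformer decoder (6 layers, 8 heads, hidden size 64,
feed-forward 512 by default) embeds the token sequence, applies masked
self-attention, cross-attention `Attention(V′, G₀, G₀)`, and a feed-forward
block per layer (residual + layer norm), and a softmax generator head
reconstructs the molecule. Training minimizes the token-level KL divergence
against the one-hot original — the masked cross-entropy
`−(1/L) Σᵢ log p(tᵢ)` — with Adam (defaults: 200 epochs, batch 4, lr 1e-4).

The cross-attention matrices are first-class outputs: averaging attention
weight over layers, heads and molecule positions gives a per-gene score,
a gene ranking, and the Top-N statistic (does any known interacting gene of
the molecule rank in the top N?).

## Worked example

```python
from gexmol import make_dataset, TranscriptomeMoleculeModel
from gexmol.attention import gene_scores
from gexmol.metrics import evaluate_set

# 50 paired samples; each molecule has one planted informative gene
ds = make_dataset(50, gene_count=978, noise_sd=0.0, effect_size=5.0, seed=11)

model = TranscriptomeMoleculeModel(ds, d=32, n_layers=2, n_heads=2, d_ff=64,
                                   dropout=0.0)
res = model.fit(epochs=200, lr=1e-3, seed=0)
print(f"reconstruction accuracy: {res.reconstruction_accuracy(ds):.3f}")

mols = res.generate(ds.profile(0), n=1000, seed=1)
report = evaluate_set([m.smiles for m in mols], ds.smiles,
                      with_properties=False)
print(report.as_dict())

rec = res.reconstruct(ds.profile(0), ds.smiles[0])[1]
planted = next(iter(ds.assoc[ds.smiles[0]]))
print("planted gene rank:", gene_scores(rec).rank_of(planted))
```

prints (CPU, ~4 min):

```
reconstruction accuracy: 0.968
{'n_generated': 1000, 'validity': 1.0, 'uniqueness': 0.057, 'novelty': 0.066,
 'internal_diversity': 0.6096228373253012, 'n_trivial': 0}
planted gene rank: 1
```

Read: every sampled molecule is valid (structural guarantee of the codec);
a 56-molecule training pool memorized to 97% token accuracy mostly re-emits
pool molecules, so uniqueness and novelty are low at this toy scale (they
are corpus-size-bound, unlike validity); and the gene planted for this
sample's molecule is ranked first by cross-attention — the attribution
mechanism recovers the planted association.

A CLI mirrors the library: `gexmol make-synthetic | train | generate |
evaluate | rank-genes | compare-schemes` (see `gexmol --help`).

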