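# Methods

## Model

`gexmol` couples a transformer *decoder* to a gene-expression conditioning
encoder. There is no sequence encoder: the conditioning matrix G₀ plays the
role that encoder states play in a translation model.

**Conditioning encoder.** A record's cell line is one-hot encoded over a
fixed registry (default: the 14 high-coverage L1000 compound-perturbation
lines) and linearly mapped to the hidden size *d*. Each of the 978 gene
difference values is embedded by a numeric scheme (below) and mapped
raw→*d* by a linear layer shared across genes (a per-gene variant is
available via `per_gene_projection=True`). The cell row is prepended to the
978 gene rows — concatenation along the *sequence* axis, never flattening —
and the (979, d) stack passes through a shared linear layer and a two-layer
feed-forward block with ReLU on the first layer. Keeping genes as rows is a
load-bearing choice: cross-attention keys must be per-gene for per-gene
attribution to exist. Under the default shared projection, gene *identity*
enters G₀ only through the gene's numeric value; cross-attention is
permutation-invariant over conditioning rows (tested), which is exactly the
symmetry the planted-association recovery experiment exploits.

**Numeric embedding schemes.** Values are signed decimals with exactly one
fractional digit. Schemes:

| scheme          | layout                                   | raw_dim | range |
|-----------------|------------------------------------------|---------|-------|
| value           | the number itself                        | 1       | unbounded |
| one_hot         | sign ‖ one-hot(int part) ‖ one-hot(digit)| 63      | ±51.9 |
| binary          | sign ‖ 5-bit int ‖ 4-bit digit           | 10      | ±31.9 |
| tenfold_binary  | sign ‖ 9-bit of round(\|e\|·10)          | 10      | ±51.1 |

The sign bit is 1 iff the value is strictly positive. All bit extraction
goes through the exact scaled integer `floor(|e|·10 + 0.5)` so floating
residue can never flip a bit (14.4 encodes 144, never 143). The one_hot
integer bucket count defaults to 52 so its range matches tenfold-binary's;
it is configurable. Out-of-range values are *errors* at the embedding
boundary; ingestion paths (`difference_and_round`, `make_dataset`,
profile validation) clip to the scheme range with a warning instead,
because real difference tables can contain outliers and silently dropping
samples would bias the pairing. The binary scheme's 5-bit integer field
caps at 31 — narrower than tenfold-binary's span; we clip rather than guess
what an upstream pipeline would have done.

**Decoder.** Token embedding (+ fixed sinusoidal positions; the
conditioning rows get none — gene order is arbitrary), N layers of
masked self-attention → cross-attention (molecule states as queries, G₀ as
keys and values) → position-wise feed-forward, each residual + layer norm.
Post-norm is the default (original transformer convention); pre-norm is a
config flag. Cross-attention conditions on G₀ at *every* layer. The
generator head is linear + softmax over the vocabulary. Defaults follow the
reference setting: d=64, 6 layers, 8 heads, d_ff=512, dropout 0.1.

**Loss.** Token-level KL divergence between the one-hot original molecule
and the reconstruction distribution, which reduces to masked cross-entropy
`−(1/L)Σ log p(tᵢ)` over non-PAD positions, token-weighted across batches
so the epoch loss is independent of how shuffling groups samples.

**Training.** Teacher forcing, Adam (the de-facto choice for transformer
training; the optimizer is not otherwise pinned down), defaults 200 epochs
/ batch 4 / lr 1e-4. All randomness — init, shuffling, dropout — derives
from one seed; identical seeds give bit-identical histories. Checkpoints
store parameters, config, vocabulary and its hash; loading verifies the
hash. Desk-scale probes (`overfit_probe`, the acceptance script) use lr
1e-3: a memorization run of a width-32 model over a few hundred epochs
wants the fastest stable step size, and Adam at 1e-3 is the standard
small-model setting.

## Molecular string codec

Molecules are token strings in a self-referencing alphabet (16 atom tokens
with bond-order prefixes, branch and ring tokens with overloaded index
digits). Decoding is a total function: bond orders are capped at remaining
valences, unrealizable branch/ring instructions are dropped, and any token
doubles as a base-16 index digit where an index is expected — so *every*
sequence, including uniformly random ones, derives a valid molecule. This
structural guarantee, not the quality of training, is what makes generation
validity 100%; the property is asserted over ≥1500 random sequences.

Supported subset: neutral organic molecules over C, N, O, F, S, P, Cl, Br,
I; kekulized bonds; no stereochemistry, charges, isotopes, radicals or
multi-fragment species. Encoding anything outside raises `CodecError` and
vocabulary building reports (never silently drops) such molecules. Encoding
is a DFS over the kekulized graph emitting branch-wrapped subtrees and
ring-closure tokens; round-trip to canonical SMILES is exact on the bundled
pool and is the invariant the encoder is tested against. BOS/EOS/PAD/UNK
are vocabulary artifacts of autoregressive generation, not codec tokens;
an immediate-EOS sample decodes to the empty molecule, which RDKit parses —
such outputs are counted valid but flagged `n_trivial` in reports and
excluded from property tables and diversity.

## Generation and attribution

Sampling is autoregressive with multinomial draws from the
temperature-scaled softmax (greedy and top-k available). Stochastic
decoding is the default because observed uniqueness well below 100% under a
deterministic decoder would be impossible. Decoding uses per-layer KV
caches; the incremental path is tested to match the full forward pass to
1e-10, so caching is an optimization with no semantic content. Sequences
that reach `max_len` (corpus maximum + 2 by default) are closed and
decoded; derivation always terminates.

Attention records are taken from a teacher-forced pass over the finished
sequence (for generated molecules as well as reconstructions), giving
clean L×979 rows for every layer and head. The per-gene score is the
uniform mean over layers, heads and non-PAD positions — the simplest
order-invariant reduction; last-layer-only is available for sensitivity
analysis. Ranks are 1-based descending with ties broken by gene-list
order. Top-N is the binary per-sample indicator that a known interacting
gene ranks ≤ N; its permutation null 1 − C(G−k, N)/C(G, N) is computed
exactly. The planted-gene significance test permutes the pairing between
rankings and planted genes (add-one-corrected one-sided p).

## Synthetic data

`make_dataset` emulates the *structure* of an L1000-derived paired dataset:
uniform cell line, uniform molecule from a bundled pool of 56 small neutral
drug-like molecules, baseline differences ~ N(0, noise_sd) rounded to one
decimal and clipped to the scheme range, and each molecule's planted
gene(s) shifted by ±effect_size. Defaults noise_sd=1.0 and effect_size=5.0:
landmark-gene difference values are mostly a few units in magnitude, and a
5σ planted shift is a strong, unambiguous association — the point of the
generator is a recoverable ground truth, not realism. What it deliberately
does **not** simulate: transcriptomic covariance between genes, plate and
batch effects, dose–time response, or many-to-many molecule–gene maps.
Passing tests therefore demonstrate that the machinery (embedding,
conditioning, attribution) works when a signal exists; they say nothing
about signal strength in real perturbation data.

## Numerical choices and degenerate inputs

- float64 throughout; gradients verified against central finite
  differences at 1e-6 tolerance.
- Softmax and cross-entropy use max-shifted stable forms; attention
  masking adds −1e9 rather than −inf to keep the backward pass finite.
- Xavier-uniform init for linear maps, N(0, 0.02) for token embeddings,
  seeded.
- Empty molecule (no non-PAD positions), empty metric sets, zero-length
  corpora, and rank cuts outside [1, G] are errors, not silent defaults.
- Non-finite training loss aborts with diagnostics rather than continuing.

## Scales used by the test suite and acceptance script

Chosen once as the package's desk-scale study conditions: width-32,
2-layer, 2-head models; 20–100 samples at the full 978-gene conditioning
width where the claim depends on it (validity, overfit recovery, planted
attribution), 12–30 genes in unit tests of mechanics; 1000-molecule
samples for validity measurements; 100-epoch training in the
scheme-comparison harness with 500 molecules per scheme. The harness
compares schemes on identical data and seeds, so rows differ only in the
numeric embedding.

## Known limitations

- The codec subset excludes charged species (e.g. nitro written as an
  ion pair), stereochemistry and isotopes; corpus molecules outside the
  subset are reported and must be curated away by the caller.
- The shared gene projection means two genes with equal values have
  identical conditioning rows; attribution then identifies *which row
  carries the signal*, not gene identity per se. The per-gene projection
  restores identity at a large parameter cost.
- Training is plain CPU numpy: appropriate for desk-scale experiments
  (minutes), not for corpus-scale runs.
- Uniqueness/novelty/diversity at desk scale reflect the tiny molecule
  pool and are not comparable to corpus-scale numbers; validity is the
  only scale-free metric here.
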