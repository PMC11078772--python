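"""Autoregressive sampling of molecules conditioned on an expression profile.

Sampling is multinomial from the temperature-scaled softmax by default
(greedy and top-k available).  Every emitted index sequence is decoded
through the robust codec, so every returned molecule is chemically valid by
construction — trained or not.  Attention records are taken from a
teacher-forced pass over each finished sequence, so the record covers the
whole molecule with clean rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import no_grad
from .network import AttentionRecord
from .vocab import BOS, EOS, PAD


@dataclass
class GeneratedMolecule:
    smiles: str
    tokens: np.ndarray            # BOS ... EOS (no PAD)
    attention: AttentionRecord | None = None

    @property
    def is_trivial(self) -> bool:
        """True for a zero-atom derivation (e.g. immediate EOS)."""
        return self.smiles == ""


def _sample_indices(probs: np.ndarray, rng: np.random.Generator,
                    temperature: float, top_k: int | None,
                    greedy: bool) -> np.ndarray:
    """One next-token draw per row of probs (B, V)."""
    if greedy or temperature == 0.0:
        return probs.argmax(axis=-1)
    if temperature != 1.0:
        logp = np.log(np.clip(probs, 1e-300, None)) / temperature
        logp -= logp.max(axis=-1, keepdims=True)
        probs = np.exp(logp)
        probs /= probs.sum(axis=-1, keepdims=True)
    if top_k is not None:
        cut = np.sort(probs, axis=-1)[:, -top_k][:, None]
        probs = np.where(probs >= cut, probs, 0.0)
        probs /= probs.sum(axis=-1, keepdims=True)
    cdf = probs.cumsum(axis=-1)
    cdf /= cdf[:, -1:]
    u = rng.random((probs.shape[0], 1))
    return (cdf < u).sum(axis=-1)


def sample(results, profile, n: int, temperature: float = 1.0,
           top_k: int | None = None, greedy: bool = False, seed: int = 0,
           with_attention: bool = False, batch_size: int = 100
           ) -> list[GeneratedMolecule]:
    """Draw ``n`` molecules from a fitted results object."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return []
    net, vocab = results.network, results.vocab
    max_len = net.cfg.max_len
    rng = np.random.default_rng(seed)
    out: list[GeneratedMolecule] = []
    for start in range(0, n, batch_size):
        b = min(batch_size, n - start)
        with no_grad():
            g0 = results._condition(profile, b)
            caches = net.start_cache(g0)
            seqs = np.full((b, max_len), PAD, dtype=np.int64)
            seqs[:, 0] = BOS
            done = np.zeros(b, dtype=bool)
            length = np.ones(b, dtype=int)
            for t in range(1, max_len):
                probs = net.step(seqs[:, t - 1], t - 1, caches)
                nxt = _sample_indices(probs, rng, temperature,
                                      top_k, greedy)
                nxt = np.where(done, PAD, nxt)
                seqs[:, t] = nxt
                length = np.where(done, length, t + 1)
                done |= nxt == EOS
                if done.all():
                    break
            if not done.all():  # truncated at max_len: close the sequences
                for i in np.nonzero(~done)[0]:
                    seqs[i, max_len - 1] = EOS
                    length[i] = max_len

        for i in range(b):
            toks = seqs[i, :length[i]].copy()
            record = None
            if with_attention:
                with no_grad():
                    _, cross = net.predict_proba(
                        toks[None, :], results._condition(profile, 1))
                record = AttentionRecord(weights=cross[:, 0],
                                         n_tokens=len(toks),
                                         gene_count=net.cfg.gene_count)
            out.append(GeneratedMolecule(smiles=vocab.decode(toks),
                                         tokens=toks, attention=record))
    return out
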