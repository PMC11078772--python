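"""Token dictionary and molecule <-> index-sequence conversion."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import codec

PAD, BOS, EOS, UNK = 0, 1, 2, 3
RESERVED = ["<pad>", "<bos>", "<eos>", "<unk>"]


@dataclass
class RejectionReport:
    """SMILES the vocabulary builder could not tokenize, with reasons."""

    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __bool__(self):
        return bool(self.rejected)


class Vocabulary:
    """Bijective token<->index map with fixed reserved indices 0..3.

    Token order is the sorted set of tokens seen in the corpus, so the map
    is a pure function of the corpus *content* (idempotent, order- and
    duplicate-insensitive).
    """

    def __init__(self, tokens: list[str]):
        non_reserved = sorted(set(tokens) - set(RESERVED))
        self._tokens = RESERVED + non_reserved
        self._index = {t: i for i, t in enumerate(self._tokens)}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_corpus(cls, smiles_corpus: list[str]
                    ) -> tuple["Vocabulary", RejectionReport]:
        if not smiles_corpus:
            raise ValueError("cannot build a vocabulary from an empty corpus")
        tokens: set[str] = set()
        report = RejectionReport()
        for smi in dict.fromkeys(smiles_corpus):  # dedupe, keep order
            try:
                tokens.update(codec.encode_smiles(smi))
            except codec.CodecError as exc:
                report.rejected.append((smi, str(exc)))
        if not tokens:
            raise ValueError("no corpus molecule could be tokenized")
        return cls(sorted(tokens)), report

    # -- basic protocol ------------------------------------------------------
    def __len__(self):
        return len(self._tokens)

    def __contains__(self, token: str):
        return token in self._index

    @property
    def tokens(self) -> list[str]:
        return list(self._tokens)

    def index(self, token: str) -> int:
        return self._index[token]

    def token(self, index: int) -> str:
        return self._tokens[index]

    def content_hash(self) -> str:
        import hashlib
        return hashlib.sha256("\n".join(self._tokens).encode()).hexdigest()[:16]

    # -- molecule conversion ---------------------------------------------------
    def encode(self, smiles: str, strict: bool = True) -> np.ndarray:
        """SMILES -> [BOS, token indices..., EOS] (int array)."""
        toks = codec.encode_smiles(smiles)
        idx = [BOS]
        for t in toks:
            if t in self._index:
                idx.append(self._index[t])
            elif strict:
                raise KeyError(f"token {t} of {smiles!r} not in vocabulary")
            else:
                idx.append(UNK)
        idx.append(EOS)
        return np.array(idx, dtype=np.int64)

    def decode(self, indices) -> str:
        """Index sequence -> SMILES.  Total: any sequence decodes validly.

        Reserved indices are skipped (EOS does not truncate here; strip
        generation artifacts before calling if that matters).
        """
        toks = [self._tokens[i] for i in np.asarray(indices).tolist()
                if 0 <= i < len(self._tokens) and i > UNK]
        return codec.tokens_to_smiles(toks)

    # -- persistence ---------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"tokens": self._tokens[len(RESERVED):]})

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        return cls(json.loads(payload)["tokens"])


def max_token_length(smiles_corpus: list[str]) -> int:
    """Longest tokenization in the corpus, counting BOS and EOS."""
    best = 0
    for smi in smiles_corpus:
        try:
            best = max(best, len(codec.encode_smiles(smi)) + 2)
        except codec.CodecError:
            continue
    return best
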