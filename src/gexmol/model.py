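"""Model / Results surface for the gene-expression-conditioned generator.

Usage follows the fitted-model idiom::

    ds = make_dataset(200, seed=1)
    model = TranscriptomeMoleculeModel(ds, d=32, n_layers=2, n_heads=2)
    res = model.fit(epochs=100, seed=1)
    print(res.summary())
    mols = res.generate(ds.profile(0), n=1000, seed=2)

The model is built from a paired dataset (profiles + molecules); ``fit``
runs teacher-forced training of the transformer decoder under the
reconstruction loss and returns a results object carrying the trained
network, the loss history, and everything generation, attention analysis
and evaluation need.
"""

from __future__ import annotations

import json
import time

import numpy as np
import pandas as pd

from . import generation as _generation
from .autodiff import masked_cross_entropy, no_grad
from .data import PairedDataset, ExpressionProfile
from .network import (AttentionRecord, ConditionalMoleculeDecoder,
                      ModelConfig, cell_onehot, make_optimizer)
from .schemes import embed_values
from .vocab import PAD, Vocabulary, max_token_length


class TranscriptomeMoleculeModel:
    """Conditional molecule generator specified by a paired dataset."""

    def __init__(self, dataset: PairedDataset,
                 vocabulary: Vocabulary | None = None,
                 config: ModelConfig | None = None, **overrides):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.dataset = dataset
        if vocabulary is None:
            vocabulary, rejected = Vocabulary.from_corpus(dataset.smiles)
            if rejected:
                raise ValueError(
                    f"{len(rejected.rejected)} molecule(s) cannot be "
                    f"tokenized: {rejected.rejected[:3]} ...")
        self.vocab = vocabulary
        if config is None:
            defaults = dict(vocab_size=len(self.vocab),
                            gene_count=dataset.gene_count,
                            n_cell_lines=len(dataset.cell_registry),
                            max_len=max_token_length(dataset.smiles))
            defaults.update(overrides)
            config = ModelConfig(**defaults)
        self.config = config
        self._prepare_arrays()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cell_col: str = "cell_line",
                       smiles_col: str = "smiles", **kw):
        dataset = PairedDataset.from_frame(df, cell_col=cell_col,
                                           smiles_col=smiles_col)
        return cls(dataset, **kw)

    @classmethod
    def from_csv(cls, path, **kw):
        return cls(PairedDataset.read_csv(path), **kw)

    # ------------------------------------------------------------------
    def _prepare_arrays(self):
        ds, cfg = self.dataset, self.config
        seqs = [self.vocab.encode(s) for s in ds.smiles]
        missing = [s for s, q in zip(ds.smiles, seqs) if q is None]
        if missing:
            raise ValueError(f"vocabulary does not cover: {missing[:3]}")
        L = max(len(q) for q in seqs)
        if L > cfg.max_len:
            raise ValueError(f"corpus needs max_len >= {L}")
        tok = np.full((len(ds), L), PAD, dtype=np.int64)
        for i, q in enumerate(seqs):
            tok[i, :len(q)] = q
        self._tokens = tok
        scheme = cfg.embedding_scheme
        self._raw = embed_values(scheme.clip(ds.values, warn=True), scheme)
        self._cells = cell_onehot(ds.cell_lines, ds.cell_registry)

    # ------------------------------------------------------------------
    def fit(self, epochs: int = 200, batch_size: int = 4, lr: float = 1e-4,
            seed: int = 0, val_fraction: float = 0.0,
            val_indices=None, verbose: bool = False,
            log_file=None, patience: int | None = None
            ) -> "TranscriptomeMoleculeResults":
        """Teacher-forced training; returns the fitted results object.

        All randomness (parameter init, shuffling, dropout) derives from
        ``seed``; identical seeds give bit-identical loss histories.
        """
        if epochs < 1 or batch_size < 1 or lr < 0:
            raise ValueError("epochs/batch_size must be >=1 and lr >= 0")
        n = len(self.dataset)
        rng = np.random.default_rng(seed)
        net = ConditionalMoleculeDecoder(self.config,
                                         np.random.default_rng(seed))
        drop_rng = np.random.default_rng(rng.integers(2 ** 31))
        shuffle_rng = np.random.default_rng(rng.integers(2 ** 31))

        if val_indices is None and val_fraction > 0:
            val_indices = shuffle_rng.permutation(n)[:max(1, int(val_fraction * n))]
        val_indices = np.asarray(val_indices, dtype=int) if val_indices is not None \
            else np.array([], dtype=int)
        train_idx = np.setdiff1d(np.arange(n), val_indices)
        if train_idx.size == 0:
            raise ValueError("no training samples left after the split")

        opt = make_optimizer(net, lr)
        history, val_history = [], []
        log_fh = open(log_file, "a") if log_file else None
        best_val, since_best = np.inf, 0
        t0 = time.time()
        try:
            for epoch in range(epochs):
                order = shuffle_rng.permutation(train_idx)
                nll_sum = tok_sum = 0.0
                for start in range(0, order.size, batch_size):
                    idx = order[start:start + batch_size]
                    loss, n_tok = self._step(net, opt, idx, drop_rng)
                    nll_sum += loss * n_tok
                    tok_sum += n_tok
                # token-weighted: independent of how shuffling groups batches
                epoch_loss = float(nll_sum / tok_sum)
                if not np.isfinite(epoch_loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} "
                        f"(lr={lr}, batch={batch_size}); aborting")
                history.append(epoch_loss)
                if val_indices.size:
                    val_history.append(self._eval_loss(net, val_indices))
                    if val_history[-1] < best_val - 1e-9:
                        best_val, since_best = val_history[-1], 0
                    else:
                        since_best += 1
                        if patience is not None and since_best > patience:
                            break
                if log_fh:
                    rec = {"epoch": epoch, "loss": epoch_loss,
                           "elapsed_s": round(time.time() - t0, 2)}
                    if val_indices.size:
                        rec["val_loss"] = val_history[-1]
                    log_fh.write(json.dumps(rec) + "\n")
                if verbose and (epoch % 10 == 0 or epoch == epochs - 1):
                    print(f"epoch {epoch:4d}  loss {epoch_loss:.4f}")
        finally:
            if log_fh:
                log_fh.close()
        return TranscriptomeMoleculeResults(
            network=net, vocab=self.vocab, config=self.config,
            cell_registry=tuple(self.dataset.cell_registry),
            genes=list(self.dataset.genes),
            training_smiles=list(self.dataset.smiles),
            loss_history=np.array(history),
            val_history=np.array(val_history),
            fit_params={"epochs": epochs, "batch_size": batch_size,
                        "lr": lr, "seed": seed,
                        "n_train": int(train_idx.size),
                        "n_val": int(val_indices.size)})

    def _step(self, net, opt, idx, drop_rng) -> float:
        tok = self._tokens[idx]
        g0 = net.encode_condition(self._cells[idx], self._raw[idx])
        inputs, targets = tok[:, :-1], tok[:, 1:]
        pad_keys = inputs == PAD
        logits, _ = net.forward(inputs, g0, pad_mask=pad_keys,
                                rng=drop_rng, training=True)
        mask = targets != PAD
        loss = masked_cross_entropy(logits, targets, mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
        return float(loss.data), int(mask.sum())

    def _eval_loss(self, net, idx) -> float:
        with no_grad():
            tok = self._tokens[idx]
            g0 = net.encode_condition(self._cells[idx], self._raw[idx])
            inputs, targets = tok[:, :-1], tok[:, 1:]
            logits, _ = net.forward(inputs, g0, pad_mask=inputs == PAD)
            return float(masked_cross_entropy(logits, targets,
                                              targets != PAD).data)


class TranscriptomeMoleculeResults:
    """Fitted generator: parameters, history, generation and diagnostics."""

    def __init__(self, network: ConditionalMoleculeDecoder, vocab: Vocabulary,
                 config: ModelConfig, cell_registry, genes, training_smiles,
                 loss_history, val_history=None, fit_params=None):
        self.network = network
        self.vocab = vocab
        self.config = config
        self.cell_registry = tuple(cell_registry)
        self.genes = list(genes)
        self.training_smiles = list(training_smiles)
        self.loss_history = np.asarray(loss_history)
        self.val_history = np.asarray(val_history if val_history is not None
                                      else [])
        self.fit_params = dict(fit_params or {})

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Gene-expression-conditioned molecule generator",
            "=" * 54,
            f"{'hidden size d':28s}{cfg.d:>10d}",
            f"{'decoder layers':28s}{cfg.n_layers:>10d}",
            f"{'attention heads':28s}{cfg.n_heads:>10d}",
            f"{'feed-forward width':28s}{cfg.d_ff:>10d}",
            f"{'embedding scheme':28s}{cfg.scheme:>18s}",
            f"{'genes / conditioning rows':28s}"
            f"{cfg.gene_count:>6d} /{cfg.gene_count + 1:>5d}",
            f"{'vocabulary size':28s}{cfg.vocab_size:>10d}",
            f"{'parameters':28s}{self.n_parameters:>10d}",
            "-" * 54,
        ]
        for k, v in self.fit_params.items():
            lines.append(f"{k:28s}{v!s:>18s}")
        if self.loss_history.size:
            lines.append(f"{'final train loss':28s}"
                         f"{self.loss_history[-1]:>18.4f}")
        if self.val_history.size:
            lines.append(f"{'final val loss':28s}"
                         f"{self.val_history[-1]:>18.4f}")
        return "\n".join(lines)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.network.parameters()))

    # -- conditioning helpers -------------------------------------------
    def _condition(self, profile: ExpressionProfile, batch: int):
        profile.validate(self.config.gene_count, self.cell_registry,
                         self.config.embedding_scheme)
        scheme = self.config.embedding_scheme
        raw = embed_values(scheme.clip(profile.values), scheme)
        raw = np.broadcast_to(raw, (batch,) + raw.shape).copy()
        cells = cell_onehot([profile.cell_line] * batch, self.cell_registry)
        return self.network.encode_condition(cells, raw)

    # -- generation ------------------------------------------------------
    def generate(self, profile: ExpressionProfile, n: int = 100,
                 temperature: float = 1.0, top_k: int | None = None,
                 greedy: bool = False, seed: int = 0,
                 with_attention: bool = False, batch_size: int = 100):
        """Sample ``n`` molecules conditioned on ``profile``; reproducible
        under ``seed``.  Returns a list of GeneratedMolecule."""
        return _generation.sample(self, profile, n, temperature=temperature,
                                  top_k=top_k, greedy=greedy, seed=seed,
                                  with_attention=with_attention,
                                  batch_size=batch_size)

    # -- reconstruction / attention -------------------------------------
    def reconstruct(self, profile: ExpressionProfile, smiles: str
                    ) -> tuple[np.ndarray, AttentionRecord]:
        """Teacher-forced pass; returns (greedy token predictions,
        cross-attention record) for one (profile, molecule) pair."""
        seq = self.vocab.encode(smiles)
        with no_grad():
            g0 = self._condition(profile, 1)
            probs, cross = self.network.predict_proba(seq[None, :-1], g0)
        record = AttentionRecord(weights=cross[:, 0],
                                 n_tokens=len(seq) - 1,
                                 gene_count=self.config.gene_count)
        return probs[0].argmax(axis=-1), record

    def reconstruction_accuracy(self, dataset: PairedDataset) -> float:
        """Greedy teacher-forced token accuracy over a dataset."""
        correct = total = 0
        for i in range(len(dataset)):
            seq = self.vocab.encode(dataset.smiles[i])
            pred, _ = self.reconstruct(dataset.profile(i), dataset.smiles[i])
            target = seq[1:]
            correct += int((pred[:len(target)] == target).sum())
            total += len(target)
        return correct / total

    def attention_records(self, dataset: PairedDataset
                          ) -> list[AttentionRecord]:
        """Per-sample cross-attention records from reconstruction passes."""
        return [self.reconstruct(dataset.profile(i), dataset.smiles[i])[1]
                for i in range(len(dataset))]

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param_{i:04d}": a
                  for i, a in enumerate(self.network.state_arrays())}
        meta = {"config": self.config.to_dict(),
                "vocab": json.loads(self.vocab.to_json()),
                "vocab_hash": self.vocab.content_hash(),
                "cell_registry": list(self.cell_registry),
                "genes": self.genes,
                "training_smiles": self.training_smiles,
                "fit_params": self.fit_params}
        np.savez(path, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            loss_history=self.loss_history, val_history=self.val_history,
            **arrays)

    @classmethod
    def load(cls, path) -> "TranscriptomeMoleculeResults":
        with np.load(path) as payload:
            meta = json.loads(bytes(payload["meta"]).decode())
            cfg = ModelConfig.from_dict(meta["config"])
            vocab = Vocabulary(meta["vocab"]["tokens"])
            if vocab.content_hash() != meta["vocab_hash"]:
                raise ValueError("checkpoint vocabulary hash mismatch")
            net = ConditionalMoleculeDecoder(cfg, np.random.default_rng(0))
            arrays = [payload[k] for k in sorted(payload.files)
                      if k.startswith("param_")]
            net.load_state_arrays(arrays)
            return cls(network=net, vocab=vocab, config=cfg,
                       cell_registry=meta["cell_registry"],
                       genes=meta["genes"],
                       training_smiles=meta["training_smiles"],
                       loss_history=payload["loss_history"],
                       val_history=payload["val_history"],
                       fit_params=meta["fit_params"])
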