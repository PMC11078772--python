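"""Four-scheme comparison harness.

Trains one model per numeric embedding scheme on the same paired dataset,
samples a fixed number of molecules from each, and tabulates
validity / uniqueness / novelty / internal diversity per scheme, with the
seeds and scale recorded alongside.  Intended to be run at desk scale
(reduced width/epochs) — the ranking between schemes, not the absolute
numbers, is the object of interest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import PairedDataset
from .metrics import evaluate_set
from .model import TranscriptomeMoleculeModel
from .schemes import SCHEME_NAMES

DEFAULT_SCHEMES = SCHEME_NAMES


def compare_schemes(dataset: PairedDataset,
                    schemes=DEFAULT_SCHEMES,
                    epochs: int = 100, batch_size: int = 4,
                    lr: float = 1e-4, n_generate: int = 500,
                    seed: int = 0, temperature: float = 1.0,
                    profile_index: int = 0, verbose: bool = False,
                    **model_kwargs) -> pd.DataFrame:
    """One row per scheme: validity / uniqueness / novelty / InDiv.

    The same dataset, fit seed and sampling seed are used for every scheme,
    so rows differ only in the numeric embedding of the conditioning values.
    """
    rows = []
    for scheme in schemes:
        model = TranscriptomeMoleculeModel(dataset, scheme=scheme,
                                           **model_kwargs)
        res = model.fit(epochs=epochs, batch_size=batch_size, lr=lr,
                        seed=seed, verbose=verbose)
        mols = res.generate(dataset.profile(profile_index), n=n_generate,
                            temperature=temperature, seed=seed + 1)
        report = evaluate_set([m.smiles for m in mols], dataset.smiles,
                              with_properties=False)
        rows.append({"scheme": scheme,
                     "validity": report.validity,
                     "novelty": report.novelty,
                     "uniqueness": report.uniqueness,
                     "internal_diversity": report.internal_diversity,
                     "n_generated": n_generate,
                     "epochs": epochs, "fit_seed": seed,
                     "sample_seed": seed + 1,
                     "final_loss": float(res.loss_history[-1])})
    return pd.DataFrame(rows)


def overfit_probe(dataset: PairedDataset, epochs: int = 300,
                  seed: int = 0, lr: float = 1e-3, batch_size: int = 4,
                  **model_kwargs) -> dict:
    """Small-capacity memorization check: fit a tiny model on a tiny
    dataset and report greedy teacher-forced reconstruction accuracy.

    The learning rate defaults to 1e-3 (not the full-scale 1e-4): a
    memorization probe over a few hundred epochs on a width-32 model wants
    the fastest stable step size, and Adam at 1e-3 is the standard choice
    at this scale.
    """
    defaults = dict(d=32, n_layers=2, n_heads=2, d_ff=64, dropout=0.0)
    defaults.update(model_kwargs)
    model = TranscriptomeMoleculeModel(dataset, **defaults)
    res = model.fit(epochs=epochs, seed=seed, lr=lr, batch_size=batch_size)
    return {"accuracy": res.reconstruction_accuracy(dataset),
            "final_loss": float(res.loss_history[-1]),
            "results": res}
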