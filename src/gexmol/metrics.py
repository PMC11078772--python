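"""Evaluation suite for generated molecule sets.

Validity, uniqueness, novelty, internal diversity (1 minus the mean
pairwise RDKFingerprint Tanimoto similarity over all ordered pairs,
self-pairs included — so a single-molecule set scores exactly 0), plus
per-molecule QED, Ertl synthetic-accessibility, logP and molecular weight.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import Crippen, Descriptors, QED, RDConfig

RDLogger.DisableLog("rdApp.*")

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (Ertl & Schuffenhauer SA score, ships with RDKit)


def _mol(smiles) -> Chem.Mol | None:
    if smiles is None:
        return None
    return Chem.MolFromSmiles(smiles)


def canonical(smiles) -> str | None:
    mol = _mol(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def validity(smiles_list) -> float:
    """Fraction of entries whose SMILES parses (None counts as invalid)."""
    if not len(smiles_list):
        raise ValueError("validity of an empty set is undefined")
    return float(np.mean([_mol(s) is not None for s in smiles_list]))


def valid_subset(smiles_list) -> list[str]:
    return [s for s in smiles_list if _mol(s) is not None]


def uniqueness(valid_smiles) -> float:
    """Fraction of distinct canonical forms among valid molecules."""
    if not len(valid_smiles):
        raise ValueError("uniqueness of an empty set is undefined")
    canon = [canonical(s) for s in valid_smiles]
    return len(set(canon)) / len(canon)


def novelty(valid_smiles, training_set) -> float:
    """Fraction of valid molecules whose canonical form is not in training."""
    if not len(valid_smiles):
        raise ValueError("novelty of an empty set is undefined")
    train = {canonical(s) for s in training_set}
    canon = [canonical(s) for s in valid_smiles]
    return float(np.mean([c not in train for c in canon]))


def internal_diversity(smiles_list) -> float:
    """1 - mean Tanimoto similarity over all ordered pairs (incl. self)."""
    mols = [_mol(s) for s in smiles_list]
    mols = [m for m in mols if m is not None and m.GetNumAtoms() > 0]
    if not mols:
        raise ValueError("internal diversity of an empty set is undefined")
    fps = [Chem.RDKFingerprint(m) for m in mols]
    n = len(fps)
    total = 0.0
    for i, fp in enumerate(fps):
        total += float(np.sum(DataStructs.BulkTanimotoSimilarity(fp, fps)))
    return 1.0 - total / (n * n)


def property_table(smiles_list) -> pd.DataFrame:
    """Per-molecule QED, SA, logP, MW; failures recorded as NaN, not fatal."""
    rows = []
    for s in smiles_list:
        mol = _mol(s)
        rec = {"smiles": s, "qed": np.nan, "sa": np.nan,
               "logp": np.nan, "mw": np.nan}
        if mol is not None and mol.GetNumAtoms() > 0:
            try:
                rec.update(qed=QED.qed(mol),
                           sa=sascorer.calculateScore(mol),
                           logp=Crippen.MolLogP(mol),
                           mw=Descriptors.MolWt(mol))
            except Exception:
                pass
        rows.append(rec)
    return pd.DataFrame(rows, columns=["smiles", "qed", "sa", "logp", "mw"])


@dataclass
class GenerationReport:
    """Aggregate metrics plus the per-molecule property table."""

    n_generated: int
    validity: float
    uniqueness: float
    novelty: float
    internal_diversity: float
    n_trivial: int = 0
    properties: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def as_dict(self) -> dict:
        return {"n_generated": self.n_generated, "validity": self.validity,
                "uniqueness": self.uniqueness, "novelty": self.novelty,
                "internal_diversity": self.internal_diversity,
                "n_trivial": self.n_trivial}


def evaluate_set(generated_smiles, training_set,
                 with_properties: bool = True) -> GenerationReport:
    valid = valid_subset(generated_smiles)
    nontrivial = [s for s in valid if s != ""]
    return GenerationReport(
        n_generated=len(generated_smiles),
        validity=validity(generated_smiles),
        uniqueness=uniqueness(valid),
        novelty=novelty(valid, training_set),
        internal_diversity=internal_diversity(nontrivial),
        n_trivial=len(valid) - len(nontrivial),
        properties=property_table(nontrivial) if with_properties
        else pd.DataFrame())


def plot_property_distributions(table: pd.DataFrame,
                                reference: pd.DataFrame | None = None,
                                path=None):
    """Histogram panels of MW / logP / QED / SA (generated vs reference)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    props = ["mw", "logp", "qed", "sa"]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, prop in zip(axes.ravel(), props):
        ax.hist(table[prop].dropna(), bins=30, alpha=0.6, density=True,
                label="generated")
        if reference is not None and prop in reference:
            ax.hist(reference[prop].dropna(), bins=30, alpha=0.4,
                    density=True, label="reference")
        ax.set_xlabel(prop.upper())
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
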