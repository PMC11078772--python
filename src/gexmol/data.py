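"""Paired (expression profile, molecule) datasets: containers, IO, synthesis.

The synthetic generator emulates the structure of an L1000-derived training
set: each record couples a cell-line label and a 978-long vector of
per-gene expression differences (sample minus control, one decimal place)
with the SMILES of the perturbing molecule.  Associations are *planted*:
every pool molecule is assigned one (or more) informative genes whose
difference value is shifted by +/- effect_size above the Gaussian baseline,
giving downstream attention attribution a known ground truth.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemes import EmbeddingScheme, get_scheme

#: the 14 highest-coverage cell lines of the L1000 compound-perturbation set
DEFAULT_CELL_LINES = ("A375", "A549", "HA1E", "HEK293", "HELA", "HEPG2",
                      "HT29", "JURKAT", "MCF10A", "MCF7", "MDAMB231", "PC3",
                      "THP1", "YAPC")

DEFAULT_GENE_COUNT = 978


def gene_names(gene_count: int = DEFAULT_GENE_COUNT) -> list[str]:
    return [f"G{i:04d}" for i in range(gene_count)]


def load_molecule_pool() -> list[str]:
    """The bundled pool of small drug-like molecules (codec-representable)."""
    text = (importlib.resources.files("gexmol") / "molecule_pool.smi").read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


@dataclass
class ExpressionProfile:
    """One cell line plus its ordered vector of gene-expression differences."""

    cell_line: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def validate(self, gene_count: int = DEFAULT_GENE_COUNT,
                 registry=DEFAULT_CELL_LINES,
                 scheme: EmbeddingScheme | None = None) -> "ExpressionProfile":
        if self.cell_line not in registry:
            raise KeyError(f"unknown cell line {self.cell_line!r}; "
                           f"registry has {len(registry)} entries")
        if self.values.shape != (gene_count,):
            raise ValueError(
                f"expected {gene_count} values, got {self.values.shape}")
        if np.any(np.abs(self.values * 10 - np.round(self.values * 10)) > 1e-6):
            raise ValueError("values must have exactly one fractional digit")
        if scheme is not None and scheme.max_abs is not None \
                and np.any(np.abs(self.values) > scheme.max_abs + 1e-9):
            raise ValueError(
                f"profile exceeds the {scheme.name} representable range")
        return self


@dataclass
class PairedDataset:
    """Aligned (profile, molecule) records plus provenance of planted structure."""

    cell_lines: list[str]
    values: np.ndarray          # (n_samples, gene_count)
    smiles: list[str]
    genes: list[str] = field(default_factory=list)
    cell_registry: tuple = DEFAULT_CELL_LINES
    assoc: dict = field(default_factory=dict)   # smiles -> {gene_idx: sign}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.genes:
            self.genes = gene_names(self.values.shape[1])
        n = self.values.shape[0]
        if not (len(self.cell_lines) == n == len(self.smiles)):
            raise ValueError("cell_lines, values and smiles must align")

    def __len__(self):
        return self.values.shape[0]

    @property
    def gene_count(self) -> int:
        return self.values.shape[1]

    def profile(self, i: int) -> ExpressionProfile:
        return ExpressionProfile(self.cell_lines[i], self.values[i])

    # -- IO -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.genes)
        df.insert(0, "cell_line", self.cell_lines)
        df["smiles"] = self.smiles
        return df

    def to_csv(self, path, sep=",") -> None:
        self.to_frame().to_csv(path, index=False, sep=sep,
                               float_format="%.1f")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_col: str = "cell_line",
                   smiles_col: str = "smiles",
                   cell_registry=DEFAULT_CELL_LINES) -> "PairedDataset":
        genes = [c for c in df.columns if c not in (cell_col, smiles_col)]
        return cls(cell_lines=df[cell_col].tolist(),
                   values=df[genes].to_numpy(dtype=float),
                   smiles=df[smiles_col].tolist(),
                   genes=genes, cell_registry=cell_registry)

    @classmethod
    def read_csv(cls, path, sep=None, **kw) -> "PairedDataset":
        df = pd.read_csv(path, sep=sep, engine="python")
        return cls.from_frame(df, **kw)


def difference_and_round(sample, control, max_abs: float = 51.1) -> np.ndarray:
    """Element-wise sample - control, rounded to one decimal, range-clipped."""
    sample = np.asarray(sample, dtype=float)
    control = np.asarray(control, dtype=float)
    if sample.shape != control.shape:
        raise ValueError(
            f"sample/control length mismatch: {sample.shape} vs {control.shape}")
    diff = np.round(sample - control, 1)
    over = np.abs(diff) > max_abs + 1e-9
    if over.any():
        warnings.warn(
            f"{int(over.sum())} difference value(s) exceed +/-{max_abs}; "
            "clipping to the representable range", stacklevel=2)
        diff = np.clip(diff, -max_abs, max_abs)
    return diff


def make_dataset(n_samples: int,
                 n_cell_lines: int = len(DEFAULT_CELL_LINES),
                 gene_count: int = DEFAULT_GENE_COUNT,
                 molecule_pool: list[str] | None = None,
                 assoc: dict | None = None,
                 noise_sd: float = 1.0,
                 effect_size: float = 5.0,
                 seed: int = 0,
                 scheme: str | EmbeddingScheme = "tenfold_binary"
                 ) -> PairedDataset:
    """Sample a paired dataset with planted gene->molecule associations.

    Each record draws a cell line uniformly, a molecule uniformly from the
    pool, a baseline difference vector N(0, noise_sd), then shifts the
    molecule's informative gene(s) by sign * effect_size.  Values are
    rounded to one decimal and clipped to the embedding scheme's range, so
    every generated profile is representable by all discrete schemes whose
    limit is at least the clip bound.
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    pool = molecule_pool if molecule_pool is not None else load_molecule_pool()
    if not pool:
        raise ValueError("molecule pool is empty")
    registry = tuple(DEFAULT_CELL_LINES[:n_cell_lines]) if \
        n_cell_lines <= len(DEFAULT_CELL_LINES) else tuple(
            [f"CL{i:03d}" for i in range(n_cell_lines)])

    rng = np.random.default_rng(seed)
    if assoc is None:
        informative = rng.choice(gene_count, size=len(pool), replace=(
            len(pool) > gene_count))
        signs = rng.choice([-1.0, 1.0], size=len(pool))
        assoc = {smi: {int(g): float(s)}
                 for smi, g, s in zip(pool, informative, signs)}
    else:
        for smi, genes_ in assoc.items():
            for g in genes_:
                if not 0 <= int(g) < gene_count:
                    raise ValueError(f"gene index {g} out of range for "
                                     f"gene_count={gene_count}")

    cells = [registry[i] for i in rng.integers(0, len(registry), n_samples)]
    mols = [pool[i] for i in rng.integers(0, len(pool), n_samples)]
    values = rng.normal(0.0, noise_sd, size=(n_samples, gene_count)) \
        if noise_sd > 0 else np.zeros((n_samples, gene_count))
    for row, smi in enumerate(mols):
        for g, sign in assoc.get(smi, {}).items():
            values[row, int(g)] += float(sign) * effect_size
    values = np.round(values, 1)
    values = scheme.clip(values, warn=False) if scheme.max_abs is not None \
        else values

    return PairedDataset(cell_lines=cells, values=values, smiles=mols,
                         genes=gene_names(gene_count),
                         cell_registry=registry, assoc=assoc)
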