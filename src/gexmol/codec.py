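"""Robust self-referencing molecular string codec.

Molecules are written as token sequences (SELFIES-style) in which *every*
sequence — including uniformly random ones — derives a chemically valid
structure.  Validity is enforced at decode time by a derivation automaton
that caps each requested bond at the remaining valence of both endpoints and
silently drops branch/ring instructions that cannot be realized.  This
structural guarantee is what lets a conditional generator emit 100% valid
molecules regardless of how well it is trained.

Token forms::

    [C] [=C] [#C] ...        atom with the bond order joining it to the chain
    [Branch1] i ...          side chain; i (1 index token) gives its length
    [Branch2] i j ...        side chain with a 2-token (base-16) length
    [Ring1] i                ring bond to the atom i+1 steps back
    [Ring2] i j              ring bond with a 2-token distance
    [=Ring1] / [=Ring2]      double-bond ring closure

Every token doubles as an index digit (its alphabet position mod 16) when it
follows a Branch/Ring token, so no sequence can be ill-formed.

Supported chemistry: neutral organic molecules over C, N, O, F, S, P, Cl,
Br, I — kekulized bonds, no stereochemistry, charges, isotopes or radicals.
Encoding rejects anything outside this subset with :class:`CodecError`;
decoding never fails.
"""

from __future__ import annotations

import re
from collections import deque

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 6, "P": 5,
               "Cl": 1, "Br": 1, "I": 1}

_PREFIX = {1: "", 2: "=", 3: "#"}
_ORDER = {"": 1, "=": 2, "#": 3}
_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
              3: Chem.BondType.TRIPLE}

# 16 atom tokens first, so index digits 0..15 are all atom tokens.
ATOM_TOKENS = ["[C]", "[=C]", "[#C]", "[N]", "[=N]", "[#N]", "[O]", "[=O]",
               "[S]", "[=S]", "[P]", "[=P]", "[F]", "[Cl]", "[Br]", "[I]"]
STRUCT_TOKENS = ["[Branch1]", "[Branch2]", "[Ring1]", "[Ring2]",
                 "[=Ring1]", "[=Ring2]"]
ALPHABET = ATOM_TOKENS + STRUCT_TOKENS
_INDEX_OF = {tok: i % 16 for i, tok in enumerate(ALPHABET)}

_ATOM_RE = re.compile(r"^\[([=#]?)(C[lr]?|N|O|S|P|F|Br|I)\]$")
_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")


class CodecError(ValueError):
    """Molecule outside the codec's representable subset."""


def tokens_to_string(tokens: list[str]) -> str:
    return "".join(tokens)


def string_to_tokens(s: str) -> list[str]:
    return _TOKEN_RE.findall(s)


def index_value(token: str) -> int:
    """The index digit a token contributes after a Branch/Ring token."""
    return _INDEX_OF.get(token, 0)


# --------------------------------------------------------------------------
# decoding: token sequence -> molecule (total function)
# --------------------------------------------------------------------------

class _Graph:
    def __init__(self):
        self.symbols: list[str] = []
        self.bonds: dict[tuple[int, int], int] = {}
        self.used: list[int] = []

    def add_atom(self, sym: str) -> int:
        self.symbols.append(sym)
        self.used.append(0)
        return len(self.symbols) - 1

    def free(self, i: int) -> int:
        return MAX_VALENCE[self.symbols[i]] - self.used[i]

    def add_bond(self, i: int, j: int, order: int) -> None:
        key = (min(i, j), max(i, j))
        self.bonds[key] = order
        self.used[i] += order
        self.used[j] += order

    def has_bond(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.bonds


def _pop_index(toks: deque, k: int) -> int | None:
    """Read k index-digit tokens (base 16, big-endian)."""
    if len(toks) < k:
        toks.clear()
        return None
    value = 0
    for _ in range(k):
        value = value * 16 + index_value(toks.popleft())
    return value


def _derive(graph: _Graph, toks: deque, attach: int | None,
            reserve_first: bool) -> None:
    current = attach
    first_bond = attach is not None
    while toks:
        tok = toks.popleft()
        m = _ATOM_RE.match(tok)
        if m:
            order = _ORDER[m.group(1)]
            sym = m.group(2)
            if current is None:
                current = graph.add_atom(sym)
            else:
                avail = graph.free(current)
                if reserve_first and first_bond:
                    avail -= 1
                if avail <= 0:
                    return  # chain cannot be extended; derivation stops
                new = graph.add_atom(sym)
                order = min(order, avail, MAX_VALENCE[sym])
                graph.add_bond(current, new, order)
                current = new
            first_bond = False
        elif tok in ("[Branch1]", "[Branch2]"):
            k = 1 if tok == "[Branch1]" else 2
            n = _pop_index(toks, k)
            if n is None:
                return
            length = n + 1
            sub = deque(toks.popleft() for _ in range(min(length, len(toks))))
            if current is not None and graph.free(current) >= 2:
                _derive(graph, sub, attach=current, reserve_first=True)
            # else: branch cannot attach; its tokens are discarded
        elif tok in ("[Ring1]", "[Ring2]", "[=Ring1]", "[=Ring2]"):
            order = 2 if tok.startswith("[=") else 1
            k = 2 if tok.endswith("2]") else 1
            n = _pop_index(toks, k)
            if n is None:
                return
            if current is None:
                continue
            target = current - (n + 1)
            if target < 0 or target == current or graph.has_bond(current, target):
                continue
            order = min(order, graph.free(current), graph.free(target))
            if order >= 1:
                graph.add_bond(current, target, order)
        # any other token (PAD/BOS/EOS/UNK or foreign) is skipped


def decode_tokens(tokens: list[str]) -> Chem.Mol:
    """Derive a sanitized RDKit molecule from any token sequence.

    An all-structural or empty sequence yields the (valid) empty molecule.
    """
    graph = _Graph()
    _derive(graph, deque(tokens), attach=None, reserve_first=False)
    rw = Chem.RWMol()
    for sym in graph.symbols:
        rw.AddAtom(Chem.Atom(sym))
    for (i, j), order in graph.bonds.items():
        rw.AddBond(i, j, _BOND_TYPE[order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def tokens_to_smiles(tokens: list[str]) -> str:
    """Canonical SMILES of the derived molecule ('' for an empty derivation)."""
    mol = decode_tokens(tokens)
    if mol.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(mol)


# --------------------------------------------------------------------------
# encoding: molecule -> token sequence
# --------------------------------------------------------------------------

def _prepare_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CodecError(f"unparseable SMILES: {smiles!r}")
    if "." in Chem.MolToSmiles(mol):
        raise CodecError(f"multi-fragment molecules not supported: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in MAX_VALENCE:
            raise CodecError(f"element {sym} outside the supported set")
        if atom.GetFormalCharge() != 0:
            raise CodecError(f"charged atoms not supported: {smiles!r}")
        if atom.GetIsotope() != 0 or atom.GetNumRadicalElectrons() != 0:
            raise CodecError(f"isotopes/radicals not supported: {smiles!r}")
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        if atom.GetExplicitValence() > MAX_VALENCE[atom.GetSymbol()]:
            raise CodecError(
                f"valence of {atom.GetSymbol()} exceeds codec maximum")
    return mol


def _atom_token(sym: str, order: int) -> str:
    return f"[{_PREFIX[order]}{sym}]"


def _index_tokens(n: int, k: int) -> list[str]:
    digits = []
    for _ in range(k):
        digits.append(ALPHABET[n % 16])
        n //= 16
    if n:
        raise CodecError("index overflow")
    return digits[::-1]


def _ring_tokens(order: int, n: int) -> list[str]:
    if order == 3:
        raise CodecError("triple-bond ring closures not supported")
    prefix = "=" if order == 2 else ""
    if n < 16:
        return [f"[{prefix}Ring1]"] + _index_tokens(n, 1)
    if n < 256:
        return [f"[{prefix}Ring2]"] + _index_tokens(n, 2)
    raise CodecError("ring span too large")


def _branch_wrap(sub: list[str]) -> list[str]:
    n = len(sub) - 1
    if n < 16:
        return ["[Branch1]"] + _index_tokens(n, 1) + sub
    if n < 256:
        return ["[Branch2]"] + _index_tokens(n, 2) + sub
    raise CodecError("branch too long")


def encode_smiles(smiles: str) -> list[str]:
    """Token sequence that decodes back to the same canonical molecule."""
    mol = _prepare_mol(smiles)
    if mol.GetNumAtoms() == 0:
        return []
    order_of: dict[int, int] = {}
    counter = [0]
    ring_done: set[frozenset] = set()

    def bond_int(i: int, j: int) -> int:
        return int(mol.GetBondBetweenAtoms(i, j).GetBondTypeAsDouble())

    def visit(a: int, parent: int | None) -> list[str]:
        order_of[a] = counter[0]
        counter[0] += 1
        atom = mol.GetAtomWithIdx(a)
        first = parent is None
        toks = [_atom_token(atom.GetSymbol(),
                            1 if first else bond_int(parent, a))]
        nbr_ids = sorted(n.GetIdx() for n in atom.GetNeighbors())
        for b in nbr_ids:
            key = frozenset((a, b))
            if b in order_of and b != parent and key not in ring_done:
                ring_done.add(key)
                toks += _ring_tokens(bond_int(a, b), order_of[a] - order_of[b] - 1)
        while True:
            unvisited = [b for b in nbr_ids if b not in order_of]
            if not unvisited:
                break
            b = unvisited[0]
            ring_done.add(frozenset((a, b)))  # tree bond, never a ring closure
            sub = visit(b, a)
            if len(unvisited) == 1:
                toks += sub
            else:
                toks += _branch_wrap(sub)
        return toks

    return visit(0, None)


def roundtrips(smiles: str) -> bool:
    """True if encode->decode reproduces the canonical (stereo-free) form."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    Chem.RemoveStereochemistry(mol)
    return tokens_to_smiles(encode_smiles(smiles)) == Chem.MolToSmiles(mol)
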