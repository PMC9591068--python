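"""A compact SELFIES encoder/decoder for the common organic subset.

SELFIES is a molecular string representation in which every word (a
bracketed symbol such as ``[C]``, ``[=O]``, ``[Branch1]``, ``[Ring1]``)
corresponds to a chemically meaningful construct, so token lists are
chemically interpretable in a way raw SMILES characters are not.

This module implements a self-contained codec covering neutral organic
molecules built from B, C, N, O, S, P and the halogens with single,
double and triple bonds, branches (``Branch1``/``Branch2``) and rings
(``Ring1``/``Ring2``). Aromatic systems are handled by kekulizing first.
Charged, isotopic, stereo-annotated or otherwise exotic SMILES raise
``ValueError("SELFIES conversion failed")`` and are skipped upstream.

Encoding always starts from the RDKit-canonical kekulized form of the
input, so the word list is canonical per molecule; decoding is intended
for streams produced by this encoder (it performs no valence-capping
derivation rules for arbitrary streams) and is used to verify round
trips: ``decode(encode(s))`` is the same molecule as ``s``.
"""

from __future__ import annotations

import re

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

_ATOMS = ("Cl", "Br", "B", "C", "N", "O", "S", "P", "F", "I")
_BOND_CHAR = {"": Chem.BondType.SINGLE, "=": Chem.BondType.DOUBLE,
              "#": Chem.BondType.TRIPLE}

# SELFIES index alphabet: the symbol at position n encodes the integer n.
INDEX_ALPHABET = ["[C]", "[Ring1]", "[Ring2]", "[Branch1]", "[=Branch1]",
                  "[#Branch1]", "[Branch2]", "[=Branch2]", "[#Branch2]",
                  "[O]", "[N]", "[=N]", "[=C]", "[#C]", "[S]", "[P]"]
_INDEX_OF = {s: i for i, s in enumerate(INDEX_ALPHABET)}

_TOKEN_RE = re.compile(r"Cl|Br|[BCNOSPFI]|[=#]|[()]|[0-9]")


class _ConversionError(ValueError):
    pass


def _fail() -> "_ConversionError":
    return _ConversionError("SELFIES conversion failed")


def _canonical_kekule(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise _fail()
    for atom in mol.GetAtoms():
        if (atom.GetFormalCharge() != 0 or atom.GetIsotope() != 0
                or atom.GetNumRadicalElectrons() != 0
                or atom.GetSymbol() not in _ATOMS):
            raise _fail()
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
        return Chem.MolToSmiles(mol, kekuleSmiles=True)
    except Exception as exc:  # noqa: BLE001 - rdkit raises various types
        raise _fail() from exc


def _lex(smiles: str) -> list[str]:
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise _fail()
    return tokens


def _index_symbols(n: int) -> list[str]:
    """Encode a non-negative integer as one (n<16) or two index symbols."""
    if n < 16:
        return [INDEX_ALPHABET[n]]
    if n < 256:
        return [INDEX_ALPHABET[n // 16], INDEX_ALPHABET[n % 16]]
    raise _fail()


def encode_selfies(smiles: str) -> list[str]:
    """Translate a SMILES string into its SELFIES word list."""
    if not smiles:
        raise ValueError("empty sequence")
    canonical = _canonical_kekule(smiles)
    tokens = _lex(canonical)
    out: list[str] = []
    atom_counter = [0]  # derived-atom count, shared across branch recursion
    open_rings: dict[str, tuple[int, str]] = {}
    pos = [0]

    def emit_chain(symbols: list[str]) -> None:
        bond = ""
        while pos[0] < len(tokens):
            tok = tokens[pos[0]]
            if tok in ("=", "#"):
                bond = tok
                pos[0] += 1
            elif tok == "(":
                pos[0] += 1
                inner: list[str] = []
                emit_chain(inner)
                if not tokens[pos[0] - 1] == ")":
                    raise _fail()
                n = len(inner)
                branch_bond = inner[0][1] if inner[0][1] in "=#" else ""
                kind = "Branch1" if n <= 16 else "Branch2"
                symbols.append(f"[{branch_bond}{kind}]")
                symbols.extend(_index_symbols(n - 1))
                symbols.extend(inner)
            elif tok == ")":
                pos[0] += 1
                return
            elif tok.isdigit():
                pos[0] += 1
                if tok in open_rings:
                    partner, open_bond = open_rings.pop(tok)
                    ring_bond = bond or open_bond
                    dist = atom_counter[0] - 1 - partner  # Q + 1
                    kind = "Ring1" if dist <= 16 else "Ring2"
                    symbols.append(f"[{ring_bond}{kind}]")
                    symbols.extend(_index_symbols(dist - 1))
                else:
                    open_rings[tok] = (atom_counter[0] - 1, bond)
                bond = ""
            else:  # atom
                pos[0] += 1
                symbols.append(f"[{bond}{tok}]")
                atom_counter[0] += 1
                bond = ""
        return

    emit_chain(out)
    if open_rings or pos[0] != len(tokens):
        raise _fail()
    return out


_ATOM_SYM_RE = re.compile(r"\[([=#]?)(Cl|Br|[BCNOSPFI])\]")
_CTRL_SYM_RE = re.compile(r"\[([=#]?)(Branch[12]|Ring[12])\]")


def decode_selfies(symbols: list[str]) -> str:
    """Rebuild a canonical SMILES string from an encoded word list."""
    mol = Chem.RWMol()
    derived: list[int] = []  # rdkit atom indices in derivation order

    def read_index(pos: int, n_syms: int) -> tuple[int, int]:
        vals = []
        for k in range(n_syms):
            if pos + k >= len(symbols) or symbols[pos + k] not in _INDEX_OF:
                raise _fail()
            vals.append(_INDEX_OF[symbols[pos + k]])
        n = vals[0] if n_syms == 1 else vals[0] * 16 + vals[1]
        return n, pos + n_syms

    def derive(pos: int, end: int, parent: int | None) -> int:
        prev = parent
        while pos < end:
            sym = symbols[pos]
            m = _ATOM_SYM_RE.fullmatch(sym)
            if m:
                idx = mol.AddAtom(Chem.Atom(m.group(2)))
                derived.append(idx)
                if prev is not None:
                    mol.AddBond(prev, idx, _BOND_CHAR[m.group(1)])
                prev = idx
                pos += 1
                continue
            c = _CTRL_SYM_RE.fullmatch(sym)
            if not c or prev is None:
                raise _fail()
            kind = c.group(2)
            n_idx = 1 if kind.endswith("1") else 2
            if kind.startswith("Branch"):
                length, pos = read_index(pos + 1, n_idx)
                length += 1
                if pos + length > end:
                    raise _fail()
                derive(pos, pos + length, prev)
                pos += length
            else:  # Ring
                dist, pos = read_index(pos + 1, n_idx)
                dist += 1
                cur = derived.index(prev)
                partner = cur - dist
                if partner < 0:
                    raise _fail()
                mol.AddBond(prev, derived[partner], _BOND_CHAR[c.group(1)])
        return pos

    derive(0, len(symbols), None)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # noqa: BLE001
        raise _fail() from exc
    return Chem.MolToSmiles(out)


def same_molecule(smiles_a: str, smiles_b: str) -> bool:
    """True when two SMILES strings denote the same molecule."""
    ma, mb = Chem.MolFromSmiles(smiles_a), Chem.MolFromSmiles(smiles_b)
    if ma is None or mb is None:
        return False
    return Chem.MolToSmiles(ma) == Chem.MolToSmiles(mb)
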