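"""Canonical atomic and molecular signatures at tunable diameter *d*.

A molecular signature encodes each heavy atom of a compound by a canonical
string describing its bonded neighborhood up to radius ``d/2`` (the *diameter*
``d`` counts bonds across the neighborhood and must be even).  The multiset of
atomic signatures over all heavy atoms is the molecular signature — an integer
fingerprint on which reaction rules and Tanimoto similarity operate.

The canonical string is a rooted tree serialization: starting at the root
atom, neighbors are expanded breadth-wise without immediate backtracking along
the incoming edge, children sorted lexicographically by their recursively
computed strings.  Atom labels carry element, implicit-hydrogen count and
formal charge (``[C;H3;0]``); stereochemistry and isotopes are discarded.
The scheme is deterministic and invariant under any relabeling of atom
indices, and truncating a signature's tree to a smaller even diameter yields
the signature at that diameter (diameter refinement).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

# bond-order symbols used inside canonical strings
_BOND_SYMBOL = {1: "-", 2: "=", 3: "#", "ar": ":"}

BondOrder = object  # 1 | 2 | 3 | "ar"


class StructureParseError(ValueError):
    """Raised when a SMILES or Molfile cannot be parsed."""


class SignatureError(ValueError):
    """Raised on invalid signature parameters (odd diameter, bad root...)."""


@dataclass(frozen=True)
class Atom:
    symbol: str
    charge: int
    n_h: int


@dataclass
class Molecule:
    """Labelled graph of heavy atoms; hydrogens are implicit in atom labels."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, object]]  # (i, j, order in {1,2,3,"ar"})
    id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references invalid atom index")
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if order not in _BOND_SYMBOL:
                raise ValueError(f"unsupported bond order {order!r}")

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    def neighbors(self) -> list[list[tuple[int, object]]]:
        adj: list[list[tuple[int, object]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj


@dataclass(frozen=True)
class AtomicSignature:
    text: str
    root: int
    diameter: int


@dataclass
class SignatureVector:
    """Multiset of canonical atomic-signature strings at a fixed diameter."""

    counts: dict[str, int]
    diameter: int

    def __post_init__(self) -> None:
        self.counts = {k: int(v) for k, v in self.counts.items() if v}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("signature counts must be positive")

    def total(self) -> int:
        return sum(self.counts.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureVector):
            return NotImplemented
        return self.diameter == other.diameter and self.counts == other.counts

    def to_tsv(self) -> str:
        """Two-column TSV (signature string, count); bit-exact round-trip."""
        lines = [f"# diameter\t{self.diameter}"]
        for key in sorted(self.counts):
            lines.append(f"{key}\t{self.counts[key]}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "SignatureVector":
        diameter = None
        counts: dict[str, int] = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                _, _, val = line.partition("\t")
                diameter = int(val)
                continue
            key, _, val = line.rpartition("\t")
            counts[key] = int(val)
        if diameter is None:
            raise ValueError("missing diameter header")
        return cls(counts=counts, diameter=diameter)


def _molecule_from_rdkit(rdmol: "Chem.Mol", mol_id: str) -> Molecule:
    Chem.RemoveStereochemistry(rdmol)
    atoms = []
    for a in rdmol.GetAtoms():
        atoms.append(Atom(symbol=a.GetSymbol(), charge=a.GetFormalCharge(),
                          n_h=a.GetTotalNumHs()))
    bonds = []
    for b in rdmol.GetBonds():
        if b.GetIsAromatic():
            order: object = "ar"
        else:
            o = b.GetBondTypeAsDouble()
            if o not in (1.0, 2.0, 3.0):
                raise StructureParseError(
                    f"unsupported bond type {b.GetBondType()} in {mol_id or 'molecule'}")
            order = int(o)
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return Molecule(atoms=atoms, bonds=bonds, id=mol_id)


def parse_structure(text: str, format: str = "smiles", mol_id: str = "") -> Molecule:
    """Parse a SMILES string or MDL Molfile (V2000) into a :class:`Molecule`.

    Hydrogens are made implicit; stereochemistry is discarded.
    """
    if format == "smiles":
        rdmol = Chem.MolFromSmiles(text, sanitize=True)
        if rdmol is None:
            raise StructureParseError(f"invalid SMILES: {text!r}")
    elif format == "molfile":
        rdmol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
        if rdmol is None:
            raise StructureParseError("invalid MDL Molfile (see lines above the counts line)")
    else:
        raise ValueError(f"unknown structure format {format!r}")
    return _molecule_from_rdkit(rdmol, mol_id)


def _atom_label(atom: Atom) -> str:
    return f"[{atom.symbol};H{atom.n_h};{atom.charge}]"


def _expand(mol: Molecule, adj, atom: int, depth: int, came_from: int) -> str:
    s = _atom_label(mol.atoms[atom])
    if depth > 0:
        children = []
        for nbr, order in adj[atom]:
            if nbr == came_from:
                continue
            children.append(_BOND_SYMBOL[order] + _expand(mol, adj, nbr, depth - 1, atom))
        if children:
            s += "(" + "".join(sorted(children)) + ")"
    return s


def atomic_signature(mol: Molecule, root: int, diameter: int) -> AtomicSignature:
    """Canonical string over the rooted neighborhood of radius ``diameter/2``."""
    if diameter < 0 or diameter % 2:
        raise SignatureError(f"diameter must be even and non-negative, got {diameter}")
    if not 0 <= root < mol.n_heavy:
        raise SignatureError(f"root atom {root} out of range")
    adj = mol.neighbors()
    text = _expand(mol, adj, root, diameter // 2, came_from=-1)
    return AtomicSignature(text=text, root=root, diameter=diameter)


def molecular_signature(mol: Molecule, diameter: int) -> SignatureVector:
    """Multiset of atomic signatures over all heavy atoms of ``mol``."""
    counts = Counter(
        atomic_signature(mol, i, diameter).text for i in range(mol.n_heavy))
    return SignatureVector(counts=dict(counts), diameter=diameter)


def tanimoto(a: SignatureVector, b: SignatureVector) -> float:
    """Multiset Tanimoto similarity: sum(min) / sum(max) over signature counts."""
    if a.diameter != b.diameter:
        raise ValueError(
            f"diameter mismatch: {a.diameter} vs {b.diameter}")
    keys = set(a.counts) | set(b.counts)
    if not keys:
        return 1.0
    num = sum(min(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
    den = sum(max(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
    return num / den
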