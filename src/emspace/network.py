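"""Metabolic network data model, TSV readers/writers, balance validation
and compound search.

File dialect
------------
Metabolites TSV (tab-separated, ``#`` comment lines ignored)::

    id  name  smiles  endogenous{0,1}  toxicity  formula  [side{0,1}]

``toxicity`` is log10(IC50) toward the chassis (higher = less toxic); empty
cells mean absent.  ``formula`` is a Hill-notation string (``C9H11NO3``) and
may be left empty when a SMILES is given.  The optional ``side`` column marks
freely available cofactor-pool compounds.

Reactions TSV::

    id  2 A + B => C | reversible{0,1} | dG | EC | gene:score;gene:score [| origin | rule_id]

Stoichiometric coefficients are rationals (``1/2`` allowed); ``dG`` is a
standard Gibbs free energy in kcal/mol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, NamedTuple, Optional

from .signatures import (Molecule, SignatureVector, molecular_signature,
                         parse_structure, tanimoto)


class NetworkError(ValueError):
    pass


@dataclass
class Metabolite:
    id: str
    name: str = ""
    structure: Optional[Molecule] = None
    endogenous: bool = False
    toxicity: Optional[float] = None  # log10(IC50)
    formula: Optional[dict[str, int]] = None
    smiles: str = ""

    def element_counts(self) -> Optional[dict[str, int]]:
        """Element counts incl. hydrogens, from formula or structure."""
        if self.formula is not None:
            return dict(self.formula)
        if self.structure is not None:
            counts: dict[str, int] = {}
            n_h = 0
            for atom in self.structure.atoms:
                counts[atom.symbol] = counts.get(atom.symbol, 0) + 1
                n_h += atom.n_h
            if n_h:
                counts["H"] = counts.get("H", 0) + n_h
            return counts
        return None

    def charge(self) -> Optional[int]:
        if self.structure is not None:
            return sum(a.charge for a in self.structure.atoms)
        return None


@dataclass
class Reaction:
    id: str
    stoich: dict[str, Fraction]  # negative = substrate, positive = product
    reversible: bool = False
    delta_g: Optional[float] = None  # kcal/mol
    ec: Optional[str] = None
    genes: list[tuple[str, float]] = field(default_factory=list)
    origin: str = "known"  # known | putative
    rule_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.stoich = {m: Fraction(c) for m, c in self.stoich.items() if c != 0}
        if not self.substrates() or not self.products():
            raise NetworkError(
                f"reaction {self.id!r} needs at least one substrate and one product")
        if self.origin not in ("known", "putative"):
            raise NetworkError(f"reaction {self.id!r}: bad origin {self.origin!r}")

    def substrates(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoich.items() if c < 0}

    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoich.items() if c > 0}

    def stoich_key(self) -> frozenset:
        return frozenset((m, c) for m, c in self.stoich.items())


@dataclass
class MetabolicNetwork:
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    side_compounds: set[str] = field(default_factory=set)

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise NetworkError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise NetworkError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoich if m not in self.metabolites]
        if missing:
            raise NetworkError(
                f"reaction {rxn.id!r} references unknown metabolites: {missing}")
        self.reactions[rxn.id] = rxn

    def endogenous_ids(self) -> set[str]:
        return {m.id for m in self.metabolites.values() if m.endogenous}

    def copy(self) -> "MetabolicNetwork":
        net = MetabolicNetwork(side_compounds=set(self.side_compounds))
        net.metabolites = dict(self.metabolites)
        net.reactions = dict(self.reactions)
        return net


@dataclass
class FBAModel:
    """Stoichiometric model for flux balance analysis.

    ``stoich[rxn][met]`` is the signed coefficient; boundary reactions may
    have substrates or products only.
    """

    metabolites: list[str]
    reactions: list[str]
    stoich: dict[str, dict[str, float]]
    lower: dict[str, float]
    upper: dict[str, float]
    objective: str

    def __post_init__(self) -> None:
        if self.objective not in self.reactions:
            raise NetworkError(f"objective reaction {self.objective!r} not in model")


# ---------------------------------------------------------------------------
# formulas and equations

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise NetworkError(f"cannot parse formula {text!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text) or not counts:
        raise NetworkError(f"cannot parse formula {text!r}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    # Hill order: C, H, then alphabetical
    keys = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in keys)


def parse_equation(text: str) -> dict[str, Fraction]:
    """Parse ``2 A + B => C`` into a signed stoichiometry map."""
    if "=>" not in text:
        raise NetworkError(f"equation {text!r} lacks '=>'")
    lhs, _, rhs = text.partition("=>")
    stoich: dict[str, Fraction] = {}

    def side(part: str, sign: int) -> None:
        part = part.strip()
        if not part:
            return
        for term in part.split(" + "):
            term = term.strip()
            if not term:
                continue
            bits = term.split()
            if len(bits) == 2:
                coeff, met = Fraction(bits[0]), bits[1]
            elif len(bits) == 1:
                coeff, met = Fraction(1), bits[0]
            else:
                raise NetworkError(f"cannot parse term {term!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff

    side(lhs, -1)
    side(rhs, +1)
    return stoich


def format_equation(stoich: dict[str, Fraction]) -> str:
    def side(items: dict[str, Fraction]) -> str:
        terms = []
        for met in sorted(items):
            c = items[met]
            terms.append(met if c == 1 else f"{c} {met}")
        return " + ".join(terms)

    subs = {m: -c for m, c in stoich.items() if c < 0}
    prods = {m: c for m, c in stoich.items() if c > 0}
    return f"{side(subs)} => {side(prods)}"


# ---------------------------------------------------------------------------
# TSV I/O

def _parse_metabolite_row(row: list[str], lineno: int) -> tuple[Metabolite, bool]:
    if len(row) < 6:
        raise NetworkError(f"metabolites line {lineno}: expected >= 6 columns")
    mid, name, smiles, endo, tox, formula = row[:6]
    side = len(row) > 6 and row[6].strip() == "1"
    structure = None
    if smiles.strip():
        structure = parse_structure(smiles.strip(), "smiles", mol_id=mid)
    return Metabolite(
        id=mid, name=name,
        structure=structure, smiles=smiles.strip(),
        endogenous=endo.strip() == "1",
        toxicity=float(tox) if tox.strip() else None,
        formula=parse_formula(formula.strip()) if formula.strip() else None,
    ), side


def _parse_reaction_row(rid: str, spec: str) -> Reaction:
    fields = [f.strip() for f in spec.split("|")]
    if len(fields) < 1:
        raise NetworkError(f"reaction {rid!r}: empty definition")
    fields += [""] * (7 - len(fields))
    eq, rev, dg, ec, genes_s, origin, rule_id = fields[:7]
    genes = []
    if genes_s:
        for pair in genes_s.split(";"):
            gid, _, score = pair.partition(":")
            genes.append((gid.strip(), float(score)))
    return Reaction(
        id=rid, stoich=parse_equation(eq),
        reversible=rev == "1",
        delta_g=float(dg) if dg else None,
        ec=ec or None, genes=genes,
        origin=origin or "known",
        rule_id=rule_id or None,
    )


def load_network(metabolites_path: str, reactions_path: str) -> MetabolicNetwork:
    """Load a network from the documented two-file TSV dialect."""
    net = MetabolicNetwork()
    with open(metabolites_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            met, side = _parse_metabolite_row(line.split("\t"), lineno)
            net.add_metabolite(met)
            if side:
                net.side_compounds.add(met.id)
    with open(reactions_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise NetworkError(f"reactions line {lineno}: expected 'id<TAB>definition'")
            net.add_reaction(_parse_reaction_row(parts[0].strip(), parts[1]))
    return net


def write_network(net: MetabolicNetwork, metabolites_path: str,
                  reactions_path: str) -> None:
    with open(metabolites_path, "w") as fh:
        fh.write("# id\tname\tsmiles\tendogenous\ttoxicity\tformula\tside\n")
        for mid in sorted(net.metabolites):
            m = net.metabolites[mid]
            fh.write("\t".join([
                m.id, m.name, m.smiles,
                "1" if m.endogenous else "0",
                "" if m.toxicity is None else repr(m.toxicity),
                "" if m.formula is None else format_formula(m.formula),
                "1" if mid in net.side_compounds else "0",
            ]) + "\n")
    with open(reactions_path, "w") as fh:
        fh.write("# id\tequation | reversible | dG | EC | genes | origin | rule_id\n")
        for rid in sorted(net.reactions):
            r = net.reactions[rid]
            genes = ";".join(f"{g}:{s}" for g, s in r.genes)
            fh.write(f"{rid}\t{format_equation(r.stoich)} | "
                     f"{'1' if r.reversible else '0'} | "
                     f"{'' if r.delta_g is None else repr(r.delta_g)} | "
                     f"{r.ec or ''} | {genes} | {r.origin} | {r.rule_id or ''}\n")


_INF = float("inf")


def load_fba_model(path: str) -> FBAModel:
    """Load an FBA model from a TSV with columns
    ``id  equation  lb  ub  objective{0,1}`` (boundary rows may leave one
    equation side empty, e.g. ``=> glc`` for an uptake)."""
    reactions: list[str] = []
    stoich: dict[str, dict[str, float]] = {}
    lower: dict[str, float] = {}
    upper: dict[str, float] = {}
    mets: set[str] = set()
    objective = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise NetworkError(f"FBA model line {lineno}: expected 5 columns")
            rid, eq, lb, ub, obj = cols
            if rid in stoich:
                raise NetworkError(f"duplicate FBA reaction id {rid!r}")
            coeffs = {m: float(c) for m, c in parse_equation(eq).items()}
            reactions.append(rid)
            stoich[rid] = coeffs
            mets.update(coeffs)
            lower[rid] = float(lb) if lb.strip() not in ("", "-inf") else -_INF
            upper[rid] = float(ub) if ub.strip() not in ("", "inf") else _INF
            if obj.strip() == "1":
                objective = rid
    if objective is None:
        raise NetworkError("FBA model declares no objective reaction")
    return FBAModel(metabolites=sorted(mets), reactions=reactions,
                    stoich=stoich, lower=lower, upper=upper, objective=objective)


def write_fba_model(model: FBAModel, path: str) -> None:
    def fmt(x: float) -> str:
        if x == _INF:
            return "inf"
        if x == -_INF:
            return "-inf"
        return repr(x)

    with open(path, "w") as fh:
        fh.write("# id\tequation\tlb\tub\tobjective\n")
        for rid in model.reactions:
            eq = format_equation({m: Fraction(c).limit_denominator(10 ** 9)
                                  for m, c in model.stoich[rid].items()})
            fh.write(f"{rid}\t{eq}\t{fmt(model.lower[rid])}\t"
                     f"{fmt(model.upper[rid])}\t"
                     f"{'1' if rid == model.objective else '0'}\n")


# ---------------------------------------------------------------------------
# balance validation

def validate_balance(rxn: Reaction, net: MetabolicNetwork) -> bool:
    """True iff element counts (and total charge, when every participant's
    charge is known) of substrates equal those of products, stoichiometry-
    weighted."""
    totals: dict[str, Fraction] = {}
    charges_known = True
    charge_total = Fraction(0)
    for mid, coeff in rxn.stoich.items():
        met = net.metabolites.get(mid)
        if met is None:
            raise NetworkError(f"reaction {rxn.id!r}: unknown metabolite {mid!r}")
        counts = met.element_counts()
        if counts is None:
            raise NetworkError(
                f"cannot judge balance of {rxn.id!r}: metabolite {mid!r} has "
                f"neither formula nor structure")
        for elem, n in counts.items():
            totals[elem] = totals.get(elem, Fraction(0)) + coeff * n
        q = met.charge()
        if q is None:
            charges_known = False
        else:
            charge_total += coeff * q
    if any(v != 0 for v in totals.values()):
        return False
    if charges_known and charge_total != 0:
        return False
    return True


def filter_balanced(net: MetabolicNetwork, log: Optional[list[str]] = None
                    ) -> MetabolicNetwork:
    """Return a copy of ``net`` with unbalanced (or unjudgeable) reactions
    removed; removal count appended to ``log`` when given."""
    out = net.copy()
    removed = []
    for rid, rxn in net.reactions.items():
        try:
            ok = validate_balance(rxn, net)
        except NetworkError:
            ok = False
        if not ok:
            removed.append(rid)
    for rid in removed:
        del out.reactions[rid]
    if log is not None:
        log.append(f"filter_balanced removed {len(removed)} reaction(s): "
                   + ",".join(sorted(removed)))
    return out


# ---------------------------------------------------------------------------
# compound search

class SearchHit(NamedTuple):
    metabolite: Metabolite
    similarity: float
    status: str  # "endogenous" | "heterologous"


def search_compound(query, net: MetabolicNetwork, k: int = 10,
                    diameter: int = 4) -> list[SearchHit]:
    """Rank network metabolites against a name or structure query.

    Name queries: case-insensitive exact matches (similarity 1.0) first, then
    substring matches scored by length ratio.  Structure queries: multiset
    Tanimoto similarity between molecular signatures at ``diameter``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    hits: list[SearchHit] = []
    if isinstance(query, str):
        q = query.strip().lower()
        for mid in sorted(net.metabolites):
            met = net.metabolites[mid]
            names = [met.name.lower(), mid.lower()]
            if q in (n for n in names if n):
                sim = 1.0
            elif any(q in n for n in names if n):
                sim = max((len(q) / len(n)) for n in names if n and q in n)
            else:
                continue
            hits.append(SearchHit(met, sim,
                                  "endogenous" if met.endogenous else "heterologous"))
    elif isinstance(query, Molecule):
        qsig = molecular_signature(query, diameter)
        for mid in sorted(net.metabolites):
            met = net.metabolites[mid]
            if met.structure is None:
                continue
            sim = tanimoto(qsig, molecular_signature(met.structure, diameter))
            hits.append(SearchHit(met, sim,
                                  "endogenous" if met.endogenous else "heterologous"))
    else:
        raise TypeError("query must be a name string or a Molecule")
    hits.sort(key=lambda h: (-h.similarity, h.metabolite.id))
    return hits[:k]
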