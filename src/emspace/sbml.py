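"""SBML Level 3 export of enumerated pathways, with gene-construct choices
embedded as machine-readable annotations.

One species is written per pathway metabolite and one reaction per enzymatic
step (boundary uptake/exchange/sink columns are written as boundary
reactions so the document carries the full mode stoichiometry).  Construct
annotations live in a dedicated XML namespace inside the model's
``<annotation>`` block: each construct lists its per-step gene choice and
score.  ``import_pathway_sbml`` round-trips the document back to the step
stoichiometry and construct list.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional

import libsbml

from .network import MetabolicNetwork
from .ranking import Construct
from .retropath import Pathway

CONSTRUCT_NS = "https://emspace.readthedocs.io/ns/construct"


class SBMLError(RuntimeError):
    pass


def _check(obj, msg: str):
    if obj is None:
        raise SBMLError(msg)
    return obj


def export_pathway_sbml(p: Pathway, net: MetabolicNetwork,
                        constructs: Optional[list[Construct]] = None) -> str:
    """Serialize a pathway (and optional gene constructs) to SBML L3V2 text."""
    if not p.support:
        raise SBMLError("cannot export an empty pathway")
    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId(f"pathway_to_{p.target}")
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)

    mets: set[str] = set()
    for rid in p.support:
        mets |= set(net.reactions[rid].stoich)
    for mid in sorted(mets):
        met = net.metabolites[mid]
        sp = model.createSpecies()
        sp.setId(f"M_{mid}")
        sp.setName(met.name or mid)
        sp.setCompartment("cell")
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(mid in net.side_compounds)
        if met.smiles:
            sp.appendNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                           f"<p>SMILES: {met.smiles}</p></body>")

    for rid in p.support:
        rxn = net.reactions[rid]
        r = model.createReaction()
        r.setId(f"R_{rid}")
        r.setReversible(rxn.reversible)
        if rxn.ec:
            r.setName(f"{rid} (EC {rxn.ec})")
        for mid, coeff in sorted(rxn.stoich.items()):
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(f"M_{mid}")
            ref.setStoichiometry(float(abs(coeff)))
            ref.setConstant(True)

    if constructs:
        parts = [f"<constructList xmlns=\"{CONSTRUCT_NS}\">"]
        for c in constructs:
            parts.append(f"  <construct score=\"{c.score!r}\">")
            for step in sorted(c.choice):
                parts.append(f"    <step reaction=\"{step}\" gene=\"{c.choice[step]}\"/>")
            parts.append("  </construct>")
        parts.append("</constructList>")
        if model.appendAnnotation("\n".join(parts)) != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise SBMLError("failed to append construct annotation")

    doc.checkInternalConsistency()
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise SBMLError(doc.getErrorLog().toString())
    return libsbml.writeSBMLToString(doc)


def import_pathway_sbml(text: str) -> tuple[dict[str, dict[str, Fraction]],
                                            list[Construct]]:
    """Parse an exported pathway document back into per-step stoichiometry
    (reaction id -> metabolite id -> signed coefficient) and constructs."""
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise SBMLError(doc.getErrorLog().toString())
    model = _check(doc.getModel(), "document has no model")
    steps: dict[str, dict[str, Fraction]] = {}
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        rid = r.getId().removeprefix("R_")
        stoich: dict[str, Fraction] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            mid = ref.getSpecies().removeprefix("M_")
            stoich[mid] = stoich.get(mid, Fraction(0)) - \
                Fraction(ref.getStoichiometry()).limit_denominator(10 ** 9)
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            mid = ref.getSpecies().removeprefix("M_")
            stoich[mid] = stoich.get(mid, Fraction(0)) + \
                Fraction(ref.getStoichiometry()).limit_denominator(10 ** 9)
        steps[rid] = stoich
    constructs: list[Construct] = []
    ann = model.getAnnotation()
    if ann is not None:
        for i in range(ann.getNumChildren()):
            node = ann.getChild(i)
            if node.getName() != "constructList":
                continue
            for j in range(node.getNumChildren()):
                cnode = node.getChild(j)
                if cnode.getName() != "construct":
                    continue
                score = float(cnode.getAttrValue("score"))
                choice: dict[str, str] = {}
                for k in range(cnode.getNumChildren()):
                    snode = cnode.getChild(k)
                    if snode.getName() == "step":
                        choice[snode.getAttrValue("reaction")] = \
                            snode.getAttrValue("gene")
                constructs.append(Construct(choice=choice, score=score))
    return steps, constructs
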