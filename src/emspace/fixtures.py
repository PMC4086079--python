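"""Built-in example networks: the raspberry-ketone design case and seeded
random networks with planted pathways.

The raspberry-ketone network carries the seven heterologous steps needed to
produce 4-(4-hydroxyphenyl)butan-2-one in an *E. coli* chassis: the natural
two-step route from coumaroyl-CoA (benzalacetone synthase BAS, then
benzalacetone reductase BAR), coumaroyl-CoA supply via 4-coumarate--CoA
ligase (4CL), and three alternative entries into 4-coumarate from endogenous
metabolites — cinnamate 4-hydroxylase (C4H, EC 1.14.13.11) from
*trans*-cinnamate, tyrosine ammonia-lyase (TAL, EC 4.3.1.5) from tyrosine,
and the two-step hydroxyphenylpyruvate reductase (HPPR, EC 1.1.1.237) plus
4-hydroxyphenyllactate hydro-lyase route from 4-hydroxyphenylpyruvate.
All structures are real SMILES (full CoA and NAD(P) cofactors) and every
reaction is element- and charge-balanced.  Gene scores, toxicities and ΔG°
values are fixture inputs of realistic magnitude, chosen so that the three
routes differ on every ranking axis.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction

from .network import FBAModel, MetabolicNetwork, Metabolite, Reaction

_INF = float("inf")


@dataclass
class FixtureSpec:
    """Parameters of a seeded random network (identical spec => identical
    network, byte-identical TSV output)."""

    name: str = "random"
    seed: int = 0
    parameters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# raspberry-ketone network

_COA_CORE = ("CC(C)(COP(=O)(O)OP(=O)(O)OCC1OC(n2cnc3c(N)ncnc32)C(O)C1OP(=O)(O)O)"
             "C(O)C(=O)NCCC(=O)NCCS")
_NAD_CORE = ("C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(OP(=O)(O)O)C3O)"
             "C(O)C2O")

# id, name, smiles, endogenous, toxicity(log10 IC50), side-compound flag
_RASPBERRY_METABOLITES = [
    ("tyr", "L-tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O", True, -0.70, False),
    ("cin", "trans-cinnamate", "OC(=O)/C=C/c1ccccc1", True, -0.95, False),
    ("hpp", "4-hydroxyphenylpyruvate", "OC(=O)C(=O)Cc1ccc(O)cc1", True, -0.88, False),
    ("cou", "4-coumarate", "OC(=O)C=Cc1ccc(O)cc1", False, -1.009, False),
    ("hpl", "3-(4-hydroxyphenyl)lactate", "OC(=O)C(O)Cc1ccc(O)cc1", False, -1.077, False),
    ("couCoA", "4-coumaroyl-CoA", _COA_CORE + "C(=O)C=Cc1ccc(O)cc1", False, -1.009, False),
    ("hba", "4-hydroxybenzalacetone", "CC(=O)C=Cc1ccc(O)cc1", False, -1.009, False),
    ("rket", "raspberry ketone", "CC(=O)CCc1ccc(O)cc1", False, -0.60, False),
    ("coa", "coenzyme A", _COA_CORE, True, None, True),
    ("malCoA", "malonyl-CoA", _COA_CORE + "C(=O)CC(=O)O", True, None, True),
    ("atp", "ATP", "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O",
     True, None, True),
    ("amp", "AMP", "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)O)C(O)C1O", True, None, True),
    ("ppi", "diphosphate", "OP(=O)(O)OP(=O)(O)O", True, None, True),
    ("nadph", "NADPH", "NC(=O)C1=CN(" + _NAD_CORE + ")C=CC1", True, None, True),
    ("nadp", "NADP+", "NC(=O)c1ccc[n+](" + _NAD_CORE + ")c1", True, None, True),
    ("nh3", "ammonia", "N", True, None, True),
    ("h2o", "water", "O", True, None, True),
    ("co2", "carbon dioxide", "O=C=O", True, None, True),
    ("o2", "oxygen", "O=O", True, None, True),
    ("h", "proton", "[H+]", True, None, True),
]

# id, equation, dG(kcal/mol), EC, gene candidates
_RASPBERRY_REACTIONS = [
    ("TAL", "tyr => cou + nh3", -6.2, "4.3.1.5",
     [("tal_Rg", 0.50), ("tal_Se", 0.31)]),
    ("C4H", "cin + o2 + nadph + h => cou + nadp + h2o", 21.611, "1.14.13.11",
     [("c4h_At", 0.448), ("c4h_Ps", 0.30)]),
    ("HPPR", "hpp + nadph + h => hpl + nadp", 20.0, "1.1.1.237",
     [("hppr_Cb", 0.95), ("hppr_So", 0.62)]),
    ("HPLH", "hpl => cou + h2o", -1.567, None,
     [("hplh_Cb", 0.935), ("hplh_x1", 0.40)]),
    ("4CL", "cou + atp + coa => couCoA + amp + ppi", -15.0, "6.2.1.12",
     [("4cl_At", 0.65), ("4cl_Pc", 0.52), ("4cl_Nt", 0.33)]),
    ("BAS", "couCoA + malCoA + h2o => hba + 2 co2 + 2 coa", 2.0, "2.3.1.-",
     [("bas_Ri", 0.45), ("bas_Rp", 0.28)]),
    ("BAR", "hba + nadph + h => rket + nadp", -7.437, "1.1.1.-",
     [("bar_Ri", 0.58), ("bar_x1", 0.41)]),
]


def raspberry_network() -> tuple[MetabolicNetwork, set[str], str]:
    """The raspberry-ketone design network.

    Returns (network, chassis seed metabolites, target id).  Chassis seeds
    are the endogenous non-cofactor metabolites (tyrosine, trans-cinnamate,
    4-hydroxyphenylpyruvate); the target is raspberry ketone.
    """
    from .network import parse_equation
    net = MetabolicNetwork()
    for mid, name, smiles, endo, tox, side in _RASPBERRY_METABOLITES:
        from .signatures import parse_structure
        net.add_metabolite(Metabolite(
            id=mid, name=name, smiles=smiles,
            structure=parse_structure(smiles, "smiles", mol_id=mid),
            endogenous=endo, toxicity=tox))
        if side:
            net.side_compounds.add(mid)
    for rid, eq, dg, ec, genes in _RASPBERRY_REACTIONS:
        net.add_reaction(Reaction(
            id=rid, stoich=parse_equation(eq), reversible=False,
            delta_g=dg, ec=ec, genes=list(genes), origin="known"))
    seeds = {"tyr", "cin", "hpp"}
    return net, seeds, "rket"


# ---------------------------------------------------------------------------
# toy FBA chassis model

def toy_fba_model() -> FBAModel:
    """Hand-solvable chassis model: glucose uptake (bound 10) feeding the
    three raspberry precursors and a biomass drain on glucose.

    Wild-type biomass optimum is 10; with growth fraction 0 each precursor's
    availability is 10 (all uptake divertible to its synthesis).
    """
    stoich = {
        "UPT_GLC": {"glc": 1.0},
        "MK_TYR": {"glc": -1.0, "tyr": 1.0},
        "MK_CIN": {"glc": -1.0, "cin": 1.0},
        "MK_HPP": {"glc": -1.0, "hpp": 1.0},
        "DR_TYR": {"tyr": -1.0},
        "DR_CIN": {"cin": -1.0},
        "DR_HPP": {"hpp": -1.0},
        "BIOMASS": {"glc": -1.0},
    }
    reactions = list(stoich)
    return FBAModel(
        metabolites=sorted({m for c in stoich.values() for m in c}),
        reactions=reactions, stoich=stoich,
        lower={r: 0.0 for r in reactions},
        upper={"UPT_GLC": 10.0, **{r: _INF for r in reactions if r != "UPT_GLC"}},
        objective="BIOMASS")


# ---------------------------------------------------------------------------
# promiscuity toy universe

def promiscuity_universe() -> tuple[MetabolicNetwork, set[str], str]:
    """Small universe where rule generality visibly depends on diameter.

    The template reaction R1 reduces pyruvate to lactate with a two-substrate
    hydride donor pair (isopropanol/acetone).  2-oxobutanoate, also present,
    has an identical reaction-center environment at d = 0 but differs at
    d >= 2 (methyl vs ethyl flank), so network extension adds putative
    reductions and keto/hydroxy hydride transfers at d = 0 only — and with
    them additional routes to the target (one pathway at d >= 2, more at
    d = 0).
    """
    from .network import parse_equation
    from .signatures import parse_structure
    net = MetabolicNetwork()

    def met(mid: str, name: str, smi: str, endo: bool = False,
            side: bool = False) -> None:
        net.add_metabolite(Metabolite(
            id=mid, name=name, smiles=smi,
            structure=parse_structure(smi, "smiles", mol_id=mid),
            endogenous=endo))
        if side:
            net.side_compounds.add(mid)

    met("pyr", "pyruvate", "CC(=O)C(=O)O", endo=True)
    met("lac", "(S)-lactate", "CC(O)C(=O)O")
    met("oxb", "2-oxobutanoate", "CCC(=O)C(=O)O", endo=True)
    met("hxb", "2-hydroxybutanoate", "CCC(O)C(=O)O")
    met("tgt", "glyceraldehyde", "OCC(O)C=O")
    met("meoh", "methanol", "CO", side=True)
    met("h2o", "water", "O", endo=True, side=True)
    met("iproh", "isopropanol", "CC(O)C", endo=True, side=True)
    met("acet", "acetone", "CC(=O)C", endo=True, side=True)
    net.add_reaction(Reaction(
        "R1", parse_equation("pyr + iproh => lac + acet"),
        genes=[("g_r1", 0.8)]))
    net.add_reaction(Reaction(
        "R2", parse_equation("lac => tgt"), genes=[("g_r2", 0.7)]))
    net.add_reaction(Reaction(
        "R3", parse_equation("hxb + h2o => tgt + meoh"), genes=[("g_r3", 0.6)]))
    return net, {"pyr", "oxb"}, "tgt"


# ---------------------------------------------------------------------------
# seeded random networks with planted pathways

def random_network(spec: FixtureSpec
                   ) -> tuple[MetabolicNetwork, set[str], str]:
    """Seeded random network with ``n_routes`` disjoint planted
    precursor->target routes of ``planted_depth`` steps, decorated with
    ``n_distractors`` mass-conserving distractor reactions that never
    produce the target or a planted intermediate.

    Metabolite formulas are synthetic (C_k H_2k O_k) and every generated
    reaction conserves them, so fixture networks pass balance validation.
    """
    p = spec.parameters
    depth = int(p.get("planted_depth", 3))
    n_routes = int(p.get("n_routes", 1))
    n_distract = int(p.get("n_distractors", 0))
    if depth < 1 or n_routes < 1 or n_distract < 0:
        raise ValueError(f"infeasible random-network parameters: {p}")
    rng = random.Random(spec.seed)
    net = MetabolicNetwork()

    def add_met(mid: str, size: int, endogenous: bool = False) -> None:
        net.add_metabolite(Metabolite(
            id=mid, name=mid, endogenous=endogenous,
            formula={"C": size, "H": 2 * size, "O": size}))

    target = "target"
    add_met(target, 6)
    planted: set[str] = {target}
    for r in range(n_routes):
        prev = f"pre{r}"
        add_met(prev, 6, endogenous=True)
        planted.add(prev)
        for s in range(depth):
            nxt = target if s == depth - 1 else f"m{r}_{s}"
            if nxt != target:
                add_met(nxt, 6)
                planted.add(nxt)
            net.add_reaction(Reaction(
                id=f"P{r}_{s}", stoich={prev: Fraction(-1), nxt: Fraction(1)},
                reversible=False, origin="known",
                genes=[(f"g{r}_{s}", round(rng.uniform(0.2, 0.95), 3))]))
            prev = nxt
    pool: list[tuple[str, int]] = []
    for i in range(max(n_distract, 1) + 2):
        size = rng.randint(1, 9)
        mid = f"d{i}"
        add_met(mid, size, endogenous=rng.random() < 0.3)
        pool.append((mid, size))
    made = 0
    attempts = 0
    while made < n_distract and attempts < 50 * n_distract + 50:
        attempts += 1
        (a, sa), (b, sb) = rng.sample(pool, 2)
        if sa == sb:
            rid = f"D{made}"
            stoich = {a: Fraction(-1), b: Fraction(1)}
        else:
            src, ssrc = (a, sa) if sa > sb else (b, sb)
            other = ssrc - min(sa, sb)
            match = [m for m, s in pool if s == other and m != src]
            if not match:
                continue
            rid = f"D{made}"
            stoich = {src: Fraction(-1),
                      (a if src == b else b): Fraction(1),
                      match[0]: Fraction(1)}
            if len(stoich) < 3:
                continue
        if any(m in planted and c > 0 for m, c in stoich.items()):
            continue
        try:
            net.add_reaction(Reaction(id=rid, stoich=stoich,
                                      reversible=rng.random() < 0.3,
                                      origin="known"))
            made += 1
        except Exception:
            continue
    seeds = {m.id for m in net.metabolites.values() if m.endogenous}
    return net, seeds, target
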