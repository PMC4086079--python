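"""Reaction rules at diameter *d* and promiscuity-driven network extension.

A reaction rule is the signed difference between the molecular signatures of
a reaction's products and substrates at a fixed diameter.  Because any atom
environment unchanged by the transformation cancels in the difference, the
rule captures only the chemistry around the reaction center; the smaller the
diameter, the more generic the rule.  Applying a rule to new substrate
combinations over the *known-metabolite universe* predicts putative
promiscuous reactions: candidate product multisets are those whose signature
vectors sum exactly to ``sum(substrate signatures) + delta``, which by
construction conserves atom counts.  Iterating rule application to a fixpoint
yields the extended metabolic space.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional

from .network import MetabolicNetwork, Metabolite, NetworkError, Reaction
from .signatures import molecular_signature


class RuleError(ValueError):
    pass


@dataclass
class ReactionRule:
    """Signed signature difference (products minus substrates) at diameter d."""

    id: str
    diameter: int
    delta: dict[str, int]
    substrate_arity: int
    product_arity: int
    template_reaction_ids: list[str]
    # properties inherited by putative reactions (from the first template)
    reversible: bool = False
    ec: Optional[str] = None
    genes: list[tuple[str, float]] = field(default_factory=list)

    def key(self) -> tuple:
        return (self.diameter, frozenset(self.delta.items()),
                self.substrate_arity, self.product_arity)


class SignatureCache:
    """Memoized per-metabolite molecular signatures at a fixed diameter."""

    def __init__(self, diameter: int):
        self.diameter = diameter
        self._sigs: dict[str, Counter] = {}
        self._atoms: dict[str, int] = {}

    def get(self, met: Metabolite) -> Counter:
        if met.structure is None:
            raise RuleError(f"metabolite {met.id!r} has no structure")
        if met.id not in self._sigs:
            sv = molecular_signature(met.structure, self.diameter)
            self._sigs[met.id] = Counter(sv.counts)
            self._atoms[met.id] = sv.total()
        return self._sigs[met.id]

    def n_atoms(self, met: Metabolite) -> int:
        self.get(met)
        return self._atoms[met.id]


def _int_coeff(rxn: Reaction, mid: str, coeff: Fraction) -> int:
    if coeff.denominator != 1:
        raise RuleError(
            f"reaction {rxn.id!r}: non-integer stoichiometry {coeff} for {mid!r}; "
            f"rules require integer coefficients")
    return int(coeff)


def derive_rule(rxn: Reaction, net: MetabolicNetwork, diameter: int,
                cache: Optional[SignatureCache] = None,
                rule_id: Optional[str] = None) -> ReactionRule:
    """Derive the reaction rule of ``rxn`` at ``diameter``.

    ``delta`` = sum over products of stoich x signature minus the same sum
    over substrates; arities are the total substrate/product coefficients.
    """
    cache = cache or SignatureCache(diameter)
    delta: Counter = Counter()
    sub_arity = prod_arity = 0
    for mid, coeff in sorted(rxn.stoich.items()):
        met = net.metabolites.get(mid)
        if met is None or met.structure is None:
            raise RuleError(
                f"cannot derive rule for {rxn.id!r}: metabolite {mid!r} lacks a structure")
        n = _int_coeff(rxn, mid, coeff)
        sig = cache.get(met)
        for k, v in sig.items():
            delta[k] += n * v
        if n < 0:
            sub_arity += -n
        else:
            prod_arity += n
    return ReactionRule(
        id=rule_id or f"rule_d{diameter}_{rxn.id}",
        diameter=diameter,
        delta={k: v for k, v in delta.items() if v},
        substrate_arity=sub_arity,
        product_arity=prod_arity,
        template_reaction_ids=[rxn.id],
        reversible=rxn.reversible, ec=rxn.ec, genes=list(rxn.genes),
    )


def derive_rule_set(net: MetabolicNetwork, diameters: Iterable[int],
                    log: Optional[list[str]] = None) -> list[ReactionRule]:
    """One rule per (reaction, diameter), deduplicated by
    (diameter, delta, arities) with template ids merged.  Reactions lacking
    structures are skipped (logged)."""
    rules: dict[tuple, ReactionRule] = {}
    skipped: list[str] = []
    for d in diameters:
        cache = SignatureCache(d)
        for rid in sorted(net.reactions):
            rxn = net.reactions[rid]
            try:
                rule = derive_rule(rxn, net, d, cache=cache)
            except RuleError:
                skipped.append(f"{rid}@d={d}")
                continue
            k = rule.key()
            if k in rules:
                rules[k].template_reaction_ids.append(rid)
            else:
                rules[k] = rule
    out = sorted(rules.values(),
                 key=lambda r: (r.diameter, sorted(r.template_reaction_ids)))
    for i, rule in enumerate(out):
        rule.id = f"rule_d{rule.diameter}_{i:03d}"
        rule.template_reaction_ids.sort()
    if log is not None and skipped:
        log.append(f"derive_rule_set skipped {len(skipped)} reaction/diameter "
                   f"pairs lacking structures: {','.join(skipped)}")
    return out


def _candidate_products(rule: ReactionRule, substrates: tuple[Metabolite, ...],
                        universe: MetabolicNetwork,
                        cache: SignatureCache) -> list[tuple[str, ...]]:
    """All multisets of ``product_arity`` universe metabolites whose
    signatures sum exactly to ``sum(substrate sigs) + delta``."""
    target: Counter = Counter()
    for met in substrates:
        target += cache.get(met)
    for k, v in rule.delta.items():
        target[k] += v
    target = +target if all(v >= 0 for v in target.values()) else None
    if target is None:
        return []
    target = Counter({k: v for k, v in target.items() if v})
    total = sum(target.values())

    # candidates sorted by descending atom count for pruning
    cands = [universe.metabolites[mid] for mid in sorted(universe.metabolites)
             if universe.metabolites[mid].structure is not None]
    cands.sort(key=lambda m: (-cache.n_atoms(m), m.id))

    results: list[tuple[str, ...]] = []

    def search(idx: int, slots: int, remaining: Counter, rem_total: int,
               chosen: list[str]) -> None:
        if slots == 0:
            if rem_total == 0:
                results.append(tuple(chosen))
            return
        for i in range(idx, len(cands)):
            met = cands[i]
            na = cache.n_atoms(met)
            if na > rem_total:
                continue
            if na * slots < rem_total:
                break  # sorted descending: no remaining combo can reach total
            sig = cache.get(met)
            if any(remaining[k] < v for k, v in sig.items()):
                continue
            chosen.append(met.id)
            search(i, slots - 1, remaining - sig, rem_total - na, chosen)
            chosen.pop()

    search(0, rule.product_arity, target, total, [])
    return sorted(results)


def apply_rule(rule: ReactionRule, substrates: tuple[Metabolite, ...],
               universe: MetabolicNetwork,
               cache: Optional[SignatureCache] = None,
               skip_existing: bool = True) -> list[Reaction]:
    """Apply ``rule`` to a substrate combination over the known-metabolite
    universe, emitting putative reactions.

    When ``skip_existing`` is true, candidates whose stoichiometry coincides
    with an existing reaction of ``universe`` are suppressed; pass false to
    observe the template closure (a rule applied to its own template
    substrates regenerates the template products).  Candidates whose net
    stoichiometry cancels entirely (identity chemistry) are dropped.
    """
    if len(substrates) != rule.substrate_arity:
        raise RuleError(
            f"rule {rule.id!r} expects {rule.substrate_arity} substrates, "
            f"got {len(substrates)}")
    cache = cache or SignatureCache(rule.diameter)
    existing = {r.stoich_key() for r in universe.reactions.values()} if skip_existing else set()
    sub_counts = Counter(m.id for m in substrates)
    out: list[Reaction] = []
    seen: set[frozenset] = set()
    for prods in _candidate_products(rule, substrates, universe, cache):
        stoich: dict[str, Fraction] = {}
        for mid, n in sub_counts.items():
            stoich[mid] = stoich.get(mid, Fraction(0)) - n
        for mid in prods:
            stoich[mid] = stoich.get(mid, Fraction(0)) + 1
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not any(c < 0 for c in stoich.values()) or not any(c > 0 for c in stoich.values()):
            continue
        key = frozenset(stoich.items())
        if key in seen or key in existing:
            continue
        seen.add(key)
        rid = ("ems_" + rule.id + "__"
               + ".".join(sorted(sub_counts.elements()))
               + "__" + ".".join(prods))
        out.append(Reaction(
            id=rid, stoich=stoich, reversible=rule.reversible,
            ec=rule.ec, genes=list(rule.genes),
            origin="putative", rule_id=rule.id))
    return out


def extend_network(net: MetabolicNetwork, rules: list[ReactionRule],
                   max_iterations: int = 50,
                   substrate_cap: int = 2, product_cap: int = 3,
                   log: Optional[list[str]] = None
                   ) -> tuple[MetabolicNetwork, bool, int]:
    """Extend ``net`` with putative promiscuous reactions to a fixpoint.

    Each iteration sweeps every rule over all substrate combinations of the
    (fixed) metabolite universe; new reactions are added until a sweep adds
    nothing or ``max_iterations`` is reached.  Rules whose arities exceed the
    caps are skipped for enumeration (combinatorial control).
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    out = net.copy()
    caches: dict[int, SignatureCache] = {}
    mets = [out.metabolites[mid] for mid in sorted(out.metabolites)
            if out.metabolites[mid].structure is not None]
    converged = False
    iterations = 0
    for _ in range(max_iterations):
        iterations += 1
        added = 0
        for rule in rules:
            if rule.substrate_arity > substrate_cap or rule.product_arity > product_cap:
                continue
            cache = caches.setdefault(rule.diameter, SignatureCache(rule.diameter))
            for combo in itertools.combinations_with_replacement(mets, rule.substrate_arity):
                for rxn in apply_rule(rule, combo, out, cache=cache):
                    if rxn.id not in out.reactions:
                        out.add_reaction(rxn)
                        added += 1
        if log is not None:
            log.append(f"extension iteration {iterations}: {added} reaction(s) added")
        if added == 0:
            converged = True
            break
    return out, converged, iterations


# ---------------------------------------------------------------------------
# rule set serialization

def rules_to_tsv(rules: list[ReactionRule]) -> str:
    lines = ["# id\tdiameter\tdelta_json\tsubstrate_arity\tproduct_arity\ttemplates"]
    for r in rules:
        lines.append("\t".join([
            r.id, str(r.diameter),
            json.dumps(r.delta, sort_keys=True),
            str(r.substrate_arity), str(r.product_arity),
            ",".join(r.template_reaction_ids),
        ]))
    return "\n".join(lines) + "\n"


def rules_from_tsv(text: str, net: Optional[MetabolicNetwork] = None
                   ) -> list[ReactionRule]:
    rules = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rid, d, delta, sa, pa, templates = line.split("\t")
        tids = templates.split(",") if templates else []
        rule = ReactionRule(
            id=rid, diameter=int(d),
            delta={k: int(v) for k, v in json.loads(delta).items()},
            substrate_arity=int(sa), product_arity=int(pa),
            template_reaction_ids=tids)
        if net is not None and tids and tids[0] in net.reactions:
            t = net.reactions[tids[0]]
            rule.reversible, rule.ec, rule.genes = t.reversible, t.ec, list(t.genes)
        rules.append(rule)
    return rules
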