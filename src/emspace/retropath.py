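"""Retrosynthetic scope computation, stoichiometric-matrix construction and
elementary-flux-mode enumeration of target-producing pathways.

The scope is computed in two passes: a forward reachability fixpoint from the
chassis metabolites (a reaction fires when all its substrates are reachable;
side compounds are always available), then a backward pruning pass from the
target that retains only reactions able to participate in a target-producing
route.  The scope's stoichiometric matrix opens boundary columns — uptake for
endogenous precursors, reversible exchange for side compounds, and a single
target sink — and all pathways are enumerated as its elementary flux modes
(EFMs) with positive sink flux, using exact rational arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Optional

from .network import MetabolicNetwork, NetworkError

UPTAKE_PREFIX = "UPT_"
EXCHANGE_PREFIX = "EXC_"
SINK_PREFIX = "SINK_"


class NoPathwayError(ValueError):
    """Target cannot be reached from the chassis."""


@dataclass
class Scope:
    reactions: set[str]
    metabolites: set[str]
    precursors: set[str]
    target: str


@dataclass
class StoichiometricMatrix:
    """Metabolites x reactions matrix over exact rationals with boundary
    columns (uptake / exchange / sink) appended."""

    met_ids: list[str]
    col_ids: list[str]
    entries: dict[str, dict[str, Fraction]]  # col -> met -> coeff
    reversible: dict[str, bool]
    kinds: dict[str, str]  # col -> reaction|uptake|exchange|sink
    sink_col: str
    target: str

    def column(self, col: str) -> list[Fraction]:
        e = self.entries[col]
        return [e.get(m, Fraction(0)) for m in self.met_ids]


@dataclass
class Pathway:
    """A target-producing elementary flux mode of the scope matrix."""

    flux: dict[str, Fraction]  # column id -> flux (integer-scaled)
    target: str
    precursors: set[str]       # endogenous metabolites drawn by this mode
    support: tuple[str, ...]   # non-boundary reaction ids, sorted
    n_steps: int
    n_putative: int

    @property
    def sink_flux(self) -> Fraction:
        for col, v in self.flux.items():
            if col.startswith(SINK_PREFIX):
                return v
        return Fraction(0)

    def uptake_of(self, met_id: str) -> Fraction:
        return self.flux.get(UPTAKE_PREFIX + met_id, Fraction(0))


# ---------------------------------------------------------------------------
# scope

def forward_reachable(net: MetabolicNetwork, seeds: set[str]) -> set[str]:
    """Least fixpoint of metabolites reachable from ``seeds``; a reaction
    fires when all substrates are reachable (side compounds always are),
    reversible reactions fire in both directions."""
    unknown = seeds - set(net.metabolites)
    if unknown:
        raise NetworkError(f"seed metabolites not in network: {sorted(unknown)}")
    reach = set(seeds) | set(net.side_compounds)
    changed = True
    while changed:
        changed = False
        for rxn in net.reactions.values():
            subs, prods = set(rxn.substrates()), set(rxn.products())
            if subs <= reach and not prods <= reach:
                reach |= prods
                changed = True
            if rxn.reversible and prods <= reach and not subs <= reach:
                reach |= subs
                changed = True
    return reach


def backward_prune(net: MetabolicNetwork, reachable: set[str], target: str) -> Scope:
    """Backward fixpoint from ``target``: retain every fireable reaction that
    produces a needed metabolite; consumed metabolites become needed, and only
    non-endogenous ones are expanded further.  Precursors are the needed
    endogenous metabolites."""
    if target not in net.metabolites:
        raise NetworkError(f"target {target!r} not in network")
    if target not in reachable:
        raise NoPathwayError(
            f"no pathway: target {target!r} is not reachable from the chassis")
    endo = net.endogenous_ids()
    side = net.side_compounds
    needed: set[str] = {target}
    frontier = [target]
    scope_rxns: set[str] = set()
    while frontier:
        met = frontier.pop()
        for rid, rxn in net.reactions.items():
            subs, prods = rxn.substrates(), rxn.products()
            directions = []
            if met in prods and set(subs) <= reachable:
                directions.append(subs)
            if rxn.reversible and met in subs and set(prods) <= reachable:
                directions.append(prods)
            if not directions:
                continue
            scope_rxns.add(rid)
            for consumed in directions:
                for m in consumed:
                    if m in side or m in needed:
                        continue
                    needed.add(m)
                    if m not in endo:
                        frontier.append(m)
    mets: set[str] = {target}
    for rid in scope_rxns:
        mets |= set(net.reactions[rid].stoich)
    return Scope(reactions=scope_rxns, metabolites=mets,
                 precursors=(needed & endo) - side, target=target)


def build_stoichiometric_matrix(scope: Scope, net: MetabolicNetwork
                                ) -> StoichiometricMatrix:
    """Matrix of the scope with uptake columns for precursors, reversible
    exchange columns for side compounds, and one irreversible target sink."""
    if not scope.reactions:
        raise NetworkError("empty scope: no reactions to build a matrix from")
    met_ids = sorted(scope.metabolites)
    entries: dict[str, dict[str, Fraction]] = {}
    reversible: dict[str, bool] = {}
    kinds: dict[str, str] = {}
    col_ids: list[str] = []
    for rid in sorted(scope.reactions):
        rxn = net.reactions[rid]
        col_ids.append(rid)
        entries[rid] = dict(rxn.stoich)
        reversible[rid] = rxn.reversible
        kinds[rid] = "reaction"
    for mid in sorted(scope.precursors):
        cid = UPTAKE_PREFIX + mid
        col_ids.append(cid)
        entries[cid] = {mid: Fraction(1)}
        reversible[cid] = False
        kinds[cid] = "uptake"
    for mid in sorted(net.side_compounds & scope.metabolites):
        cid = EXCHANGE_PREFIX + mid
        col_ids.append(cid)
        entries[cid] = {mid: Fraction(1)}
        reversible[cid] = True
        kinds[cid] = "exchange"
    sink = SINK_PREFIX + scope.target
    col_ids.append(sink)
    entries[sink] = {scope.target: Fraction(-1)}
    reversible[sink] = False
    kinds[sink] = "sink"
    return StoichiometricMatrix(
        met_ids=met_ids, col_ids=col_ids, entries=entries,
        reversible=reversible, kinds=kinds, sink_col=sink, target=scope.target)


# ---------------------------------------------------------------------------
# elementary flux modes (exact rational double-description tableau)

def _normalize(vec: list[Fraction]) -> list[Fraction]:
    """Scale to the smallest non-negative integer vector."""
    denom_lcm = 1
    for v in vec:
        if v:
            denom_lcm = denom_lcm * v.denominator // gcd(denom_lcm, v.denominator)
    ints = [int(v * denom_lcm) for v in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    return [Fraction(v) for v in ints]


def _efm_irreversible(columns: list[list[Fraction]], n_mets: int
                      ) -> list[list[Fraction]]:
    """EFMs of S v = 0, v >= 0 for a fully irreversible system given the
    matrix as a list of columns; Schuster-style tableau with a pairwise
    support-minimality test."""
    n = len(columns)
    rows = [([Fraction(int(i == j)) for j in range(n)], list(columns[i]))
            for i in range(n)]
    for j in range(n_mets):
        zero, plus, minus = [], [], []
        for vec, rest in rows:
            if rest[j] == 0:
                zero.append((vec, rest))
            elif rest[j] > 0:
                plus.append((vec, rest))
            else:
                minus.append((vec, rest))
        cand = list(zero)
        for pv, pr in plus:
            for mv, mr in minus:
                a, b = -mr[j], pr[j]
                vec = [a * x + b * y for x, y in zip(pv, mv)]
                rest = [a * x + b * y for x, y in zip(pr, mr)]
                whole = _normalize(vec + rest)  # one scale for both parts
                cand.append((whole[:n], whole[n:]))
        supports = [frozenset(i for i, v in enumerate(vec) if v) for vec, _ in cand]
        keep = []
        for i, (vec, rest) in enumerate(cand):
            minimal = True
            for k, sup in enumerate(supports):
                if k != i and sup < supports[i]:
                    minimal = False
                    break
            if minimal:
                keep.append((vec, rest))
        # drop duplicates (same support, proportional vectors)
        uniq: dict[tuple, tuple] = {}
        for vec, rest in keep:
            uniq.setdefault(tuple(vec), (vec, rest))
        rows = list(uniq.values())
    return [_normalize(vec) for vec, _ in rows]


def elementary_flux_modes(matrix: StoichiometricMatrix
                          ) -> list[dict[str, Fraction]]:
    """Complete, duplicate-free elementary flux modes of the matrix.

    Reversible columns are split into forward/backward parts, the
    irreversible EFMs computed exactly, futile forward+backward two-cycles
    removed, and modes mapped back to signed fluxes on the original columns
    (smallest-integer scaling; a fully reversible mode is reported once, with
    its sink — or first support column — positive)."""
    cols: list[list[Fraction]] = []
    col_map: list[tuple[str, int]] = []  # (col id, sign)
    for cid in matrix.col_ids:
        col = matrix.column(cid)
        cols.append(col)
        col_map.append((cid, +1))
        if matrix.reversible[cid]:
            cols.append([-v for v in col])
            col_map.append((cid, -1))
    raw = _efm_irreversible(cols, len(matrix.met_ids))
    modes: dict[tuple, dict[str, Fraction]] = {}
    for vec in raw:
        flux: dict[str, Fraction] = {}
        both = False
        for v, (cid, sign) in zip(vec, col_map):
            if v:
                flux[cid] = flux.get(cid, Fraction(0)) + sign * v
        # detect futile two-cycles: forward and backward of one column only
        support = [c for c, v in flux.items() if v]
        if not support:
            continue
        used = {}
        for v, (cid, sign) in zip(vec, col_map):
            if v:
                used.setdefault(cid, set()).add(sign)
        if any(len(s) == 2 for s in used.values()):
            continue  # both directions of a split column: futile cycle
        flux = {c: v for c, v in flux.items() if v}
        # canonical sign: sink positive, else first support column positive
        order = sorted(flux)
        ref = matrix.sink_col if flux.get(matrix.sink_col) else order[0]
        if flux[ref] < 0:
            if all(matrix.reversible[c] for c in flux):
                flux = {c: -v for c, v in flux.items()}
            else:
                continue  # infeasible orientation
        vals = _normalize([flux.get(c, Fraction(0)) for c in matrix.col_ids])
        flux = {c: v for c, v in zip(matrix.col_ids, vals) if v}
        modes[tuple(sorted(flux.items()))] = flux
    return [modes[k] for k in sorted(modes)]


# ---------------------------------------------------------------------------
# pathway enumeration

def enumerate_pathways(net: MetabolicNetwork, chassis_seeds: set[str],
                       target: str) -> list[Pathway]:
    """Scope -> matrix -> EFM; keep modes with positive target-sink flux,
    ordered lexicographically by reaction support."""
    if target not in net.metabolites:
        raise NetworkError(f"target {target!r} not in network")
    reach = forward_reachable(net, chassis_seeds)
    scope = backward_prune(net, reach, target)
    if not scope.reactions:
        return []
    matrix = build_stoichiometric_matrix(scope, net)
    pathways: list[Pathway] = []
    for flux in elementary_flux_modes(matrix):
        if flux.get(matrix.sink_col, Fraction(0)) <= 0:
            continue
        support = tuple(sorted(
            c for c in flux if matrix.kinds[c] == "reaction"))
        precursors = {c[len(UPTAKE_PREFIX):] for c in flux
                      if matrix.kinds[c] == "uptake" and flux[c] > 0}
        n_putative = sum(
            1 for c in support if net.reactions[c].origin == "putative")
        pathways.append(Pathway(
            flux=flux, target=target, precursors=precursors,
            support=support, n_steps=len(support), n_putative=n_putative))
    pathways.sort(key=lambda p: p.support)
    return pathways
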