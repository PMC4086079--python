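"""Multi-criteria pathway scoring: gene score, toxicity, maximum allowable
yield (FBA), Gibbs energy, and k-best gene-construct enumeration.

The total score of a pathway is a weighted sum of four criteria normalized
across the enumerated set, with fixed directions: higher gene score, higher
log10(IC50) (less toxic), higher yield and lower summed ΔG° are all better.
Published totals from any particular server deployment are not reproducible
because the weights used there are unpublished; the defaults here are equal
weights with min-max normalization.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .network import FBAModel, MetabolicNetwork
from .retropath import Pathway, UPTAKE_PREFIX

logger = logging.getLogger("emspace.ranking")

INF = float("inf")


class FBAError(RuntimeError):
    pass


@dataclass
class PathwayScore:
    """The eight ranked quantities of one pathway."""

    total: float
    gene_score: float
    n_steps: int
    n_putative: int
    toxicity: Optional[float]      # mean log10(IC50) over intermediates
    yield_: Optional[float]        # mol target per unit flux basis
    gibbs_sum: float               # kcal/mol
    n_unfavorable: int
    bottleneck: Optional[str] = None


@dataclass
class ScoreWeights:
    w_gene: float = 1.0
    w_tox: float = 1.0
    w_yield: float = 1.0
    w_gibbs: float = 1.0
    normalization: str = "minmax"  # minmax | zscore | none


@dataclass
class Construct:
    choice: dict[str, str]  # step (reaction id) -> gene id
    score: float


# ---------------------------------------------------------------------------
# per-pathway criteria

def gene_score(p: Pathway, net: MetabolicNetwork) -> float:
    """Mean over steps of the best candidate gene score; a step without
    candidates contributes 0 (logged)."""
    if not p.support:
        return 0.0
    total = 0.0
    for rid in p.support:
        genes = net.reactions[rid].genes
        if not genes:
            logger.info("gene_score: step %s has no gene candidates; counts as 0", rid)
            continue
        total += max(s for _, s in genes)
    return total / len(p.support)


def pathway_intermediates(p: Pathway, net: MetabolicNetwork) -> set[str]:
    """Metabolites both produced and consumed by the pathway's enzymatic
    steps, excluding precursors, side compounds and the target."""
    produced: set[str] = set()
    consumed: set[str] = set()
    for rid in p.support:
        v = p.flux[rid]
        for mid, coeff in net.reactions[rid].stoich.items():
            net_flow = v * coeff
            if net_flow > 0:
                produced.add(mid)
            elif net_flow < 0:
                consumed.add(mid)
    inter = (produced & consumed) - p.precursors - net.side_compounds - {p.target}
    return inter


def toxicity_score(p: Pathway, net: MetabolicNetwork) -> Optional[float]:
    """Mean log10(IC50) over pathway intermediates with known values;
    ``None`` (neutral ranking contribution) when no value is available."""
    vals = []
    for mid in sorted(pathway_intermediates(p, net)):
        tox = net.metabolites[mid].toxicity
        if tox is None:
            logger.info("toxicity_score: intermediate %s has no log(IC50); skipped", mid)
        else:
            vals.append(tox)
    if not vals:
        return None
    return sum(vals) / len(vals)


def gibbs_metrics(p: Pathway, net: MetabolicNetwork) -> tuple[float, int]:
    """(sum of step ΔG° in kcal/mol, number of steps with ΔG° > 0);
    steps lacking ΔG° contribute 0 and are excluded from the count."""
    total = 0.0
    unfavorable = 0
    for rid in p.support:
        dg = net.reactions[rid].delta_g
        if dg is None:
            logger.info("gibbs_metrics: step %s has no ΔG°; contributes 0", rid)
            continue
        total += dg
        if dg > 0:
            unfavorable += 1
    return total, unfavorable


# ---------------------------------------------------------------------------
# flux balance analysis

def _lp(model: FBAModel, objective_col: str, maximize: bool = True,
        extra_cols: Optional[dict[str, dict[str, float]]] = None,
        extra_constraints: Optional[list[tuple[dict[str, float], float]]] = None,
        ) -> tuple[dict[str, float], float]:
    """Solve max/min c'v s.t. S v = 0, lb <= v <= ub (+ optional columns and
    >=-constraints); exact problem sizes here are tiny."""
    cols = list(model.reactions)
    stoich = {r: dict(model.stoich.get(r, {})) for r in cols}
    lower = dict(model.lower)
    upper = dict(model.upper)
    if extra_cols:
        for cid, coef in extra_cols.items():
            cols.append(cid)
            stoich[cid] = dict(coef)
            lower[cid] = 0.0
            upper[cid] = INF
    mets = model.metabolites
    m_idx = {m: i for i, m in enumerate(mets)}
    A_eq = np.zeros((len(mets), len(cols)))
    for j, cid in enumerate(cols):
        for mid, coeff in stoich[cid].items():
            A_eq[m_idx[mid], j] = float(coeff)
    c = np.zeros(len(cols))
    c[cols.index(objective_col)] = -1.0 if maximize else 1.0
    A_ub, b_ub = None, None
    if extra_constraints:
        A_ub = np.zeros((len(extra_constraints), len(cols)))
        b_ub = np.zeros(len(extra_constraints))
        for i, (coefs, rhs) in enumerate(extra_constraints):  # sum >= rhs
            for cid, coeff in coefs.items():
                A_ub[i, cols.index(cid)] = -coeff
            b_ub[i] = -rhs
    bounds = [(lower.get(cid, 0.0), None if upper.get(cid, INF) == INF
               else upper.get(cid, INF)) for cid in cols]
    bounds = [(None if lb == -INF else lb, ub) for lb, ub in bounds]
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(len(mets)), A_ub=A_ub, b_ub=b_ub,
                  bounds=bounds, method="highs")
    if res.status == 3:
        raise FBAError(f"objective {objective_col!r} is unbounded")
    if res.status != 0:
        raise FBAError(f"LP failed ({res.status}): {res.message}")
    flux = {cid: float(v) for cid, v in zip(cols, res.x)}
    return flux, (-res.fun if maximize else res.fun)


def fba_optimize(model: FBAModel) -> tuple[dict[str, float], float]:
    """Maximize the biomass objective under steady state and bounds;
    returns (flux vector, objective value)."""
    return _lp(model, model.objective, maximize=True)


def max_allowable_yield(p: Pathway, model: FBAModel,
                        growth_fraction: float = 0.0
                        ) -> tuple[float, Optional[str]]:
    """Minimum over precursors of (available drain flux / stoichiometric
    demand per unit target); returns (yield, bottleneck precursor).

    Availability of precursor *q* is the maximum flux of a synthetic drain of
    *q* subject to biomass >= growth_fraction x wild-type optimum.
    """
    missing = [q for q in sorted(p.precursors) if q not in model.metabolites]
    if missing:
        raise FBAError(f"precursors absent from the FBA model: {missing}")
    sink = p.sink_flux
    if sink <= 0:
        raise ValueError("pathway has no positive target sink flux")
    constraints = None
    if growth_fraction > 0:
        _, wt = fba_optimize(model)
        constraints = [({model.objective: 1.0}, growth_fraction * wt)]
    best: Optional[tuple[float, str]] = None
    for q in sorted(p.precursors):
        drain = f"__drain_{q}"
        _, avail = _lp(model, drain, maximize=True,
                       extra_cols={drain: {q: -1.0}},
                       extra_constraints=constraints)
        demand = float(p.uptake_of(q) / sink)
        if demand <= 0:
            continue
        y = avail / demand
        if best is None or y < best[0]:
            best = (y, q)
    if best is None:
        raise FBAError("pathway draws no precursor; yield undefined")
    return best


# ---------------------------------------------------------------------------
# total score and ranking

def _score_components(pathways: list[Pathway], net: MetabolicNetwork,
                      model: Optional[FBAModel],
                      growth_fraction: float) -> list[PathwayScore]:
    scores = []
    for p in pathways:
        g = gene_score(p, net)
        tox = toxicity_score(p, net)
        gsum, unfav = gibbs_metrics(p, net)
        y: Optional[float] = None
        bneck: Optional[str] = None
        if model is not None:
            y, bneck = max_allowable_yield(p, model, growth_fraction)
        scores.append(PathwayScore(
            total=0.0, gene_score=g, n_steps=p.n_steps, n_putative=p.n_putative,
            toxicity=tox, yield_=y, gibbs_sum=gsum, n_unfavorable=unfav,
            bottleneck=bneck))
    return scores


def _normalize_axis(values: list[Optional[float]], higher_better: bool,
                    mode: str) -> list[float]:
    present = [v for v in values if v is not None]
    if not present:
        return [0.5] * len(values)
    if mode == "none":
        out = [(v if v is not None else sum(present) / len(present)) for v in values]
        return [v if higher_better else -v for v in out]
    if mode == "zscore":
        mu = sum(present) / len(present)
        sd = (sum((v - mu) ** 2 for v in present) / len(present)) ** 0.5
        out = [0.0 if v is None else ((v - mu) / sd if sd else 0.0) for v in values]
        return [v if higher_better else -v for v in out]
    if mode == "minmax":
        lo, hi = min(present), max(present)
        span = hi - lo
        out = []
        for v in values:
            if v is None or span == 0:
                out.append(0.5)
            else:
                x = (v - lo) / span
                out.append(x if higher_better else 1.0 - x)
        return out
    raise ValueError(f"unknown normalization {mode!r}")


def total_score(scores: list[PathwayScore],
                weights: Optional[ScoreWeights] = None) -> list[float]:
    """Weighted sum of the four normalized criteria across the pathway set
    (higher gene score / log(IC50) / yield better; lower ΔG sum better)."""
    if not scores:
        return []
    w = weights or ScoreWeights()
    g = _normalize_axis([s.gene_score for s in scores], True, w.normalization)
    t = _normalize_axis([s.toxicity for s in scores], True, w.normalization)
    y = _normalize_axis([s.yield_ for s in scores], True, w.normalization)
    dg = _normalize_axis([s.gibbs_sum for s in scores], False, w.normalization)
    return [w.w_gene * gi + w.w_tox * ti + w.w_yield * yi + w.w_gibbs * di
            for gi, ti, yi, di in zip(g, t, y, dg)]


def rank_pathways(pathways: list[Pathway], net: MetabolicNetwork,
                  model: Optional[FBAModel] = None,
                  weights: Optional[ScoreWeights] = None,
                  growth_fraction: float = 0.0
                  ) -> list[tuple[Pathway, PathwayScore]]:
    """Score every pathway and order by descending total (ties broken by
    fewer steps, then lexicographic support)."""
    scores = _score_components(pathways, net, model, growth_fraction)
    totals = total_score(scores, weights)
    for s, tot in zip(scores, totals):
        s.total = tot
    ranked = sorted(zip(pathways, scores),
                    key=lambda ps: (-ps[1].total, ps[1].n_steps, ps[0].support))
    return ranked


def ranking_table_tsv(ranked: list[tuple[Pathway, PathwayScore]]) -> str:
    """Summary table mirroring the ranked-pathway report columns."""
    lines = ["Rank\tTotal score\tGene score\tSteps\tPutatives\tToxicity\t"
             "Yield\tGibbs\tUnfavorable\tReactions"]
    for i, (p, s) in enumerate(ranked, 1):
        lines.append("\t".join([
            str(i), f"{s.total:.3f}", f"{s.gene_score:.3f}",
            str(s.n_steps), str(s.n_putative),
            "" if s.toxicity is None else f"{s.toxicity:.3f}",
            "" if s.yield_ is None else f"{s.yield_:.2e}",
            f"{s.gibbs_sum:.3f}", str(s.n_unfavorable),
            ",".join(p.support)]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# k-best gene constructs

def top_constructs(p: Pathway, net: MetabolicNetwork, k: int = 10
                   ) -> list[Construct]:
    """The ``k`` highest-scoring assignments of one gene per step, by lazy
    best-first enumeration over the per-step candidate lists (no Cartesian
    product); construct score = mean of chosen gene scores, ties broken by
    the gene-id tuple."""
    if k < 1:
        raise ValueError("k must be >= 1")
    steps = list(p.support)
    cand: list[list[tuple[str, float]]] = []
    for rid in steps:
        genes = net.reactions[rid].genes
        if not genes:
            raise ValueError(f"step {rid!r} has no gene candidates; construct impossible")
        cand.append(sorted(genes, key=lambda g: (-g[1], g[0])))
    n = len(steps)

    def entry(idx: tuple[int, ...]):
        total = sum(cand[i][j][1] for i, j in enumerate(idx))
        genes = tuple(cand[i][j][0] for i, j in enumerate(idx))
        return (-total / n, genes, idx)

    start = tuple([0] * n)
    heap = [entry(start)]
    seen = {start}
    out: list[Construct] = []
    while heap and len(out) < k:
        neg_score, genes, idx = heapq.heappop(heap)
        out.append(Construct(
            choice={steps[i]: cand[i][j][0] for i, j in enumerate(idx)},
            score=-neg_score))
        for i in range(n):
            if idx[i] + 1 < len(cand[i]):
                nxt = idx[:i] + (idx[i] + 1,) + idx[i + 1:]
                if nxt not in seen:
                    seen.add(nxt)
                    heapq.heappush(heap, entry(nxt))
    return out
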