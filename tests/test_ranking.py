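"""Pathway scoring, FBA, yield LP, total score, k-best constructs."""

import itertools
from fractions import Fraction

import pytest

from emspace.network import (FBAModel, MetabolicNetwork, Metabolite, Reaction,
                             parse_equation)
from emspace.ranking import (FBAError, PathwayScore, ScoreWeights, fba_optimize,
                             gene_score, gibbs_metrics, max_allowable_yield,
                             rank_pathways, top_constructs, total_score,
                             toxicity_score)
from emspace.retropath import Pathway

INF = float("inf")


def pathway(support, flux_extra=None, precursors=frozenset({"q"}),
            target="t", sink=1):
    flux = {rid: Fraction(1) for rid in support}
    flux[f"SINK_{target}"] = Fraction(sink)
    for q in precursors:
        flux.setdefault(f"UPT_{q}", Fraction(1))
    if flux_extra:
        flux.update({k: Fraction(v) for k, v in flux_extra.items()})
    return Pathway(flux=flux, target=target, precursors=set(precursors),
                   support=tuple(sorted(support)), n_steps=len(support),
                   n_putative=0)


def scoring_net(steps):
    """Chain network q -> i1 -> ... -> t with per-step (genes, dG, tox)."""
    net = MetabolicNetwork()
    names = ["q"] + [f"i{k}" for k in range(1, len(steps))] + ["t"]
    for mid in names:
        net.add_metabolite(Metabolite(id=mid, name=mid,
                                      endogenous=(mid == "q")))
    for k, (rid, genes, dg, tox) in enumerate(steps):
        net.add_reaction(Reaction(
            id=rid, stoich=parse_equation(f"{names[k]} => {names[k + 1]}"),
            genes=genes, delta_g=dg))
        if k < len(steps) - 1 and tox is not None:
            net.metabolites[names[k + 1]].toxicity = tox
    return net


class TestGeneScore:
    def test_all_best_one(self):
        net = scoring_net([("a", [("g1", 1.0)], None, None),
                           ("b", [("g2", 1.0)], None, None)])
        assert gene_score(pathway(("a", "b")), net) == 1.0

    def test_mean_of_best_per_step(self):
        net = scoring_net([("a", [("g1", 0.4), ("g1b", 0.1)], None, None),
                           ("b", [("g2", 0.8)], None, None)])
        assert gene_score(pathway(("a", "b")), net) == pytest.approx(0.6)

    def test_step_without_candidates_counts_zero(self):
        net = scoring_net([("a", [("g1", 0.9)], None, -1.0),
                           ("b", [("g2", 0.9)], None, -1.0),
                           ("c", [], None, None)])
        assert gene_score(pathway(("a", "b", "c")), net) == pytest.approx(0.6)


class TestToxicity:
    def test_uniform(self):
        net = scoring_net([("a", [], None, -1.0), ("b", [], None, -1.0),
                           ("c", [], None, None)])
        assert toxicity_score(pathway(("a", "b", "c")), net) == pytest.approx(-1.0)

    def test_mean(self):
        net = scoring_net([("a", [], None, -2.0), ("b", [], None, 0.0),
                           ("c", [], None, None)])
        assert toxicity_score(pathway(("a", "b", "c")), net) == pytest.approx(-1.0)

    def test_one_step_pathway_has_no_intermediates(self):
        net = scoring_net([("a", [], None, None)])
        assert toxicity_score(pathway(("a",)), net) is None


class TestGibbs:
    @pytest.mark.parametrize("dgs,expected", [
        ((-5.0, -3.0), (-8.0, 0)),
        ((-5.0, 2.0), (-3.0, 1)),
        ((1.0, 1.0, -10.0), (-8.0, 2)),
    ])
    def test_sum_and_unfavorable_count(self, dgs, expected):
        steps = [(f"r{k}", [], dg, None) for k, dg in enumerate(dgs)]
        net = scoring_net(steps)
        p = pathway(tuple(f"r{k}" for k in range(len(dgs))))
        total, unfav = gibbs_metrics(p, net)
        assert total == pytest.approx(expected[0])
        assert unfav == expected[1]

    def test_missing_dg_contributes_zero_and_uncounted(self):
        net = scoring_net([("a", [], None, None), ("b", [], 3.0, None)])
        assert gibbs_metrics(pathway(("a", "b")), net) == (3.0, 1)


def toy_3rxn_model(uptake=10.0):
    return FBAModel(
        metabolites=["A"],
        reactions=["upt", "conv", "biomass"],
        stoich={"upt": {"A": 1.0}, "conv": {"A": -1.0}, "biomass": {"A": -1.0}},
        lower={"upt": 0.0, "conv": 0.0, "biomass": 0.0},
        upper={"upt": uptake, "conv": 0.0, "biomass": INF},
        objective="biomass")


class TestFBA:
    def test_toy_optimum_equals_uptake_bound(self):
        _, obj = fba_optimize(toy_3rxn_model(10.0))
        assert obj == pytest.approx(10.0)

    def test_zero_uptake_zero_biomass(self):
        _, obj = fba_optimize(toy_3rxn_model(0.0))
        assert obj == pytest.approx(0.0)

    def test_unbounded_objective_flagged(self):
        model = FBAModel(metabolites=["A"], reactions=["src", "biomass"],
                         stoich={"src": {"A": 1.0}, "biomass": {"A": -1.0}},
                         lower={"src": 0.0, "biomass": 0.0},
                         upper={"src": INF, "biomass": INF},
                         objective="biomass")
        with pytest.raises(FBAError, match="unbounded"):
            fba_optimize(model)


class TestMaxAllowableYield:
    def model_one_precursor(self, cap=10.0):
        return FBAModel(
            metabolites=["glc", "q"],
            reactions=["upt", "mk_q", "biomass"],
            stoich={"upt": {"glc": 1.0}, "mk_q": {"glc": -1.0, "q": 1.0},
                    "biomass": {"glc": -1.0}},
            lower={r: 0.0 for r in ("upt", "mk_q", "biomass")},
            upper={"upt": cap, "mk_q": INF, "biomass": INF},
            objective="biomass")

    def test_single_precursor_demand_two(self):
        p = pathway(("a",), flux_extra={"UPT_q": 2})
        y, bottleneck = max_allowable_yield(p, self.model_one_precursor(10.0))
        assert y == pytest.approx(5.0)
        assert bottleneck == "q"

    def test_min_over_precursors_and_bottleneck(self):
        model = FBAModel(
            metabolites=["glc", "q", "s"],
            reactions=["upt", "mk_q", "mk_s", "biomass"],
            stoich={"upt": {"glc": 1.0}, "mk_q": {"glc": -1.0, "q": 1.0},
                    "mk_s": {"glc": -1.0, "s": 1.0}, "biomass": {"glc": -1.0}},
            lower={r: 0.0 for r in ("upt", "mk_q", "mk_s", "biomass")},
            upper={"upt": 10.0, "mk_q": INF, "mk_s": 3.0, "biomass": INF},
            objective="biomass")
        p = pathway(("a",), precursors=frozenset({"q", "s"}),
                    flux_extra={"UPT_q": 2, "UPT_s": 1})
        y, bottleneck = max_allowable_yield(p, model)
        # q: 10/2 = 5 ; s: 3/1 = 3 -> min is s
        assert y == pytest.approx(3.0)
        assert bottleneck == "s"

    def test_zero_availability_zero_yield(self):
        p = pathway(("a",), flux_extra={"UPT_q": 1})
        y, _ = max_allowable_yield(p, self.model_one_precursor(0.0))
        assert y == pytest.approx(0.0)

    def test_missing_precursor_is_error(self):
        p = pathway(("a",), precursors=frozenset({"zz"}))
        with pytest.raises(FBAError, match="zz"):
            max_allowable_yield(p, self.model_one_precursor())

    def test_monotone_in_demand(self):
        model = self.model_one_precursor(10.0)
        yields = []
        for demand in (1, 2, 4, 8):
            p = pathway(("a",), flux_extra={"UPT_q": demand})
            yields.append(max_allowable_yield(p, model)[0])
        assert yields == sorted(yields, reverse=True)

    def test_growth_fraction_reduces_availability(self):
        model = self.model_one_precursor(10.0)
        p = pathway(("a",), flux_extra={"UPT_q": 1})
        y_free = max_allowable_yield(p, model, growth_fraction=0.0)[0]
        y_half = max_allowable_yield(p, model, growth_fraction=0.5)[0]
        assert y_half == pytest.approx(5.0)
        assert y_free == pytest.approx(10.0)


def make_score(gene=0.5, tox=-1.0, yld=1.0, gibbs=0.0, steps=2):
    return PathwayScore(total=0.0, gene_score=gene, n_steps=steps,
                        n_putative=0, toxicity=tox, yield_=yld,
                        gibbs_sum=gibbs, n_unfavorable=0)


class TestTotalScore:
    def test_single_pathway_finite(self):
        totals = total_score([make_score()])
        assert totals == [pytest.approx(2.0)]  # four criteria at 0.5 each

    def test_gibbs_direction(self):
        lo = make_score(gibbs=-10.0)
        hi = make_score(gibbs=5.0)
        t = total_score([lo, hi])
        assert t[0] > t[1]

    def test_three_pathway_hand_table(self):
        # min-max by hand: gene (0,0.5,1); tox (1,0,0.5); yield (0,1,0.5);
        # gibbs reversed (1,0,0.5)
        s = [make_score(gene=0.2, tox=-1.0, yld=1.0, gibbs=-5.0),
             make_score(gene=0.4, tox=-3.0, yld=3.0, gibbs=5.0),
             make_score(gene=0.6, tox=-2.0, yld=2.0, gibbs=0.0)]
        t = total_score(s)
        assert t == [pytest.approx(2.0), pytest.approx(1.5), pytest.approx(2.5)]

    def test_permutation_invariance(self):
        s = [make_score(gene=g, gibbs=dg) for g, dg in
             [(0.1, -3.0), (0.9, 2.0), (0.4, 0.0)]]
        base = total_score(s)
        for perm in itertools.permutations(range(3)):
            t = total_score([s[i] for i in perm])
            assert [t[perm.index(i)] for i in range(3)] == pytest.approx(base)

    def test_empty_list(self):
        assert total_score([]) == []

    def test_weights_scale_contributions(self):
        s = [make_score(gene=0.0), make_score(gene=1.0)]
        t = total_score(s, ScoreWeights(w_gene=10.0, w_tox=0, w_yield=0, w_gibbs=0))
        assert t == [pytest.approx(0.0), pytest.approx(10.0)]


class TestRankPathways:
    def test_fixture_ranking_has_all_quantities(self, raspberry,
                                                raspberry_pathways, toy_model):
        net, _, _ = raspberry
        ranked = rank_pathways(raspberry_pathways, net, toy_model)
        assert len(ranked) == 3
        totals = [s.total for _, s in ranked]
        assert totals == sorted(totals, reverse=True)
        for _, s in ranked:
            assert s.toxicity is not None and s.yield_ is not None
            assert s.n_unfavorable <= s.n_steps
        # the thermodynamically favorable ammonia-lyase route wins
        assert ranked[0][0].support == ("4CL", "BAR", "BAS", "TAL")
        assert ranked[0][1].gene_score == pytest.approx(0.545)
        assert ranked[0][1].gibbs_sum == pytest.approx(-26.637)
        assert ranked[0][1].n_unfavorable == 1

    def test_without_model_yield_is_neutral(self, raspberry, raspberry_pathways):
        net, _, _ = raspberry
        ranked = rank_pathways(raspberry_pathways, net, model=None)
        assert all(s.yield_ is None for _, s in ranked)


class TestTopConstructs:
    def test_single_choice(self):
        net = scoring_net([("a", [("g1", 0.5)], None, None),
                           ("b", [("g2", 0.7)], None, None)])
        cons = top_constructs(pathway(("a", "b")), net, k=10)
        assert len(cons) == 1
        assert cons[0].choice == {"a": "g1", "b": "g2"}
        assert cons[0].score == pytest.approx(0.6)

    def test_three_by_three_gives_nine_descending(self):
        genes_a = [("a1", 0.9), ("a2", 0.5), ("a3", 0.1)]
        genes_b = [("b1", 0.8), ("b2", 0.4), ("b3", 0.2)]
        net = scoring_net([("a", genes_a, None, None),
                           ("b", genes_b, None, None)])
        cons = top_constructs(pathway(("a", "b")), net, k=10)
        assert len(cons) == 9
        scores = [c.score for c in cons]
        assert scores == sorted(scores, reverse=True)
        assert cons[0].choice == {"a": "a1", "b": "b1"}

    def test_matches_brute_force_4_steps_5_genes(self):
        steps = []
        for k in range(4):
            genes = [(f"s{k}g{j}", round(0.05 + 0.19 * ((j * 7 + k * 3) % 5), 3))
                     for j in range(5)]
            steps.append((f"r{k}", genes, None, None))
        net = scoring_net(steps)
        p = pathway(tuple(f"r{k}" for k in range(4)))
        cons = top_constructs(p, net, k=10)
        brute = []
        for combo in itertools.product(*[s[1] for s in steps]):
            score = sum(g[1] for g in combo) / 4
            brute.append((score, tuple(g[0] for g in combo)))
        brute.sort(key=lambda x: (-x[0], x[1]))
        got = [(c.score, tuple(c.choice[f"r{k}"] for k in range(4)))
               for c in cons]
        assert [(pytest.approx(s), g) for s, g in brute[:10]] == got

    def test_step_without_candidates_is_error(self):
        net = scoring_net([("a", [], None, None)])
        with pytest.raises(ValueError, match="no gene candidates"):
            top_constructs(pathway(("a",)), net, k=3)

    def test_bad_k_rejected(self):
        net = scoring_net([("a", [("g", 1.0)], None, None)])
        with pytest.raises(ValueError):
            top_constructs(pathway(("a",)), net, k=0)
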