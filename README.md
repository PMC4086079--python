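# emspace

Retrosynthetic design of heterologous metabolic pathways in an *extended
metabolic space*: molecular-signature reaction rules, enzyme-promiscuity-driven
network extension, elementary-flux-mode pathway enumeration into a chassis
organism, and multi-criteria pathway/construct ranking.

## Who this is for

Metabolic engineers and systems biologists who want to ask: *which sets of
heterologous enzymatic steps could make compound X in* E. coli *(or another
chassis), including steps no database records but that known enzymes could
plausibly catalyze — and which of those routes is worth building?*

## The method

**Molecular signatures.** A compound is coded as the multiset of canonical
strings σ_d(a), one per heavy atom *a*, each describing *a*'s bonded
neighborhood up to radius *d*/2 (*d* is the *diameter*, always even). Atom
labels carry element, implicit-H count and formal charge; the multiset
Tanimoto index Σ min / Σ max compares two compounds.

**Reaction rules.** A reaction with stoichiometry S → P yields the rule

    Δ_d = Σ_{p∈P} n_p·σ_d(p) − Σ_{s∈S} n_s·σ_d(s),

the signed signature difference. Environments unchanged by the
transformation cancel, so Δ_d captures only the reaction-center chemistry;
smaller *d* gives a more generic rule.

**Network extension.** Applying every rule to all substrate combinations of
the known-metabolite universe predicts *putative* promiscuous reactions: a
product multiset Q is accepted when Σ σ_d(Q) equals Σ σ_d(substrates) + Δ_d
exactly (which conserves atom counts by construction). Iterating to a
fixpoint yields the extended metabolic space. Because signature truncation
commutes with these sums, the putative set at a smaller diameter is a
superset of the set at any larger diameter.

**Pathway enumeration.** For a target compound, a forward reachability pass
from the chassis metabolites and a backward pruning pass from the target
give the *scope*; its stoichiometric matrix (with uptake columns for
endogenous precursors, reversible exchanges for cofactor-pool side
compounds, and one target sink) is analyzed by exact-rational elementary
flux mode (EFM) enumeration. Every EFM with positive sink flux is one
candidate pathway.

**Ranking.** Each pathway is scored on eight quantities: total score, gene
score (mean best per-step gene prediction), step count, putative-step count,
mean intermediate toxicity log10(IC50), maximum allowable yield
min_q(availability_q / demand_q) from per-precursor FBA drains, summed
ΔG°, and count of thermodynamically unfavorable steps (ΔG° > 0). The total
is a weighted sum of min-max-normalized criteria; the top-k gene constructs
per pathway are enumerated lazily without building the Cartesian product.

## Worked example

The built-in fixture is the raspberry-ketone design case: seven heterologous
steps (TAL, C4H, HPPR + hydroxyphenyllactate hydro-lyase, 4CL, BAS, BAR)
with full structures, balanced stoichiometry, gene candidates, toxicities
and ΔG° values.

```python
from emspace import (enumerate_pathways, rank_pathways, ranking_table_tsv,
                     raspberry_network, toy_fba_model)

net, seeds, target = raspberry_network()
pathways = enumerate_pathways(net, seeds, target)   # 3 elementary modes
print(ranking_table_tsv(rank_pathways(pathways, net, model=toy_fba_model())))
```

prints

```
Rank  Total score  Gene score  Steps  Putatives  Toxicity  Yield     Gibbs    Unfavorable  Reactions
1     2.572        0.545       4      0          -1.009    1.00e+01  -26.637  1            4CL,BAR,BAS,TAL
2     1.614        0.713       5      0          -1.026    1.00e+01  -2.004   2            4CL,BAR,BAS,HPLH,HPPR
3     1.500        0.532       4      0          -1.009    1.00e+01  1.174    2            4CL,BAR,BAS,C4H
```

Three routes reach raspberry ketone, entering 4-coumarate by tyrosine
ammonia-lyase (4 steps), the hydroxyphenylpyruvate reduction route (5 steps)
or cinnamate 4-hydroxylase (4 steps); none needs a putative step. The
tyrosine route wins on thermodynamics (ΔG° sum −26.637 kcal/mol, one
unfavorable step). Yields come from the bundled toy chassis model (uptake
bound 10, one precursor unit per target unit); total scores depend on the
chosen weights and normalization (defaults: equal weights, min-max over the
enumerated set). The `examples/` scripts walk through signatures/similarity,
rule derivation/extension and the full design run; there is also a CLI
(`emspace sign|rules|extend|design|search`).

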