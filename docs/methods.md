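# Methods

This note records the model, the numerical and design choices, and the
limits of what the bundled study cases can show.

## Signature coding

An atomic signature at diameter *d* is a canonical serialization of the
rooted neighborhood of radius *d*/2 around one heavy atom. The
implementation expands a rooted tree: from each atom it visits every
neighbor except the one it arrived from (rings are therefore traversed from
both sides up to the radius), children are sorted lexicographically by their
recursively computed strings, and bond orders are encoded as `-`, `=`, `#`
and `:` (aromatic, as perceived by RDKit and applied identically to all
molecules, so rules cancel consistently). Atom labels are
`[element;H<count>;<charge>]`; stereochemistry and isotopes are discarded.
Odd diameters are rejected — the diameter counts bonds across the
neighborhood, and rule diameters in use are even.

Properties that follow from this scheme and are exercised by the tests:
invariance under any relabeling of atom indices; *diameter refinement*
(atoms with equal signatures at *d* are equal at every smaller even
diameter, because truncating the expansion tree is deterministic); and
count-sum = heavy-atom count for molecular signatures.

The canonical strings are one deterministic choice among many; signature
strings produced by other tools cannot be compared byte-for-byte, only
structurally.

## Reaction rules and extension

A rule is the exact signed difference of product and substrate signature
multisets, weighted by stoichiometry. Integer coefficients are required for
rule derivation (a rational-stoichiometry reaction has no natural substrate
multiset). Identity chemistry — a substrate converted into an identically
coded product — cancels to an empty difference; note that the network
representation stores signed stoichiometry, so a literal A → A reaction has
an empty map and is rejected at construction; identity chemistry is
expressed as A → B with structurally identical A and B.

Rule application searches, for a given substrate tuple, all multisets of
`product_arity` universe metabolites whose signatures sum exactly to
Σ σ_d(substrates) + Δ_d. The search memoizes per-metabolite signatures,
orders candidates by descending atom count and prunes on remaining atom
budget; because the universe is fixed to known metabolites and product
arity is small (≤ 3 by default), this exact multiset-sum is cheap. Matching
conserves atom counts automatically, so every putative reaction passes
balance validation whenever formulas are available.

Extension sweeps every rule over all substrate combinations
(`itertools.combinations_with_replacement` over metabolites with
structures) until a sweep adds no reaction or the iteration cap is reached.
Enumeration is capped at substrate arity 2 and product arity 3
(configurable): rules beyond the caps are still derived and applicable
directly, but are skipped during combinatorial enumeration. Cofactors are
genuine rule participants (no co-substrate subtraction scheme), which keeps
rules mass-consistent; a practical consequence is that multi-cofactor
reactions exceed the arity cap and do not generalize during extension
unless the caps are raised. Putative reactions inherit reversibility, EC
and gene candidates from their template — the only information source
available for a predicted promiscuous activity.

Because signature truncation commutes with multiset sums and differences,
any product multiset matching at diameter *d* also matches at every smaller
diameter: the putative-reaction set is monotone non-increasing in *d*. The
tests check this on a keto-acid toy universe where the reduction rule
transfers to a second substrate at *d* = 0 but not at *d* ≥ 2.

## Scope and pathway enumeration

Forward reachability is a least fixpoint with AND-semantics (a reaction
fires only when all substrates are reachable; side compounds are always
available; reversible reactions fire both ways). Backward pruning from the
target retains reactions that are fireable and produce a needed metabolite;
consumed metabolites become needed, and only non-endogenous ones are
expanded further. Precursors are the needed endogenous metabolites. The
scope over-approximates participation; exactness is enforced by the EFM
stage, where any reaction that cannot carry steady-state flux to the sink
simply appears in no mode.

The scope's stoichiometric matrix keeps every scope metabolite as a
balanced row and opens boundary columns instead of deleting rows: one
irreversible uptake per precursor, one reversible exchange per side
compound, one irreversible target sink. This keeps the net stoichiometric
balance of a pathway (metabolite exchange) readable directly off the mode.

EFMs are computed with a Schuster-style double-description tableau over
exact `fractions.Fraction` arithmetic: reversible columns are split,
metabolite constraints are eliminated one at a time combining positive and
negative rows, and candidates whose support strictly contains another
candidate's support are discarded at each step. Futile two-cycles
(forward + backward of one split column) are removed, fully reversible
modes are reported once with a canonical sign, and vectors are scaled to
the smallest integers. An independent brute-force oracle (subset
enumeration with sympy nullspaces) verifies the implementation on hundreds
of seeded random matrices in the test suite. Internal cycles (modes not
using the sink) are computed but filtered out of pathway results; pathway
identity is the support set, and results are ordered lexicographically by
support before ranking. No pathway-length bound is applied beyond matrix
size.

## Ranking

- **Gene score** — mean over steps of the best candidate score; a step with
  no candidates contributes 0 and is logged. Per-step alternatives are
  covered by the construct view instead of entering the mean.
- **Toxicity** — mean log10(IC50) over intermediates (metabolites both
  produced and consumed by the enzymatic steps, excluding precursors, side
  compounds and the target — the target's own toxicity is a property of the
  product, not the route). Missing values are skipped and logged; a pathway
  with no valued intermediate gets a neutral contribution.
- **Yield** — for each precursor *q*, availability is the maximum flux of a
  synthetic drain of *q* in the chassis FBA model subject to biomass ≥
  γ·(wild-type optimum); γ defaults to 0 (flux bounds alone constrain the
  diversion) and is raisable where growth coupling matters. Demand is the
  mode's uptake of *q* per unit sink flux. The score is min_q
  availability/demand with the arg-min reported as the bottleneck. LPs are
  solved with scipy's HiGHS interface; problems here are tiny and
  numerically benign.
- **Gibbs** — sum of step ΔG° (kcal/mol) and the count of steps with
  ΔG° > 0; steps without ΔG° contribute 0, are excluded from the count,
  and are logged.
- **Total** — weighted sum of the four criteria normalized across the
  enumerated set (min-max by default; z-score and raw available), with
  fixed directions: higher gene score, higher log10(IC50), higher yield,
  lower ΔG° sum. Degenerate axes (all equal, or all missing) normalize to
  0.5 so they cannot reorder the set. Ties break by step count then
  lexicographic support. Published total scores from any particular server
  deployment are **not** reproducible here: the weights used there are
  unpublished; only the component quantities are comparable.
- **Constructs** — k-best assignment of one gene per step by best-first
  heap search over the sorted candidate lists (exact, lazy, no Cartesian
  product), ties broken by the gene-id tuple.

## Fixtures: what they emulate and what they don't

The raspberry-ketone network carries the seven literature-named
heterologous steps with real SMILES, including full CoA and NAD(P)
cofactors and explicit protons; every reaction is element- and
charge-balanced (the BAS condensation is written with a water substrate to
close the balance exactly). Gene scores, toxicities and ΔG° values are
fixture inputs of realistic magnitude — per-step values were chosen so the
three routes differ on every ranking axis (route sums: −26.637 / 1.174 /
−2.004 kcal/mol with 1/2/2 unfavorable steps; mean intermediate toxicities
−1.009 / −1.009 / −1.026) — they are inputs to the method, not predictions
by it. The chassis is represented by its endogenous metabolite list plus a
deliberately hand-solvable toy FBA model (glucose uptake bound 10 feeding
the three precursors and a biomass drain), not a genome-scale
reconstruction: fixture yields therefore demonstrate the LP mechanics, not
physiological yields.

The random-network generator plants one or more disjoint
precursor-to-target routes of a given depth and decorates them with
mass-conserving distractor reactions (synthetic formulas C_k H_2k O_k;
distractors never produce the target or a planted intermediate, so the
planted route is always among the enumerated modes). It emulates network
shape for property tests — reachability, EFM counts, determinism — not
chemistry: distractor metabolites carry formulas, not structures, so
rule-based extension does not apply to them.

Passing tests on these fixtures show the algorithms are correct at desk
scale; they say nothing about coverage or runtime on database-scale
networks (thousands of metabolites), where the extension step is the known
bottleneck.

## Numerical and convention choices

- All stoichiometry and EFM arithmetic is exact-rational; floats appear
  only in scores and LPs.
- Balance validation checks element counts always, total charge only when
  every participant's charge is known (structures present); formula-only
  records are element-checked.
- Problem sizes in the test suite: EFM oracle comparisons use 200 random
  matrices with 3–5 metabolites and 5–12 columns; planted-route recovery
  uses 40 seeds; relabeling invariance uses 100 permutations at d = 8.
- TSV writers emit sorted rows so identical inputs are byte-identical
  (load → write → load is idempotent).
- Name search ranks exact (case-insensitive) matches at similarity 1.0
  before substring matches scored by length ratio; structure search uses
  Tanimoto at d = 4 by default.
- SBML export is Level 3 Version 2; gene constructs are embedded as a
  dedicated XML namespace inside the model annotation (one document per
  pathway), and `import_pathway_sbml` round-trips stoichiometry and
  constructs.

## Known limitations

- No de novo product structures: extension only recombines known
  metabolites, by design.
- No stereochemistry, tautomers or pKa handling in signatures.
- The tableau EFM algorithm is exponential in the worst case; it is meant
  for scope-sized matrices (tens of columns), not genome-scale models.
- Gene scores, toxicities and ΔG° are consumed as inputs; the package does
  not predict them.
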