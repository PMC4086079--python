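"""End-to-end pathway design for raspberry ketone.

Enumerates every heterologous route from E. coli endogenous metabolites to
raspberry ketone as elementary flux modes of the retrosynthetic scope, ranks
them on gene score, toxicity, FBA yield and Gibbs energy, prints the summary
table, and exports the best pathway (with its top gene constructs) to SBML.
"""

from emspace import (enumerate_pathways, export_pathway_sbml, rank_pathways,
                     ranking_table_tsv, raspberry_network, top_constructs,
                     toy_fba_model)

net, seeds, target = raspberry_network()
pathways = enumerate_pathways(net, seeds, target)
print(f"{len(pathways)} pathways from {sorted(seeds)} to {target}\n")

ranked = rank_pathways(pathways, net, model=toy_fba_model())
print(ranking_table_tsv(ranked))
# each row is one elementary mode: its enzymatic steps, how many of them are
# putative, mean intermediate toxicity (log10 IC50, higher = safer), the
# FBA-limited yield from the bottleneck precursor, and summed reaction ΔG°

best, best_score = ranked[0]
print(f"best route: {' -> '.join(best.support)}")
print(f"precursor(s): {sorted(best.precursors)}, "
      f"bottleneck: {best_score.bottleneck}")

constructs = top_constructs(best, net, k=5)
print("\ntop gene constructs (one gene per step, score = mean gene score):")
for c in constructs:
    steps = ", ".join(f"{s}:{g}" for s, g in sorted(c.choice.items()))
    print(f"  {c.score:.3f}  {steps}")

sbml = export_pathway_sbml(best, net, constructs)
print(f"\nSBML export: {len(sbml)} characters, "
      f"{sbml.count('<reaction ')} reaction elements")
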