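"""Reaction rules and promiscuity-driven network extension.

Derives signature-difference rules from a small keto-acid universe and shows
how the diameter d controls generalization: at d = 0 the keto -> hydroxy
reduction rule transfers to a second keto acid (a putative promiscuous
reaction), while at d >= 2 the rule is too specific to fire.
"""

from emspace import derive_rule_set, enumerate_pathways, extend_network
from emspace.fixtures import promiscuity_universe

net, seeds, target = promiscuity_universe()
print("known reactions:", sorted(net.reactions))

for d in (0, 2):
    rules = derive_rule_set(net, [d])
    extended, converged, iters = extend_network(net, rules, max_iterations=10)
    putative = [r for r in extended.reactions.values() if r.origin == "putative"]
    pathways = enumerate_pathways(extended, seeds, target)
    print(f"\ndiameter d={d}: {len(rules)} rules, "
          f"{len(putative)} putative reactions after {iters} iteration(s) "
          f"(converged={converged}), {len(pathways)} pathway(s) to {target}")
    for r in sorted(putative, key=lambda r: r.id):
        subs = "+".join(sorted(m for m, c in r.stoich.items() if c < 0))
        prods = "+".join(sorted(m for m, c in r.stoich.items() if c > 0))
        print(f"  putative {subs} => {prods}   (rule {r.rule_id})")
# smaller diameter = more generic rules = larger extended metabolic space:
# the d=0 extension opens a second route to the target via 2-hydroxybutanoate,
# and predicts keto/hydroxy hydride transfers between the two acid pairs
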