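"""Molecular signatures and compound similarity.

Codes a few small molecules into signature vectors at increasing diameter d
and compares them with the multiset Tanimoto index, then searches the
raspberry-ketone network by name and by structure.
"""

from emspace import (molecular_signature, parse_structure, raspberry_network,
                     search_compound, tanimoto)

ethanol = parse_structure("CCO", "smiles")
print("ethanol signature, d=0:", molecular_signature(ethanol, 0).counts)
print("ethanol signature, d=2:", molecular_signature(ethanol, 2).counts)
# at d=0 each atom contributes only its own label; at d=2 every atom also
# encodes its bonded neighborhood, so all three atoms become distinct

coumarate = parse_structure("OC(=O)C=Cc1ccc(O)cc1", "smiles")
cinnamate = parse_structure("OC(=O)C=Cc1ccccc1", "smiles")
for d in (0, 2, 4):
    s = tanimoto(molecular_signature(coumarate, d),
                 molecular_signature(cinnamate, d))
    print(f"Tanimoto(4-coumarate, cinnamate) at d={d}: {s:.3f}")
# similarity drops as d grows: larger environments separate the hydroxylated
# ring from the plain one

net, _, _ = raspberry_network()
print("\nname search 'raspberry':")
for hit in search_compound("raspberry", net, k=3):
    print(f"  {hit.metabolite.id:8s} {hit.metabolite.name:22s} "
          f"sim={hit.similarity:.2f} ({hit.status})")
print("structure search for 4-hydroxybenzalacetone:")
for hit in search_compound(parse_structure("CC(=O)C=Cc1ccc(O)cc1", "smiles"),
                           net, k=3):
    print(f"  {hit.metabolite.id:8s} {hit.metabolite.name:22s} "
          f"sim={hit.similarity:.2f} ({hit.status})")
# the top structural hit is the compound itself (similarity 1.0); the next
# hits are its closest structural relatives in the network
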