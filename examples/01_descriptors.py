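"""Generate MNA descriptors for a few molecules.

Each molecule is reduced to its unique set of level-1 and level-2
atom-neighbourhood strings; stereoisomers collapse to the same set.
"""

from cytosar import descriptor_set, parse_structure

for smiles in ["CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1"]:
    mol = parse_structure(smiles)
    ds = descriptor_set(mol, validated=True)
    print(f"\n{smiles}: {len(ds)} unique descriptors")
    for d in ds.sorted()[:8]:
        print("  ", d)

cis = descriptor_set(parse_structure("C/C=C\\C"), validated=True)
trans = descriptor_set(parse_structure("C/C=C/C"), validated=True)
print("\ncis/trans butene descriptor sets identical:",
      cis.descriptors == trans.descriptors)
# The printed strings carry no bond symbols: double bonds show up only
# through reduced hydrogen counts, and ring atoms lose the "-" mark.
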