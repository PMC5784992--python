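"""Admissibility screening of input structures.

A structure is modellable only if it is a single neutral covalent
component with >= 3 carbons, bond orders 1-3 and MW < 1250 Da. Every
violated criterion is reported, not just the first.
"""

from cytosar import parse_structure, validate_structure

cases = {
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "ethane (too few C)": "CC",
    "acetate anion": "CC(=O)[O-]",
    "sodium acetate": "CC(=O)[O-].[Na+]",
}
for name, smiles in cases.items():
    report = validate_structure(parse_structure(smiles))
    status = "ok" if report.passed else ", ".join(report.failures)
    print(f"{name:22s} MW={report.molecular_weight:7.2f}  {status}")

# Charged salts can be rescued explicitly before validation:
mol = parse_structure("CCC(=O)[O-].[Na+]", strip_salts=True, neutralize=True)
print("salt-stripped + neutralized:", validate_structure(mol).passed)
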