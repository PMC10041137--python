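"""Fingerprints, Tanimoto similarity and structural similarity profiles.

Builds a five-drug table inline, fingerprints it, and prints the Tanimoto
similarity matrix plus one drug's similarity profile (SSP) against the
others.  Values are in [0, 1]: 1.0 on the diagonal (a drug vs itself),
near 0 for structurally unrelated molecules.
"""

from ddiscreen import DrugRecord, ReferenceSet, build_ssp, fingerprint, tanimoto

drugs = [
    DrugRecord("d1", "ethanol", "CCO"),
    DrugRecord("d2", "propanol", "CCCO"),
    DrugRecord("d3", "benzene", "c1ccccc1"),
    DrugRecord("d4", "toluene", "Cc1ccccc1"),
    DrugRecord("d5", "acetic acid", "CC(=O)O"),
]

fps = {d.drug_id: fingerprint(d) for d in drugs}

print("Tanimoto similarity matrix (radius-2 Morgan, 2048 bits):")
print("            " + "  ".join(f"{d.name[:8]:>8}" for d in drugs))
for a in drugs:
    row = "  ".join(f"{tanimoto(fps[a.drug_id], fps[b.drug_id]):8.3f}" for b in drugs)
    print(f"{a.name[:10]:>10}  {row}")

ref = ReferenceSet.from_drugs(drugs)
ssp = build_ssp(drugs[1], ref)
print(f"\nSSP of {drugs[1].name} against the 5-drug reference: {ssp.values.round(3)}")
print("Coordinate 2 is 1.0 because propanol is itself reference entry 2.")
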