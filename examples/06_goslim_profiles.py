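"""Compare coarse functional profiles of known vs predicted partners.

Given any accession → category map (e.g. GOslim molecular-function terms),
the summary counts proteins per category; a protein mapped to several
categories contributes to each.
"""

from protint import goslim_summary
from protint.scan import goslim_side_by_side

category_map = {
    "P001": {"transcription regulator activity"},
    "P002": {"transcription regulator activity", "nucleic acid binding"},
    "P003": {"kinase activity"},
    "C001": {"kinase activity"},
    "C002": {"kinase activity", "signal transduction activity"},
    "C003": {"cytoskeletal activity"},
}

known = ["P001", "P002", "P003", "P004"]          # P004 has no mapping
predicted = ["C001", "C002", "C003"]

table = goslim_summary(known, category_map)
print(f"known partners: {table.n_mapped}/{table.n_proteins} mapped, "
      f"{table.unmapped} unmapped")
print(table.to_frame().to_string(index=False))

print("\nknown vs predicted:")
print(goslim_side_by_side(known, predicted, category_map).to_string(index=False))
print("\nA category present only among predictions (here cytoskeletal activity)")
print("is the kind of signal that suggests a new functional class of partners.")
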