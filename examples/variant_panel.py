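"""Build the 13-member engineered FGF1 variant panel.

Every variant stacks the FGFR-disrupting pair (Y94A, N95A) and the six
stabilizing substitutions on the FGF1 scaffold, then adds a combination of
the four heparan-sulfate affinity mutations A=N114R, B=S116R, C=S17K,
D=L72R. Printed below: each variant, its affinity-mutation set, and how
many residues separate it from the base scaffold FGF1_HS.
"""

from fgfhs import build_variant_panel, panel_sequences

panel = build_variant_panel()
seqs = panel_sequences()
hs = seqs["FGF1_HS"]

print(f"{'variant':<14} {'affinity mutations':<22} residues changed vs FGF1_HS")
for v in panel:
    muts = ", ".join(m.label for m in v.hs_mutations) or "-"
    hamming = sum(a != b for a, b in zip(hs, seqs[v.name]))
    print(f"{v.name:<14} {muts:<22} {hamming}")

diff = [i + 1 for i, (a, b) in enumerate(zip(hs, seqs["FGF1_HS_BCD"])) if a != b]
print(f"\nFGF1_HS_BCD differs from FGF1_HS at positions {diff} "
      "(Gimenez-Gallego numbering) - the S17K, L72R and S116R sites.")
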