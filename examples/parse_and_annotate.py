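"""Parse vendor lipid shorthand and annotate a small panel.

Lipid names arrive as strings like ``PE(P-18:0/20:4)``; downstream
statistics need their class, chain length and saturation.
"""

from lipidstat import annotate_panel, classify_chain_length, parse_lipid_name

names = [
    "FFA(16:0)",          # palmitic acid: saturated free fatty acid
    "FFA(18:2)",          # linoleic acid: polyunsaturated
    "PE(P-18:0/20:4)",    # plasmalogen PE, chains summed to 38:4
    "TAG52:2-FA18:1",     # one TAG isotopomer feature (per-acyl transition)
    "AC(18:0)",           # stearoylcarnitine
]

print(annotate_panel(names).to_string())

ac = parse_lipid_name("AC(18:0)")
print(
    f"\nAC(18:0) chain window: {classify_chain_length(ac, 'acylcarnitine')} "
    "(C16-C20 counts toward the numerator of the beta-oxidation ratio)"
)
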