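"""Diet formulation: hitting a target P:L ratio from a base pollen.

The base multifloral pollen holds 191.40 µg/mg protein and 34.40 µg/mg lipid
(P:L 5.6:1). We ask for a lipid-rich 0.4:1 diet and a protein-shifted 6.6:1
diet and print the additive masses (casein / canola oil, per mg of pollen)
plus the resulting compositions.
"""

from pollenniche import REFERENCE_DIETS, formulate_diet, pl_ratio

BASE_PROTEIN, BASE_LIPID = 191.40, 34.40

for target in (191.40 / 443.18, 6.6):
    diet = formulate_diet(BASE_PROTEIN, BASE_LIPID, target_ratio=target)
    print(
        f"target {target:.2f}:1 -> add {1000 * diet.protein_additive:.2f} ug "
        f"protein + {1000 * diet.lipid_additive:.2f} ug lipid per mg pollen; "
        f"composition {diet.protein:.2f}/{diet.lipid:.2f} ug/mg "
        f"(P:L {pl_ratio(diet.protein, diet.lipid):.2f}:1)"
    )

print("\nBundled experimental diet table (printed label vs computed ratio):")
for name, group, label, protein, lipid, n in REFERENCE_DIETS:
    if protein is None:
        print(f"  {name:<24} {label:>7}  (homogenized provisions, presumed)")
    else:
        print(f"  {name:<24} {label:>7}  computed {pl_ratio(protein, lipid):.1f}:1")
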