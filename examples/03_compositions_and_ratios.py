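"""Class and orientation composition summaries with ratio statistics.

Shows the two counting units: lncRNA class composition counts each DE
lncRNA once, while orientation composition counts every called pair.
"""

from lncpair import (
    GeneratorConfig, call_regulation, class_composition, composition_ratio,
    find_pairs, generate, lnc_class_map, orientation_composition,
)

dataset = generate(GeneratorConfig(seed=7))
pairs = find_pairs(dataset.features)
classes = lnc_class_map(dataset.features)

comparison = "Aer/Rt"  # aerial vs root cells of a colony biofilm
lnc_de = [r for r in dataset.de_tables[comparison] if r.feature_id in classes]

up = class_composition(lnc_de, classes, "up")
down = class_composition(lnc_de, classes, "down")
print(f"lncRNAs upregulated in aerial cells ({comparison}): n={up.total}")
print(up.to_frame().to_string())
print(f"\nlncRNAs upregulated in root cells: n={down.total}")
print(down.to_frame().to_string())

ratio = composition_ratio(down, up, "CUT")
if ratio.defined:
    print(f"\nCUTs up in roots vs aerial cells: {ratio.numerator}/"
          f"{ratio.denominator} = {float(ratio):.2f}x")
else:
    print("\nCUT ratio undefined (no CUTs upregulated in aerial cells)")

regulated = call_regulation(pairs, dataset.de_tables[comparison], comparison)
for call in ("antiregulated", "coregulated"):
    comp = orientation_composition(regulated, call)
    print(f"\n{call} pairs by orientation (n={comp.total}, "
          f"modal={', '.join(comp.modal)}):")
    print(comp.to_frame().to_string())
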