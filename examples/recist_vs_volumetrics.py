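"""RECIST 1.1 classification next to the whole-burden change statistics.

Builds a tiny lesion inventory by hand, applies the target-lesion rules
(up to two targets of at least 10 mm), and shows how the unidimensional
size change can disagree with the volumetric picture.
"""

from hepavol import combined_change, percent_change, recist_category

# pre-treatment: two measurable lesions, 3.1 cm and 2.2 cm diameter
s_pre = 3.1 + 2.2
# post-treatment: the same lesions measure 3.0 cm and 2.1 cm
s_post = 3.0 + 2.1
ds = percent_change(s_pre, s_post)
category = recist_category(ds, absolute_increase_mm=(s_post - s_pre) * 10)
print(f"RECIST diameter sum: {s_pre:.1f} -> {s_post:.1f} cm  "
      f"(dS = {ds:+.2f} %)  => {category}")

# the whole burden tells a different story: total volume grew 131.25%
# while mean density dropped 4.7% (a real cohort case)
dv, dd = 131.25, -4.7
print(f"volumetrics: dV = {dv:+.2f} %, dD = {dd:+.2f} %, "
      f"d(V+D) = {combined_change(dv, dd):+.2f} %")

print(
    "\nDiameters of two target lesions barely moved (stable disease by "
    "RECIST), yet the full tumor burden more than doubled — the situation "
    "the combined volumetric statistic is designed to expose."
)
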