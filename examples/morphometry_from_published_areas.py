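"""Relative morphometric parameters from absolute compartment areas.

Feeds one section's automatically and manually measured absolute areas
(um^2) through the morphometry formulas and prints the derived relative
parameters plus the automatic-vs-manual relative differences.  Differences of
a few percent for media/lumen/plaque and below 7% for lipids indicate the two
measurement routes agree.
"""

from omsbseg import auto_manual_agreement, morphometry_from_areas
from omsbseg.morphometry import format_record

auto = morphometry_from_areas(
    media_area=161_749, lumen_area=36_900, plaque_area=283_017,
    collagen_area=41_446, lipid_area=37_317,
    section_id="section-1-auto",
)
manual = morphometry_from_areas(
    media_area=155_723, lumen_area=38_097, plaque_area=285_795,
    lipid_area=39_553,  # dispersed collagen is not manually traceable
    section_id="section-1-manual",
)

print(format_record(auto))
print()
print(format_record(manual))
print()
print("automatic vs manual relative difference (%):")
for name, diff in auto_manual_agreement(auto, manual).items():
    print(f"  {name:<8s} {'undefined' if diff is None else f'{diff:.2f}'}")
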