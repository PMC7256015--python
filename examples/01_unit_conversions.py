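"""Concentration bookkeeping of the contrast-agent calibration series.

Converts the molar tube series (mM of element) to the mg/mL scale of
material images, and prints the labeling viability ratio.
"""

import numpy as np

from spcct import molar_to_mass_concentration, relative_viability

gold_mm = np.array([0, 10, 15, 20, 30, 40], dtype=float)
iodine_mm = np.array([0, 10, 15, 20, 30, 40, 60], dtype=float)

gold = molar_to_mass_concentration(gold_mm, "gold")
iodine = molar_to_mass_concentration(iodine_mm, "iodine")

print("gold tubes   (mM -> mg/mL):", {int(m): round(float(c), 3) for m, c in zip(gold_mm, gold)})
print("iodine tubes (mM -> mg/mL):", {int(m): round(float(c), 3) for m, c in zip(iodine_mm, iodine)})
print(f"common range: 0 - {max(gold.max(), iodine.max()):.1f} mg/mL")
# Both series top out just below 8 mg/mL: 40 mM gold and 60 mM iodine carry
# nearly the same elemental mass per volume, so one display window fits both.

print(f"viability of labeled vs control cells: {relative_viability(77, 86):.1f} %")
# Gold loading costs the macrophages about a tenth of their baseline viability.
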