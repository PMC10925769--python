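"""Age-dependent involution curves and thymic carrying capacities.

Evaluates the calibrated wet-weight, TES-proportion and cortico-medullary
curves at a few ages and combines them into the cortex/medulla carrying
capacities, including the 0-to-1-year mean used to pin the homeostasis
model in infants.
"""

from thymosim import (InvolutionParams, capacities, cm_ratio,
                      infant_capacities, tes_fraction, wet_weight)

p = InvolutionParams()
print(f"calibrated involution parameters: {p}\n")

print(f"{'age':>4}  {'WW (g)':>8}  {'TES (%)':>8}  {'CM':>6}  "
      f"{'T_cort_max':>11}  {'T_med_max':>11}")
for age in (0, 1, 10, 20, 40, 70):
    c = capacities(age, p)
    print(f"{age:>4}  {wet_weight(age, p):8.2f}  {tes_fraction(age, p):8.2f}  "
          f"{cm_ratio(age, p):6.3f}  {c.t_cort_max:11.3e}  {c.t_med_max:11.3e}")

ic = infant_capacities(p)
print(f"\ninfant (0-1 y mean) capacities: cortex {ic.t_cort_max:.3e}, "
      f"medulla {ic.t_med_max:.3e} cells")
print("Wet weight barely moves before age ~40 while the TES proportion and")
print("the cortico-medullary ratio decay from birth, so both niches shrink")
print("steadily with age and the cortex shrinks faster than the medulla.")
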