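"""Free <-> total hydrocortisone under saturable plasma protein binding.

Builds a typical plasma milieu (albumin 600 uM; CBG 700 nM, 13% of it in
the low-affinity cleaved state) and walks the binding equilibrium in both
directions, printing how much drug each protein carries and how the
unbound fraction grows as CBG saturates.
"""

import numpy as np

from hcpk import (BindingSystem, bound_breakdown, fraction_unbound,
                  free_from_total, total_from_free)

system = BindingSystem(TotA=600_000.0, TotC_total=700.0, RC=0.13)

print("free nM   total nM   fu      alb-bound  CBGi-bound  CBGe-bound")
for F in [1.0, 10.0, 50.0, 200.0, 1000.0]:
    tot = total_from_free(F, system)
    fu = fraction_unbound(F, system)
    alb, cbgi, cbge = bound_breakdown(F, system)
    print(f"{F:7.1f} {tot:10.1f} {fu:7.4f} {alb:10.2f} {cbgi:11.2f} "
          f"{cbge:11.2f}")

# The inverse direction: what a measured total of 300 nM implies.
F = free_from_total(300.0, system)
print(f"\nmeasured total 300.0 nM -> free {F:.2f} nM "
      f"(fu = {F / 300.0:.4f})")

# fu rises with concentration because the high-affinity CBG pool
# saturates first; albumin (Kd 330 uM) never saturates at therapeutic
# levels.  The dilute limit is the lowest fu the milieu allows:
print(f"dilute-limit fu: {fraction_unbound(0.0, system):.4f}")
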