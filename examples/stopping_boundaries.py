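"""Group-sequential efficacy boundaries for interim monitoring.

Compares the three supported boundary families at a two-look design with
two-sided alpha 0.05: Haybittle-Peto keeps an extreme fixed interim threshold
(z = 3.29 for p* = 0.001) and a near-nominal final test; O'Brien-Fleming
shrinks the threshold as information accrues; alpha-spending reproduces the
O'Brien-Fleming shape via the Lan-DeMets spending function.
"""

from fmams import boundary_table

for kind in ("haybittle_peto", "obrien_fleming", "alpha_spending"):
    b = boundary_table(kind, K=2, alpha=0.05, sided=2)
    print(f"{kind:>16}: interim z = {b[0]:.4f}, final z = {b[1]:.4f}")

print(
    "\nA definitive-outcome z above the interim boundary stops the arm for"
    "\nefficacy; the final thresholds stay close to the fixed-sample 1.96, so"
    "\nlittle power is spent on the early look."
)
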