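"""Renal physiology in five lines: clearance ratio, banding, forward model.

Builds a handful of mechanistic compounds, pushes them through the forward
model CLr = (1-FR)(fu,p x GFR + CLs) and shows how the clearance ratio
CR = CLr/(fu,p x GFR) bands each one into reabsorption (R), intermediate
(IM) or secretion (S) type.
"""

from renalxcrete import MechanismParams, classify_cr_type, compute_cr, forward_clr
from renalxcrete.pk_core import per_kg_to_absolute, DEFAULT_CONSTANTS

print(f"GFR = {DEFAULT_CONSTANTS.gfr} mL/min/kg "
      f"({per_kg_to_absolute(DEFAULT_CONSTANTS.gfr, 70.0):.0f} mL/min in a 70 kg adult)\n")

compounds = [
    ("strongly reabsorbed, lipophilic", MechanismParams(fup=0.9, fr=0.85)),
    ("pure filtration, highly bound", MechanismParams(fup=0.05)),
    ("pure filtration, unbound", MechanismParams(fup=1.0)),
    ("actively secreted", MechanismParams(fup=0.3, cls=2.5)),
]
print(f"{'mechanism':35s} {'CLr (mL/min/kg)':>16s} {'CR':>6s}  type")
for name, params in compounds:
    clr = forward_clr(params)
    cr = compute_cr(clr, params.fup)
    print(f"{name:35s} {clr:16.3f} {cr:6.2f}  {classify_cr_type(cr).value}")

# CLr is what the kidney achieves; CR says how it compares with the passive
# filtration of the unbound drug: CR < 0.67 means net tubular reabsorption,
# CR >= 1.5 net transporter secretion, and in between filtration dominates
# (for pure filtration CR = 1 exactly, whatever the plasma binding).
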