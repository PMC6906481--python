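"""Generate a synthetic clearance dataset and inspect its structure.

The generator samples mechanistic truth per compound (fu,p, FR, CLs),
produces noisy observed CLr through the forward model, and rejection-
resamples until every label is self-consistent with the clearance-ratio
banding.  The descriptor matrix plants informative columns among noise.
"""

import numpy as np

from renalxcrete.synthetic import (
    SyntheticConfig,
    generate_descriptor_matrix,
    generate_pk_table,
)

config = SyntheticConfig(seed=0)  # default composition: 94 R / 86 IM / 180 S
records, truth = generate_pk_table(config)
matrix = generate_descriptor_matrix(records, config, truth)

print(f"{len(records)} compounds; descriptor matrix {matrix.values.shape}")
print(truth["cr_type"].value_counts().to_string(), "\n")

for cr_type in ("R", "IM", "S"):
    sub = truth[truth["cr_type"] == cr_type]
    r = np.corrcoef(np.log10(sub["clr_observed"]), np.log10(sub["fup"]))[0, 1]
    print(f"{cr_type}: median CLr {sub['clr_observed'].median():5.2f} mL/min/kg, "
          f"r(log CLr, log fu,p) = {r:.2f}")

# The within-type correlation of clearance with the unbound fraction is
# strong in every type (filtration only moves unbound drug, and secretion is
# transporter access to unbound drug) — which is exactly why fu,p is such a
# valuable descriptor for the per-type regressors.
r_inf = np.corrcoef(matrix.values["inf000_log_clr"], np.log10(truth["clr_true"]))[0, 1]
print(f"\nplanted descriptor vs log CLr: r = {r_inf:.2f} (recoverable signal)")
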