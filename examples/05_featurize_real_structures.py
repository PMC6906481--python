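"""Featurize real drug structures with the RDKit backend.

Computes the 2D-descriptor block and the three binary fingerprint families
for a dozen drug-like molecules, applies the failed-descriptor exclusion,
and shows the block bookkeeping.
"""

from renalxcrete.featurize import drop_failed_features, featurize
from renalxcrete.synthetic import fixture_structures

matrix = featurize(fixture_structures())
matrix = drop_failed_features(matrix)

print(f"{len(matrix.row_ids)} compounds x {len(matrix.feature_names)} features")
for block in ("descriptor_2d", "fp_extended", "fp_klekota_roth", "fp_atompairs_2d"):
    print(f"  {block:18s} {len(matrix.features_in_block(block)):5d} columns")

mw = matrix.values["descriptor_2d.MolWt"]
logp = matrix.values["descriptor_2d.MolLogP"]
print("\ncompound          MolWt   SLogP")
for cid in matrix.row_ids[:6]:
    print(f"{cid:15s} {mw[cid]:7.1f} {logp[cid]:7.2f}")

# Descriptor columns whose computation fails for any compound are dropped
# column-wise, so every surviving feature is defined for every compound —
# the contract the downstream selection cascade and learners rely on.
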