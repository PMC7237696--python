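"""Enrichment/depletion of mutations across genomic region sets.

Plants mutations uniformly except for a 50% thinning inside CDS, then tests
each region set with a one-sided binomial test and derives the CDS
depletion factor dp that feeds the oncogenic-risk model.
"""

import mutload as ml

ref = ml.generate_reference(200_000, 0.41, seed=31)
regions = ml.generate_region_sets(
    ref, {"genic": 0.40, "CDS": 0.015, "promoter": 0.02, "LAD": 0.30}, seed=32
)
callable_set = ml.CallableRegionSet.from_intervals(
    [("toy_1", 0, len(ref.sequences["toy_1"]))]
)

muts = ml.sample_positions_uniform(
    ref, 200_000, seed=33, thin_region=regions["CDS"], keep_prob=0.5
)
table = ml.enrichment_table(muts, regions, callable_set)
print(table.to_string(index=False))

cds = ml.enrichment_test(muts, regions["CDS"], callable_set, "CDS")
dp = ml.depletion_factor(cds)
print(f"\nCDS depletion factor dp = {dp.dp:.3f} (planted 0.5; dp=1 means no depletion)")
# dp multiplies the coding mutation rate in the risk model: a 2% depletion in
# real stem cells corresponds to dp ~ 0.98.
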