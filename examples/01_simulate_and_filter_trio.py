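"""Simulate a clone/subclone trio and recover the planted culture mutations.

Builds a 100 kb toy reference, plants germline variants, pre-clonal
mutations, culture-acquired mutations (the measurement target), post-clonal
low-VAF mutations and recurrent-artifact positions, then runs the SBS and
indel filter chains and compares the result with the planted truth.
"""

import mutload as ml

ref = ml.generate_reference(total_length=100_000, gc_fraction=0.41, seed=1)
cfg = ml.TrioSimConfig(
    n_germline=100, n_pre_clonal=20, n_culture=50, n_subclonal=30,
    n_artifact_positions=5, n_culture_indels=10, n_germline_indels=20, seed=7,
)
trio, truth = ml.simulate_trio(ref, cfg)
print(f"planted variants by class: {truth.table['class'].value_counts().to_dict()}")

joint = ml.intersect_callable(list(trio.callable_regions.values()))
blacklist = ml.build_blacklist(trio.panel)  # positions recurring in >= 3 unrelated individuals
sbs = ml.filter_sbs(trio, joint, blacklist)
indels = ml.filter_indels(trio, joint, blacklist)

got = {(m.contig, m.position, m.alt) for m in sbs}
want = truth.keys_of_class("culture", var_class="SBS")
tp = len(got & want)
print(f"filtered SBS: {len(sbs)}  (true culture SBS: {len(want)}, recovered: {tp})")
print(f"filtered indels: {len(indels)}  (planted culture indels: "
      f"{len(truth.keys_of_class('culture', var_class='indel'))})")

report = ml.check_clonality([m.vaf("subclone") for m in sbs])
print(f"clonality: median subclone VAF {report.median_vaf:.3f}, pass={report.passed}")
# The filter keeps subclone-unique clonal variants (VAF ~0.5) and discards
# germline/pre-clonal (present in reference or clone), post-clonal (VAF < 0.3)
# and blacklisted artifact positions.
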