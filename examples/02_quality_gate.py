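"""Score serum integrity from fibrinopeptide-A fragment content.

fpA degrades under poor storage: high-mass fragments (m/z 1350.6, 1465.63)
convert into low-mass ones (905.46, 1077.53). A sample passes when its
overall fpA abundance exceeds 33.33% of a pristine reference AND its
high-mass percentage exceeds 66.67% of the low-mass percentage.
"""

from dataclasses import replace

import serapept as sp
from serapept.preprocess_align import PreprocessConfig, average_replicates

base = sp.CohortConfig(group_sizes={"control": 10}, seed=2)
reference = sp.reference_peaklist(base)
merge = replace(PreprocessConfig(), replicate_min_presence=1)

for label, deg in [("pristine", 0.0), ("borderline", 0.30), ("degraded", 0.60)]:
    cfg = replace(base, degradation_range=(deg, deg))
    samples, manifest = sp.generate_cohort(cfg)
    scores = {}
    for s in samples:
        merged = average_replicates(s.replicates, merge)
        merged.sample_id = s.sample_id
        scores[s.sample_id] = sp.compute_sdqs(merged, reference)
    selected, report = sp.select_samples(manifest, scores)
    sc = scores[samples[0].sample_id]
    print(f"{label:10s} deg={deg:.2f}: selected {len(selected)}/10, "
          f"high-mass {sc.high_mass_pct:.0f}% / low-mass {sc.low_mass_pct:.0f}%")
# Selection drops from 10/10 to 0/10 as degradation crosses ~1/3, the point
# where the high/low fpA ratio falls below the 66.67% threshold.
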