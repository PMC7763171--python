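"""Preprocess replicate peak lists into a cross-sample aligned table.

Steps: normalize to the internal standard (abundance scale + constant-offset
m/z recalibration), sum isotope envelopes, average technical replicates
(signal kept when present in >=3 of 4), align representatives across samples
(signal kept when present in >=5 samples), then drop fpA/fpB and contaminant
masses.
"""

import serapept as sp
from serapept.preprocess_align import PreprocessConfig

cfg = sp.CohortConfig(seed=4, group_sizes={"control": 8, "non_metastatic": 10,
                                           "metastatic": 10})
samples, manifest = sp.generate_cohort(cfg)

pre = PreprocessConfig()
representatives = {s.sample_id: sp.preprocess_sample(s.replicates, pre)
                   for s in samples}
table = sp.align_samples(representatives, manifest, pre)
print(f"aligned: {table.abundance.shape[0]} signals x "
      f"{table.abundance.shape[1]} samples")

table = sp.exclude_signals(table, pre.exclusion_masses, pre.exclusion_tolerance)
removed = table.provenance["excluded_signals"]
print(f"after exclusion: {table.abundance.shape[0]} signals "
      f"({len(removed)} removed)")
for mz, reason in sorted(removed.items()):
    print(f"  excluded {mz:9.3f}: {reason}")
# The four fpA quality-gate fragments are excluded because they drove sample
# selection (keeping them would bias the differential analysis); 1051.71 is
# a known plastic-tube polymer contaminant.
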