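"""Bootstrap occurrence-frequency validation of the differential signature.

100 datasets are drawn by resampling samples with replacement within each
group (conserving the group-size ratio); SAM is re-run on each, and we count
how often each candidate signal stays significant (p < 0.05) with its
original effect direction.
"""

import serapept as sp
from serapept.differential import SamConfig
from serapept.validation import BootstrapConfig

cfg = sp.CohortConfig(seed=2)
samples, manifest = sp.generate_cohort(cfg, peak_lists=False)
table = sp.exclude_signals(sp.cohort_to_table(samples, manifest))

report = sp.bootstrap_validate(
    table,
    {"control_vs_non_metastatic": ("control", "non_metastatic"),
     "control_vs_metastatic": ("control", "metastatic")},
    SamConfig(n_permutations=300, seed=2),
    BootstrapConfig(n_datasets=100, seed=2))
print(report.round({"q_value_original": 4}).to_string(index=False))
# Occurrences near 100/100 mean the signal's significance is stable under
# cohort resampling, not an artefact of a few influential sera.
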