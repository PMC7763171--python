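"""Matrix-adduct annotation and peptide identity cross-checks.

CHCA (the MALDI matrix) attaches to peptide ions in +189.04 Da steps, so
aligned signal lists contain parent/adduct pairs that are instrumental
artefacts, not independent analytes. Theoretical monoisotopic masses of
candidate peptide sequences cross-check signal identities.
"""

import serapept as sp

signals = [1561.720, 2021.084, 2210.130, 2399.165]
for ann in sp.find_adducts(signals, sp.AdductRule(tolerance=0.05)):
    print(f"{ann.adduct_mz:9.3f} = {ann.parent_mz:9.3f} + "
          f"{ann.multiplicity} x 189.04  (error {ann.mass_error:+.3f} Da)")

for seq, observed in [("TATSEYQTFFNPR", 1561.72),      # prothrombin fragment
                      ("SSKITHRIHWESASLLR", 2021.084)]:  # complement C3f
    mz = sp.peptide_mz(seq)
    print(f"{seq:20s} [M+H]+ = {mz:9.3f}, observed {observed:9.3f} "
          f"(delta {mz - observed:+.3f} Da)")
# 2210.13 and 2399.17 are single and double CHCA adducts of the C3f signal;
# their biology is that of the 2021.08 parent. The C3f theoretical mass sits
# ~0.02 Da above the observed signal; the discrepancy is reported, not
# corrected.
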