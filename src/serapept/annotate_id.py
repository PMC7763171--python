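"""Matrix-adduct annotation and theoretical peptide mass arithmetic.

MALDI with an α-cyano-4-hydroxycinnamic acid (CHCA) matrix produces adduct
ions displaced from their parent peptide by multiples of 189.04 Da (one CHCA
molecule). ``find_adducts`` scans an aligned signal list for such
parent/adduct pairs. ``peptide_mz`` computes monoisotopic [M+zH]z+ values
from a sequence for identity cross-checks against observed signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AdductRule", "AdductAnnotation", "find_adducts", "peptide_mz",
           "CHCA_ADDUCT_MASS", "PROTON_MASS", "WATER_MASS"]

#: one α-cyano-4-hydroxycinnamic acid molecule
CHCA_ADDUCT_MASS = 189.04
PROTON_MASS = 1.00728
WATER_MASS = 18.01056

#: monoisotopic residue masses, Da (IUPAC/Unimod standard values)
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}


@dataclass
class AdductRule:
    adduct_mass: float = CHCA_ADDUCT_MASS
    max_multiples: int = 2
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.adduct_mass <= 0:
            raise ValueError("adduct_mass must be > 0")
        if self.max_multiples < 1:
            raise ValueError("max_multiples must be >= 1")


@dataclass
class AdductAnnotation:
    parent_mz: float
    adduct_mz: float
    multiplicity: int
    mass_error: float  # observed spacing minus multiplicity * adduct_mass


def find_adducts(signals, rule: AdductRule | None = None) -> list[AdductAnnotation]:
    """Find candidate matrix-adduct pairs among aligned signal m/z values.

    Every ordered pair (parent < candidate) whose spacing is within
    ``tolerance`` of k · adduct_mass (k = 1..max_multiples) is reported.
    When several parents explain one adduct at the same multiplicity class,
    the parent with the smallest absolute mass error wins.
    """
    rule = rule or AdductRule()
    mz = np.sort(np.asarray(list(signals), dtype=float))
    best: dict[float, AdductAnnotation] = {}
    for i, parent in enumerate(mz):
        for cand in mz[i + 1:]:
            spacing = cand - parent
            for k in range(1, rule.max_multiples + 1):
                err = spacing - k * rule.adduct_mass
                if abs(err) <= rule.tolerance:
                    ann = AdductAnnotation(float(parent), float(cand), k, float(err))
                    prev = best.get(float(cand))
                    if prev is None or abs(ann.mass_error) < abs(prev.mass_error):
                        best[float(cand)] = ann
    return sorted(best.values(), key=lambda a: (a.adduct_mz, a.multiplicity))


def peptide_mz(sequence: str, charge: int = 1) -> float:
    """Monoisotopic m/z of [M + charge·H]^charge+ for a peptide sequence.

    m/z = (sum of residue masses + water + charge · proton) / charge.
    Raises on any character outside the 20 standard residues, naming the
    offending position.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    total = WATER_MASS
    for pos, ch in enumerate(sequence.upper(), start=1):
        try:
            total += RESIDUE_MASSES[ch]
        except KeyError:
            raise ValueError(f"unknown residue {ch!r} at position {pos}") from None
    return (total + charge * PROTON_MASS) / charge
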