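"""Serum degradation quality gating via fibrinopeptide-A fragment content.

Fibrinopeptide A (fpA) degrades predictably under poor sample handling: the
intact high-mass fragments (m/z 1350.6, 1465.63) are progressively converted
into low-mass fragments (m/z 905.46, 1077.53). A sample's degradation quality
score compares (a) its total fpA-fragment abundance against a reference
spectrum of assessed quality and (b) the percentage of fpA signal carried by
high-mass versus low-mass fragments. A sample is selected only when both
criteria pass, with strict ``>`` comparisons:

* overall fpA abundance > 33.33% of the reference's fpA abundance;
* high-mass fpA percentage > 66.67% of the low-mass fpA percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import PeakList

__all__ = ["FpaConfig", "QualityScore", "compute_sdqs", "select_samples"]

FPA_HIGH_MASS = (1350.6, 1465.63)
FPA_LOW_MASS = (905.46, 1077.53)


@dataclass
class FpaConfig:
    high_mass_fragments: tuple[float, ...] = FPA_HIGH_MASS
    low_mass_fragments: tuple[float, ...] = FPA_LOW_MASS
    #: extra fpA/fpB masses used only by the downstream exclusion filter
    #: (see preprocess_align.fpa_fpb_exclusion_masses for the full ladder)
    extended_fpa_fpb_masses: tuple[float, ...] = ()
    match_tolerance: float = 0.3
    overall_threshold: float = 1 / 3  # 33.33% of reference fpA abundance
    ratio_threshold: float = 2 / 3    # high% must exceed 66.67% of low%

    def __post_init__(self) -> None:
        if not (0 < self.overall_threshold <= 1 and 0 < self.ratio_threshold <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.match_tolerance <= 0:
            raise ValueError("match_tolerance must be > 0")
        if set(self.high_mass_fragments) & set(self.low_mass_fragments):
            raise ValueError("high- and low-mass fragment lists must be disjoint")


@dataclass
class QualityScore:
    sample_id: str
    overall_fraction_of_reference: float
    high_mass_pct: float
    low_mass_pct: float
    pass_overall: bool
    pass_ratio: bool
    selected: bool = field(init=False)

    def __post_init__(self) -> None:
        self.selected = self.pass_overall and self.pass_ratio


def _fragment_abundance(pl: PeakList, fragments: tuple[float, ...], tol: float) -> float:
    """Sum abundances of peaks within ``tol`` of any listed fragment mass."""
    total = 0.0
    for frag in fragments:
        hits = np.abs(pl.mz - frag) <= tol
        total += float(pl.abundance[hits].sum())
    return total


def compute_sdqs(sample: PeakList, reference: PeakList, cfg: FpaConfig | None = None) -> QualityScore:
    """Degradation quality score of ``sample`` against ``reference``.

    The overall fraction is the sample's total fpA-fragment abundance divided
    by the reference's; the high/low percentages are taken over the sample's
    own fpA abundance only (not the whole-spectrum TIC). A sample with no
    matched fpA fragment scores 0 and is not selected (not an error).
    """
    cfg = cfg or FpaConfig()
    all_frags = tuple(cfg.high_mass_fragments) + tuple(cfg.low_mass_fragments)
    ref_total = _fragment_abundance(reference, all_frags, cfg.match_tolerance)
    if ref_total <= 0:
        raise ValueError("reference spectrum contains no fpA fragment within tolerance")
    high = _fragment_abundance(sample, tuple(cfg.high_mass_fragments), cfg.match_tolerance)
    low = _fragment_abundance(sample, tuple(cfg.low_mass_fragments), cfg.match_tolerance)
    total = high + low
    overall = total / ref_total
    if total <= 0:
        return QualityScore(sample.sample_id, 0.0, 0.0, 0.0, False, False)
    high_pct = 100.0 * high / total
    low_pct = 100.0 * low / total
    pass_overall = overall > cfg.overall_threshold
    # strict: high% must strictly exceed ratio_threshold * low%
    pass_ratio = high_pct > cfg.ratio_threshold * low_pct
    return QualityScore(sample.sample_id, overall, high_pct, low_pct, pass_overall, pass_ratio)


def select_samples(manifest: pd.DataFrame, scores: dict[str, QualityScore]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply quality gating to a cohort manifest.

    Parameters
    ----------
    manifest : DataFrame with a ``sample_id`` column.
    scores : one :class:`QualityScore` per sample_id.

    Returns
    -------
    (selected manifest, QC report) — the report lists every sample's score
    components, pass flags and a human-readable exclusion reason.
    """
    missing = set(manifest["sample_id"]) - set(scores)
    if missing:
        raise ValueError(f"no quality score for samples: {sorted(missing)}")
    rows = []
    for sid in manifest["sample_id"]:
        sc = scores[sid]
        if sc.selected:
            reason = ""
        else:
            parts = []
            if not sc.pass_overall:
                parts.append("overall fpA abundance below reference threshold")
            if not sc.pass_ratio:
                parts.append("high/low fpA ratio below threshold (degraded)")
            reason = "; ".join(parts)
        rows.append({
            "sample_id": sid,
            "overall_fraction_of_reference": sc.overall_fraction_of_reference,
            "high_mass_pct": sc.high_mass_pct,
            "low_mass_pct": sc.low_mass_pct,
            "pass_overall": sc.pass_overall,
            "pass_ratio": sc.pass_ratio,
            "selected": sc.selected,
            "exclusion_reason": reason,
        })
    report = pd.DataFrame(rows)
    selected_ids = set(report.loc[report["selected"], "sample_id"])
    selected = manifest[manifest["sample_id"].isin(selected_ids)].reset_index(drop=True)
    if selected.empty:
        warnings.warn("quality gate excluded every sample", stacklevel=2)
    return selected, report
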