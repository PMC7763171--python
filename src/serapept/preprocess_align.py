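"""Peak-list preprocessing and cross-sample alignment.

The stage mirrors the standard MALDI serum-profiling workflow:

1. **normalize** — divide abundances by the spiked internal-standard peak and
   recalibrate m/z with a constant offset pinning the standard to its known
   position (default 1420.77 Da, the singly protonated ion of the MW 1419.76
   standard peptide).
2. **sum_isotopes** — collapse isotopic envelopes (spacing 1.00335 Da) onto
   their monoisotopic member, summing abundance.
3. **average_replicates** — merge the technical replicates of a sample into a
   representative peak list; a signal must appear in at least
   ``replicate_min_presence`` replicates (default 3 of 4).
4. **align_samples** — single-linkage clustering of representative peaks
   across samples; clusters spanning at least ``alignment_min_presence``
   samples (default 5, the size that protects signals private to the
   smallest group) become columns of the aligned table.
5. **exclude_signals** — drop fpA/fpB-related masses (they drive the quality
   gate, so keeping them would circularly drive the outcome) and known
   contaminants such as the polypropylene/polyethylene polymer at m/z 1051.71.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quality_gate import FPA_HIGH_MASS, FPA_LOW_MASS
from .spectra_io import PeakList

__all__ = [
    "PreprocessConfig",
    "AlignedTable",
    "MissingStandardError",
    "fpa_fpb_exclusion_masses",
    "normalize",
    "sum_isotopes",
    "average_replicates",
    "align_samples",
    "exclude_signals",
    "preprocess_sample",
]

ISOTOPE_SPACING = 1.00335  # Da, averagine C13-C12

#: polymer contaminant leaching from plastic tubes
CONTAMINANT_MZ = 1051.71

#: default exclusion set: the four fpA quality-gate fragments + contaminant
DEFAULT_EXCLUSIONS: dict[float, str] = {
    **{m: "fpA/fpB fragment" for m in FPA_HIGH_MASS + FPA_LOW_MASS},
    CONTAMINANT_MZ: "contaminant",
}

FPA_SEQUENCE = "ADSGEGDFLAEGGGVR"   # human fibrinopeptide A
FPB_SEQUENCE = "QGVNDNEEGFFSAR"     # human fibrinopeptide B (des-pyroGlu form)


def fpa_fpb_exclusion_masses(min_length: int = 5) -> dict[float, str]:
    """Extended exclusion list: the serum aminopeptidase degradation ladder.

    Fibrinopeptides degrade in serum by progressive N-terminal truncation,
    so every C-terminal suffix of fpA/fpB down to ``min_length`` residues is
    a potential fragment signal. Returns [M+H]+ of each suffix mapped to a
    reason string. The full-length fpA ladder reproduces the quality-gate
    masses (e.g. des-A fpA at 1465.65, des-AD at 1350.63) to ~0.02 Da of
    their conventional values.
    """
    from .annotate_id import peptide_mz
    masses: dict[float, str] = {}
    for name, seq in (("fpA", FPA_SEQUENCE), ("fpB", FPB_SEQUENCE)):
        for start in range(0, len(seq) - min_length + 1):
            suffix = seq[start:]
            masses[round(peptide_mz(suffix), 4)] = f"{name} fragment ({suffix})"
    return masses


class MissingStandardError(ValueError):
    """The internal-standard peak was not found within tolerance."""


@dataclass
class PreprocessConfig:
    internal_standard_mz: float = 1420.77  # [M+H]+ of the MW 1419.76 standard
    standard_tolerance: float = 0.5
    isotope_spacing: float = ISOTOPE_SPACING
    isotope_tolerance: float = 0.05
    max_isotopes: int = 5
    replicate_min_presence: int = 3
    alignment_min_presence: int = 5
    alignment_tolerance: float = 0.3
    exclusion_masses: dict[float, str] = field(default_factory=lambda: dict(DEFAULT_EXCLUSIONS))
    exclusion_tolerance: float = 0.3

    def __post_init__(self) -> None:
        if self.replicate_min_presence < 1 or self.alignment_min_presence < 1:
            raise ValueError("presence thresholds must be >= 1")
        for name in ("standard_tolerance", "isotope_tolerance",
                     "alignment_tolerance", "exclusion_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def provenance(self) -> dict:
        return {
            "internal_standard_mz": self.internal_standard_mz,
            "replicate_min_presence": self.replicate_min_presence,
            "alignment_min_presence": self.alignment_min_presence,
            "alignment_tolerance": self.alignment_tolerance,
            "max_isotopes": self.max_isotopes,
        }


@dataclass
class AlignedTable:
    """Signals × samples abundance matrix with per-sample annotations.

    ``abundance`` is indexed by consensus m/z labels (rows = signals,
    columns = sample ids); absent entries are 0, reflecting a
    presence/absence signal model rather than missingness. ``samples``
    carries group/age/gender per sample id.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def signals(self) -> np.ndarray:
        return self.abundance.index.to_numpy(dtype=float)

    def groups(self) -> pd.Series:
        return self.samples["group"]

    def validate(self, min_presence: int | None = None) -> None:
        if list(self.abundance.columns) != list(self.samples.index):
            raise ValueError("abundance columns and sample annotations disagree")
        if min_presence is not None:
            presence = (self.abundance > 0).sum(axis=1)
            bad = presence[presence < min_presence]
            if not bad.empty:
                raise ValueError(f"signals below presence threshold: {list(bad.index)}")


def normalize(peaklist: PeakList, cfg: PreprocessConfig | None = None) -> PeakList:
    """Normalize abundances and recalibrate m/z against the internal standard.

    Abundances are divided by the standard's abundance (so the standard
    becomes exactly 1) and all m/z are shifted by a single constant so the
    standard sits exactly at ``internal_standard_mz``. Normalizing an
    already-normalized list is the identity.
    """
    cfg = cfg or PreprocessConfig()
    dev = np.abs(peaklist.mz - cfg.internal_standard_mz)
    i = int(np.argmin(dev)) if dev.size else -1
    if i < 0 or dev[i] > cfg.standard_tolerance:
        raise MissingStandardError(
            f"internal standard {cfg.internal_standard_mz} not found within "
            f"{cfg.standard_tolerance} Da in replicate {peaklist.replicate!r} "
            f"of sample {peaklist.sample_id!r}")
    shift = cfg.internal_standard_mz - peaklist.mz[i]
    scale = peaklist.abundance[i]
    if scale <= 0:
        raise MissingStandardError("internal standard has non-positive abundance")
    return PeakList(peaklist.mz + shift, peaklist.abundance / scale,
                    sample_id=peaklist.sample_id, replicate=peaklist.replicate,
                    meta={**peaklist.meta, "mz_shift": shift, "norm_factor": scale})


def sum_isotopes(peaklist: PeakList, cfg: PreprocessConfig | None = None) -> PeakList:
    """Collapse isotopic envelopes onto their lowest-mass (monoisotopic) peak.

    Chains are grown greedily from low m/z: starting at the lightest
    unconsumed peak, successive peaks within ``isotope_tolerance`` of the
    expected +1.00335 Da position join the chain, up to ``max_isotopes``
    members. The chain collapses to its head with abundance equal to the
    chain sum, so total abundance is conserved.
    """
    cfg = cfg or PreprocessConfig()
    n = len(peaklist)
    consumed = np.zeros(n, dtype=bool)
    out_mz: list[float] = []
    out_ab: list[float] = []
    mz, ab = peaklist.mz, peaklist.abundance
    for i in range(n):
        if consumed[i]:
            continue
        chain = [i]
        consumed[i] = True
        last = mz[i]
        while len(chain) < cfg.max_isotopes:
            target = last + cfg.isotope_spacing
            # nearest unconsumed peak to the expected isotope position
            cand = np.flatnonzero(~consumed & (np.abs(mz - target) <= cfg.isotope_tolerance))
            if cand.size == 0:
                break
            j = int(cand[np.argmin(np.abs(mz[cand] - target))])
            chain.append(j)
            consumed[j] = True
            last = mz[j]
        out_mz.append(mz[chain[0]])
        out_ab.append(float(ab[chain].sum()))
    return PeakList(np.array(out_mz), np.array(out_ab), sample_id=peaklist.sample_id,
                    replicate=peaklist.replicate, meta=dict(peaklist.meta))


def _gap_clusters(sorted_mz: np.ndarray, tolerance: float) -> list[slice]:
    """Single-linkage clusters over sorted m/z: break where gap > tolerance."""
    if sorted_mz.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(sorted_mz) > tolerance) + 1
    bounds = [0, *breaks.tolist(), sorted_mz.size]
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def average_replicates(replicates: list[PeakList], cfg: PreprocessConfig | None = None) -> PeakList:
    """Merge technical replicates into one representative peak list.

    Peaks are matched across replicates by single-linkage clustering within
    ``alignment_tolerance``; a matched signal is kept only when present in at
    least ``replicate_min_presence`` replicates, with abundance the mean over
    the replicates where present and m/z the mean of the matched positions.
    """
    cfg = cfg or PreprocessConfig()
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates to average")
    all_mz = np.concatenate([r.mz for r in replicates])
    all_ab = np.concatenate([r.abundance for r in replicates])
    all_rep = np.concatenate([np.full(len(r), k) for k, r in enumerate(replicates)])
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_ab, all_rep = all_mz[order], all_ab[order], all_rep[order]
    out_mz: list[float] = []
    out_ab: list[float] = []
    for sl in _gap_clusters(all_mz, cfg.alignment_tolerance):
        reps = all_rep[sl]
        if np.unique(reps).size < cfg.replicate_min_presence:
            continue
        # one value per replicate: nearest-to-centre peak if a replicate
        # contributed several
        centre = float(all_mz[sl].mean())
        per_rep: dict[int, tuple[float, float]] = {}
        for m, a, r in zip(all_mz[sl], all_ab[sl], reps):
            prev = per_rep.get(int(r))
            if prev is None or abs(m - centre) < abs(prev[0] - centre):
                per_rep[int(r)] = (m, a)
        mzs = np.array([v[0] for v in per_rep.values()])
        abs_ = np.array([v[1] for v in per_rep.values()])
        out_mz.append(float(mzs.mean()))
        out_ab.append(float(abs_.mean()))
    order2 = np.argsort(out_mz)
    sample_id = replicates[0].sample_id
    return PeakList(np.array(out_mz)[order2], np.array(out_ab)[order2], sample_id=sample_id)


def align_samples(representatives: dict[str, PeakList],
                  samples: pd.DataFrame | None = None,
                  cfg: PreprocessConfig | None = None) -> AlignedTable:
    """Align representative peak lists across samples into a table.

    Single-linkage clustering of all representative peaks within
    ``alignment_tolerance``; clusters spanning at least
    ``alignment_min_presence`` samples become rows (labelled by the cluster
    mean m/z). When a cluster contains two peaks from one sample, the peak
    nearest the cluster mean is kept with a warning. Absent entries are 0.
    """
    cfg = cfg or PreprocessConfig()
    sample_ids = list(representatives)
    if len(sample_ids) < cfg.alignment_min_presence:
        raise ValueError(
            f"need >= {cfg.alignment_min_presence} samples, got {len(sample_ids)}")
    all_mz = np.concatenate([representatives[s].mz for s in sample_ids])
    all_ab = np.concatenate([representatives[s].abundance for s in sample_ids])
    all_sid = np.concatenate([np.full(len(representatives[s]), k)
                              for k, s in enumerate(sample_ids)])
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_ab, all_sid = all_mz[order], all_ab[order], all_sid[order]

    labels: list[float] = []
    columns: list[dict[int, float]] = []
    dup_warned = False
    for sl in _gap_clusters(all_mz, cfg.alignment_tolerance):
        sids = all_sid[sl]
        if np.unique(sids).size < cfg.alignment_min_presence:
            continue
        centre = float(all_mz[sl].mean())
        entry: dict[int, tuple[float, float]] = {}
        for m, a, s in zip(all_mz[sl], all_ab[sl], sids):
            prev = entry.get(int(s))
            if prev is not None:
                dup_warned = True
                if abs(m - centre) >= abs(prev[0] - centre):
                    continue
            entry[int(s)] = (m, a)
        labels.append(round(centre, 4))
        columns.append({s: v[1] for s, v in entry.items()})
    if dup_warned:
        warnings.warn("a cluster contained two peaks from one sample; kept nearest",
                      stacklevel=2)
    mat = np.zeros((len(labels), len(sample_ids)))
    for row, entry in enumerate(columns):
        for s, a in entry.items():
            mat[row, s] = a
    abundance = pd.DataFrame(mat, index=pd.Index(labels, name="mz"), columns=sample_ids)
    abundance = abundance.sort_index()
    if samples is None:
        samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    else:
        samples = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
        samples = samples.loc[sample_ids]
    prov = {**cfg.provenance(), "n_signals": len(labels), "n_samples": len(sample_ids)}
    return AlignedTable(abundance, samples, provenance=prov)


def exclude_signals(table: AlignedTable,
                    exclusion_masses: dict[float, str] | list[float] | None = None,
                    tolerance: float | None = None) -> AlignedTable:
    """Drop table rows whose m/z matches an exclusion mass within tolerance.

    ``exclusion_masses`` maps mass → reason (a bare list gets the reason
    "excluded mass"). Removed labels and reasons are recorded in provenance.
    """
    if exclusion_masses is None:
        exclusion_masses = dict(DEFAULT_EXCLUSIONS)
    if not isinstance(exclusion_masses, dict):
        exclusion_masses = {m: "excluded mass" for m in exclusion_masses}
    tol = tolerance if tolerance is not None else 0.3
    labels = table.abundance.index.to_numpy(dtype=float)
    removed: dict[float, str] = {}
    keep_mask = np.ones(labels.size, dtype=bool)
    for mass, reason in exclusion_masses.items():
        hits = np.abs(labels - mass) <= tol
        for lab in labels[hits]:
            removed[float(lab)] = reason
        keep_mask &= ~hits
    out = AlignedTable(table.abundance.loc[keep_mask], table.samples,
                       provenance={**table.provenance,
                                   "excluded_signals": removed,
                                   "n_signals_after_exclusion": int(keep_mask.sum())})
    return out


def preprocess_sample(replicates: list[PeakList],
                      cfg: PreprocessConfig | None = None) -> PeakList:
    """Normalize + deisotope each replicate, then average into a representative.

    Replicates whose internal standard is missing are flagged unusable and
    dropped with a warning (the presence threshold still applies to the
    original replicate count).
    """
    cfg = cfg or PreprocessConfig()
    processed = []
    for rep in replicates:
        try:
            processed.append(sum_isotopes(normalize(rep, cfg), cfg))
        except MissingStandardError as exc:
            warnings.warn(f"replicate dropped: {exc}", stacklevel=2)
    if len(processed) < cfg.replicate_min_presence:
        raise ValueError(
            f"sample {replicates[0].sample_id!r}: only {len(processed)} usable "
            f"replicates, need {cfg.replicate_min_presence}")
    return average_replicates(processed, cfg)
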