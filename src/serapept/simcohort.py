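"""Synthetic serum-peptidome cohorts with known ground truth.

The generator emulates the statistical structure a MALDI-TOF serum profiling
study assumes, so every downstream stage (quality gating, peak detection,
alignment, SAM, bootstrap validation) can be tested offline against planted
truth:

* three groups (defaults: 19 healthy controls, 80 non-metastatic and 92
  metastatic cancer patients) with group-specific age/gender distributions;
* four technical replicates per sample, each a centroided peak list (profile
  scans can be rendered on demand);
* a panel of ~100 signals in m/z 800–3000 including a spiked internal
  standard (MW 1419.76, observed [M+H]+ 1420.77), the four fibrinopeptide-A
  quality-gate fragments, a polymer contaminant at m/z 1051.71, CHCA matrix
  adducts, and designated signals carrying multiplicative group effects;
* a per-sample degradation level in [0, 1] that transfers abundance from the
  high-mass fpA fragments to the low-mass ones (the footprint the quality
  score detects);
* noise: per-sample biological log-normal dispersion, per-replicate spot
  intensity log-normal factor (cancelled by internal-standard
  normalization), per-peak replicate log-normal noise, per-replicate
  constant m/z calibration offset (cancelled by recalibration) and per-peak
  m/z jitter.

Ground-truth sample-level abundances are stored on every sample; analysis
stages never read them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate_id import CHCA_ADDUCT_MASS
from .preprocess_align import CONTAMINANT_MZ, ISOTOPE_SPACING, AlignedTable
from .quality_gate import FPA_HIGH_MASS, FPA_LOW_MASS
from .spectra_io import PeakList, Spectrum, write_peaklist_text

__all__ = [
    "SignalSpec", "NoiseModel", "CovariateSpec", "CohortConfig",
    "SyntheticSample", "default_signal_panel", "generate_cohort",
    "render_profile", "write_cohort", "cohort_to_table", "reference_peaklist",
]

INTERNAL_STANDARD_MZ = 1420.77  # [M+H]+ of the MW 1419.76 spiked peptide

ROLES = ("analyte", "internal_standard", "fpA_fragment_high",
         "fpA_fragment_low", "fpB_fragment", "contaminant")


@dataclass
class SignalSpec:
    """One planted signal.

    ``group_effects`` maps group label to a multiplicative fold on the base
    abundance (missing groups default to 1). ``adduct_of`` ties the signal's
    biological noise draw (and, when no explicit effects are given, its group
    effects) to a parent signal's, as matrix adducts track their parent ion.
    ``sporadic_rate`` is the probability an individual replicate lacks the
    signal.
    """

    mz: float
    base_abundance: float
    group_effects: dict[str, float] = field(default_factory=dict)
    isotope_envelope: tuple[float, ...] = (1.0,)
    adduct_of: tuple[float, int] | None = None
    role: str = "analyte"
    sporadic_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"signal {self.mz}: unknown role {self.role!r}")
        if self.base_abundance < 0:
            raise ValueError(f"signal {self.mz}: base_abundance must be >= 0")
        if any(f <= 0 for f in self.group_effects.values()):
            raise ValueError(f"signal {self.mz}: group effects must be > 0")
        if not 0 <= self.sporadic_rate <= 1:
            raise ValueError(f"signal {self.mz}: sporadic_rate must lie in [0, 1]")


@dataclass
class NoiseModel:
    """Dispersion parameters (log-normal sigmas unless noted)."""

    sample_sigma: float = 0.5      # biological, per sample per signal
    replicate_sigma: float = 0.15  # per replicate per signal
    spot_sigma: float = 0.30       # per replicate, all signals jointly
    mz_jitter_sd: float = 0.01     # Da, per peak
    calibration_sd: float = 0.05   # Da, per replicate constant offset
    baseline_sigma: float = 0.0    # additive Gaussian noise on rendered profiles
    #: biological sigma shared by all fpA/fpB fragments of a sample: the
    #: fragments co-vary (one parent molecule), so the high/low ratio the
    #: quality gate reads reflects degradation, not independent noise.
    fpa_sigma: float = 0.2

    def scaled(self, factor: float) -> "NoiseModel":
        return NoiseModel(self.sample_sigma * factor, self.replicate_sigma * factor,
                          self.spot_sigma * factor, self.mz_jitter_sd * factor,
                          self.calibration_sd * factor, self.baseline_sigma * factor,
                          self.fpa_sigma * factor)


NO_NOISE = NoiseModel(0, 0, 0, 0, 0, 0, 0)


@dataclass
class CovariateSpec:
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    female_prop: float


#: demographics of the emulated cohort (ages in years)
DEFAULT_COVARIATES: dict[str, CovariateSpec] = {
    "control": CovariateSpec(54, 8, (40, 67), 10 / 19),
    "non_metastatic": CovariateSpec(71, 10, (44, 89), 26 / 80),
    "metastatic": CovariateSpec(71, 12, (34, 93), 28 / 92),
}

DEFAULT_GROUP_SIZES = {"control": 19, "non_metastatic": 80, "metastatic": 92}


@dataclass
class CohortConfig:
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    signal_panel: list[SignalSpec] = field(default_factory=lambda: default_signal_panel())
    replicates_per_sample: int = 4
    scans_per_replicate: int = 15
    mz_range: tuple[float, float] = (800.0, 3000.0)
    noise: NoiseModel = field(default_factory=NoiseModel)
    degradation_range: tuple[float, float] = (0.0, 0.15)
    covariates: dict[str, CovariateSpec] = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group_sizes[{g!r}] must be >= 1, got {n}")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError(f"mz_range bounds must be ordered, got {self.mz_range}")
        for spec in self.signal_panel:
            if not lo <= spec.mz <= hi:
                raise ValueError(f"signal {spec.mz} outside mz_range {self.mz_range}")
        n_std = sum(1 for s in self.signal_panel if s.role == "internal_standard")
        if n_std != 1:
            raise ValueError(f"panel must contain exactly one internal standard, got {n_std}")
        if self.replicates_per_sample < 1 or self.scans_per_replicate < 1:
            raise ValueError("replicates_per_sample and scans_per_replicate must be >= 1")
        if not 0 <= self.degradation_range[0] <= self.degradation_range[1] <= 1:
            raise ValueError("degradation_range must be ordered within [0, 1]")
        for g in self.group_sizes:
            if g not in self.covariates:
                raise ValueError(f"no covariate model for group {g!r}")


@dataclass
class SyntheticSample:
    sample_id: str
    group: str
    age: float
    gender: str
    degradation: float
    replicates: list[PeakList]
    truth: dict[float, float]  # signal m/z -> sample-level abundance


# ---------------------------------------------------------------------------
# default panel

_SIGNATURE_EFFECTS = {
    # m/z : (base, {group: fold})  — magnitudes of the emulated study design
    1561.72: (0.25, {"non_metastatic": 16.4, "metastatic": 17.8}),
    2021.084: (6.0, {"non_metastatic": 2.63, "metastatic": 2.92}),
    2399.165: (0.6, {"non_metastatic": 6.7, "metastatic": 6.9}),
}

_ENVELOPE = (1.0, 0.6, 0.25)  # generic +1 isotope pattern for ~1-2 kDa peptides


def default_signal_panel(n_null: int = 98) -> list[SignalSpec]:
    """Default planted panel: 98 null analytes, 3 differential signals, one
    parent-tracking CHCA adduct, internal standard, 4 fpA fragments and the
    polymer contaminant (108 signals; 103 survive the exclusion filter)."""
    panel: list[SignalSpec] = [
        SignalSpec(INTERNAL_STANDARD_MZ, 100.0, role="internal_standard",
                   isotope_envelope=_ENVELOPE),
        SignalSpec(FPA_LOW_MASS[0], 40.0, role="fpA_fragment_low", isotope_envelope=_ENVELOPE),
        SignalSpec(FPA_LOW_MASS[1], 40.0, role="fpA_fragment_low", isotope_envelope=_ENVELOPE),
        SignalSpec(FPA_HIGH_MASS[0], 60.0, role="fpA_fragment_high", isotope_envelope=_ENVELOPE),
        SignalSpec(FPA_HIGH_MASS[1], 60.0, role="fpA_fragment_high", isotope_envelope=_ENVELOPE),
        SignalSpec(CONTAMINANT_MZ, 2.0, role="contaminant",
                   group_effects={"non_metastatic": 2.5, "metastatic": 2.7}),
        # single CHCA adduct of the 2021.084 parent: tracks the parent
        SignalSpec(2021.084 + CHCA_ADDUCT_MASS + 0.006, 1.5,
                   adduct_of=(2021.084, 1), isotope_envelope=_ENVELOPE),
    ]
    for mz, (base, effects) in _SIGNATURE_EFFECTS.items():
        adduct = (2021.084, 2) if mz == 2399.165 else None
        panel.append(SignalSpec(mz, base, group_effects=dict(effects),
                                isotope_envelope=_ENVELOPE, adduct_of=adduct))
    # deterministic pseudo-random null analytes, kept clear of named masses
    rng = np.random.default_rng(74110)
    named = np.array([s.mz for s in panel])
    nulls: list[float] = []
    while len(nulls) < n_null:
        mz = float(np.round(rng.uniform(810, 2990), 3))
        taken = np.concatenate([named, np.array(nulls)]) if nulls else named
        if np.all(np.abs(taken - mz) > 4.0):
            nulls.append(mz)
    for mz in sorted(nulls):
        base = float(np.round(np.exp(rng.uniform(np.log(0.5), np.log(20.0))), 3))
        panel.append(SignalSpec(mz, base, isotope_envelope=_ENVELOPE))
    return sorted(panel, key=lambda s: s.mz)


# ---------------------------------------------------------------------------
# generation

def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


_FPA_ROLES = ("fpA_fragment_high", "fpA_fragment_low", "fpB_fragment")


def _sample_truth(panel: list[SignalSpec], group: str, degradation: float,
                  noise: NoiseModel, rng: np.random.Generator) -> dict[float, float]:
    """Sample-level abundances: base × group fold × biological log-normal,
    then fpA mass transfer proportional to the degradation level."""
    sigma = noise.sample_sigma
    # fibrinopeptide fragments share one biological factor per sample
    fpa_bio = float(np.exp(rng.normal(0.0, noise.fpa_sigma))) if noise.fpa_sigma > 0 else 1.0
    bio = {}
    for spec in panel:
        if spec.role in _FPA_ROLES:
            bio[spec.mz] = fpa_bio
        else:
            bio[spec.mz] = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
    by_mz = {spec.mz: spec for spec in panel}
    amounts: dict[float, float] = {}
    for spec in panel:
        if spec.role == "internal_standard":
            amounts[spec.mz] = spec.base_abundance  # spiked: no biological noise
            continue
        effects, noise = spec.group_effects, bio[spec.mz]
        if spec.adduct_of is not None and spec.adduct_of[0] in by_mz:
            parent = by_mz[spec.adduct_of[0]]
            noise = bio[parent.mz]
            if not effects:
                effects = parent.group_effects
        amounts[spec.mz] = spec.base_abundance * effects.get(group, 1.0) * noise
    if degradation > 0:
        high = [s.mz for s in panel if s.role == "fpA_fragment_high"]
        low = [s.mz for s in panel if s.role == "fpA_fragment_low"]
        if high and low:
            moved = degradation * sum(amounts[m] for m in high)
            low_base_total = sum(by_mz[m].base_abundance for m in low)
            for m in high:
                amounts[m] *= (1.0 - degradation)
            for m in low:
                share = by_mz[m].base_abundance / low_base_total
                amounts[m] += moved * share
    return amounts


def _replicate_peaklist(sample_id: str, rep: int, panel: list[SignalSpec],
                        truth: dict[float, float], noise: NoiseModel,
                        rng: np.random.Generator) -> PeakList:
    spot = float(np.exp(rng.normal(0.0, noise.spot_sigma))) if noise.spot_sigma > 0 else 1.0
    calib = float(rng.normal(0.0, noise.calibration_sd)) if noise.calibration_sd > 0 else 0.0
    mzs: list[float] = []
    abunds: list[float] = []
    for spec in panel:
        if spec.sporadic_rate > 0 and rng.random() < spec.sporadic_rate:
            continue
        amount = truth[spec.mz] * spot
        if noise.replicate_sigma > 0:
            amount *= float(np.exp(rng.normal(0.0, noise.replicate_sigma)))
        env = np.asarray(spec.isotope_envelope, dtype=float)
        env = env / env.sum()  # envelope carries the signal's total abundance
        for k, rel in enumerate(env):
            mz = spec.mz + k * ISOTOPE_SPACING + calib
            if noise.mz_jitter_sd > 0:
                mz += float(rng.normal(0.0, noise.mz_jitter_sd))
            mzs.append(mz)
            abunds.append(amount * rel)
    order = np.argsort(mzs)
    mz_arr = np.asarray(mzs)[order]
    ab_arr = np.asarray(abunds)[order]
    # merge coincidental collisions closer than the PeakList duplicate limit
    keep_mz: list[float] = []
    keep_ab: list[float] = []
    for m, a in zip(mz_arr, ab_arr):
        if keep_mz and m - keep_mz[-1] < 1e-6:
            keep_ab[-1] += a
        else:
            keep_mz.append(float(m))
            keep_ab.append(float(a))
    return PeakList(np.array(keep_mz), np.array(keep_ab),
                    sample_id=sample_id, replicate=rep)


def generate_cohort(config: CohortConfig, peak_lists: bool = True,
                    ) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Generate a cohort of synthetic samples plus a manifest.

    Deterministic for a fixed config seed. The expected abundance of signal
    *s* in a sample of group *g* is base_abundance(s) × group_effect(s, g)
    (biological noise is mean-one on the ratio-of-means scale).

    ``peak_lists=False`` skips rendering replicate peak lists (samples carry
    only ground-truth abundances) — much faster when only the between-sample
    structure is needed, e.g. via :func:`cohort_to_table`.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[SyntheticSample] = []
    rows = []
    for group, n in config.group_sizes.items():
        cov = config.covariates[group]
        for k in range(n):
            sid = f"{group}_{k + 1:03d}"
            age = _truncnorm(rng, cov.age_mean, cov.age_sd, *cov.age_range)
            gender = "F" if rng.random() < cov.female_prop else "M"
            lo, hi = config.degradation_range
            degradation = float(rng.uniform(lo, hi)) if hi > lo else lo
            truth = _sample_truth(config.signal_panel, group, degradation,
                                  config.noise, rng)
            reps = [_replicate_peaklist(sid, r, config.signal_panel, truth,
                                        config.noise, rng)
                    for r in range(config.replicates_per_sample)] if peak_lists else []
            samples.append(SyntheticSample(sid, group, age, gender, degradation,
                                           reps, truth))
            rows.append({"sample_id": sid, "group": group,
                         "age": round(age, 1), "gender": gender})
    manifest = pd.DataFrame(rows)
    return samples, manifest


def reference_peaklist(config: CohortConfig) -> PeakList:
    """Quality-gate reference: a pristine (zero-degradation, zero-noise)
    rendering of the control-group expectation of the panel."""
    pristine = replace(config, noise=NO_NOISE, degradation_range=(0.0, 0.0))
    rng = np.random.default_rng(0)
    group = next(iter(config.group_sizes))
    truth = _sample_truth(pristine.signal_panel, group, 0.0, NO_NOISE, rng)
    return _replicate_peaklist("reference", 0, pristine.signal_panel, truth,
                               NO_NOISE, rng)


def render_profile(sample: SyntheticSample, peak_width: float = 0.25,
                   grid_step: float = 0.05,
                   mz_range: tuple[float, float] = (800.0, 3000.0),
                   scans: int = 15, baseline_sigma: float = 0.0,
                   seed: int = 0) -> dict[int, list[Spectrum]]:
    """Render each replicate peak list as profile scans.

    Every centroid becomes a Gaussian of sigma ``peak_width`` whose integral
    equals its abundance; the ``scans`` scans of a replicate differ only by
    additive Gaussian baseline noise of sd ``baseline_sigma``.
    """
    if peak_width <= 0 or grid_step <= 0:
        raise ValueError("peak_width and grid_step must be > 0")
    if grid_step > peak_width:
        import warnings
        warnings.warn("grid step coarser than peak width; peaks may be missed",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    grid = np.arange(mz_range[0], mz_range[1] + grid_step / 2, grid_step)
    out: dict[int, list[Spectrum]] = {}
    norm = 1.0 / (peak_width * np.sqrt(2 * np.pi))
    for pl in sample.replicates:
        clean = np.zeros_like(grid)
        for mz, ab in zip(pl.mz, pl.abundance):
            lo = np.searchsorted(grid, mz - 5 * peak_width)
            hi = np.searchsorted(grid, mz + 5 * peak_width)
            clean[lo:hi] += ab * norm * np.exp(-0.5 * ((grid[lo:hi] - mz) / peak_width) ** 2)
        scans_out = []
        for s in range(scans):
            noise = rng.normal(0.0, baseline_sigma, grid.size) if baseline_sigma > 0 else 0.0
            scans_out.append(Spectrum(grid.copy(), np.maximum(clean + noise, 0.0),
                                      sample_id=sample.sample_id, replicate=pl.replicate))
        out[pl.replicate if pl.replicate is not None else 0] = scans_out
    return out


def write_cohort(samples: list[SyntheticSample], manifest: pd.DataFrame,
                 outdir: str | Path) -> pd.DataFrame:
    """Write replicate peak lists as 2-column text files plus manifest.csv.

    Returns the manifest augmented with a ``files`` column (';'-joined
    relative paths). Output is byte-stable for a fixed cohort.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files_col = []
    by_id = {s.sample_id: s for s in samples}
    for sid in manifest["sample_id"]:
        sample = by_id[sid]
        names = []
        for pl in sample.replicates:
            name = f"{sid}_rep{pl.replicate}.txt"
            write_peaklist_text(pl, outdir / name)
            names.append(name)
        files_col.append(";".join(names))
    out = manifest.copy()
    out["files"] = files_col
    out.to_csv(outdir / "manifest.csv", index=False)
    return out


def cohort_to_table(samples: list[SyntheticSample], manifest: pd.DataFrame,
                    normalize: bool = True) -> AlignedTable:
    """Aligned table built directly from ground-truth sample-level abundances.

    Bypasses peak-list rendering and replicate averaging — useful for
    statistical checks where only the between-sample structure matters.
    Abundances are divided by the internal standard's amount when
    ``normalize`` is set, matching the pipeline's scale.
    """
    mzs = sorted(samples[0].truth)
    data = {}
    for s in samples:
        col = np.array([s.truth[m] for m in mzs])
        if normalize:
            std = [m for m in mzs if abs(m - INTERNAL_STANDARD_MZ) < 0.01]
            if std:
                col = col / s.truth[std[0]]
        data[s.sample_id] = col
    abundance = pd.DataFrame(data, index=pd.Index(np.round(mzs, 4), name="mz"))
    ann = manifest.set_index("sample_id")[["group", "age", "gender"]]
    return AlignedTable(abundance, ann.loc[abundance.columns],
                        provenance={"source": "simulated ground truth"})
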