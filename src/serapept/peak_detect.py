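"""Two-step centroid peak picking for profile spectra.

Step 1 takes every strict local maximum as a candidate. Step 2 estimates a
running-median baseline and a windowed MAD noise level around each candidate
and keeps candidates whose baseline-subtracted apex exceeds ``snr`` times the
noise. This is the standard median-filter peak picker for linear MALDI-TOF
serum profiles; defaults (half-window 20 points, SNR 2.5) suit ~0.1 Da grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import PeakList, Spectrum

__all__ = ["PeakDetectConfig", "find_local_maxima", "filter_snr", "detect_peaks"]

# MAD -> sigma for a normal distribution
_MAD_SCALE = 1.4826


@dataclass
class PeakDetectConfig:
    half_window: int = 20
    snr: float = 2.5
    noise_floor_epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValueError("half_window must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")

    def provenance(self) -> dict:
        return {"half_window": self.half_window, "snr": self.snr}


def find_local_maxima(spectrum: Spectrum) -> PeakList:
    """Candidate peaks: points strictly higher than both neighbours.

    Endpoints are never candidates; ties (plateaus) fail the strict
    comparison and are not candidates.
    """
    y = spectrum.intensity
    if y.size < 3:
        return PeakList(np.empty(0), np.empty(0), sample_id=spectrum.sample_id,
                        replicate=spectrum.replicate)
    mask = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
    idx = np.flatnonzero(mask) + 1
    return PeakList(spectrum.mz[idx], y[idx], sample_id=spectrum.sample_id,
                    replicate=spectrum.replicate, meta={"indices": idx})


def _window_stats(y: np.ndarray, i: int, hw: int) -> tuple[float, float]:
    lo = max(0, i - hw)
    hi = min(y.size, i + hw + 1)
    win = y[lo:hi]
    baseline = float(np.median(win))
    noise = _MAD_SCALE * float(np.median(np.abs(win - baseline)))
    return baseline, noise


def filter_snr(candidates: PeakList, spectrum: Spectrum,
               cfg: PeakDetectConfig | None = None) -> PeakList:
    """Keep candidates whose apex rises ``snr``-fold above local noise.

    Baseline is the median of the window ``[i-half_window, i+half_window]``
    (truncated at the spectrum bounds); noise is the MAD of that window
    around the baseline, scaled to a normal sigma and clamped below by
    ``noise_floor_epsilon`` so an exactly-flat background never divides
    by zero.
    """
    cfg = cfg or PeakDetectConfig()
    idx = candidates.meta.get("indices")
    if idx is None:
        # map candidate m/z back onto the grid
        idx = np.searchsorted(spectrum.mz, candidates.mz)
    y = spectrum.intensity
    keep = []
    for i in np.asarray(idx, dtype=int):
        baseline, noise = _window_stats(y, int(i), cfg.half_window)
        snr_i = (y[i] - baseline) / max(noise, cfg.noise_floor_epsilon)
        if snr_i >= cfg.snr:
            keep.append(int(i))
    keep_arr = np.array(keep, dtype=int)
    return PeakList(spectrum.mz[keep_arr], y[keep_arr], sample_id=spectrum.sample_id,
                    replicate=spectrum.replicate, meta={"indices": keep_arr})


def detect_peaks(spectrum: Spectrum, cfg: PeakDetectConfig | None = None) -> PeakList:
    """Full two-step detection: local maxima then SNR filtering."""
    cfg = cfg or PeakDetectConfig()
    return filter_snr(find_local_maxima(spectrum), spectrum, cfg)
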