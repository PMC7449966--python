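"""Fluorescence preprocessing and peak-wavelength feature extraction.

Emission spectra excited at 365 nm (NADH/collagen band) and 450 nm (FAD
band) are dark-corrected and cropped to an analysis band that starts one
guard interval above the long-pass filter edge blocking the backscattered
excitation (FGL400 for 365 nm, FGL495 for 450 nm).  The diagnostic features
are the emission peak wavelengths λ365 and λ450 — scale-invariant, hence
robust to the unreliable absolute fluorescence amplitudes of perfused
liver — taken from the lightly smoothed spectrum.  Site-level features are
medians over replicate spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_forward import Spectrum

__all__ = [
    "ANALYSIS_BANDS",
    "FluorescenceMeasurement",
    "FeatureVector",
    "NoPeakError",
    "preprocess_fluorescence",
    "peak_wavelength",
    "aggregate_site_features",
]

# analysis bands: long-pass filter cutoff + 10 nm guard, within the
# 400-900 nm detection range
ANALYSIS_BANDS = {365.0: (410.0, 700.0), 450.0: (505.0, 800.0)}
LOW_SIGNAL_THRESHOLD = 1e-9


class NoPeakError(ValueError):
    """Raised when a spectrum carries no usable fluorescence signal."""


@dataclass
class FluorescenceMeasurement:
    excitation: float
    emission: Spectrum
    analysis_band: tuple

    def __post_init__(self) -> None:
        lo, hi = self.analysis_band
        if not 400.0 <= lo < hi <= 900.0:
            raise ValueError("analysis band must lie inside 400-900 nm")
        cutoff = {365.0: 400.0, 450.0: 495.0}[float(self.excitation)]
        if lo < cutoff:
            raise ValueError(
                f"band lower edge {lo} below the {cutoff} nm filter cutoff")


@dataclass
class FeatureVector:
    """One classifier input row: per-site medians of the three features."""

    lambda365: float
    lambda450: float
    sto2: float
    label: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.label not in ("liver", "tumor"):
            raise ValueError("label must be 'liver' or 'tumor'")
        if not 0.0 <= self.sto2 <= 1.0:
            raise ValueError("sto2 must lie in [0, 1]")


def preprocess_fluorescence(raw: Spectrum, dark: Spectrum,
                            excitation: float) -> FluorescenceMeasurement:
    """Dark-subtract, floor at zero and crop to the excitation's band."""
    exc = float(excitation)
    if exc not in ANALYSIS_BANDS:
        raise ValueError("excitation must be 365 or 450 nm")
    if (raw.wavelengths.shape != dark.wavelengths.shape
            or not np.allclose(raw.wavelengths, dark.wavelengths)):
        raise ValueError("raw and dark spectra are on different grids")
    lo, hi = ANALYSIS_BANDS[exc]
    sel = (raw.wavelengths >= lo) & (raw.wavelengths <= hi)
    vals = np.clip(raw.values[sel] - dark.values[sel], 0.0, None)
    meta = dict(raw.meta)
    meta["low_signal"] = bool(vals.max(initial=0.0) <= LOW_SIGNAL_THRESHOLD)
    emission = Spectrum(raw.wavelengths[sel], vals, kind="fluorescence",
                        meta=meta)
    return FluorescenceMeasurement(excitation=exc, emission=emission,
                                   analysis_band=(lo, hi))


def peak_wavelength(m: FluorescenceMeasurement,
                    smooth_window: float = 5.0) -> float:
    """Wavelength (nm) of the maximum of the smoothed emission spectrum.

    Smoothing is a moving average over ``smooth_window`` nm (0 disables
    it); exact ties resolve to the shortest wavelength.
    """
    spec = m.emission
    if spec.wavelengths.size == 0 or m.emission.meta.get("low_signal"):
        raise NoPeakError("no usable fluorescence signal in the band")
    vals = spec.values
    if smooth_window > 0:
        step = np.median(np.diff(spec.wavelengths))
        half = max(0, int(round(smooth_window / (2.0 * step))))
        if half > 0:
            kernel = np.ones(2 * half + 1)
            norm = np.convolve(np.ones_like(vals), kernel, mode="same")
            vals = np.convolve(vals, kernel, mode="same") / norm
    if vals.max() <= LOW_SIGNAL_THRESHOLD:
        raise NoPeakError("signal below the low-signal threshold")
    return float(spec.wavelengths[int(np.argmax(vals))])


def aggregate_site_features(fluor365, fluor450, sto2_estimates, label: str,
                            subject_id) -> FeatureVector:
    """Combine replicate measurements of one site into one feature row.

    ``fluor365`` / ``fluor450`` are sequences of
    :class:`FluorescenceMeasurement`; ``sto2_estimates`` a sequence of
    saturation values.  Medians are used throughout (robust to occasional
    outlier spectra).
    """
    missing = [name for name, seq in
               (("365 nm fluorescence", fluor365),
                ("450 nm fluorescence", fluor450),
                ("StO2", sto2_estimates)) if len(seq) == 0]
    if missing:
        raise ValueError(f"incomplete feature set, missing: {missing}")
    lam365 = float(np.median([peak_wavelength(m) for m in fluor365]))
    lam450 = float(np.median([peak_wavelength(m) for m in fluor450]))
    sto2 = float(np.median([float(s) for s in sto2_estimates]))
    return FeatureVector(lambda365=lam365, lambda450=lam450, sto2=sto2,
                         label=label, subject_id=str(subject_id))
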