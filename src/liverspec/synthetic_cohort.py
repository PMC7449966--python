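"""Synthetic measurement cohort emulating the optical-biopsy study design.

Each subject contributes one intact-liver site and one tumor site; each
site carries 20 fluorescence spectra per excitation source (365 and
450 nm) and 100 diffuse reflectance spectra, matching the clinical
acquisition protocol.  The generator encodes the two effects the study
relies on, with configurable sizes:

* tumor oxygen saturation above liver (arterial supply of hepatic tumors)
  — default means 0.75 vs 0.55, between-subject spread 0.08;
* liver fluorescence peaks red-shifted relative to tumor (bile/bilirubin
  contribution of hepatocyte-rich tissue) — default 15-nm shift at both
  excitations, between-subject spread 4 nm.

Fluorescence emission is a single Gaussian band (only the peak wavelength
is consumed downstream); reflectance spectra come from the Monte Carlo
forward model with site-level tissue compositions, a random
collection-efficiency scale per replicate, and relative measurement noise.
Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluor_features import aggregate_site_features, preprocess_fluorescence
from .spectra_forward import Spectrum, default_forward
from .sto2_inverse import FIT_BAND, estimate_saturation
from .tissue_optics import TissueComposition

__all__ = [
    "CohortConfig",
    "SiteMeasurements",
    "SyntheticCohort",
    "generate_fluorescence_spectrum",
    "generate_drs_measurement",
    "generate_cohort",
    "extract_features",
]

FLUOR_GRID = np.arange(400.0, 900.5, 1.0)
DRS_GRID = np.arange(FIT_BAND[0], FIT_BAND[1] + 1.0, 2.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design constants and effect sizes of the synthetic cohort."""

    n_subjects: int = 20
    fs_replicates: int = 20
    drs_replicates: int = 100
    liver_sto2_mean: float = 0.55
    tumor_sto2_mean: float = 0.75
    sto2_sd: float = 0.08
    liver_peak365: float = 510.0
    tumor_peak365: float = 495.0
    liver_peak450: float = 560.0
    tumor_peak450: float = 545.0
    peak_sd: float = 4.0
    band_sigma: float = 25.0
    peak_jitter: float = 1.5
    fluor_amplitude: float = 1000.0
    fluor_noise: float = 5.0
    drs_noise_frac: float = 0.01
    blood_fraction_range: tuple = (0.05, 0.15)
    scattering_amplitude_range: tuple = (8.0, 20.0)
    scattering_power_range: tuple = (0.8, 1.6)

    def __post_init__(self) -> None:
        if self.fs_replicates < 1 or self.drs_replicates < 1:
            raise ValueError("replicate counts must be >= 1")

    def sto2_mean(self, tissue: str) -> float:
        return {"liver": self.liver_sto2_mean,
                "tumor": self.tumor_sto2_mean}[tissue]

    def peak_mean(self, tissue: str, excitation: float) -> float:
        return {("liver", 365.0): self.liver_peak365,
                ("tumor", 365.0): self.tumor_peak365,
                ("liver", 450.0): self.liver_peak450,
                ("tumor", 450.0): self.tumor_peak450}[(tissue,
                                                       float(excitation))]


@dataclass
class SiteMeasurements:
    subject_id: str
    tissue: str                      # "liver" | "tumor"
    fluorescence: dict               # excitation -> list[Spectrum]
    drs: list
    true_sto2: float
    true_peak365: float
    true_peak450: float
    composition: TissueComposition


@dataclass
class SyntheticCohort:
    config: CohortConfig
    seed: int
    sites: list = field(default_factory=list)

    @property
    def ground_truth(self) -> pd.DataFrame:
        rows = [{"subject": s.subject_id, "tissue": s.tissue,
                 "true_sto2": s.true_sto2, "true_peak365": s.true_peak365,
                 "true_peak450": s.true_peak450} for s in self.sites]
        return pd.DataFrame(rows)


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def generate_fluorescence_spectrum(tissue: str, excitation: float,
                                   config: CohortConfig,
                                   rng: np.random.Generator,
                                   subject_peak: float | None = None
                                   ) -> Spectrum:
    """One Gaussian-band emission spectrum on the 400-900 nm grid.

    ``subject_peak`` pins the subject-level peak (drawn from the
    configured distribution when omitted); replicate-level jitter and
    additive detector noise are applied on top.
    """
    if float(excitation) not in (365.0, 450.0):
        raise ValueError("excitation must be 365 or 450 nm")
    if subject_peak is None:
        subject_peak = _truncnorm(rng, config.peak_mean(tissue, excitation),
                                  config.peak_sd, 420.0, 880.0)
    peak = subject_peak + (config.peak_jitter * rng.standard_normal()
                           if config.peak_jitter > 0 else 0.0)
    amp = config.fluor_amplitude * (1.0 + 0.2 * rng.standard_normal())
    amp = max(amp, 0.1 * config.fluor_amplitude)
    vals = amp * np.exp(-0.5 * ((FLUOR_GRID - peak) / config.band_sigma) ** 2)
    if config.fluor_noise > 0:
        vals = vals + config.fluor_noise * rng.standard_normal(vals.shape)
    return Spectrum(FLUOR_GRID.copy(), vals, kind="fluorescence",
                    meta={"tissue": tissue, "excitation": float(excitation),
                          "true_peak": float(subject_peak)})


def _draw_composition(tissue: str, config: CohortConfig,
                      rng: np.random.Generator) -> TissueComposition:
    S = _truncnorm(rng, config.sto2_mean(tissue), config.sto2_sd, 0.0, 1.0)
    B = rng.uniform(*config.blood_fraction_range)
    a = rng.uniform(*config.scattering_amplitude_range)
    b = rng.uniform(*config.scattering_power_range)
    return TissueComposition(blood_fraction=B, oxygen_saturation=S,
                             water_fraction=0.7, scattering_amplitude=a,
                             scattering_power=b)


def generate_drs_measurement(tissue: str, config: CohortConfig,
                             rng: np.random.Generator, forward=None,
                             composition: TissueComposition | None = None
                             ) -> Spectrum:
    """One noisy reflectance spectrum for a fresh (or given) composition."""
    if forward is None:
        forward = default_forward()
    if composition is None:
        composition = _draw_composition(tissue, config, rng)
    clean = forward.spectrum(composition, DRS_GRID).values
    scale = float(np.exp(rng.normal(0.0, 0.25)))  # collection efficiency
    vals = clean * scale
    if config.drs_noise_frac > 0:
        vals = vals * (1.0 + config.drs_noise_frac
                       * rng.standard_normal(vals.shape))
    return Spectrum(DRS_GRID.copy(), np.clip(vals, 0.0, None),
                    kind="reflectance",
                    meta={"tissue": tissue,
                          "true_sto2": composition.oxygen_saturation})


def generate_cohort(config: CohortConfig | None = None,
                    seed: int = 0, forward=None) -> SyntheticCohort:
    """Full synthetic cohort: per subject one liver and one tumor site."""
    config = config or CohortConfig()
    if forward is None:
        forward = default_forward()
    rng = np.random.default_rng(seed)
    cohort = SyntheticCohort(config=config, seed=seed)
    for i in range(1, config.n_subjects + 1):
        for tissue in ("liver", "tumor"):
            comp = _draw_composition(tissue, config, rng)
            peak365 = _truncnorm(rng, config.peak_mean(tissue, 365.0),
                                 config.peak_sd, 420.0, 690.0)
            peak450 = _truncnorm(rng, config.peak_mean(tissue, 450.0),
                                 config.peak_sd, 515.0, 790.0)
            fluor = {365.0: [], 450.0: []}
            for exc, peak in ((365.0, peak365), (450.0, peak450)):
                for _ in range(config.fs_replicates):
                    fluor[exc].append(generate_fluorescence_spectrum(
                        tissue, exc, config, rng, subject_peak=peak))
            clean = forward.spectrum(comp, DRS_GRID).values
            drs = []
            for _ in range(config.drs_replicates):
                scale = float(np.exp(rng.normal(0.0, 0.25)))
                vals = clean * scale
                if config.drs_noise_frac > 0:
                    vals = vals * (1.0 + config.drs_noise_frac
                                   * rng.standard_normal(vals.shape))
                drs.append(Spectrum(DRS_GRID.copy(),
                                    np.clip(vals, 0.0, None),
                                    kind="reflectance",
                                    meta={"tissue": tissue}))
            cohort.sites.append(SiteMeasurements(
                subject_id=str(i), tissue=tissue, fluorescence=fluor,
                drs=drs, true_sto2=comp.oxygen_saturation,
                true_peak365=peak365, true_peak450=peak450,
                composition=comp))
    return cohort


def extract_features(cohort: SyntheticCohort, model) -> list:
    """Feature vectors (per-site medians) for every site of the cohort.

    ``model`` is a trained saturation regressor; fluorescence peaks are
    extracted after standard preprocessing with a zero dark frame.
    """
    dark = Spectrum(FLUOR_GRID.copy(), np.zeros_like(FLUOR_GRID),
                    kind="dark")
    features = []
    for site in cohort.sites:
        meas365 = [preprocess_fluorescence(sp, dark, 365.0)
                   for sp in site.fluorescence[365.0]]
        meas450 = [preprocess_fluorescence(sp, dark, 450.0)
                   for sp in site.fluorescence[450.0]]
        sto2 = [estimate_saturation(model, sp).value for sp in site.drs]
        features.append(aggregate_site_features(
            meas365, meas450, sto2, label=site.tissue,
            subject_id=site.subject_id))
    return features
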