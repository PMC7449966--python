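"""Chromophore-based absorption/scattering model of liver tissue.

The absorption coefficient of perfused tissue is modelled as a linear mix of
whole-blood hemoglobin (oxy and deoxy fractions set by the oxygen saturation
``S``) and water,

    mu_a(l) = B * [S * mua_HbO2(l) + (1 - S) * mua_Hb(l)] + W * mua_water(l),

with ``B`` the blood volume fraction and ``W`` the water fraction.  Reduced
scattering follows the usual power law ``mus' = a * (l / 500 nm)**(-b)``.
Hemoglobin curves refer to whole blood at 150 g/L total hemoglobin, so ``B``
reads directly as a blood volume fraction.  A pinned liver reference table
(absorption, scattering, anisotropy, refractive index on 10-nm nodes over
360-1000 nm) supplies the medium for the photon-transport simulations.

Internal units: lengths in cm, coefficients in 1/cm, wavelengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreSpectra",
    "TissueComposition",
    "OpticalProperties",
    "WavelengthRangeError",
    "load_chromophores",
    "absorption_from_composition",
    "scattering_from_composition",
    "liver_reference_properties",
    "isosbestic_wavelength",
]


class WavelengthRangeError(ValueError):
    """Raised when a wavelength falls outside a bundled table's support."""


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Absorption spectra of the modelled chromophores on a shared grid.

    Hemoglobin columns are whole-blood absorption (1/cm) at the reference
    concentration of 150 g/L; water is pure-water absorption (1/cm).
    """

    wavelength_grid: np.ndarray
    absorption_oxyhemoglobin: np.ndarray
    absorption_deoxyhemoglobin: np.ndarray
    absorption_water: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength_grid, float)
        if w.ndim != 1 or not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be 1-D strictly increasing")
        for name in ("absorption_oxyhemoglobin", "absorption_deoxyhemoglobin",
                     "absorption_water"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != w.shape:
                raise ValueError(f"{name} must match the wavelength grid")
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")

    def _check(self, wavelength) -> None:
        lam = np.atleast_1d(np.asarray(wavelength, float))
        lo, hi = self.wavelength_grid[0], self.wavelength_grid[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise WavelengthRangeError(
                f"wavelength outside chromophore range [{lo}, {hi}] nm")

    def oxy(self, wavelength):
        self._check(wavelength)
        return np.interp(wavelength, self.wavelength_grid,
                         self.absorption_oxyhemoglobin)

    def deoxy(self, wavelength):
        self._check(wavelength)
        return np.interp(wavelength, self.wavelength_grid,
                         self.absorption_deoxyhemoglobin)

    def water(self, wavelength):
        self._check(wavelength)
        return np.interp(wavelength, self.wavelength_grid,
                         self.absorption_water)


@dataclass(frozen=True)
class TissueComposition:
    """Physiological parameters defining the optical model of one tissue.

    blood_fraction
        Blood volume fraction B in [0, 1] (whole blood at 150 g/L Hb).
    oxygen_saturation
        Hemoglobin oxygen saturation S in [0, 1].
    water_fraction
        Water volume fraction W in [0, 1]; B + W <= 1.
    scattering_amplitude, scattering_power
        Reduced scattering at 500 nm (1/cm) and the power-law exponent.
    anisotropy, refractive_index
        Scattering anisotropy g in (-1, 1); refractive index n >= 1.
    """

    blood_fraction: float
    oxygen_saturation: float
    water_fraction: float
    scattering_amplitude: float
    scattering_power: float
    anisotropy: float = 0.9
    refractive_index: float = 1.38

    def __post_init__(self) -> None:
        for name in ("blood_fraction", "oxygen_saturation", "water_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.blood_fraction + self.water_fraction > 1.0 + 1e-12:
            raise ValueError("blood_fraction + water_fraction must be <= 1")
        if self.scattering_power < 0:
            raise ValueError("scattering_power must be >= 0")
        if not -1.0 < self.anisotropy < 1.0:
            raise ValueError("anisotropy must lie in (-1, 1)")
        if self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1")


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous-medium optical properties at one wavelength (1/cm, nm)."""

    mu_a: float
    mu_s: float
    g: float
    n: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("n must be >= 1")

    @property
    def mu_s_reduced(self) -> float:
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s


_CHROMO_CACHE: ChromophoreSpectra | None = None
_LIVER_CACHE: np.ndarray | None = None


def load_chromophores(path=None) -> ChromophoreSpectra:
    """Load the bundled chromophore table (or an override CSV)."""
    global _CHROMO_CACHE
    if path is None and _CHROMO_CACHE is not None:
        return _CHROMO_CACHE
    if path is None:
        src = resources.files("liverspec.data").joinpath(
            "blood_water_absorption.csv")
        with src.open("r") as fh:
            arr = pd.read_csv(fh, comment="#")
    else:
        arr = pd.read_csv(path, comment="#")
    chromo = ChromophoreSpectra(
        wavelength_grid=arr["wavelength_nm"].to_numpy(float),
        absorption_oxyhemoglobin=arr["mua_oxyhemoglobin"].to_numpy(float),
        absorption_deoxyhemoglobin=arr["mua_deoxyhemoglobin"].to_numpy(float),
        absorption_water=arr["mua_water"].to_numpy(float),
    )
    if path is None:
        _CHROMO_CACHE = chromo
    return chromo


def absorption_from_composition(comp: TissueComposition, wavelength,
                                chromo: ChromophoreSpectra | None = None):
    """Absorption coefficient (1/cm) of the chromophore mix at ``wavelength``.

    Linear in the blood and water fractions; raises
    :class:`WavelengthRangeError` outside the chromophore grid.
    """
    if chromo is None:
        chromo = load_chromophores()
    B = comp.blood_fraction
    S = comp.oxygen_saturation
    W = comp.water_fraction
    mua = B * (S * chromo.oxy(wavelength) + (1.0 - S) * chromo.deoxy(wavelength))
    mua = mua + W * chromo.water(wavelength)
    return mua


def scattering_from_composition(comp: TissueComposition, wavelength):
    """Return ``(mus_reduced, mus)`` in 1/cm from the power-law model."""
    lam = np.asarray(wavelength, float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    if comp.anisotropy >= 1.0:
        raise ValueError("anisotropy must be < 1")
    musp = comp.scattering_amplitude * (lam / 500.0) ** (-comp.scattering_power)
    mus = musp / (1.0 - comp.anisotropy)
    return musp, mus


def _liver_table():
    global _LIVER_CACHE
    if _LIVER_CACHE is None:
        src = resources.files("liverspec.data").joinpath(
            "liver_optical_properties.csv")
        with src.open("r") as fh:
            _LIVER_CACHE = pd.read_csv(fh, comment="#")
    return _LIVER_CACHE


def liver_reference_properties(wavelength: float,
                               table=None) -> OpticalProperties:
    """Pinned liver optical properties, linearly interpolated on 10-nm nodes.

    Valid for 360-1000 nm (the table extends below the chromophore grid to
    cover the 365-nm fluorescence excitation); no extrapolation.
    """
    arr = _liver_table() if table is None else table
    lam = float(wavelength)
    w = np.asarray(arr["wavelength_nm"], float)
    lo, hi = w[0], w[-1]
    if not lo <= lam <= hi:
        raise WavelengthRangeError(
            f"wavelength {lam} nm outside liver table range [{lo}, {hi}]")
    return OpticalProperties(
        mu_a=float(np.interp(lam, w, np.asarray(arr["mua_1_cm"], float))),
        mu_s=float(np.interp(lam, w, np.asarray(arr["mus_1_cm"], float))),
        g=float(np.interp(lam, w, np.asarray(arr["g"], float))),
        n=float(np.interp(lam, w, np.asarray(arr["n"], float))),
        wavelength=lam,
    )


def isosbestic_wavelength(chromo: ChromophoreSpectra | None = None,
                          window=(760.0, 850.0)) -> float:
    """Wavelength where the bundled oxy and deoxy curves cross in ``window``.

    Located by linear interpolation of the sign change of (oxy - deoxy);
    with the bundled data this falls in the 790-810 nm isosbestic region.
    """
    if chromo is None:
        chromo = load_chromophores()
    w = chromo.wavelength_grid
    sel = (w >= window[0]) & (w <= window[1])
    ww = w[sel]
    d = (chromo.absorption_oxyhemoglobin[sel]
         - chromo.absorption_deoxyhemoglobin[sel])
    sign = np.sign(d)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        raise ValueError("no oxy/deoxy crossing found in window")
    i = idx[0]
    # linear interpolation of the zero of d between nodes i and i+1
    return float(ww[i] - d[i] * (ww[i + 1] - ww[i]) / (d[i + 1] - d[i]))
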