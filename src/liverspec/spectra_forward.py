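"""Forward generation and calibration of diffuse reflectance spectra.

Two forward routes produce the probe's detected reflectance for a given
:class:`~liverspec.tissue_optics.TissueComposition`:

``simulate_drs``
    Reference route: one full Monte Carlo transport run per wavelength node
    (default 10-nm spacing), linearly interpolated to the requested grid.

``WhiteMonteCarloForward``
    Accelerated route for bulk spectrum generation (regressor training
    sets, synthetic cohorts).  A zero-absorption ("white") transport run is
    performed once per scattering node and every in-cone surface exit is
    recorded as (detector arc fraction, path length); the reflectance at
    any absorption then follows from Beer-Lambert reweighting
    ``R = (1 - R_specular) * mean(frac * exp(-mu_a * L))``, interpolated
    log-log across the scattering grid.  Anisotropy and refractive index
    are fixed model constants here, which is adequate because they enter
    the inverse problem only as nuisance shape factors.

Calibration follows the two-reference scheme of fiber-probe spectrometry:
a dark spectrum and a Spectralon (ideal Lambertian) reference, with
``R = (raw - dark) / (reference - dark)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _mc_kernels as _k
from .photon_mc import ProbeGeometry, SimulationConfig, run_simulation
from .tissue_optics import (TissueComposition, OpticalProperties,
                            absorption_from_composition, load_chromophores,
                            scattering_from_composition)

__all__ = [
    "Spectrum",
    "CalibrationError",
    "simulate_drs",
    "calibrate_reflectance",
    "apply_noise",
    "WhiteMonteCarloForward",
]

SPECTRUM_KINDS = ("raw", "dark", "reference", "reflectance", "fluorescence")


class CalibrationError(ValueError):
    pass


@dataclass
class Spectrum:
    """Wavelength grid (nm, strictly increasing) plus values and provenance."""

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.values = np.asarray(self.values, float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != \
                self.values.shape:
            raise ValueError("wavelengths and values must be equal-length 1-D")
        if self.wavelengths.size and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}")
        if self.kind == "reflectance" and np.any(self.values < 0):
            raise ValueError("reflectance values must be non-negative")

    def interp(self, wavelengths) -> np.ndarray:
        """Linear interpolation onto ``wavelengths`` (must lie inside grid)."""
        w = np.asarray(wavelengths, float)
        if w.min() < self.wavelengths[0] or w.max() > self.wavelengths[-1]:
            raise ValueError("requested band not covered by spectrum")
        return np.interp(w, self.wavelengths, self.values)

    def crop(self, lo: float, hi: float) -> "Spectrum":
        sel = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        return Spectrum(self.wavelengths[sel], self.values[sel],
                        kind=self.kind, meta=dict(self.meta))


def _composition_properties(comp: TissueComposition, lam: float,
                            chromo) -> OpticalProperties:
    mua = float(absorption_from_composition(comp, lam, chromo))
    _, mus = scattering_from_composition(comp, lam)
    return OpticalProperties(mu_a=mua, mu_s=float(mus), g=comp.anisotropy,
                             n=comp.refractive_index, wavelength=lam)


def simulate_drs(comp: TissueComposition, geometry: ProbeGeometry,
                 wavelengths, config: SimulationConfig | None = None,
                 node_spacing: float = 10.0, chromo=None) -> Spectrum:
    """Detected reflectance spectrum by direct per-node Monte Carlo.

    One transport run per node (``node_spacing`` nm), then linear
    interpolation to ``wavelengths``.  Reproducible given ``config.seed``;
    node runs use consecutive sub-seeds.
    """
    if chromo is None:
        chromo = load_chromophores()
    if config is None:
        config = SimulationConfig(n_photons=100_000, track_map=False)
    lam = np.asarray(wavelengths, float)
    lo, hi = lam.min(), lam.max()
    nodes = np.unique(np.concatenate([np.arange(lo, hi, node_spacing),
                                      [hi]]))
    r_nodes = np.empty_like(nodes)
    for i, node in enumerate(nodes):
        props = _composition_properties(comp, float(node), chromo)
        cfg = SimulationConfig(**{**config.__dict__,
                                  "seed": config.seed + i,
                                  "track_map": False})
        r_nodes[i] = run_simulation(geometry, props, cfg).detected_fraction
    return Spectrum(lam, np.interp(lam, nodes, r_nodes), kind="reflectance",
                    meta={"forward": "direct_mc", "seed": config.seed,
                          "n_photons": config.n_photons,
                          "node_spacing": node_spacing})


def calibrate_reflectance(raw: Spectrum, dark: Spectrum,
                          reference: Spectrum) -> Spectrum:
    """``(raw - dark) / (reference - dark)`` on a shared grid."""
    for other in (dark, reference):
        if (other.wavelengths.shape != raw.wavelengths.shape
                or not np.allclose(other.wavelengths, raw.wavelengths)):
            raise CalibrationError("spectra are on different wavelength grids")
    denom = reference.values - dark.values
    bad = denom <= 0
    if bad.any():
        lam_bad = raw.wavelengths[bad][0]
        raise CalibrationError(
            f"reference does not exceed dark at {lam_bad:.1f} nm")
    vals = (raw.values - dark.values) / denom
    return Spectrum(raw.wavelengths, np.clip(vals, 0.0, None),
                    kind="reflectance", meta={"calibrated": True})


def apply_noise(spec: Spectrum, noise_floor: float, shot_scale: float,
                seed: int) -> Spectrum:
    """Additive Gaussian noise with signal-dependent spread.

    sigma(lambda) = noise_floor + shot_scale * sqrt(max(value, 0)); the
    result is reproducible for a fixed ``seed`` and unbiased in the mean.
    """
    if noise_floor < 0 or shot_scale < 0:
        raise ValueError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = noise_floor + shot_scale * np.sqrt(np.clip(spec.values, 0, None))
    vals = spec.values + rng.standard_normal(spec.values.shape) * sigma
    kind = spec.kind
    if kind == "reflectance":
        vals = np.clip(vals, 0.0, None)
    return Spectrum(spec.wavelengths, vals, kind=kind,
                    meta={**spec.meta, "noise_floor": noise_floor,
                          "shot_scale": shot_scale, "noise_seed": seed})


class WhiteMonteCarloForward:
    """Accelerated reflectance forward model from white-MC path records.

    The model medium is isotropically scattering at the reduced scattering
    coefficient (first-order similarity, mu_s_model = mu_s'); this keeps the
    zero-absorption baselines cheap while preserving the absorption-path
    statistics that carry the oxygen-saturation signature.

    Parameters
    ----------
    geometry : probe geometry used for all baseline runs.
    mus_grid : model scattering coefficients (1/cm, = mu_s' for g = 0) of
        the baseline runs; queries interpolate log-reflectance in log(mu_s)
        between nodes.
    g, n : anisotropy and refractive index of the model medium.
    n_photons : packets per baseline node.
    seed : base seed; node ``i`` runs with ``seed + i``.
    """

    def __init__(self, geometry: ProbeGeometry | None = None,
                 mus_grid=None, g: float = 0.0, n: float = 1.38,
                 n_photons: int = 3_000_000, seed: int = 12345,
                 max_path: float = 12.0):
        self.geometry = geometry or ProbeGeometry()
        self.mus_grid = np.asarray(
            mus_grid if mus_grid is not None else np.geomspace(1.5, 24.0, 8),
            float)
        self.g = g
        self.n = n
        self.n_photons = n_photons
        self.seed = seed
        self.max_path = max_path
        self._records = None

    def _ensure_baselines(self) -> None:
        if self._records is not None:
            return
        geo = self.geometry
        cos_cone = geo.cone_cosine(self.n)
        recs = []
        for i, mus in enumerate(self.mus_grid):
            fr, ll = _k.white_paths(
                np.uint32((self.seed + i) % (2 ** 32)), self.n_photons,
                float(mus), self.g, self.n, geo.ambient_index,
                geo.source_radius, geo.detector_radius, geo.separation,
                cos_cone, cos_cone, self.max_path,
                max(10_000, self.n_photons // 4))
            recs.append((fr, ll))
        self._records = recs
        self._w0 = 1.0 - _k.fresnel_unpolarized(1.0, geo.ambient_index,
                                                self.n)

    def _node_reflectance(self, i: int, mu_a) -> np.ndarray:
        fr, ll = self._records[i]
        mu_a = np.atleast_1d(np.asarray(mu_a, float))
        out = np.exp(-np.outer(mu_a, ll)) @ fr
        return self._w0 * out / self.n_photons

    def reflectance(self, mu_a, mu_s):
        """Detected fraction for absorption ``mu_a`` and scattering ``mu_s``
        (both 1/cm, scalars or same-shape arrays)."""
        self._ensure_baselines()
        mu_a = np.atleast_1d(np.asarray(mu_a, float))
        mu_s = np.atleast_1d(np.asarray(mu_s, float))
        mu_s = np.broadcast_to(mu_s, mu_a.shape)
        grid = self.mus_grid
        if np.any(mu_s < grid[0]) or np.any(mu_s > grid[-1]):
            raise ValueError("mu_s outside the baseline scattering grid")
        idx = np.clip(np.searchsorted(grid, mu_s) - 1, 0, len(grid) - 2)
        out = np.empty(mu_a.shape)
        for i in np.unique(idx):
            sel = idx == i
            r_lo = self._node_reflectance(i, mu_a[sel])
            r_hi = self._node_reflectance(i + 1, mu_a[sel])
            t = (np.log(mu_s[sel]) - np.log(grid[i])) / \
                (np.log(grid[i + 1]) - np.log(grid[i]))
            out[sel] = np.exp((1 - t) * np.log(np.maximum(r_lo, 1e-300))
                              + t * np.log(np.maximum(r_hi, 1e-300)))
        return out

    def spectrum(self, comp: TissueComposition, wavelengths,
                 chromo=None) -> Spectrum:
        """Reflectance spectrum of ``comp`` on ``wavelengths`` (nm)."""
        if chromo is None:
            chromo = load_chromophores()
        lam = np.asarray(wavelengths, float)
        mua = absorption_from_composition(comp, lam, chromo)
        musp, _ = scattering_from_composition(comp, lam)
        mus = musp / (1.0 - self.g)  # model medium uses the fixed g
        vals = self.reflectance(np.atleast_1d(mua), np.atleast_1d(mus))
        return Spectrum(lam, vals, kind="reflectance",
                        meta={"forward": "white_mc", "seed": self.seed,
                              "n_photons": self.n_photons})


_DEFAULT_FORWARD: WhiteMonteCarloForward | None = None


def default_forward() -> WhiteMonteCarloForward:
    """Process-wide shared accelerated forward model (lazily built)."""
    global _DEFAULT_FORWARD
    if _DEFAULT_FORWARD is None:
        _DEFAULT_FORWARD = WhiteMonteCarloForward()
    return _DEFAULT_FORWARD
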