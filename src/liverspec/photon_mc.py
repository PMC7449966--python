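"""Weighted Monte Carlo photon transport for a two-fiber needle probe.

The medium is homogeneous and semi-infinite (tissue fills z >= 0); the probe
face occludes the surface, so the ambient index at z = 0 is the fused-silica
value everywhere.  A source fiber launches packets uniformly over its face
into the Snell-consistent acceptance cone; a detector fiber at a fixed
center-to-center separation collects packets that exit within its face and
inside the same in-tissue cone.  Scattering follows Henyey-Greenstein;
absorption is handled by weight attenuation with unbiased Russian roulette.

Outputs are the detected fraction, per-photon detection records, the
sampling-volume cross-section through the two fiber centers (visitation
weight of detected photons, normalized to its maximum) and the fluence-depth
profile averaged over the probe footprint (absorption estimator, normalized
to its near-surface maximum).  The sensing depth is the deepest voxel of the
sampling map above a relative threshold (default 1e-3, the dynamic range of
the detector); the penetration depth is the deepest bin where the normalized
fluence stays above the same threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _mc_kernels as _k
from .tissue_optics import OpticalProperties

__all__ = [
    "ProbeGeometry",
    "PhotonState",
    "SimulationConfig",
    "SamplingVolumeMap",
    "FluenceMap",
    "SimulationResult",
    "GeometryError",
    "EmptyMapError",
    "fresnel_reflectance",
    "launch",
    "sample_step",
    "scatter_hg",
    "absorb_and_roulette",
    "boundary_interaction",
    "run_simulation",
    "sensing_depth",
    "penetration_depth",
    "save_result_h5",
]

DETECTED_PHOTON_DTYPE = np.dtype([
    ("exit_x", float), ("exit_y", float), ("exit_cosine", float),
    ("weight", float), ("path_length", float), ("max_depth", float),
])


class GeometryError(ValueError):
    """Invalid probe geometry (e.g. acceptance cone undefined)."""


class EmptyMapError(ValueError):
    """Raised when a depth is requested from a map with no detected signal."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Two-fiber probe: 100 um source, 200 um detector, 220 um apart, NA 0.22.

    Lengths in cm.  ``ambient_index`` is the fused-silica probe face in
    contact with the tissue.
    """

    source_radius: float = 0.005
    detector_radius: float = 0.010
    separation: float = 0.022
    numerical_aperture: float = 0.22
    ambient_index: float = 1.46

    def __post_init__(self) -> None:
        if self.source_radius <= 0 or self.detector_radius <= 0:
            raise GeometryError("fiber radii must be positive")
        if self.separation < 0:
            raise GeometryError("separation must be >= 0")
        if not 0.0 < self.numerical_aperture < 1.0:
            raise GeometryError("numerical aperture must lie in (0, 1)")

    def cone_cosine(self, tissue_n: float) -> float:
        """Cosine of the in-tissue acceptance half-angle asin(NA / n)."""
        ratio = self.numerical_aperture / tissue_n
        if ratio > 1.0:
            raise GeometryError("NA / tissue index exceeds 1: cone undefined")
        return float(np.sqrt(1.0 - ratio * ratio))

    def swapped(self) -> "ProbeGeometry":
        """Geometry with source and detector fibers exchanged."""
        return dataclasses.replace(self, source_radius=self.detector_radius,
                                   detector_radius=self.source_radius)


@dataclass
class PhotonState:
    """Mutable packet state used by the stepwise (non-kernel) operations."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    path_length: float = 0.0
    max_depth: float = 0.0
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.direction = np.asarray(self.direction, float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("weight must lie in (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Photon budget, variance-reduction settings and scoring grids.

    The sampling-volume grid covers ``x_extent`` laterally and ``z_extent``
    in depth at ``voxel_size`` resolution, collapsed over a slab of
    half-width ``slab_half`` (default: half a voxel) through the fiber
    centers.  Fluence is scored versus depth in ``fluence_bin`` slabs inside
    a cylinder of radius ``fluence_radius`` (default: the 1-mm probe
    footprint) about the source axis.
    """

    n_photons: int = 1_000_000
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    voxel_size: float = 0.001
    x_extent: tuple = (-0.06, 0.10)
    z_extent: float = 0.25
    slab_half: float | None = None
    fluence_depth: float = 2.5
    fluence_bin: float = 0.005
    fluence_radius: float = 0.05
    max_path: float = 100.0
    detection_threshold: float = 1e-3
    track_map: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.roulette_threshold < 1.0:
            raise ValueError("roulette_threshold must lie in (0, 1)")
        if not 0.0 < self.roulette_survival <= 1.0:
            raise ValueError("roulette_survival must lie in (0, 1]")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not 0.0 < self.detection_threshold <= 1.0:
            raise ValueError("detection_threshold must lie in (0, 1]")


@dataclass
class SamplingVolumeMap:
    """Detected-photon visitation weight on the x-z cross-section.

    ``values[i, j]`` covers voxel ``x[i], z[j]`` (bin centers); normalized so
    the maximum is 1 when any photon was detected, ``empty`` otherwise.
    """

    x: np.ndarray
    z: np.ndarray
    values: np.ndarray
    empty: bool = False


@dataclass
class FluenceMap:
    """Normalized fluence versus depth (1 at its near-surface maximum)."""

    z: np.ndarray
    values: np.ndarray
    empty: bool = False


@dataclass
class SimulationResult:
    detected_fraction: float
    detected: np.ndarray           # DETECTED_PHOTON_DTYPE records
    n_detected: int
    sampling_map: SamplingVolumeMap
    fluence: FluenceMap
    ledger: dict
    config: SimulationConfig
    geometry: ProbeGeometry
    properties: OpticalProperties

    @property
    def detected_fraction_stderr(self) -> float:
        """Binomial-style MC standard error of the detected fraction."""
        n = self.config.n_photons
        f = self.detected_fraction
        return float(np.sqrt(max(f * (1.0 - f), 0.0) / n))


def fresnel_reflectance(cos_i: float, n1: float, n2: float) -> float:
    """Unpolarized Fresnel power reflectance (1.0 beyond the critical angle)."""
    return float(_k.fresnel_unpolarized(float(cos_i), float(n1), float(n2)))


def launch(geometry: ProbeGeometry, tissue_n: float, rng: np.random.Generator,
           n: int = 1):
    """Sample ``n`` initial packet states for the source fiber.

    Positions are uniform over the fiber face at z = 0; directions uniform
    in solid angle within the cone of half-angle asin(NA / tissue_n); the
    initial weight is 1 minus the specular (normal-incidence) Fresnel loss
    at the probe-tissue interface.
    """
    cos_min = geometry.cone_cosine(tissue_n)
    r = geometry.source_radius * np.sqrt(rng.random(n))
    ang = 2.0 * np.pi * rng.random(n)
    pos = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])
    uz = 1.0 - rng.random(n) * (1.0 - cos_min)
    st = np.sqrt(np.clip(1.0 - uz ** 2, 0.0, None))
    phi = 2.0 * np.pi * rng.random(n)
    dirs = np.column_stack([st * np.cos(phi), st * np.sin(phi), uz])
    w0 = 1.0 - fresnel_reflectance(1.0, geometry.ambient_index, tissue_n)
    states = [PhotonState(position=pos[i], direction=dirs[i], weight=w0)
              for i in range(n)]
    return states[0] if n == 1 else states


def sample_step(mu_t: float, rng: np.random.Generator, size=None):
    """Exponential free path, ``-ln(xi) / mu_t`` with xi clamped away from 0."""
    if mu_t <= 0:
        raise ValueError("mu_t must be positive")
    u = np.clip(rng.random(size), 1e-12, 1.0 - 1e-16)
    return -np.log(1.0 - u) / mu_t


def scatter_hg(g: float, rng: np.random.Generator, size=None):
    """Henyey-Greenstein deflection cosine(s) with mean cosine ``g``."""
    if not -1.0 < g < 1.0:
        raise ValueError("g must lie in (-1, 1)")
    u = rng.random(size)
    if np.ndim(u) == 0:
        return float(_k.hg_cosine(g, float(u)))
    return np.array([_k.hg_cosine(g, float(v)) for v in np.ravel(u)]
                    ).reshape(np.shape(u))


def absorb_and_roulette(photon: PhotonState, albedo: float,
                        config: SimulationConfig,
                        rng: np.random.Generator) -> PhotonState:
    """One interaction: attenuate by the albedo, then unbiased roulette."""
    if not 0.0 <= albedo <= 1.0:
        raise ValueError("albedo must lie in [0, 1]")
    photon.weight *= albedo
    if photon.alive and photon.weight < config.roulette_threshold:
        if rng.random() < config.roulette_survival:
            photon.weight /= config.roulette_survival
        else:
            photon.weight = 0.0
            photon.alive = False
    return photon


def boundary_interaction(photon: PhotonState, n_tissue: float,
                         n_ambient: float, rng: np.random.Generator) -> str:
    """Fresnel decision at z = 0; returns ``"reflected"`` or
    ``"transmitted"`` and mirrors the z-direction on reflection."""
    cos_i = -photon.direction[2]
    if cos_i <= 0:
        raise ValueError("photon must be crossing z=0 upward")
    if rng.random() < fresnel_reflectance(cos_i, n_tissue, n_ambient):
        photon.direction[2] = -photon.direction[2]
        return "reflected"
    photon.alive = False
    return "transmitted"


def run_simulation(geometry: ProbeGeometry, props: OpticalProperties,
                   config: SimulationConfig) -> SimulationResult:
    """Transport ``config.n_photons`` packets and score all estimators.

    Weight is conserved exactly across the ledger buckets (specular,
    absorbed, detected, escaped, path-terminated, net roulette).  Identical
    seed and config reproduce the result bit-for-bit.
    """
    cos_cone = geometry.cone_cosine(props.n)
    voxel = config.voxel_size
    x_min, x_max = config.x_extent
    nx = int(np.ceil((x_max - x_min) / voxel))
    nz = int(np.ceil(config.z_extent / voxel))
    fl_nz = int(np.ceil(config.fluence_depth / config.fluence_bin))
    slab_half = (voxel / 2.0 if config.slab_half is None
                 else float(config.slab_half))
    det_cap = int(min(config.n_photons, 2_000_000))
    out = _k.propagate(
        np.uint32(config.seed % (2 ** 32)), int(config.n_photons),
        float(props.mu_a), float(props.mu_s), float(props.g),
        float(props.n), float(geometry.ambient_index),
        float(geometry.source_radius), float(geometry.detector_radius),
        float(geometry.separation), cos_cone, cos_cone,
        bool(config.track_map), nx, nz, float(voxel), float(x_min),
        slab_half, fl_nz, float(config.fluence_bin),
        float(config.fluence_radius),
        float(config.roulette_threshold), float(config.roulette_survival),
        float(config.max_path), det_cap, 400_000)
    (specular, absorbed, detected_w, escaped, terminated, roulette_net,
     n_det, dx, dy, dcos, dw, dlen, dzmax, svmap, fl_acc) = out

    detected = np.zeros(len(dx), dtype=DETECTED_PHOTON_DTYPE)
    detected["exit_x"] = dx
    detected["exit_y"] = dy
    detected["exit_cosine"] = dcos
    detected["weight"] = dw
    detected["path_length"] = dlen
    detected["max_depth"] = dzmax

    x_axis = x_min + (np.arange(nx) + 0.5) * voxel
    z_axis = (np.arange(nz) + 0.5) * voxel
    sv_empty = not (config.track_map and svmap.max() > 0)
    sv_values = svmap / svmap.max() if not sv_empty else svmap
    fl_z = (np.arange(fl_nz) + 0.5) * config.fluence_bin
    fl_empty = not fl_acc.max() > 0
    fl_values = fl_acc / fl_acc.max() if not fl_empty else fl_acc

    ledger = {
        "launched": float(config.n_photons),
        "specular": float(specular),
        "absorbed": float(absorbed),
        "detected": float(detected_w),
        "escaped": float(escaped),
        "terminated": float(terminated),
        "roulette_net": float(roulette_net),
    }
    return SimulationResult(
        detected_fraction=float(detected_w) / config.n_photons,
        detected=detected,
        n_detected=int(n_det),
        sampling_map=SamplingVolumeMap(x_axis, z_axis, sv_values, sv_empty),
        fluence=FluenceMap(fl_z, fl_values, fl_empty),
        ledger=ledger,
        config=config,
        geometry=geometry,
        properties=props,
    )


def sensing_depth(smap: SamplingVolumeMap, threshold: float = 1e-3) -> float:
    """Deepest voxel (cm) of the normalized sampling map >= ``threshold``."""
    if smap.empty:
        raise EmptyMapError("sampling map holds no detected photons")
    mask = smap.values >= threshold
    if not mask.any():
        raise EmptyMapError("no voxel reaches the requested threshold")
    return float(smap.z[np.nonzero(mask.any(axis=0))[0].max()])


def penetration_depth(fluence: FluenceMap, threshold: float = 1e-3) -> float:
    """Deepest bin (cm) where the normalized fluence >= ``threshold``."""
    if fluence.empty:
        raise EmptyMapError("fluence map holds no absorbed weight")
    mask = fluence.values >= threshold
    if not mask.any():
        raise EmptyMapError("no bin reaches the requested threshold")
    return float(fluence.z[np.nonzero(mask)[0].max()])


def save_result_h5(result: SimulationResult, path) -> None:
    """Write maps, detection records and the run configuration to HDF5."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("sampling_map/x", data=result.sampling_map.x)
        h5.create_dataset("sampling_map/z", data=result.sampling_map.z)
        h5.create_dataset("sampling_map/values",
                          data=result.sampling_map.values)
        h5.create_dataset("fluence/z", data=result.fluence.z)
        h5.create_dataset("fluence/values", data=result.fluence.values)
        h5.create_dataset("detected", data=result.detected)
        h5.attrs["detected_fraction"] = result.detected_fraction
        h5.attrs["n_detected"] = result.n_detected
        for k, v in result.ledger.items():
            h5.attrs[f"ledger_{k}"] = v
        for f in dataclasses.fields(result.config):
            val = getattr(result.config, f.name)
            if val is not None:
                h5.attrs[f"config_{f.name}"] = val
        for f in dataclasses.fields(result.geometry):
            h5.attrs[f"geometry_{f.name}"] = getattr(result.geometry, f.name)
        for name in ("mu_a", "mu_s", "g", "n", "wavelength"):
            h5.attrs[f"properties_{name}"] = getattr(result.properties, name)
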