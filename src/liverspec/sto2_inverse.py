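"""Model-based inversion of diffuse reflectance to tissue oxygen saturation.

The inverse problem is solved by regression: a training set of reflectance
spectra in the 675-825 nm fitting band is produced by the Monte Carlo
forward model over a Latin-hypercube of tissue parameters (saturation S as
the target; blood fraction and the two scattering power-law parameters as
nuisances), each spectrum is normalized by its band mean (removing the
unknown collection-efficiency scale), and a small feed-forward network maps
the normalized spectrum to S.  Estimates are clipped to [0, 1] and are
exactly invariant to multiplying the input spectrum by a positive constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc
from sklearn.neural_network import MLPRegressor

from .spectra_forward import Spectrum, default_forward

__all__ = [
    "FIT_BAND",
    "TrainingSet",
    "RegressorModel",
    "SaturationEstimate",
    "TrainingError",
    "build_training_set",
    "train_saturation_regressor",
    "estimate_saturation",
    "save_model",
    "load_model",
]

FIT_BAND = (675.0, 825.0)
DEFAULT_RANGES = {
    "S": (0.0, 1.0),
    "B": (0.01, 0.2),
    "a": (5.0, 25.0),
    "b": (0.5, 2.0),
}


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainingSet:
    """Normalized band spectra (rows) with saturation targets and nuisances."""

    wavelengths: np.ndarray
    spectra: np.ndarray
    targets: np.ndarray
    nuisance: np.ndarray        # columns: B, a, b
    normalization: str
    seed: int

    def __post_init__(self) -> None:
        lo, hi = FIT_BAND
        if np.any(self.wavelengths < lo) or np.any(self.wavelengths > hi):
            raise ValueError("training grid must lie inside the fitting band")
        if self.spectra.shape != (len(self.targets), len(self.wavelengths)):
            raise ValueError("spectra matrix shape mismatch")


@dataclass
class RegressorModel:
    """Trained saturation regressor with its input pipeline parameters."""

    wavelengths: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    hidden_layer_sizes: tuple
    activation: str
    normalization: str
    seed: int
    validation_rmse: float
    mlp: MLPRegressor = field(repr=False)


@dataclass
class SaturationEstimate:
    value: float
    clipped: bool = False
    out_of_manifold: bool = False

    def __float__(self) -> float:
        return float(self.value)


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=1, keepdims=True)
    safe = np.where(mean > 0, mean, 1.0)
    return mat / safe


def build_training_set(ranges=None, n_samples: int = 2000, forward=None,
                       seed: int = 0, noise_frac: float = 0.0,
                       noise_replicas: int = 1,
                       node_spacing: float = 10.0) -> TrainingSet:
    """Latin-hypercube sample of tissue parameters with forward spectra.

    Spectra are generated on the 10-nm node grid of the fitting band,
    mean-normalized, and optionally degraded with ``noise_frac`` relative
    Gaussian noise.  ``noise_replicas > 1`` repeats every parameter point
    with independent noise draws (augmentation that teaches the regressor
    the conditional mean under measurement noise).
    """
    from .tissue_optics import TissueComposition

    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    rng_ranges = dict(DEFAULT_RANGES)
    if ranges:
        rng_ranges.update(ranges)
    if forward is None:
        forward = default_forward()
    lam = np.arange(FIT_BAND[0], FIT_BAND[1] + node_spacing / 2, node_spacing)
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    unit = sampler.random(n_samples)
    lo = np.array([rng_ranges[k][0] for k in ("S", "B", "a", "b")])
    hi = np.array([rng_ranges[k][1] for k in ("S", "B", "a", "b")])
    params = lo + unit * (hi - lo)
    spectra = np.empty((n_samples, lam.size))
    for i, (S, B, a, b) in enumerate(params):
        comp = TissueComposition(blood_fraction=B, oxygen_saturation=S,
                                 water_fraction=0.7, scattering_amplitude=a,
                                 scattering_power=b)
        try:
            spectra[i] = forward.spectrum(comp, lam).values
        except Exception as exc:  # noqa: BLE001 - annotate the sample index
            raise TrainingError(f"forward model failed at sample {i}") from exc
    targets = params[:, 0]
    nuisance = params[:, 1:]
    if noise_replicas > 1:
        spectra = np.repeat(spectra, noise_replicas, axis=0)
        targets = np.repeat(targets, noise_replicas)
        nuisance = np.repeat(nuisance, noise_replicas, axis=0)
    if noise_frac > 0:
        noise_rng = np.random.default_rng(seed + 1)
        spectra = spectra * (1.0 + noise_frac
                             * noise_rng.standard_normal(spectra.shape))
    spectra = _normalize_rows(np.clip(spectra, 0.0, None))
    return TrainingSet(wavelengths=lam, spectra=spectra,
                       targets=targets, nuisance=nuisance,
                       normalization="band_mean", seed=seed)


def train_saturation_regressor(ts: TrainingSet, hidden_layer_sizes=(64, 64),
                               activation: str = "tanh", seed: int = 0,
                               validation_fraction: float = 0.2,
                               rmse_bound: float = 0.2,
                               **mlp_kwargs) -> RegressorModel:
    """Fit the feed-forward regressor; record held-out RMSE.

    Defaults use adam with early stopping (robust for noise-augmented
    sets); ``mlp_kwargs`` override any :class:`MLPRegressor` setting (for
    example ``solver="lbfgs"`` for tight fits to noiseless sets).  Raises
    :class:`TrainingError` when the held-out RMSE exceeds ``rmse_bound``.
    """
    if len(ts.targets) < 100:
        raise ValueError("default architecture needs >= 100 samples")
    rng = np.random.default_rng(seed)
    n = len(ts.targets)
    order = rng.permutation(n)
    n_val = max(1, int(round(validation_fraction * n)))
    val_idx = order[:n_val]
    tr_idx = order[n_val:]
    mean = ts.spectra[tr_idx].mean(axis=0)
    scale = ts.spectra[tr_idx].std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    X_tr = (ts.spectra[tr_idx] - mean) / scale
    X_val = (ts.spectra[val_idx] - mean) / scale
    kwargs = dict(solver="adam", alpha=1e-4, max_iter=600,
                  early_stopping=True, n_iter_no_change=20)
    kwargs.update(mlp_kwargs)
    if kwargs.get("solver") == "lbfgs":
        kwargs.pop("early_stopping", None)
        kwargs.pop("n_iter_no_change", None)
    mlp = MLPRegressor(hidden_layer_sizes=hidden_layer_sizes,
                       activation=activation,
                       random_state=int(seed) % (2 ** 32), **kwargs)
    mlp.fit(X_tr, ts.targets[tr_idx])
    pred = np.clip(mlp.predict(X_val), 0.0, 1.0)
    rmse = float(np.sqrt(np.mean((pred - ts.targets[val_idx]) ** 2)))
    if rmse > rmse_bound:
        raise TrainingError(
            f"validation RMSE {rmse:.3f} exceeds bound {rmse_bound}; "
            f"n_train={len(tr_idx)}, loss={mlp.loss_:.4g}")
    return RegressorModel(wavelengths=ts.wavelengths.copy(),
                          feature_mean=mean, feature_scale=scale,
                          hidden_layer_sizes=tuple(hidden_layer_sizes),
                          activation=activation,
                          normalization=ts.normalization, seed=seed,
                          validation_rmse=rmse, mlp=mlp)


def estimate_saturation(model: RegressorModel,
                        spectrum: Spectrum) -> SaturationEstimate:
    """Oxygen saturation from a reflectance spectrum covering 675-825 nm.

    The spectrum is interpolated to the model grid and band-mean normalized,
    so the estimate is invariant to any positive rescaling of the input.
    Out-of-manifold inputs (non-positive or constant band) are still
    evaluated but flagged.
    """
    w = spectrum.wavelengths
    if w[0] > FIT_BAND[0] or w[-1] < FIT_BAND[1]:
        raise ValueError(
            f"spectrum must cover the {FIT_BAND[0]:.0f}-{FIT_BAND[1]:.0f} nm "
            "fitting band")
    band = spectrum.interp(model.wavelengths)
    mean = band.mean()
    out_of_manifold = bool(mean <= 0 or np.ptp(band) == 0)
    norm = band / (mean if mean > 0 else 1.0)
    x = (norm - model.feature_mean) / model.feature_scale
    raw = float(model.mlp.predict(x[None, :])[0])
    value = min(1.0, max(0.0, raw))
    return SaturationEstimate(value=value, clipped=value != raw,
                              out_of_manifold=out_of_manifold)


def save_model(model: RegressorModel, path) -> None:
    """Serialize the regressor to one portable JSON file."""
    payload = {
        "wavelengths": model.wavelengths.tolist(),
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "hidden_layer_sizes": list(model.hidden_layer_sizes),
        "activation": model.activation,
        "normalization": model.normalization,
        "seed": model.seed,
        "validation_rmse": model.validation_rmse,
        "coefs": [c.tolist() for c in model.mlp.coefs_],
        "intercepts": [c.tolist() for c in model.mlp.intercepts_],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> RegressorModel:
    with open(path) as fh:
        payload = json.load(fh)
    hidden = tuple(payload["hidden_layer_sizes"])
    mlp = MLPRegressor(hidden_layer_sizes=hidden,
                       activation=payload["activation"], solver="lbfgs")
    coefs = [np.asarray(c) for c in payload["coefs"]]
    intercepts = [np.asarray(c) for c in payload["intercepts"]]
    # minimal fitted-state reconstruction for inference
    mlp.coefs_ = coefs
    mlp.intercepts_ = intercepts
    mlp.n_layers_ = len(coefs) + 1
    mlp.n_outputs_ = 1
    mlp.out_activation_ = "identity"
    mlp.n_features_in_ = coefs[0].shape[0]
    return RegressorModel(
        wavelengths=np.asarray(payload["wavelengths"]),
        feature_mean=np.asarray(payload["feature_mean"]),
        feature_scale=np.asarray(payload["feature_scale"]),
        hidden_layer_sizes=hidden, activation=payload["activation"],
        normalization=payload["normalization"], seed=payload["seed"],
        validation_rmse=payload["validation_rmse"], mlp=mlp)
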