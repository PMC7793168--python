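"""Structured sensor-noise simulation, epoch bookkeeping and covariance.

Resting-state sensor noise is emulated as a low-rank spatially mixed AR(1)
process plus a white sensor floor: background brain activity projects to the
sensors through a small number of smooth spatial patterns and is temporally
correlated, while instrumental noise is independent across sensors and time.
Epochs are split into an evoked-averaging pool and a held-out pool used for
noise-covariance estimation, mirroring standard evoked-response practice
(defaults: 135 epochs of 0.5 s at 1000 Hz; 49 averaged, 86 for covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import scipy.linalg

__all__ = [
    "NoiseModel",
    "EpochSet",
    "NoiseCovariance",
    "simulate_epochs",
    "split_epochs",
    "evoked_noise",
    "estimate_covariance",
    "default_noise_model",
    "read_epochs",
    "write_epochs",
]


@dataclass(frozen=True)
class NoiseModel:
    """Low-rank AR(1) + white-floor sensor noise model.

    spatial_mixing : (n_sensors, n_factors)
        Columns are spatial patterns of the correlated background factors.
    ar_coefficient : float in [0, 1)
        Lag-1 autocorrelation of each factor (stationary, unit variance).
    sensor_floor : float
        Variance of the white per-sensor noise floor.
    sampling_rate : float, Hz
    """

    spatial_mixing: np.ndarray
    ar_coefficient: float = 0.95
    sensor_floor: float = 1.0
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        mix = np.atleast_2d(np.asarray(self.spatial_mixing, dtype=float))
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.sensor_floor < 0:
            raise ValueError("sensor_floor must be non-negative")
        if self.sensor_floor == 0 and mix.shape[1] < mix.shape[0]:
            raise ValueError("implied covariance not positive definite")
        object.__setattr__(self, "spatial_mixing", mix)

    @property
    def n_sensors(self) -> int:
        return self.spatial_mixing.shape[0]

    def covariance(self) -> np.ndarray:
        """Model-implied stationary sensor covariance."""
        mix = self.spatial_mixing
        return mix @ mix.T + self.sensor_floor * np.eye(self.n_sensors)


@dataclass(frozen=True)
class EpochSet:
    """A stack of equal-length sensor-noise epochs."""

    epochs: np.ndarray  # (n_epochs, n_sensors, n_times)
    epoch_duration: float
    sampling_rate: float

    def __post_init__(self) -> None:
        e = np.asarray(self.epochs, dtype=float)
        if e.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_sensors, n_times)")
        n_expected = round(self.epoch_duration * self.sampling_rate)
        if e.shape[2] != n_expected:
            raise ValueError(
                f"n_times {e.shape[2]} != duration*rate = {n_expected}"
            )
        if not np.all(np.isfinite(e)):
            raise ValueError("epochs must be finite")
        object.__setattr__(self, "epochs", e)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[2]


@dataclass(frozen=True)
class NoiseCovariance:
    """Symmetric positive-definite sensor covariance with diagonal loading."""

    C: np.ndarray
    n_epochs_used: int = 0
    loading: float = 0.0

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        if not np.allclose(C, C.T, atol=1e-12 * max(1.0, np.abs(C).max())):
            raise ValueError("C must be symmetric")
        try:
            scipy.linalg.cholesky(C, lower=True)
        except scipy.linalg.LinAlgError as err:
            raise ValueError("C must be positive definite") from err
        object.__setattr__(self, "C", 0.5 * (C + C.T))

    @property
    def n_sensors(self) -> int:
        return self.C.shape[0]

    def inv_sqrt(self) -> np.ndarray:
        """Symmetric inverse square root C^(-1/2), used for whitening."""
        w, V = scipy.linalg.eigh(self.C)
        return (V / np.sqrt(w)) @ V.T


def default_noise_model(
    n_sensors: int,
    n_factors: int = 8,
    scale: float = 1.0,
    ar_coefficient: float = 0.95,
    floor_fraction: float = 0.1,
    seed: int = 0,
) -> NoiseModel:
    """Random smooth mixing patterns with a white floor.

    ``scale`` sets the RMS amplitude of the factor contribution per sensor;
    the white floor variance is ``floor_fraction * scale**2``.
    """
    rng = np.random.default_rng(seed)
    mix = rng.standard_normal((n_sensors, n_factors))
    mix *= scale / np.sqrt(n_factors)
    return NoiseModel(
        spatial_mixing=mix,
        ar_coefficient=ar_coefficient,
        sensor_floor=floor_fraction * scale**2,
    )


def simulate_epochs(
    model: NoiseModel, n_epochs: int = 135, duration: float = 0.5, seed: int = 0
) -> EpochSet:
    """Draw mutually independent noise epochs from the model.

    Each factor follows a stationary unit-variance AR(1):
    z_t = a z_{t-1} + sqrt(1-a^2) e_t, so the marginal variance is 1 and the
    lag-1 autocorrelation equals ``a`` regardless of ``a``.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    n_times = round(duration * model.sampling_rate)
    n_factors = model.spatial_mixing.shape[1]
    a = model.ar_coefficient

    eps = rng.standard_normal((n_epochs, n_factors, n_times))
    z = np.empty_like(eps)
    z[..., 0] = eps[..., 0]
    innov = np.sqrt(1.0 - a * a)
    for t in range(1, n_times):
        z[..., t] = a * z[..., t - 1] + innov * eps[..., t]

    epochs = np.einsum("sf,eft->est", model.spatial_mixing, z)
    if model.sensor_floor > 0:
        epochs += np.sqrt(model.sensor_floor) * rng.standard_normal(
            (n_epochs, model.n_sensors, n_times)
        )
    return EpochSet(
        epochs=epochs, epoch_duration=duration, sampling_rate=model.sampling_rate
    )


def split_epochs(
    epoch_set: EpochSet, n_evoked: int = 49, seed: int = 0
) -> tuple[EpochSet, EpochSet]:
    """Randomly partition epochs into an evoked pool and a covariance pool."""
    if n_evoked >= epoch_set.n_epochs:
        raise ValueError("n_evoked must be smaller than the number of epochs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(epoch_set.n_epochs, size=n_evoked, replace=False)
    mask = np.zeros(epoch_set.n_epochs, dtype=bool)
    mask[idx] = True
    mk = lambda e: EpochSet(
        epochs=e,
        epoch_duration=epoch_set.epoch_duration,
        sampling_rate=epoch_set.sampling_rate,
    )
    return mk(epoch_set.epochs[mask]), mk(epoch_set.epochs[~mask])


def evoked_noise(
    evoked_pool: EpochSet, n_times: int = 100, seed: int = 0
) -> np.ndarray:
    """Average of one random contiguous window per pool epoch.

    Emulates the residual noise of an evoked average: the variance of the
    result shrinks like 1/n_epochs relative to a single epoch.
    """
    if n_times > evoked_pool.n_times:
        raise ValueError("window longer than epoch")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, evoked_pool.n_times - n_times + 1, evoked_pool.n_epochs)
    acc = np.zeros((evoked_pool.n_sensors, n_times))
    for e, s in enumerate(starts):
        acc += evoked_pool.epochs[e, :, s : s + n_times]
    return acc / evoked_pool.n_epochs


def estimate_covariance(pool: EpochSet, loading: float = 0.05) -> NoiseCovariance:
    """Sample covariance pooled over epochs and time, with diagonal loading.

    The per-epoch, per-sensor temporal mean is removed before pooling.
    Loading adds ``loading * mean(diag)`` to the diagonal, guaranteeing a
    positive-definite matrix suitable for whitening and inversion.
    """
    if pool.n_epochs < 2:
        raise ValueError("need at least 2 epochs to estimate covariance")
    demeaned = pool.epochs - pool.epochs.mean(axis=2, keepdims=True)
    flat = demeaned.transpose(1, 0, 2).reshape(pool.n_sensors, -1)
    n_samples = flat.shape[1]
    C = flat @ flat.T / n_samples
    if loading > 0:
        C = C + loading * np.mean(np.diag(C)) * np.eye(pool.n_sensors)
    return NoiseCovariance(C=C, n_epochs_used=pool.n_epochs, loading=loading)


def write_epochs(path, epoch_set: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("epochs", data=epoch_set.epochs)
        d.attrs["epoch_duration"] = epoch_set.epoch_duration
        d.attrs["sampling_rate"] = epoch_set.sampling_rate


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        d = f["epochs"]
        return EpochSet(
            epochs=d[()],
            epoch_duration=float(d.attrs["epoch_duration"]),
            sampling_rate=float(d.attrs["sampling_rate"]),
        )
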