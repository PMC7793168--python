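"""Free-space dipole forward model and gain-matrix I/O.

The gain matrix maps unit-amplitude dipole moments to sensor readings.
Magnetic channels use the closed-form free-space field of a current dipole
(volume currents neglected); "eeg-like" channels use the electric potential
of a dipole in an unbounded homogeneous medium.  This is a deliberate
simplification of realistic boundary-element conductor models: the fidelity
framework downstream is agnostic to forward-model realism, but absolute
field patterns here should not be compared against real head models.
"""

from __future__ import annotations

from dataclasses import dataclass

import json

import h5py
import numpy as np

__all__ = [
    "SensorArray",
    "GainMatrix",
    "SingularGeometryError",
    "dipole_field",
    "dipole_potential",
    "build_gain",
    "build_helmet_array",
    "read_gain",
    "write_gain",
]

MU0_OVER_4PI = 1e-7  # T·m/A
SIGMA = 0.33  # S/m, conductivity of the homogeneous medium for eeg-like rows
GRADIOMETER_BASELINE = 0.0168  # m, planar-gradiometer pickup-loop separation

MODALITIES = ("mag", "grad", "eeg")


class SingularGeometryError(ValueError):
    """Sensor coincides with a source location."""


@dataclass(frozen=True)
class SensorArray:
    """Sensor positions, measurement axes and modality labels."""

    positions: np.ndarray
    orientations: np.ndarray
    modality: np.ndarray  # array of str labels from MODALITIES

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        mod = np.asarray(self.modality, dtype=object)
        if pos.ndim != 2 or pos.shape[1] != 3 or ori.shape != pos.shape:
            raise ValueError("positions/orientations must be matching (n, 3)")
        if mod.shape != (pos.shape[0],):
            raise ValueError("one modality label per sensor required")
        if not set(mod) <= set(MODALITIES):
            raise ValueError(f"modality labels must be from {MODALITIES}")
        if not np.allclose(np.linalg.norm(ori, axis=1), 1.0, atol=1e-9):
            raise ValueError("sensor orientations must have unit norm")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "modality", np.asarray(mod, dtype="U8"))

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    def modality_sets(self) -> dict[str, np.ndarray]:
        """Row-index sets of the modalities present, in canonical order."""
        return {
            m: np.flatnonzero(self.modality == m)
            for m in MODALITIES
            if np.any(self.modality == m)
        }


@dataclass(frozen=True)
class GainMatrix:
    """Sensors x sources forward operator with per-row modality labels."""

    values: np.ndarray
    modality_of_row: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        mod = np.asarray(self.modality_of_row, dtype="U8")
        if v.ndim != 2:
            raise ValueError("gain must be 2-D")
        if mod.shape != (v.shape[0],):
            raise ValueError("one modality label per row required")
        if not np.all(np.isfinite(v)):
            raise ValueError("gain entries must be finite")
        colmax = np.abs(v).max(axis=0)
        if np.any(colmax <= 1e-30 * colmax.max()):
            raise ValueError("gain has an (effectively) all-zero column")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "modality_of_row", mod)

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_sources(self) -> int:
        return self.values.shape[1]

    def modality_sets(self) -> dict[str, np.ndarray]:
        return {
            m: np.flatnonzero(self.modality_of_row == m)
            for m in MODALITIES
            if np.any(self.modality_of_row == m)
        }


def dipole_field(source_pos, moment, sensor_pos) -> np.ndarray:
    """Free-space magnetic field of a current dipole, in tesla.

    B = (mu0 / 4 pi) (q x d) / |d|^3  with  d = sensor - source.
    """
    d = np.asarray(sensor_pos, float) - np.asarray(source_pos, float)
    r = np.linalg.norm(d)
    if r == 0:
        raise SingularGeometryError("sensor coincides with source")
    return MU0_OVER_4PI * np.cross(np.asarray(moment, float), d) / r**3


def dipole_potential(source_pos, moment, sensor_pos) -> float:
    """Electric potential of a current dipole in an infinite homogeneous medium."""
    d = np.asarray(sensor_pos, float) - np.asarray(source_pos, float)
    r = np.linalg.norm(d)
    if r == 0:
        raise SingularGeometryError("sensor coincides with source")
    return float(np.dot(np.asarray(moment, float), d) / (4.0 * np.pi * SIGMA * r**3))


def _tangential_axis(orientation: np.ndarray) -> np.ndarray:
    """Deterministic unit vector orthogonal to the sensor axis."""
    o = orientation
    ref = np.array([0.0, 0.0, 1.0]) if abs(o[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t = np.cross(o, ref)
    return t / np.linalg.norm(t)


def build_gain(space, sensors: SensorArray) -> GainMatrix:
    """Assemble the gain matrix for unit-amplitude (1 A·m) dipoles.

    mag rows: field projected on the sensor axis.  grad rows: difference of
    the projected field at +/- half the gradiometer baseline along a
    deterministic tangential axis, divided by the baseline (T/m).  eeg rows:
    unbounded-medium potential (volts); the sensor axis is ignored.
    """
    src = space.positions
    ori = space.orientations
    n_sens, n_src = sensors.n_sensors, src.shape[0]

    # vectorized field of all sources at a set of points, projected on axes
    def projected_field(points, axes):
        d = points[:, None, :] - src[None, :, :]  # (n_pts, n_src, 3)
        r3 = np.linalg.norm(d, axis=2) ** 3
        if np.any(r3 == 0):
            raise SingularGeometryError("sensor coincides with source")
        b = MU0_OVER_4PI * np.cross(ori[None, :, :], d) / r3[..., None]
        return np.einsum("psk,pk->ps", b, axes)

    G = np.zeros((n_sens, n_src))
    for m, rows in sensors.modality_sets().items():
        pos = sensors.positions[rows]
        ax = sensors.orientations[rows]
        if m == "mag":
            G[rows] = projected_field(pos, ax)
        elif m == "grad":
            tang = np.array([_tangential_axis(a) for a in ax])
            half = 0.5 * GRADIOMETER_BASELINE
            gp = projected_field(pos + half * tang, ax)
            gm = projected_field(pos - half * tang, ax)
            G[rows] = (gp - gm) / GRADIOMETER_BASELINE
        else:  # eeg
            d = pos[:, None, :] - src[None, :, :]
            r3 = np.linalg.norm(d, axis=2) ** 3
            if np.any(r3 == 0):
                raise SingularGeometryError("sensor coincides with source")
            G[rows] = np.einsum("psk,sk->ps", d, ori) / (4.0 * np.pi * SIGMA * r3)

    return GainMatrix(values=G, modality_of_row=sensors.modality)


def build_helmet_array(
    n_sensors: int,
    radius: float = 0.12,
    modality: str | list = "mag",
    seed: int = 0,
) -> SensorArray:
    """Quasi-uniform spherical sensor array with radial measurement axes.

    ``modality`` may be a single label applied to all sensors or a per-sensor
    list.  Sensor axes are tilted slightly off-radial (seeded) so that purely
    radial field components are not the only ones sampled.
    """
    from .geometry import _fibonacci_directions  # same lattice as sources

    u = _fibonacci_directions(n_sensors)
    rng = np.random.default_rng(seed)
    tilt = rng.standard_normal(u.shape) * 0.1
    tilt -= np.sum(tilt * u, axis=1, keepdims=True) * u
    axes = u + tilt
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    if isinstance(modality, str):
        mod = np.full(n_sensors, modality, dtype="U8")
    else:
        mod = np.asarray(modality, dtype="U8")
    return SensorArray(positions=radius * u, orientations=axes, modality=mod)


# ---------------------------------------------------------------------------
# I/O: delimited text + JSON sidecar of modality labels, or one HDF5 file.


def write_gain(gain: GainMatrix, path) -> None:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("gain", data=gain.values)
            f.create_dataset(
                "modality", data=np.asarray(gain.modality_of_row, dtype="S8")
            )
    else:
        np.savetxt(path, gain.values, delimiter="\t", fmt="%.17g")
        with open(path + ".json", "w") as f:
            json.dump({"modality": list(gain.modality_of_row)}, f)


def read_gain(path, n_sources: int | None = None) -> GainMatrix:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            values = f["gain"][()]
            modality = f["modality"][()].astype("U8")
    else:
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
        with open(path + ".json") as f:
            modality = np.asarray(json.load(f)["modality"], dtype="U8")
    if n_sources is not None and values.shape[1] != n_sources:
        raise ValueError(
            f"gain has {values.shape[1]} columns, expected {n_sources} sources"
        )
    return GainMatrix(values=values, modality_of_row=modality)
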