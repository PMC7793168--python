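"""Synthetic source spaces and disjoint patch parcellations.

A source space is a set of current dipoles sitting on a (possibly radially
perturbed) sphere.  The unperturbed sphere plays the role of an inflated
cortical surface: patch centres-of-gravity are computed there, so that a
smooth one-to-one "inflation" always exists by construction.

Dipoles are placed on a deterministic spherical Fibonacci lattice with a
small seeded tangential jitter, which gives near-uniform point density and
hence near-uniform patch areas when the sphere is tiled into patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SourceSpace",
    "Parcellation",
    "build_sphere_source_space",
    "parcellate",
    "patch_center",
    "read_source_space",
    "write_source_space",
]

# Tangential jitter of lattice points, as a fraction of the mean lattice
# spacing.  Kept below 0.25 so that each jittered point remains strictly
# closest to its own unjittered lattice direction (min lattice separation
# is ~0.85x the mean spacing), which makes n_patches == n_sources
# parcellations exactly one dipole per patch.
_JITTER_FRACTION = 0.2
# Additional jitter applied to parcellation seed directions.
_SEED_JITTER_FRACTION = 0.04


@dataclass(frozen=True)
class SourceSpace:
    """Dipole positions/orientations plus their reference-sphere projections.

    Attributes
    ----------
    positions : (n, 3) float array
        Dipole locations in metres.
    orientations : (n, 3) float array
        Unit dipole orientations (outward surface normals).
    surface_positions : (n, 3) float array
        Projections onto the unperturbed reference sphere, used as the
        "inflated" surface for centre-of-gravity computations.
    """

    positions: np.ndarray
    orientations: np.ndarray
    surface_positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        sph = np.asarray(self.surface_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if ori.shape != pos.shape or sph.shape != pos.shape:
            raise ValueError("orientations/surface_positions must match positions")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must have unit norm")
        radii = np.linalg.norm(sph, axis=1)
        if radii.size and not np.allclose(radii, radii[0], rtol=1e-6):
            raise ValueError("surface_positions must lie on a common sphere")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "surface_positions", sph)

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class Parcellation:
    """Disjoint, exhaustive grouping of dipoles into patches."""

    patch_of_source: np.ndarray
    n_patches: int = field(default=0)

    def __post_init__(self) -> None:
        lab = np.asarray(self.patch_of_source, dtype=int)
        if lab.ndim != 1:
            raise ValueError("patch_of_source must be 1-D")
        n = int(lab.max()) + 1 if lab.size else 0
        if np.any(lab < 0):
            raise ValueError("patch labels must be non-negative")
        if self.n_patches == 0:
            object.__setattr__(self, "n_patches", n)
        elif self.n_patches < n:
            raise ValueError("n_patches smaller than largest label + 1")
        present = np.unique(lab)
        if present.size != self.n_patches:
            raise ValueError("every patch must be non-empty")
        object.__setattr__(self, "patch_of_source", lab)

    @property
    def patches(self) -> list[np.ndarray]:
        """Dipole index sets, one per patch, each sorted ascending."""
        order = np.argsort(self.patch_of_source, kind="stable")
        bounds = np.searchsorted(
            self.patch_of_source[order], np.arange(self.n_patches + 1)
        )
        return [order[bounds[i] : bounds[i + 1]] for i in range(self.n_patches)]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.patch_of_source, minlength=self.n_patches)


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors via the spherical Fibonacci lattice."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _jitter_directions(
    u: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Displace unit vectors tangentially by ``fraction`` x mean spacing."""
    n = u.shape[0]
    spacing = np.sqrt(4.0 * np.pi / n)  # mean angular spacing, radians
    step = rng.standard_normal(u.shape)
    step -= (np.sum(step * u, axis=1, keepdims=True)) * u  # tangential part
    norm = np.linalg.norm(step, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    mag = fraction * spacing * rng.random((n, 1))
    out = u + step / norm * mag
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _bump_field(u: np.ndarray, rng: np.random.Generator, n_bumps: int = 12):
    """Smooth random field on the unit sphere and its tangential gradient.

    The field is a sum of wide Gaussian bumps, scaled to max |f| = 1 so that
    a bumpiness b perturbs radii by at most a factor (1 +/- b).
    """
    centers = rng.standard_normal((n_bumps, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    amps = rng.uniform(-1.0, 1.0, n_bumps)
    width = 0.5  # angular width parameter of each bump

    dots = u @ centers.T  # (n, n_bumps)
    g = np.exp((dots - 1.0) / width)
    f = g @ amps
    # ambient gradient of f: sum_j amps_j/width * g_j * c_j
    grad = (g * (amps / width)) @ centers
    # tangential projection
    grad -= np.sum(grad * u, axis=1, keepdims=True) * u
    scale = np.max(np.abs(f))
    if scale > 0:
        f = f / scale
        grad = grad / scale
    return f, grad


def build_sphere_source_space(
    n_sources: int,
    radius: float = 0.08,
    bumpiness: float = 0.1,
    seed: int = 0,
) -> SourceSpace:
    """Generate a quasi-uniform source space on a radially perturbed sphere.

    Parameters
    ----------
    n_sources : int
        Number of dipoles (>= 4).
    radius : float
        Reference sphere radius in metres.
    bumpiness : float
        Relative amplitude of the smooth radial perturbation, in [0, 0.5).
        With ``bumpiness=0`` the surface is a perfect sphere and all
        orientations are radial; radial dipoles are magnetically silent in
        spherically symmetric conductor models, so a nonzero default keeps
        every source magnetically visible.
    seed : int
        Seeds the lattice jitter and the perturbation field.

    Returns
    -------
    SourceSpace
        ``surface_positions`` are the unperturbed spherical projections;
        ``orientations`` are outward normals of the perturbed surface.
    """
    if n_sources < 4:
        raise ValueError("n_sources must be >= 4")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0.0 <= bumpiness < 0.5:
        raise ValueError("bumpiness must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    u = _jitter_directions(_fibonacci_directions(n_sources), _JITTER_FRACTION, rng)

    if bumpiness > 0:
        f, grad = _bump_field(u, rng)
        rho = radius * (1.0 + bumpiness * f)
        # normal of the radial graph r = rho(u):  u - grad_surf(rho)/rho
        normals = u - (radius * bumpiness / rho)[:, None] * grad
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    else:
        rho = np.full(n_sources, radius)
        normals = u.copy()

    return SourceSpace(
        positions=rho[:, None] * u,
        orientations=normals,
        surface_positions=radius * u,
    )


def parcellate(
    space: SourceSpace,
    n_patches: int,
    seed: int = 0,
    min_size: int = 4,
) -> Parcellation:
    """Tile the source space into disjoint patches.

    Each dipole is assigned to the nearest of ``n_patches`` quasi-uniform
    seed directions on the reference sphere (ties broken by lowest patch
    index).  Empty patches are dropped and the labels compacted.  Patches
    smaller than ``min_size`` are grown by pulling in the nearest dipoles
    from larger neighbours, emulating the 4-to-65-dipole patch-size range
    of atlas-based cortical parcellations.  When ``n_patches`` equals the
    number of dipoles, ``min_size`` growth is skipped and every patch is a
    singleton.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if n_patches > space.n_sources:
        raise ValueError("n_patches cannot exceed n_sources")

    rng = np.random.default_rng(seed)
    seeds = _jitter_directions(
        _fibonacci_directions(n_patches), _SEED_JITTER_FRACTION, rng
    )
    u = space.surface_positions / np.linalg.norm(
        space.surface_positions, axis=1, keepdims=True
    )
    # nearest seed by max dot product; argmax returns the lowest index on ties
    labels = np.argmax(u @ seeds.T, axis=1)

    # drop empty seeds, compact labels
    present = np.unique(labels)
    remap = np.full(n_patches, -1, dtype=int)
    remap[present] = np.arange(present.size)
    labels = remap[labels]
    n_eff = present.size

    if n_patches < space.n_sources and min_size > 1:
        labels = _rebalance(labels, u, n_eff, min_size)

    return Parcellation(patch_of_source=labels)


def _rebalance(
    labels: np.ndarray, u: np.ndarray, n_patches: int, min_size: int
) -> np.ndarray:
    """Grow under-sized patches by stealing nearest dipoles from larger ones."""
    labels = labels.copy()
    # patch direction = normalized mean of member directions
    for _ in range(n_patches):  # bounded number of passes
        sizes = np.bincount(labels, minlength=n_patches)
        small = np.flatnonzero(sizes < min_size)
        if small.size == 0:
            break
        p = small[0]
        members = labels == p
        center = u[members].mean(axis=0)
        center /= np.linalg.norm(center)
        # candidates: dipoles of patches that can afford to lose one
        donor_ok = sizes[labels] > min_size
        donor_ok &= ~members
        cand = np.flatnonzero(donor_ok)
        if cand.size == 0:
            break
        best = cand[np.argmax(u[cand] @ center)]
        labels[best] = p
    return labels


def patch_center(patch: np.ndarray, space: SourceSpace) -> int:
    """Dipole closest to the patch centre of gravity on the reference sphere.

    Ties are broken by lowest dipole index.
    """
    patch = np.asarray(patch, dtype=int)
    if patch.size == 0:
        raise ValueError("patch must be non-empty")
    patch = np.sort(patch)
    cg = space.surface_positions[patch].mean(axis=0)
    d = np.linalg.norm(space.surface_positions[patch] - cg, axis=1)
    return int(patch[np.argmin(d)])


# ---------------------------------------------------------------------------
# TSV interchange: one row per dipole, columns
#   x y z nx ny nz sx sy sz patch
# (metres, unit normals, reference-sphere coordinates, 0-based patch id)

_TSV_COLUMNS = ["x", "y", "z", "nx", "ny", "nz", "sx", "sy", "sz", "patch"]


def write_source_space(
    path, space: SourceSpace, parcellation: Parcellation
) -> None:
    df = pd.DataFrame(
        np.column_stack(
            [space.positions, space.orientations, space.surface_positions]
        ),
        columns=_TSV_COLUMNS[:-1],
    )
    df["patch"] = parcellation.patch_of_source
    # repr-roundtrip float formatting keeps the file bit-exact on re-read
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_source_space(path) -> tuple[SourceSpace, Parcellation]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != _TSV_COLUMNS:
        raise ValueError(
            f"source-space TSV must have columns {_TSV_COLUMNS}, got {list(df.columns)}"
        )
    space = SourceSpace(
        positions=df[["x", "y", "z"]].to_numpy(),
        orientations=df[["nx", "ny", "nz"]].to_numpy(),
        surface_positions=df[["sx", "sy", "sz"]].to_numpy(),
    )
    parc = Parcellation(patch_of_source=df["patch"].to_numpy(dtype=int))
    return space, parc
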