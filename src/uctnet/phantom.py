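"""Parametric head phantoms for transcranial ultrasound simulation.

The phantom is a closed high-velocity "skull" shell (an elliptical ring in 2D,
an ellipsoidal shell in 3D) surrounding a homogeneous soft-tissue interior,
immersed in water. A blood clot is modelled as a uniform-velocity disc (2D) or
sphere (3D) placed randomly inside the tissue. Sensors sit in the water
coupling layer just outside the skull, either on a single ring (2D) or on
stacked rings (3D).

Geometry conventions
--------------------
Cells are indexed from 0; the physical position of cell ``i`` along an axis is
``(i + 0.5) * spacing`` mm. A cell belongs to a shape iff its *center* lies
inside the shape — integer geometry, no anti-aliasing, fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Region",
    "PhantomSpec",
    "ClotSpec",
    "HeadPhantom",
    "SensorArray",
    "make_head_phantom",
    "sample_clot",
    "embed_clot",
    "place_sensors",
    "export_velocity_grid",
    "scaled_2d_spec",
    "lab_phantom_spec",
]


class Region(IntEnum):
    """Cell labels of the phantom partition."""

    WATER = 0
    SKULL = 1
    TISSUE = 2
    CLOT = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the layered head phantom.

    Velocities default to water 1480, tissue 1540, skull 2618 m/s (the skull
    value is the measured acoustic velocity of the cured-resin shell used in
    the physical phantom). Densities default to water 1000, tissue 1040,
    skull 1900 kg/m^3; they are only exercised by the variable-density solver.
    """

    dimensionality: int = 2
    grid_shape: Tuple[int, ...] = (250, 250)
    grid_spacing: float = 1.0  # mm, isotropic
    skull_outer_semi_axes: Tuple[float, ...] = (100.0, 85.0)
    skull_thickness: float = 6.0  # mm
    velocity_water: float = 1480.0  # m/s
    velocity_skull: float = 2618.0
    velocity_tissue: float = 1540.0
    density_water: float = 1000.0  # kg/m^3
    density_skull: float = 1900.0
    density_tissue: float = 1040.0

    def __post_init__(self) -> None:
        d = self.dimensionality
        if d not in (2, 3):
            raise ValueError(f"dimensionality must be 2 or 3, got {d}")
        if len(self.grid_shape) != d or len(self.skull_outer_semi_axes) != d:
            raise ValueError("grid_shape and skull_outer_semi_axes must match dimensionality")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.skull_thickness <= 0:
            raise ValueError("skull_thickness must be positive")
        if self.skull_thickness >= min(self.skull_outer_semi_axes):
            raise ValueError("skull_thickness must be smaller than the smallest semi-axis")
        for v in (self.velocity_water, self.velocity_skull, self.velocity_tissue):
            if v <= 0:
                raise ValueError("velocities must be positive")
        for rho in (self.density_water, self.density_skull, self.density_tissue):
            if rho <= 0:
                raise ValueError("densities must be positive")
        # shell fully inside the grid with >= 2 cells margin
        for n, a in zip(self.grid_shape, self.skull_outer_semi_axes):
            if a + 2.0 * self.grid_spacing > n * self.grid_spacing / 2.0:
                raise ValueError(
                    "skull shell does not fit inside the grid with a 2-cell margin"
                )

    @property
    def extent_mm(self) -> Tuple[float, ...]:
        return tuple(n * self.grid_spacing for n in self.grid_shape)

    @property
    def center_mm(self) -> Tuple[float, ...]:
        return tuple(e / 2.0 for e in self.extent_mm)


@dataclass(frozen=True)
class ClotSpec:
    """A uniform-velocity spherical (3D) / circular (2D) clot."""

    center: Tuple[float, ...]  # mm
    radius: float  # mm
    velocity: float = 1700.0  # m/s

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class HeadPhantom:
    """Velocity/density/label grids plus grid-spacing metadata."""

    velocity: np.ndarray  # m/s, float64
    density: np.ndarray  # kg/m^3
    labels: np.ndarray  # Region values, uint8
    spacing: float  # mm
    spec: Optional[PhantomSpec] = None
    clot: Optional[ClotSpec] = None

    def __post_init__(self) -> None:
        if not (self.velocity.shape == self.density.shape == self.labels.shape):
            raise ValueError("velocity, density and label grids must share a shape")
        if np.any(self.velocity <= 0) or np.any(self.density <= 0):
            raise ValueError("velocity and density must be strictly positive everywhere")

    @property
    def ndim(self) -> int:
        return self.velocity.ndim

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.velocity.shape

    def copy(self) -> "HeadPhantom":
        return HeadPhantom(
            velocity=self.velocity.copy(),
            density=self.density.copy(),
            labels=self.labels.copy(),
            spacing=self.spacing,
            spec=self.spec,
            clot=self.clot,
        )


@dataclass(frozen=True)
class SensorArray:
    """Transducer positions in mm, all inside the water coupling region."""

    positions: np.ndarray  # (count, ndim) mm
    layout: str = "ring"  # "ring" | "layered-rings"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2:
            raise ValueError("positions must be (count, ndim)")
        uniq = np.unique(pos, axis=0)
        if uniq.shape[0] != pos.shape[0]:
            raise ValueError("sensor positions must be pairwise distinct")

    @property
    def count(self) -> int:
        return int(self.positions.shape[0])

    def cell_indices(self, spacing: float) -> np.ndarray:
        """Nearest-cell index of every sensor (center-of-cell convention)."""
        return np.floor(self.positions / spacing).astype(np.int64)


def _cell_centers(shape: Sequence[int], spacing: float) -> list:
    return [(np.arange(n) + 0.5) * spacing for n in shape]


def _ellipse_mask(
    shape: Sequence[int], spacing: float, center: Sequence[float], semi_axes: Sequence[float]
) -> np.ndarray:
    axes = _cell_centers(shape, spacing)
    q = np.zeros(tuple(shape))
    for k, ax in enumerate(axes):
        sl = [None] * len(shape)
        sl[k] = slice(None)
        q = q + (((ax - center[k]) / semi_axes[k]) ** 2)[tuple(sl)]
    return q <= 1.0


def make_head_phantom(spec: PhantomSpec) -> HeadPhantom:
    """Build the clot-free layered phantom from its spec.

    The skull shell is the set difference of two concentric ellipses
    (ellipsoids) whose semi-axes differ by ``skull_thickness``; the interior
    is tissue, the exterior water.
    """
    center = spec.center_mm
    outer = _ellipse_mask(spec.grid_shape, spec.grid_spacing, center, spec.skull_outer_semi_axes)
    inner_axes = tuple(a - spec.skull_thickness for a in spec.skull_outer_semi_axes)
    inner = _ellipse_mask(spec.grid_shape, spec.grid_spacing, center, inner_axes)

    labels = np.full(spec.grid_shape, Region.WATER, dtype=np.uint8)
    labels[outer & ~inner] = Region.SKULL
    labels[inner] = Region.TISSUE

    velocity = np.full(spec.grid_shape, spec.velocity_water, dtype=np.float64)
    velocity[labels == Region.SKULL] = spec.velocity_skull
    velocity[labels == Region.TISSUE] = spec.velocity_tissue

    density = np.full(spec.grid_shape, spec.density_water, dtype=np.float64)
    density[labels == Region.SKULL] = spec.density_skull
    density[labels == Region.TISSUE] = spec.density_tissue

    return HeadPhantom(
        velocity=velocity, density=density, labels=labels, spacing=spec.grid_spacing, spec=spec
    )


def _clot_cells(
    phantom: HeadPhantom, center: Sequence[float], radius: float
) -> np.ndarray:
    """Boolean mask of cells whose center lies within the clot."""
    axes = _cell_centers(phantom.shape, phantom.spacing)
    q = np.zeros(phantom.shape)
    for k, ax in enumerate(axes):
        sl = [None] * phantom.ndim
        sl[k] = slice(None)
        q = q + (((ax - center[k]) ** 2))[tuple(sl)]
    return q <= radius**2


def sample_clot(
    phantom: HeadPhantom,
    radius_range: Tuple[float, float] = (9.0, 15.0),
    clot_velocity: float = 1700.0,
    seed: int = 0,
    max_rejections: int = 10_000,
) -> ClotSpec:
    """Draw a random clot that fits entirely inside the tissue region.

    Radius ~ Uniform(r_min, r_max); the center is uniform over the set of
    continuous positions for which every rasterized clot cell is tissue
    (rejection sampling over the tissue bounding box). Deterministic under
    ``seed``.
    """
    r_min, r_max = radius_range
    if not (0 < r_min <= r_max):
        raise ValueError("radius_range must satisfy 0 < r_min <= r_max")
    tissue = phantom.labels == np.uint8(Region.TISSUE)
    if not tissue.any():
        raise ValueError("phantom has no tissue region")

    idx = np.nonzero(tissue)
    lo = [(i.min()) * phantom.spacing for i in idx]
    hi = [(i.max() + 1) * phantom.spacing for i in idx]

    rng = np.random.default_rng(seed)
    for _ in range(max_rejections):
        radius = rng.uniform(r_min, r_max)
        center = tuple(rng.uniform(l, h) for l, h in zip(lo, hi))
        cells = _clot_cells(phantom, center, radius)
        if cells.any() and np.all(tissue[cells]):
            return ClotSpec(center=center, radius=float(radius), velocity=float(clot_velocity))
    raise RuntimeError(
        f"no feasible clot center found after {max_rejections} rejections; "
        "radius_range too large for the tissue region?"
    )


def embed_clot(phantom: HeadPhantom, clot: ClotSpec) -> HeadPhantom:
    """Return a new phantom with the clot rasterized into the tissue.

    Cells whose center lies within the clot radius take the clot velocity and
    label; every other cell is untouched. The input phantom is not mutated.
    Raises if any clot cell would fall outside the tissue region.
    """
    cells = _clot_cells(phantom, clot.center, clot.radius)
    tissue = phantom.labels == np.uint8(Region.TISSUE)
    if np.any(cells & ~tissue):
        raise ValueError("clot extends outside the tissue region")
    out = phantom.copy()
    out.velocity[cells] = clot.velocity
    out.labels[cells] = Region.CLOT
    out.clot = clot
    return out


def _ring_positions(
    center: Sequence[float], semi_axes: Sequence[float], count: int, phase: float = 0.0
) -> np.ndarray:
    theta = phase + 2.0 * np.pi * np.arange(count) / count
    return np.stack(
        [center[0] + semi_axes[0] * np.cos(theta), center[1] + semi_axes[1] * np.sin(theta)],
        axis=1,
    )


def place_sensors(
    phantom: HeadPhantom,
    count: int,
    layout: str = "ring",
    gap_mm: float = 2.0,
    layers: int = 1,
    layer_spacing_mm: float = 10.0,
) -> SensorArray:
    """Place transducers in the water gap hugging the skull exterior.

    2D ``ring``: equal-angle samples of the ellipse ``skull_outer + gap_mm``.
    3D ``layered-rings``: ``layers`` horizontal rings stacked symmetrically
    about the mid-plane at ``layer_spacing_mm`` (default 10 mm, the layer
    pitch of the physical transducer array), equal angles within each ring.
    Positions are snapped to the nearest cell center; every sensor must land
    in a water-labeled cell.
    """
    spec = phantom.spec
    if spec is None:
        raise ValueError("phantom carries no spec; cannot derive sensor geometry")
    if layout == "ring":
        if phantom.ndim != 2:
            raise ValueError("ring layout requires a 2D phantom")
        if count < 3:
            raise ValueError("a ring needs at least 3 sensors")
        axes = tuple(a + gap_mm for a in spec.skull_outer_semi_axes)
        raw = _ring_positions(spec.center_mm, axes, count)
    elif layout == "layered-rings":
        if phantom.ndim != 3:
            raise ValueError("layered-rings layout requires a 3D phantom")
        if layers < 1 or count < 3 * layers:
            raise ValueError("need at least 3 sensors per layer")
        per, extra = divmod(count, layers)
        axes = tuple(a + gap_mm for a in spec.skull_outer_semi_axes[:2])
        z0 = spec.center_mm[2] - layer_spacing_mm * (layers - 1) / 2.0
        rows = []
        for l in range(layers):
            n = per + (1 if l < extra else 0)
            ring = _ring_positions(spec.center_mm[:2], axes, n)
            z = np.full((n, 1), z0 + l * layer_spacing_mm)
            rows.append(np.concatenate([ring, z], axis=1))
        raw = np.concatenate(rows, axis=0)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    # snap to cell centers
    h = phantom.spacing
    cells = np.floor(raw / h).astype(np.int64)
    for k, n in enumerate(phantom.shape):
        if np.any((cells[:, k] < 0) | (cells[:, k] >= n)):
            raise ValueError("sensor positions fall outside the grid")
    snapped = (cells + 0.5) * h
    labels = phantom.labels[tuple(cells.T)]
    if np.any(labels != np.uint8(Region.WATER)):
        raise ValueError(
            "water gap too thin: some sensors snap onto skull/tissue cells; "
            "increase gap_mm or the grid margin"
        )
    if np.unique(cells, axis=0).shape[0] != cells.shape[0]:
        raise ValueError("sensor density too high for the grid: positions collide after snapping")
    return SensorArray(positions=snapped, layout=layout)


def export_velocity_grid(phantom: HeadPhantom, path) -> None:
    """Write the velocity grid as flat float32 binary + a JSON sidecar.

    The sidecar (``<path>.json``) records shape, spacing and memory order
    (x fastest, i.e. C order of the (…, x) array written here).
    """
    import json
    from pathlib import Path

    path = Path(path)
    phantom.velocity.astype(np.float32).tofile(path)
    sidecar = {
        "dtype": "float32",
        "shape": list(phantom.shape),
        "spacing_mm": phantom.spacing,
        "order": "x fastest (C order, last axis contiguous)",
        "units": "m/s",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def scaled_2d_spec(grid: int = 48, spacing: float = 1.0) -> PhantomSpec:
    """Desk-scale 2D phantom: the default study condition for end-to-end runs.

    A 48 mm cross-section standing in for the ~250 mm head slice at roughly
    1/5 scale: skull outer semi-axes (18, 16) mm, shell 3 mm thick.
    """
    return PhantomSpec(
        dimensionality=2,
        grid_shape=(grid, grid),
        grid_spacing=spacing,
        skull_outer_semi_axes=(0.375 * grid * spacing, 0.3334 * grid * spacing),
        skull_thickness=0.0625 * grid * spacing,
    )


def lab_phantom_spec() -> PhantomSpec:
    """Emulation of the resin laboratory phantom (50 mm clot at 2222 m/s).

    Returns the skull-shell spec; pair it with
    ``ClotSpec(center, radius=25.0, velocity=2222.0)``.
    """
    return PhantomSpec(
        dimensionality=3,
        grid_shape=(128, 150, 100),
        grid_spacing=2.0,
        skull_outer_semi_axes=(100.0, 120.0, 80.0),
        skull_thickness=8.0,
    )
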