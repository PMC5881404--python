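"""Uniform Cartesian grids and scalar fields defined on them.

A :class:`GridSpec` is a node-centred lattice: node ``(i, j, k)`` sits at
``origin + index * spacing`` (0-based, no half-cell offset).  A
:class:`ScalarField` carries real values on those nodes together with a
role tag (density, dielectric, potential, penalty, concentration) that
lets downstream operations validate their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

VALID_ROLES = {"density", "dielectric", "potential", "penalty", "concentration", "charge"}


@dataclass(frozen=True)
class GridSpec:
    """Uniform cubic-cell lattice: origin (Å), spacing (Å), shape (nodes)."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("grid origin must be finite")
        if self.spacing <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if any(int(n) < 2 for n in self.shape):
            raise ValueError(f"grid shape must be >= 2 per axis, got {self.shape}")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def upper(self) -> tuple[float, float, float]:
        """Position of the last node along each axis (Å)."""
        return tuple(
            self.origin[d] + (self.shape[d] - 1) * self.spacing for d in range(3)
        )

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Node coordinates along each axis."""
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        )

    def nodes(self) -> np.ndarray:
        """All node positions, shape ``(*shape, 3)``."""
        ax, ay, az = self.axes()
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    def to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional grid indices of Cartesian points (Å)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / self.spacing

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points fall inside the grid box."""
        idx = self.to_index(points)
        hi = np.asarray(self.shape) - 1
        return np.all((idx >= 0) & (idx <= hi), axis=-1)

    @classmethod
    def from_bounds(
        cls,
        lower: np.ndarray,
        upper: np.ndarray,
        spacing: float,
        margin_fraction: float = 0.4,
        min_margin: float = 10.0,
    ) -> "GridSpec":
        """Grid box enclosing ``[lower, upper]`` plus a solvent margin.

        The margin per side is ``max(margin_fraction * extent, min_margin)``
        so degenerate (single-atom) bounding boxes still receive a solvent
        shell.  The box is snapped outward to whole grid cells.
        """
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        extent = upper - lower
        margin = np.maximum(margin_fraction * extent, min_margin)
        lo = lower - margin
        hi = upper + margin
        shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
        return cls(origin=tuple(lo), spacing=spacing, shape=shape)


@dataclass
class ScalarField:
    """Real-valued field on a :class:`GridSpec`, tagged by role and units."""

    grid: GridSpec
    values: np.ndarray
    role: str
    units: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown field role {self.role!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    def same_grid(self, other: "ScalarField") -> bool:
        g, h = self.grid, other.grid
        return (
            g.shape == h.shape
            and np.allclose(g.origin, h.origin, atol=1e-9)
            and abs(g.spacing - h.spacing) < 1e-12
        )

    def require_same_grid(self, other: "ScalarField") -> None:
        if not self.same_grid(other):
            raise ValueError("fields are defined on different grids")

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the field at Cartesian points (Å)."""
        from scipy.ndimage import map_coordinates

        idx = self.grid.to_index(points)
        return map_coordinates(self.values, idx.T, order=1, mode="nearest")


def write_map(fld: ScalarField, path: str) -> None:
    """Write a scalar field as an OpenDX map."""
    from gridData import Grid

    g = Grid(
        fld.values,
        origin=np.asarray(fld.grid.origin),
        delta=fld.grid.spacing,
    )
    g.export(str(path), file_format="dx")


def _validate_dx_header(path: str) -> None:
    """Cross-check DX 'counts' and 'items' declarations against the data size."""
    import re

    counts = items = None
    n_data = 0
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                continue
            if "gridpositions counts" in stripped:
                counts = [int(x) for x in stripped.rsplit("counts", 1)[1].split()]
            elif stripped.startswith("object") and " items " in stripped:
                m = re.search(r"items\s+(\d+)", stripped)
                items = int(m.group(1)) if m else None
            elif items is not None:
                tokens = stripped.split()
                try:
                    n_data += len([float(t) for t in tokens])
                except ValueError:
                    continue  # trailing field/component declarations
    if counts is None or items is None:
        raise ValueError(f"{path}: missing DX grid header")
    expected = counts[0] * counts[1] * counts[2]
    if items != expected or n_data != expected:
        raise ValueError(
            f"{path}: DX header/data mismatch (counts {counts} -> {expected} nodes, "
            f"items {items}, data values {n_data})"
        )


def read_map(path: str, role: str = "dielectric", units: str = "") -> ScalarField:
    """Read an OpenDX scalar map into a :class:`ScalarField`.

    Only uniform cubic-cell maps are supported; anisotropic spacing raises.
    """
    from gridData import Grid

    _validate_dx_header(path)
    g = Grid(str(path))
    delta = np.asarray(g.delta)
    if delta.ndim > 1:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0], rtol=1e-6):
        raise ValueError(f"anisotropic grid spacing {delta} not supported")
    origin = np.asarray(g.origin, dtype=float)
    # gridData reports edge coordinates; our nodes coincide with its centers
    spec = GridSpec(origin=tuple(origin), spacing=float(delta[0]), shape=g.grid.shape)
    return ScalarField(grid=spec, values=np.asarray(g.grid), role=role, units=units)


def iter_probe_nodes(grid: GridSpec, center: np.ndarray, radius: float) -> Iterator[tuple[int, int, int]]:
    """Indices of grid nodes within ``radius`` Å of ``center``."""
    c_idx = grid.to_index(center)[0]
    r_idx = radius / grid.spacing
    lo = np.maximum(np.floor(c_idx - r_idx).astype(int), 0)
    hi = np.minimum(np.ceil(c_idx + r_idx).astype(int), np.asarray(grid.shape) - 1)
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                d = (np.array([i, j, k]) - c_idx) * grid.spacing
                if float(d @ d) <= radius * radius:
                    yield (i, j, k)


def probe_sphere_mean(fld: ScalarField, center: np.ndarray, radius: float) -> float:
    """Arithmetic mean of the field over nodes within a probe sphere.

    Raises if the sphere contains no grid node (grid too coarse).
    """
    vals = [fld.values[idx] for idx in iter_probe_nodes(fld.grid, center, radius)]
    if not vals:
        raise ValueError(
            f"probe sphere of radius {radius} Å at {np.asarray(center)} contains no "
            f"grid node; use a finer grid or a larger probe"
        )
    return float(np.mean(vals))
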