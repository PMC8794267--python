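"""Computational lattice and eggshell boundary construction.

The embryo develops inside a rigid eggshell. Imaged embryos are compressed
along the left-right (L-R) body axis by slide mounting, so the eggshell is
modelled as a prolate spheroid (anterior-posterior major semi-axis, equal
dorsal-ventral and L-R minor semi-axes) clipped by two planes normal to the
L-R axis. Body axes map to grid axes as x = A-P, y = L-R, z = D-V.

The eggshell enters the dynamics as a static phase field ``phi_e`` that is
0 inside the shell, 1 outside, with a sigmoidal transition layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError

# Reference eggshell measured on compressed wild-type embryos (micrometres).
REFERENCE_SEMI_AXIS_X = 27.5837
REFERENCE_SEMI_AXIS_Z = 18.3477
REFERENCE_TOTAL_COMPRESSION = 16.7942
REFERENCE_Y_HALF_WIDTH = 9.9506
REFERENCE_DL = 0.2508


@dataclass(frozen=True)
class GridSpec:
    """Uniform cuboid lattice.

    Parameters
    ----------
    dims : tuple of int
        Voxel counts along (x, y, z).
    dl : float
        Physical voxel pitch in micrometres per voxel.
    origin : tuple of float
        Physical coordinate (um) of the centre of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    dl: float = REFERENCE_DL
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 8 for d in self.dims):
            raise GeometryError(f"grid dims must be 3 integers >= 8, got {self.dims}")
        if not self.dl > 0:
            raise GeometryError(f"voxel pitch dl must be positive, got {self.dl}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel, um^3."""
        return self.dl**3

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge lengths of the domain box, um."""
        return tuple(d * self.dl for d in self.dims)

    @property
    def center(self) -> tuple[float, float, float]:
        """Physical coordinate of the domain centre, um."""
        return tuple(o + (d - 1) * self.dl / 2.0 for o, d in zip(self.origin, self.dims))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centres, um."""
        return tuple(
            o + self.dl * np.arange(d) for o, d in zip(self.origin, self.dims)
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse (broadcastable) physical coordinate grids, um."""
        ax, ay, az = self.axes()
        return np.meshgrid(ax, ay, az, indexing="ij", sparse=True)


@dataclass(frozen=True)
class EggshellSpec:
    """Clipped-spheroid eggshell geometry (micrometres).

    ``semi_axis_x`` is the A-P major semi-axis, ``semi_axis_z`` the D-V minor
    semi-axis (the unclipped L-R semi-axis is taken equal to it), and
    ``y_half_width`` the half extent remaining along L-R after compression.
    ``center=None`` places the shell at the grid centre.
    """

    semi_axis_x: float = REFERENCE_SEMI_AXIS_X
    semi_axis_z: float = REFERENCE_SEMI_AXIS_Z
    y_half_width: float = REFERENCE_Y_HALF_WIDTH
    compressed: bool = True
    center: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.semi_axis_x >= self.semi_axis_z > 0):
            raise GeometryError(
                "require semi_axis_x >= semi_axis_z > 0, got "
                f"({self.semi_axis_x}, {self.semi_axis_z})"
            )
        if self.compressed and self.y_half_width > self.semi_axis_z:
            raise GeometryError(
                "compressed shell requires y_half_width <= semi_axis_z"
            )
        if not self.y_half_width > 0:
            raise GeometryError("y_half_width must be positive")

    @property
    def interior_volume(self) -> float:
        """Analytic enclosed volume of the (possibly clipped) spheroid, um^3."""
        return clipped_spheroid_volume(
            self.semi_axis_x, self.semi_axis_z, min(self.y_half_width, self.semi_axis_z)
        )

    def resolved_center(self, grid: GridSpec) -> tuple[float, float, float]:
        return self.center if self.center is not None else grid.center


def clipped_spheroid_volume(a: float, b: float, h: float) -> float:
    """Volume of the spheroid x^2/a^2 + y^2/b^2 + z^2/b^2 = 1 cut to |y| <= h.

    The cross-section at fixed y is an ellipse of area pi*a*b*(1 - y^2/b^2),
    so the volume integrates in closed form.
    """
    h = min(h, b)
    return math.pi * a * b * (2.0 * h - 2.0 * h**3 / (3.0 * b**2))


def half_width_from_compression(minor_semi_axis: float, total_compression: float) -> float:
    """Remaining L-R half width after symmetric compression of the shell.

    The slide removes ``total_compression`` from the full L-R diameter, half
    from each side: ``minor_semi_axis - total_compression / 2``.
    """
    if total_compression < 0:
        raise GeometryError("total_compression must be non-negative")
    half = minor_semi_axis - total_compression / 2.0
    if half <= 0:
        raise GeometryError(
            f"compression {total_compression} exceeds diameter of semi-axis "
            f"{minor_semi_axis}"
        )
    return half


def eggshell_signed_distance(grid: GridSpec, spec: EggshellSpec) -> np.ndarray:
    """Approximate signed distance (um) to the clipped-spheroid surface.

    Negative inside the shell. The spheroid part uses the normalized implicit
    function rescaled by its local gradient norm (a first-order signed
    distance); the clip planes contribute exact plane distances; the
    intersection of interiors is the pointwise maximum.
    """
    xc, yc, zc = spec.resolved_center(grid)
    x, y, z = grid.meshgrid()
    dx, dy, dz = x - xc, y - yc, z - zc
    a, b = spec.semi_axis_x, spec.semi_axis_z
    rho = np.sqrt((dx / a) ** 2 + (dy / b) ** 2 + (dz / b) ** 2)
    grad_norm = np.sqrt((dx / a**2) ** 2 + (dy / b**2) ** 2 + (dz / b**2) ** 2)
    # At the centre rho = grad_norm = 0; the true distance there is -b.
    with np.errstate(invalid="ignore", divide="ignore"):
        d_spheroid = np.where(grad_norm > 0, (rho - 1.0) * rho / np.maximum(grad_norm, 1e-300), -b)
    d = np.asarray(d_spheroid, dtype=np.float64)
    if spec.compressed and spec.y_half_width < b:
        d = np.maximum(d, np.abs(dy) - spec.y_half_width)
    return d


def make_compressed_eggshell_field(
    grid: GridSpec, spec: EggshellSpec, interface_width: float = 2.0
):
    """Build the static eggshell phase field ``phi_e`` on ``grid``.

    ``phi_e`` is 0 deep inside the clipped spheroid, 1 outside, with a tanh
    transition of roughly ``interface_width`` voxels centred on the analytic
    surface (the 0.5 level set lies on it).
    """
    from .phase_fields import PhaseField  # deferred: avoids import cycle

    xc, yc, zc = spec.resolved_center(grid)
    margin = 2.0 * grid.dl
    for c, semi, o, n in zip(
        (xc, yc, zc),
        (spec.semi_axis_x, min(spec.y_half_width, spec.semi_axis_z), spec.semi_axis_z),
        grid.origin,
        grid.dims,
    ):
        lo, hi = o, o + (n - 1) * grid.dl
        if c - semi < lo + margin or c + semi > hi - margin:
            raise GeometryError(
                f"eggshell (semi-extent {semi:.3f} um about {c:.3f}) exceeds grid "
                f"axis range [{lo:.3f}, {hi:.3f}] with a 2-voxel margin"
            )
    if interface_width <= 0:
        raise GeometryError("interface_width must be positive")
    d = eggshell_signed_distance(grid, spec)
    values = 0.5 * (1.0 + np.tanh(2.0 * d / (interface_width * grid.dl)))
    return PhaseField(values, grid)


def derive_uncompressed_spec(compressed: EggshellSpec) -> EggshellSpec:
    """Uncompressed spheroid with the same major axis and enclosed volume.

    Used to test whether structural planarization is a consequence of the
    slide compression: the comparison shell keeps the A-P semi-axis and the
    total interior volume while removing the L-R clip.
    """
    if not compressed.compressed:
        raise GeometryError("input spec is already uncompressed")
    volume = compressed.interior_volume
    # (4/3) pi a m^2 = V  =>  m = sqrt(3 V / (4 pi a))
    minor = math.sqrt(3.0 * volume / (4.0 * math.pi * compressed.semi_axis_x))
    if not math.isfinite(minor) or minor <= 0:
        raise GeometryError("could not derive uncompressed minor semi-axis")
    if minor > compressed.semi_axis_x:
        raise GeometryError("derived minor semi-axis exceeds major semi-axis")
    return replace(
        compressed,
        semi_axis_z=minor,
        y_half_width=minor,
        compressed=False,
    )
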