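"""Geometry, media and ground-truth contrast for a 10-antenna head phantom.

The measurement cell is a 10-walled oval container with inner cross-section
220 x 180 mm, filled with a lossy liquid emulating average head tissue.  A
single ring of 10 antennas sits at the wall centers, all in one plane.
Spherical inclusions of 20/30/40 mm diameter emulate ischemic (lower
permittivity than brain) or hemorrhagic (higher permittivity) stroke lesions.

Conventions, fixed globally:

* time-harmonic factor ``exp(+j w t)``; the complex relative permittivity is
  ``eps_c = eps_r - j*sigma/(w*eps0)`` and decaying waves have ``Im(k) < 0``;
* coordinates in mm, origin at the container's XY center, z = 0 at the
  container bottom, antenna ring at z = 100 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import epsilon_0

#: inner half-axes of the oval cross-section (mm)
SEMI_X = 110.0
SEMI_Y = 90.0
#: height of the antenna ring above the container bottom (mm)
RING_Z = 100.0
#: operating frequency (Hz)
DEFAULT_FREQUENCY = 1.0e9

CLASSES = ("iStroke", "hStroke", "noStroke")


@dataclass(frozen=True)
class Medium:
    """Homogeneous non-magnetic medium: relative permittivity + conductivity."""

    eps_r: float
    sigma: float  # S/m

    def __post_init__(self) -> None:
        if self.eps_r < 1.0:
            raise ValueError(f"eps_r must be >= 1, got {self.eps_r}")
        if self.sigma < 0.0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


# nominal dielectrics of the liquid head phantom and the two stroke materials
# at 1 GHz (measured-uncertainty columns are not propagated)
HEAD = Medium(41.40, 1.04)
ISCHEMIC = Medium(31.72, 0.92)
HEMORRHAGIC = Medium(52.73, 2.85)

STROKE_MEDIA = {"iStroke": ISCHEMIC, "hStroke": HEMORRHAGIC}


def complex_permittivity(medium: Medium, frequency: float) -> complex:
    """Complex relative permittivity ``eps_r - j*sigma/(2*pi*f*eps0)``.

    Parameters
    ----------
    medium : Medium
    frequency : float
        Frequency in Hz, must be positive.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    return medium.eps_r - 1j * medium.sigma / (2.0 * np.pi * frequency * epsilon_0)


@dataclass(frozen=True)
class AntennaArray:
    """Single ring of antennas on the inner oval boundary.

    ``positions`` is an (n, 3) array in mm; all antennas share the same z.
    """

    positions: np.ndarray
    frequency: float = DEFAULT_FREQUENCY

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if not np.allclose(pos[:, 2], pos[0, 2]):
            raise ValueError("all antennas must share the same z (single ring)")

    @property
    def n_antennas(self) -> int:
        return self.positions.shape[0]


def default_array(frequency: float = DEFAULT_FREQUENCY) -> AntennaArray:
    """The default 10-antenna ring.

    Antennas sit at the wall centers of the decagonal oval: angles
    ``theta_i = 2*pi*i/10 + pi/10`` on the ellipse ``(110 cos t, 90 sin t)``,
    ring plane at z = 100 mm.  The exact vertex layout of the physical
    container is not critical; this layout is symmetric under point reflection
    through the center and is configurable by constructing
    :class:`AntennaArray` directly.
    """
    theta = 2.0 * np.pi * np.arange(10) / 10.0 + np.pi / 10.0
    pos = np.column_stack(
        [SEMI_X * np.cos(theta), SEMI_Y * np.sin(theta), np.full(10, RING_Z)]
    )
    return AntennaArray(pos, frequency)


def inside_oval(x, y, margin: float = 0.0):
    """Vectorized test: point inside the oval cross-section shrunk by ``margin`` mm."""
    ax, ay = SEMI_X - margin, SEMI_Y - margin
    return (np.asarray(x) / ax) ** 2 + (np.asarray(y) / ay) ** 2 <= 1.0


@dataclass(frozen=True)
class StrokeScenario:
    """Ground truth for one measurement: lesion label, geometry and media.

    For ``noStroke`` the center/diameter are ignored (kept for bookkeeping).
    """

    label: str
    center: tuple = (0.0, 0.0, RING_Z)  # mm
    diameter: float = 0.0  # mm
    stroke_medium: Medium | None = None
    background_medium: Medium = HEAD

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")
        if self.label != "noStroke":
            if self.diameter <= 0:
                raise ValueError("stroke scenarios need a positive diameter")
            if self.stroke_medium is None:
                object.__setattr__(self, "stroke_medium", STROKE_MEDIA[self.label])


def stroke_scenario(label, center_xy, diameter, z=RING_Z, background=HEAD):
    """Convenience constructor from an XY position (mm) at height ``z``."""
    return StrokeScenario(
        label=label,
        center=(float(center_xy[0]), float(center_xy[1]), float(z)),
        diameter=float(diameter),
        background_medium=background,
    )


@dataclass(frozen=True)
class ImagingGrid:
    """Regular axis-aligned voxel grid masked to the head oval.

    ``xs/ys/zs`` are the voxel-center coordinates along each axis (mm) and
    ``mask`` is a boolean (nx, ny, nz) array selecting voxels inside the oval.
    Field values live on the masked voxels in C (row-major) flat order.
    """

    xs: np.ndarray
    ys: np.ndarray
    zs: np.ndarray
    mask: np.ndarray
    spacing: float  # mm

    centers: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        xs = np.asarray(self.xs, float)
        ys = np.asarray(self.ys, float)
        zs = np.asarray(self.zs, float)
        mask = np.asarray(self.mask, bool)
        if mask.shape != (xs.size, ys.size, zs.size):
            raise ValueError("mask shape must be (nx, ny, nz)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        centers = np.column_stack([X[mask], Y[mask], Z[mask]])
        for name, val in (("xs", xs), ("ys", ys), ("zs", zs), ("mask", mask)):
            object.__setattr__(self, name, val)
        object.__setattr__(self, "centers", centers)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing**3)

    def embed(self, values: np.ndarray, fill=0.0) -> np.ndarray:
        """Scatter per-voxel values back into the full (nx, ny, nz) box."""
        values = np.asarray(values)
        out = np.full(self.mask.shape, fill, dtype=values.dtype)
        out[self.mask] = values
        return out

    def same_geometry(self, other: "ImagingGrid") -> bool:
        return (
            self.mask.shape == other.mask.shape
            and np.array_equal(self.mask, other.mask)
            and np.allclose(self.xs, other.xs)
            and np.allclose(self.ys, other.ys)
            and np.allclose(self.zs, other.zs)
        )


def make_grid(
    spacing: float = 5.0,
    z_extent: tuple[float, float] | None = None,
    margin: float = 0.0,
) -> ImagingGrid:
    """Build the default imaging grid.

    ``z_extent=None`` gives a single XY slice at the antenna-ring height
    (in-plane studies); a ``(zmin, zmax)`` pair gives the full 3-D slab used
    for out-of-plane studies.  Voxel centers are offset by half a voxel so no
    center falls exactly on an axis or on the oval boundary.
    """
    xs = np.arange(-SEMI_X + spacing / 2.0, SEMI_X, spacing)
    ys = np.arange(-SEMI_Y + spacing / 2.0, SEMI_Y, spacing)
    if z_extent is None:
        zs = np.array([RING_Z])
    else:
        zs = np.arange(z_extent[0], z_extent[1] + spacing / 2.0, spacing)
    in2d = inside_oval(xs[:, None], ys[None, :], margin=margin)
    mask = np.repeat(in2d[:, :, None], zs.size, axis=2)
    return ImagingGrid(xs, ys, zs, mask, spacing)


@dataclass(frozen=True)
class ContrastMap:
    """Per-voxel object function delta-O on an :class:`ImagingGrid`.

    ``kind`` is one of ``complex``, ``magnitude``, ``blurred-magnitude``.
    """

    grid: ImagingGrid
    values: np.ndarray
    kind: str = "complex"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (self.grid.n_voxels,):
            raise ValueError(
                f"values must have one entry per masked voxel "
                f"({self.grid.n_voxels}), got shape {vals.shape}"
            )
        object.__setattr__(self, "values", vals)


def true_contrast(
    scenario: StrokeScenario,
    grid: ImagingGrid,
    frequency: float = DEFAULT_FREQUENCY,
) -> ContrastMap:
    """Ground-truth contrast map of a scenario on a grid.

    delta-O(v) = (eps_c,stroke - eps_c,bg) / eps_c,bg for voxel centers inside
    the sphere, 0 elsewhere; ``noStroke`` gives the all-zero map.  A sphere
    that extends outside the masked head region is truncated with a warning.
    """
    if grid.n_voxels == 0:
        raise ValueError("grid has no masked voxels")
    values = np.zeros(grid.n_voxels, dtype=complex)
    if scenario.label == "noStroke":
        return ContrastMap(grid, values)

    ec_bg = complex_permittivity(scenario.background_medium, frequency)
    ec_st = complex_permittivity(scenario.stroke_medium, frequency)
    delta = (ec_st - ec_bg) / ec_bg

    c = np.asarray(scenario.center, float)
    r = scenario.diameter / 2.0
    inside = np.sum((grid.centers - c) ** 2, axis=1) <= r**2
    values[inside] = delta

    cx, cy, cz = c
    if not bool(inside_oval(cx, cy, margin=r)) or (
        grid.zs.size > 1 and (cz - r < grid.zs[0] or cz + r > grid.zs[-1])
    ):
        warnings.warn(
            f"sphere at {tuple(c)} (d={scenario.diameter} mm) extends outside "
            "the masked head region; contrast truncated",
            stacklevel=2,
        )
    return ContrastMap(grid, values)
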