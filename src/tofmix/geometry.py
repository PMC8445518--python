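"""Scanner geometry, reconstruction grids, and digital phantoms.

The scanner is an idealized cylinder of crystals: ``n_crystals_per_ring``
uniformly spaced in azimuth on each of ``n_rings`` rings, with no block
or gap structure.  Phantoms are ordered lists of geometric regions
(cylinders, spheres, spherical shells), each carrying an activity
concentration in kBq/cc and a 511-keV linear attenuation coefficient in
1/mm; later regions override earlier ones where they overlap.  A
generator for the NEMA image-quality layout (six spheres on a 114.4-mm
pitch circle in a warm background) is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
import yaml

__all__ = [
    "RingScanner",
    "VoxelGrid",
    "Cylinder",
    "Sphere",
    "SphericalShell",
    "Region",
    "PhantomSpec",
    "NemaLayout",
    "MU_WATER_511_PER_MM",
    "crystal_center",
    "crystal_centers",
    "rasterize_phantom",
    "nema_iq_phantom",
    "load_phantom",
    "save_phantom",
]

#: Linear attenuation coefficient of water for 511-keV photons (1/mm).
MU_WATER_511_PER_MM = 0.0096


@dataclass(frozen=True)
class RingScanner:
    """Cylindrical ring scanner; radius is measured to the crystal front face."""

    n_crystals_per_ring: int = 360
    n_rings: int = 1
    ring_radius_mm: float = 424.0
    crystal_pitch_transaxial_mm: float = 4.0
    crystal_pitch_axial_mm: float = 4.0
    crystal_depth_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.n_crystals_per_ring < 8:
            raise ValueError("need at least 8 crystals per ring")
        if self.n_rings < 1 or self.ring_radius_mm <= 0:
            raise ValueError("invalid scanner geometry")

    @property
    def axial_extent_mm(self) -> float:
        return self.n_rings * self.crystal_pitch_axial_mm

    @property
    def n_detectors(self) -> int:
        return self.n_crystals_per_ring * self.n_rings

    def flat_index(self, ring: int, crystal: int) -> int:
        return ring * self.n_crystals_per_ring + crystal

    @classmethod
    def desk_2d(cls) -> "RingScanner":
        """Single-ring desk-scale scanner: 360 crystals on a 424-mm radius."""
        return cls()

    @classmethod
    def full_3d(cls) -> "RingScanner":
        """Full-scale geometry: 666 crystals of 4x4x20 mm^3 on 48 rings."""
        return cls(
            n_crystals_per_ring=666,
            n_rings=48,
            ring_radius_mm=666 * 4.0 / (2 * math.pi),
        )


def crystal_center(scanner: RingScanner, ring: int, crystal: int) -> np.ndarray:
    """3-D center of a crystal front face, in mm.

    Crystal 0 sits at azimuth 0 (+x axis), counting counterclockwise as
    seen from +z; rings are centered axially on the scanner isocenter.
    """
    if not (0 <= ring < scanner.n_rings):
        raise ValueError(f"ring index {ring} out of range [0, {scanner.n_rings})")
    if not (0 <= crystal < scanner.n_crystals_per_ring):
        raise ValueError(
            f"crystal index {crystal} out of range [0, {scanner.n_crystals_per_ring})"
        )
    phi = 2 * math.pi * crystal / scanner.n_crystals_per_ring
    z = (ring - (scanner.n_rings - 1) / 2) * scanner.crystal_pitch_axial_mm
    r = scanner.ring_radius_mm
    return np.array([r * math.cos(phi), r * math.sin(phi), z])


def crystal_centers(scanner: RingScanner) -> np.ndarray:
    """(n_detectors, 3) array of all crystal centers, ordered by flat index."""
    rings, crystals = np.divmod(np.arange(scanner.n_detectors), scanner.n_crystals_per_ring)
    phi = 2 * np.pi * crystals / scanner.n_crystals_per_ring
    z = (rings - (scanner.n_rings - 1) / 2) * scanner.crystal_pitch_axial_mm
    r = scanner.ring_radius_mm
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class VoxelGrid:
    """Reconstruction grid centered on the scanner isocenter.

    Voxel (0, 0, 0) occupies the most-negative corner; images are indexed
    (x, y, z) and voxel centers are at ``origin + (i + 0.5) * voxel_size``.
    """

    nx: int
    ny: int
    nz: int
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1 or min(self.voxel_size_mm) <= 0:
            raise ValueError("grid dimensions and voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        dx, dy, dz = self.voxel_size_mm
        return (self.nx * dx, self.ny * dy, self.nz * dz)

    @property
    def origin_mm(self) -> np.ndarray:
        """Most-negative corner of the grid."""
        ex, ey, ez = self.extent_mm
        return np.array([-ex / 2, -ey / 2, -ez / 2])

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        d = self.voxel_size_mm[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * d

    def voxel_center(self, i: int, j: int, k: int) -> np.ndarray:
        d = np.asarray(self.voxel_size_mm)
        return self.origin_mm + (np.array([i, j, k]) + 0.5) * d

    @classmethod
    def desk_2d(cls) -> "VoxelGrid":
        """128 x 128 grid of 2-mm voxels, one 4-mm slice."""
        return cls(nx=128, ny=128, nz=1, voxel_size_mm=(2.0, 2.0, 4.0))

    @classmethod
    def full_3d(cls) -> "VoxelGrid":
        """Full-scale grid: 320 x 320 x 95 voxels of 1 x 1 x 2.08 mm^3."""
        return cls(nx=320, ny=320, nz=95, voxel_size_mm=(1.0, 1.0, 2.08))


# ---------------------------------------------------------------------------
# Phantom shapes


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned (z) circular cylinder."""

    center: tuple[float, float, float]
    radius_mm: float
    half_length_mm: float

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return ((x - cx) ** 2 + (y - cy) ** 2 <= self.radius_mm**2) & (
            np.abs(z - cz) <= self.half_length_mm
        )


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius_mm: float

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius_mm**2


@dataclass(frozen=True)
class SphericalShell:
    center: tuple[float, float, float]
    inner_radius_mm: float
    outer_radius_mm: float

    def __post_init__(self) -> None:
        if not self.outer_radius_mm > self.inner_radius_mm:
            raise ValueError("shell outer radius must exceed inner radius")

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        return (r2 > self.inner_radius_mm**2) & (r2 <= self.outer_radius_mm**2)


Shape = Union[Cylinder, Sphere, SphericalShell]


@dataclass(frozen=True)
class Region:
    shape: Shape
    activity_kBq_cc: float
    mu_511_per_mm: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.activity_kBq_cc < 0 or self.mu_511_per_mm < 0:
            raise ValueError("activity and attenuation must be nonnegative")


@dataclass(frozen=True)
class NemaLayout:
    """Analytic description of the NEMA-IQ sphere layout, used for ROI placement."""

    sphere_centers_mm: tuple[tuple[float, float, float], ...]
    sphere_inner_diameters_mm: tuple[float, ...]
    sphere_is_hot: tuple[bool, ...]
    wall_thickness_mm: float
    body_radius_mm: float
    background_kBq_cc: float
    hot_ratio: float


@dataclass(frozen=True)
class PhantomSpec:
    """Ordered region list; later regions override earlier ones on overlap."""

    regions: tuple[Region, ...]
    nema: NemaLayout | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))

    def total_activity_kBq(self, grid: VoxelGrid) -> float:
        activity, _ = rasterize_phantom(self, grid)
        return float(activity.sum() * grid.voxel_volume_cc)


def rasterize_phantom(
    phantom: PhantomSpec, grid: VoxelGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a phantom onto a grid by voxel-center membership.

    Returns ``(activity_kBq_cc, mu_511_per_mm)`` images of shape
    ``grid.shape``; voxels outside all regions are zero.
    """
    x = grid.axis_centers(0)[:, None, None]
    y = grid.axis_centers(1)[None, :, None]
    z = grid.axis_centers(2)[None, None, :]
    activity = np.zeros(grid.shape)
    mu = np.zeros(grid.shape)
    for region in phantom.regions:
        mask = region.shape.contains(x, y, z)
        activity[mask] = region.activity_kBq_cc
        mu[mask] = region.mu_511_per_mm
    return activity, mu


#: NEMA-IQ sphere inner diameters, smallest to largest (mm).
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
#: Diameter of the circle the sphere centers sit on (mm).
NEMA_PITCH_CIRCLE_MM = 114.4


def nema_iq_phantom(
    scale: float = 1.0,
    background_kBq_cc: float = 11.38,
    hot_ratio: float = 4.0,
    body_radius_mm: float = 110.0,
    body_half_length_mm: float = 100.0,
    wall_thickness_mm: float = 1.0,
    mu_511_per_mm: float = MU_WATER_511_PER_MM,
) -> PhantomSpec:
    """Build the NEMA image-quality phantom layout.

    Six spheres (inner diameters ``scale`` x {10, 13, 17, 22, 28, 37} mm)
    sit on a ``scale`` x 114.4 mm pitch circle in the central transaxial
    plane of a warm cylindrical body.  The four smallest are filled at
    ``hot_ratio`` times the background; the two largest are water-filled
    and carry no activity.  Every sphere is surrounded by a cold
    1-mm wall shell.  All regions attenuate like water at 511 keV.

    The body is modeled as a circular cylinder (radius 110 mm by default,
    roughly the torso phantom's half-width); ``scale`` shrinks the sphere
    layout for desk-size grids while the wall thickness stays fixed.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    radii = [scale * d / 2 for d in NEMA_SPHERE_DIAMETERS_MM]
    pitch_r = scale * NEMA_PITCH_CIRCLE_MM / 2
    angles = [math.radians(60 * i) for i in range(6)]
    centers = [
        (pitch_r * math.cos(a), pitch_r * math.sin(a), 0.0) for a in angles
    ]
    # adjacent spheres must not touch (wall included)
    for i in range(6):
        j = (i + 1) % 6
        d = math.dist(centers[i][:2], centers[j][:2])
        if d < radii[i] + radii[j] + 2 * wall_thickness_mm:
            raise ValueError(
                f"scale {scale} too small: spheres {i} and {j} overlap "
                f"(center distance {d:.2f} mm)"
            )
    if pitch_r + max(radii) + wall_thickness_mm > body_radius_mm:
        raise ValueError("sphere layout does not fit inside the body cylinder")

    is_hot = (True, True, True, True, False, False)
    regions = [
        Region(
            Cylinder((0.0, 0.0, 0.0), body_radius_mm, body_half_length_mm),
            activity_kBq_cc=background_kBq_cc,
            mu_511_per_mm=mu_511_per_mm,
            name="body",
        )
    ]
    for i, (c, r, hot) in enumerate(zip(centers, radii, is_hot)):
        d_mm = scale * NEMA_SPHERE_DIAMETERS_MM[i]
        regions.append(
            Region(
                SphericalShell(c, r, r + wall_thickness_mm),
                activity_kBq_cc=0.0,
                mu_511_per_mm=mu_511_per_mm,
                name=f"wall_{d_mm:g}mm",
            )
        )
        regions.append(
            Region(
                Sphere(c, r),
                activity_kBq_cc=hot_ratio * background_kBq_cc if hot else 0.0,
                mu_511_per_mm=mu_511_per_mm,
                name=f"sphere_{d_mm:g}mm",
            )
        )
    layout = NemaLayout(
        sphere_centers_mm=tuple(centers),
        sphere_inner_diameters_mm=tuple(scale * d for d in NEMA_SPHERE_DIAMETERS_MM),
        sphere_is_hot=is_hot,
        wall_thickness_mm=wall_thickness_mm,
        body_radius_mm=body_radius_mm,
        background_kBq_cc=background_kBq_cc,
        hot_ratio=hot_ratio,
    )
    return PhantomSpec(regions=tuple(regions), nema=layout)


# ---------------------------------------------------------------------------
# Phantom spec file I/O (YAML)

_SHAPE_TAGS = {"cylinder": Cylinder, "sphere": Sphere, "shell": SphericalShell}


def _shape_to_dict(shape: Shape) -> dict:
    if isinstance(shape, Cylinder):
        return {
            "type": "cylinder",
            "center": list(shape.center),
            "radius_mm": shape.radius_mm,
            "half_length_mm": shape.half_length_mm,
        }
    if isinstance(shape, Sphere):
        return {"type": "sphere", "center": list(shape.center), "radius_mm": shape.radius_mm}
    return {
        "type": "shell",
        "center": list(shape.center),
        "inner_radius_mm": shape.inner_radius_mm,
        "outer_radius_mm": shape.outer_radius_mm,
    }


def save_phantom(phantom: PhantomSpec, path) -> None:
    doc = {
        "regions": [
            {
                "name": r.name,
                "activity_kBq_cc": r.activity_kBq_cc,
                "mu_511_per_mm": r.mu_511_per_mm,
                **_shape_to_dict(r.shape),
            }
            for r in phantom.regions
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_phantom(path) -> PhantomSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    regions = []
    for entry in doc["regions"]:
        entry = dict(entry)
        name = entry.pop("name", "")
        activity = float(entry.pop("activity_kBq_cc"))
        mu = float(entry.pop("mu_511_per_mm", 0.0))
        shape_type = entry.pop("type")
        cls = _SHAPE_TAGS[shape_type]
        entry["center"] = tuple(entry["center"])
        regions.append(Region(cls(**entry), activity, mu, name))
    return PhantomSpec(regions=tuple(regions))
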