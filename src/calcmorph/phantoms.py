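"""Voxel phantoms with known geometry and HU contrast.

Study CT data are not redistributable, so the geometric contracts of the
pipeline (segmentation exactness, surface-area accuracy, thickness
recovery) are exercised on synthetic phantoms: a calcified shell of known
wall thickness embedded in a solid "artery" tube, with realistic
attenuation (calcification ~300 HU inside the calcium window, lumen ~40
HU, background 0 HU) and a 1000 HU "bone" block placed adjacent to but
outside the artery mask to exercise the upper window bound.

Voxelization rule: a voxel belongs to a shape iff its center lies inside
the continuous shape, so voxel-count volumes track analytic volumes to
within the one-voxel staircase.

The module also builds exact parametric meshes (parallel plates, annular
shell sectors, tubes) used to probe the thickness estimator in closed
form, free of voxelization artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .volumes import BinaryMask, CtVolume

HU_CALC_DEFAULT = 300.0
HU_LUMEN_DEFAULT = 40.0
HU_BACKGROUND_DEFAULT = 0.0
HU_BONE_DEFAULT = 1000.0

#: artery tube radius margin beyond the calcification outer radius (mm)
ARTERY_RADIAL_MARGIN = 1.0
#: artery tube extension beyond the calcification along its axis (mm)
ARTERY_AXIAL_MARGIN = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + HU assignment of one synthetic phantom.

    ``shape`` is one of {"annulus", "slab", "spherical_shell"}.  For the
    annulus, the calcification occupies the shell ``r1 <= r <= r2`` over
    ``arc_deg`` degrees of azimuth and height ``height``; ground-truth wall
    thickness is ``r2 - r1``.  For the slab it is a box of the given
    ``thickness`` and lateral ``extent``; for the spherical shell, the
    region between the two radii.  ``rotation_deg`` tilts the whole phantom
    (calcification and artery together) about the given axis.
    """

    shape: str = "annulus"
    r1: float = 2.0
    r2: float = 3.5
    height: float = 6.0
    arc_deg: float = 360.0
    thickness: float = 1.5  # slab only
    extent: tuple[float, float] = (10.0, 10.0)  # slab only
    spacing: float = 0.25
    hu_calc: float = HU_CALC_DEFAULT
    hu_lumen: float = HU_LUMEN_DEFAULT
    hu_background: float = HU_BACKGROUND_DEFAULT
    hu_bone: float = HU_BONE_DEFAULT
    bone: bool = True
    rotation_deg: float = 0.0
    rotation_axis: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.shape not in ("annulus", "slab", "spherical_shell"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if self.shape in ("annulus", "spherical_shell"):
            if not 0 < self.r1 < self.r2:
                raise ValueError(f"require 0 < r1 < r2, got {self.r1}, {self.r2}")
        if self.shape == "slab" and self.thickness <= 0:
            raise ValueError("slab thickness must be positive")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not HU_LO_WINDOW <= self.hu_calc <= HU_HI_WINDOW:
            raise ValueError(
                f"calcification HU {self.hu_calc} outside [{HU_LO_WINDOW}, "
                f"{HU_HI_WINDOW}]"
            )
        if self.hu_bone <= HU_HI_WINDOW:
            raise ValueError(f"bone HU must exceed {HU_HI_WINDOW}")

    @property
    def wall_thickness(self) -> float:
        """Ground-truth thickness in mm."""
        return self.thickness if self.shape == "slab" else self.r2 - self.r1


# calcium window bounds, repeated here so spec validation is self-contained
HU_LO_WINDOW = 130.0
HU_HI_WINDOW = 500.0


def _rotation_matrix(axis: int, deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    r = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    r[i, i] = c
    r[j, j] = c
    r[i, j] = -s
    r[j, i] = s
    return r


def _world_grid(half_extent, spacing):
    """Voxel-center coordinate arrays for a grid centered on the origin.

    The returned coordinates are relative to the shape center, which is
    placed at a deterministic sub-voxel offset (spacing/3) from the grid
    alignment: round-number shape boundaries (slab half-thickness, shell
    height) then fall generically between voxel centers instead of exactly
    on them, so voxel-count volumes track analytic volumes without the
    one-voxel knife-edge inclusion bias of an aligned grid.
    """
    n = [2 * (int(np.ceil(e / spacing)) + 2) for e in half_extent]
    shift = spacing / 3.0
    idx = np.indices(n, dtype=float)
    coords = [(idx[a] - (n[a] - 1) / 2) * spacing - shift for a in range(3)]
    origin = tuple(-(n[a] - 1) / 2 * spacing for a in range(3))
    return coords, origin


def _assemble(spec, calc_region, artery_region, half_extent, coords, origin):
    sp = (spec.spacing,) * 3
    hu = np.full(calc_region.shape, spec.hu_background)
    hu[artery_region] = spec.hu_lumen
    hu[calc_region] = spec.hu_calc
    if spec.bone:
        # bone block beyond the phantom in +x, outside the artery mask
        x = coords[0]
        bone_region = (x >= half_extent[0] + 0.5) & ~artery_region
        hu[bone_region] = spec.hu_bone
    vol = CtVolume(hu, sp, origin)
    artery = BinaryMask(artery_region, sp, origin)
    calc = BinaryMask(calc_region, sp, origin)
    return vol, artery, calc


def make_annulus(spec: PhantomSpec):
    """Voxelize an annular calcified shell inside a solid artery tube.

    Returns ``(ct, artery_mask, truth)`` where ``truth`` holds the
    ground-truth wall thickness, the analytic surface area and shell
    volume, and the exact calcification mask.
    """
    import warnings

    if spec.shape != "annulus":
        raise ValueError(f"spec.shape is {spec.shape!r}, expected 'annulus'")
    if spec.wall_thickness < spec.spacing:
        warnings.warn(
            f"shell thinner than one voxel ({spec.wall_thickness} mm < "
            f"{spec.spacing} mm): sub-resolution regime",
            stacklevel=2,
        )
    r_art = spec.r2 + ARTERY_RADIAL_MARGIN
    h_art = spec.height + 2 * ARTERY_AXIAL_MARGIN
    if spec.rotation_deg:
        e = float(np.hypot(r_art, h_art / 2)) + spec.spacing
        half_extent = (e, e, e)
    else:
        half_extent = (r_art + spec.spacing, r_art + spec.spacing, h_art / 2 + spec.spacing)
    coords, origin = _world_grid(half_extent, spec.spacing)
    pts = np.stack(coords)
    if spec.rotation_deg:
        rot = _rotation_matrix(spec.rotation_axis, spec.rotation_deg)
        pts = np.einsum("ab,bijk->aijk", rot.T, pts)
    x, y, z = pts
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    calc = (
        (r >= spec.r1)
        & (r <= spec.r2)
        & (np.abs(z) <= spec.height / 2)
        & (theta <= spec.arc_deg)
    )
    artery = (r <= r_art) & (np.abs(z) <= h_art / 2)
    vol, artery_mask, calc_mask = _assemble(
        spec, calc, artery, half_extent, coords, origin
    )
    frac = spec.arc_deg / 360.0
    lateral = frac * 2 * np.pi * spec.height * (spec.r1 + spec.r2)
    caps = frac * 2 * np.pi * (spec.r2**2 - spec.r1**2)
    cuts = 0.0 if spec.arc_deg >= 360 else 2 * (spec.r2 - spec.r1) * spec.height
    truth = {
        "thickness_mm": spec.wall_thickness,
        "area_mm2": lateral + caps + cuts,
        "volume_mm3": frac * np.pi * (spec.r2**2 - spec.r1**2) * spec.height,
        "calc_mask": calc_mask,
    }
    return vol, artery_mask, truth


def make_slab(spec: PhantomSpec):
    """Voxelize a flat calcified plate inside a larger artery box."""
    if spec.shape != "slab":
        raise ValueError(f"spec.shape is {spec.shape!r}, expected 'slab'")
    ex, ey = spec.extent
    t = spec.thickness
    margin_xy, margin_z = 3.0, 1.0
    hx, hy = ex / 2 + margin_xy, ey / 2 + margin_xy
    hz = t / 2 + margin_z
    if spec.rotation_deg:
        e = float(np.linalg.norm([hx, hy, hz])) + spec.spacing
        half_extent = (e, e, e)
    else:
        half_extent = (hx + spec.spacing, hy + spec.spacing, hz + spec.spacing)
    coords, origin = _world_grid(half_extent, spec.spacing)
    pts = np.stack(coords)
    if spec.rotation_deg:
        rot = _rotation_matrix(spec.rotation_axis, spec.rotation_deg)
        pts = np.einsum("ab,bijk->aijk", rot.T, pts)
    x, y, z = pts
    calc = (np.abs(x) <= ex / 2) & (np.abs(y) <= ey / 2) & (np.abs(z) <= t / 2)
    artery = (np.abs(x) <= hx) & (np.abs(y) <= hy) & (np.abs(z) <= hz)
    vol, artery_mask, calc_mask = _assemble(
        spec, calc, artery, half_extent, coords, origin
    )
    truth = {
        "thickness_mm": t,
        "area_mm2": 2 * ex * ey + 2 * t * (ex + ey),
        "volume_mm3": ex * ey * t,
        "calc_mask": calc_mask,
    }
    return vol, artery_mask, truth


def make_spherical_shell(spec: PhantomSpec):
    """Voxelize a hollow spherical calcified shell inside a solid ball."""
    if spec.shape != "spherical_shell":
        raise ValueError(f"spec.shape is {spec.shape!r}, expected 'spherical_shell'")
    r_art = spec.r2 + ARTERY_RADIAL_MARGIN
    half_extent = (r_art + spec.spacing,) * 3
    coords, origin = _world_grid(half_extent, spec.spacing)
    x, y, z = coords
    r = np.sqrt(x * x + y * y + z * z)
    calc = (r >= spec.r1) & (r <= spec.r2)
    artery = r <= r_art
    vol, artery_mask, calc_mask = _assemble(
        spec, calc, artery, half_extent, coords, origin
    )
    truth = {
        "thickness_mm": spec.wall_thickness,
        "area_mm2": 4 * np.pi * (spec.r1**2 + spec.r2**2),
        "volume_mm3": 4 / 3 * np.pi * (spec.r2**3 - spec.r1**3),
        "calc_mask": calc_mask,
    }
    return vol, artery_mask, truth


_MAKERS = {
    "annulus": make_annulus,
    "slab": make_slab,
    "spherical_shell": make_spherical_shell,
}


def make_phantom(spec: PhantomSpec):
    """Dispatch on ``spec.shape``."""
    return _MAKERS[spec.shape](spec)


def make_cohort_fixture(n: int, seed: int, spacing: float = 0.625) -> list[PhantomSpec]:
    """A deterministic ensemble of annulus specs emulating cohort deposits.

    Wall thickness spans 1.0-3.5 mm with a right-skewed distribution (thin
    shells are the common case in vivo), arc spans 90-360 degrees, and the
    resulting deposit volumes are right-skewed with a mean near the ~54 mm³
    scale reported for intracranial carotid calcification.  All draws come
    from one seeded generator so the same (n, seed) always yields the same
    list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        r1 = rng.uniform(1.1, 2.0)
        wall = 1.0 + 2.5 * rng.beta(1.2, 3.0)
        specs.append(
            PhantomSpec(
                shape="annulus",
                r1=round(r1, 3),
                r2=round(r1 + wall, 3),
                height=round(rng.uniform(1.5, 5.5), 3),
                arc_deg=round(rng.uniform(90.0, 360.0), 2),
                spacing=spacing,
                hu_calc=round(rng.uniform(200.0, 450.0), 1),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# exact parametric meshes (no voxelization)
# ---------------------------------------------------------------------------


def parallel_plates_mesh(
    separation: float, size: float = 10.0, n: int = 5
) -> trimesh.Trimesh:
    """Two congruent square plates with mirror-matched triangulation.

    The lower plate (z=0) has normals (0,0,-1), the upper (z=separation)
    has (0,0,+1) — the two outer faces of an idealized slab.  Matched
    centroids make the opposing-normal thickness exactly ``separation``
    for every face.
    """
    xs = np.linspace(-size / 2, size / 2, n + 1)
    verts, faces = [], []
    for z, flip in ((0.0, True), (separation, False)):
        base = len(verts)
        for xi in xs:
            for yi in xs:
                verts.append((xi, yi, z))
        m = n + 1
        for i in range(n):
            for j in range(n):
                a = base + i * m + j
                b, c, d = a + 1, a + m, a + m + 1
                if flip:  # wind so the normal points -z
                    faces += [(a, b, c), (b, d, c)]
                else:
                    faces += [(a, c, b), (b, c, d)]
    return trimesh.Trimesh(np.array(verts, float), np.array(faces), process=False)


def _quad_strip(p00, p01, p10, p11, faces, verts):
    # quad (p00, p01) x (p10, p11) wound so the normal follows
    # cross(p01 - p00, p10 - p00)
    a = len(verts)
    verts.extend([p00, p01, p10, p11])
    faces += [(a, a + 1, a + 2), (a + 1, a + 3, a + 2)]


def annulus_shell_mesh(
    r1: float,
    r2: float,
    height: float,
    arc_deg: float = 360.0,
    n_theta: int = 72,
    n_z: int = 24,
    n_r: int = 6,
) -> trimesh.Trimesh:
    """Exactly meshed annular shell sector with analytic outward normals.

    Surfaces: outer wall (+r̂), inner wall (−r̂), top/bottom caps (±ẑ) and,
    for ``arc_deg < 360``, two planar cut faces.  Used to probe the
    thickness estimator without voxelization artifacts.
    """
    full = arc_deg >= 360.0
    thetas = np.radians(np.linspace(0.0, arc_deg, n_theta + 1))
    zs = np.linspace(-height / 2, height / 2, n_z + 1)
    rs = np.linspace(r1, r2, n_r + 1)
    verts: list = []
    faces: list = []

    def cyl(r, th, z):
        return (r * np.cos(th), r * np.sin(th), z)

    for ti in range(n_theta):
        t0, t1 = thetas[ti], thetas[ti + 1]
        for zi in range(n_z):
            z0, z1 = zs[zi], zs[zi + 1]
            # outer wall, normal +r̂: CCW seen from outside
            _quad_strip(
                cyl(r2, t0, z0), cyl(r2, t1, z0), cyl(r2, t0, z1), cyl(r2, t1, z1),
                faces, verts,
            )
            # inner wall, normal -r̂ (toward the axis): reverse orientation
            _quad_strip(
                cyl(r1, t1, z0), cyl(r1, t0, z0), cyl(r1, t1, z1), cyl(r1, t0, z1),
                faces, verts,
            )
        for ri in range(n_r):
            ra, rb = rs[ri], rs[ri + 1]
            # top cap, normal +ẑ
            _quad_strip(
                cyl(ra, t0, zs[-1]), cyl(rb, t0, zs[-1]),
                cyl(ra, t1, zs[-1]), cyl(rb, t1, zs[-1]),
                faces, verts,
            )
            # bottom cap, normal -ẑ
            _quad_strip(
                cyl(rb, t0, zs[0]), cyl(ra, t0, zs[0]),
                cyl(rb, t1, zs[0]), cyl(ra, t1, zs[0]),
                faces, verts,
            )
    if not full:
        for th, sign in ((thetas[0], -1.0), (thetas[-1], +1.0)):
            # planar cut faces at the arc ends; outward normal ±θ̂
            for ri in range(n_r):
                ra, rb = rs[ri], rs[ri + 1]
                for zi in range(n_z):
                    z0, z1 = zs[zi], zs[zi + 1]
                    if sign < 0:
                        _quad_strip(
                            cyl(ra, th, z0), cyl(rb, th, z0),
                            cyl(ra, th, z1), cyl(rb, th, z1),
                            faces, verts,
                        )
                    else:
                        _quad_strip(
                            cyl(rb, th, z0), cyl(ra, th, z0),
                            cyl(rb, th, z1), cyl(ra, th, z1),
                            faces, verts,
                        )
    mesh = trimesh.Trimesh(np.array(verts, float), np.array(faces), process=False)
    mesh.merge_vertices()
    return mesh


def tube_mesh(radius: float, height: float, sections: int = 96) -> trimesh.Trimesh:
    """Closed cylinder (axis z, centered on the origin), outward normals."""
    return trimesh.creation.cylinder(radius=radius, height=height, sections=sections)
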