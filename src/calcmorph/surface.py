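"""Triangle-mesh surface models of binary masks.

A mask is converted to a closed triangle mesh by marching cubes at
iso-level 0.5 on the {0,1} field, with vertices mapped to world mm.  A
volume-preserving Taubin smoothing pass then removes the voxel staircase:
marching cubes on raw binary data produces 45-degree chamfer patterns
whose total area overestimates the true surface by roughly 8% regardless
of resolution, while the smoothed mesh tracks analytic areas to within a
few percent and converges under grid refinement.  The smoothing moves
vertices only; the mesh stays watertight with outward normals.

Surface area S is the sum of triangle areas over the model, reported in
mm².
"""

from __future__ import annotations

import numpy as np
import trimesh
from skimage import measure

from .volumes import BinaryMask

#: Taubin iterations at the 0.5 mm reference spacing; the effective count
#: scales with 1/spacing² so the smoothing window is a fixed physical width
#: (~1.6 mm) and the meshed area converges to the analytic surface under
#: grid refinement instead of plateauing at the staircase bias
SMOOTH_ITERATIONS_AT_HALF_MM = 10

#: below this face count the raw mesh is kept: Taubin smoothing needs a
#: neighborhood to average over and collapses voxel-scale meshes (a single
#: voxel's octahedron shrinks by ~95%) instead of de-aliasing them
MIN_FACES_FOR_SMOOTHING = 100


def default_smooth_iterations(spacing) -> int:
    """Spacing-dependent Taubin iteration count (fixed physical window)."""
    mean_sp = float(np.mean(spacing))
    return max(1, round(SMOOTH_ITERATIONS_AT_HALF_MM * (0.5 / mean_sp) ** 2))


def build_surface(
    mask: BinaryMask, smooth_iterations: int | None = None
) -> trimesh.Trimesh:
    """Mesh the boundary of a non-empty mask in world-mm coordinates.

    The field is zero-padded by one voxel so masks touching the grid edge
    still produce a closed surface.  ``smooth_iterations=None`` picks the
    spacing-scaled default; ``0`` gives the raw marching-cubes mesh.
    """
    if mask.count() == 0:
        raise ValueError("no surface: mask is empty")
    if smooth_iterations is None:
        smooth_iterations = default_smooth_iterations(mask.spacing)
    field = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.5, spacing=mask.spacing
    )
    # undo the one-voxel pad, then move into world coordinates
    verts = verts - np.asarray(mask.spacing) + np.asarray(mask.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    trimesh.repair.fix_normals(mesh)  # consistent winding, outward normals
    if smooth_iterations and len(mesh.faces) >= MIN_FACES_FOR_SMOOTHING:
        trimesh.smoothing.filter_taubin(mesh, iterations=smooth_iterations)
    return mesh


def face_normals(mesh: trimesh.Trimesh) -> np.ndarray:
    """Unit outward normal per face.

    Raises if any face is degenerate (zero area), since a degenerate face
    has no defined normal and would poison the opposing-normal search.
    """
    areas = mesh.area_faces
    bad = np.flatnonzero(areas == 0)
    if bad.size:
        raise ValueError(f"degenerate (zero-area) face at index {bad[0]}")
    return np.asarray(mesh.face_normals, dtype=float)


def face_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Area per face in mm² (half cross-product magnitude)."""
    return np.asarray(mesh.area_faces, dtype=float)


def face_centroids(mesh: trimesh.Trimesh) -> np.ndarray:
    """Per-face centroid (vertex mean), the 'center point' used for T."""
    return np.asarray(mesh.triangles_center, dtype=float)


def surface_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area S in mm²."""
    return float(face_areas(mesh).sum())


def is_watertight(mesh: trimesh.Trimesh) -> bool:
    """Every edge shared by exactly two faces."""
    return bool(mesh.is_watertight)
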