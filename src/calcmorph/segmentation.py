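"""Calcification segmentation by HU window inside an artery mask.

Voxels with attenuation in a calcium window (default 130-500 HU, both ends
inclusive) that lie inside the supplied artery label are considered
calcified.  The 130 HU floor follows the Agatston calcium-scoring
convention; the 500 HU ceiling separates vascular calcium from adjacent
bone, which the artery mask alone does not exclude reliably.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, CtVolume, GeometryError

HU_LO_DEFAULT = 130.0
HU_HI_DEFAULT = 500.0


def threshold_calcification(
    vol: CtVolume,
    artery_mask: BinaryMask,
    lo: float = HU_LO_DEFAULT,
    hi: float = HU_HI_DEFAULT,
) -> BinaryMask:
    """Binary calcification mask: ``artery_mask & (lo <= HU <= hi)``.

    Both window bounds are inclusive.  The output shares the input geometry
    and is always a subset of the artery mask.
    """
    if lo >= hi:
        raise ValueError(f"require lo < hi, got lo={lo}, hi={hi}")
    if not vol.same_geometry(artery_mask):
        raise GeometryError(
            f"volume (shape {vol.shape}, spacing {vol.spacing}) and artery "
            f"mask (shape {artery_mask.shape}, spacing {artery_mask.spacing}) "
            "do not share geometry"
        )
    calc = (vol.data >= lo) & (vol.data <= hi) & (artery_mask.data > 0)
    return BinaryMask(calc, vol.spacing, vol.origin)


def mask_volume_mm3(mask: BinaryMask) -> float:
    """Volume of a mask in mm³ (voxel count times voxel volume)."""
    return mask.count() * mask.voxel_volume


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(mask: BinaryMask, connectivity: int = 26):
    """Label connected components of a mask.

    Parameters
    ----------
    connectivity : {6, 26}
        Voxel adjacency: faces only (6) or faces+edges+corners (26).

    Returns
    -------
    labels : ndarray of int
        Same shape as the mask; 0 is background, components are 1..n.
    counts : ndarray of int
        Voxel count per component, ``counts[k]`` for label ``k + 1``.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    labels, n = ndimage.label(mask.data, structure=_STRUCTS[connectivity])
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, counts


def component_masks(mask: BinaryMask, connectivity: int = 26) -> list[BinaryMask]:
    """Split a mask into one BinaryMask per connected component."""
    labels, counts = connected_components(mask, connectivity)
    return [
        BinaryMask(labels == k + 1, mask.spacing, mask.origin)
        for k in range(len(counts))
    ]
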