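import numpy as np
import pytest

import calcmorph as cm


@pytest.fixture(scope="session")
def annulus_phantom():
    """Default annulus phantom at 0.5 mm spacing (kept coarse for speed)."""
    spec = cm.PhantomSpec(shape="annulus", r1=2.0, r2=3.5, height=6.0, spacing=0.5)
    ct, artery, truth = cm.make_annulus(spec)
    return spec, ct, artery, truth


@pytest.fixture(scope="session")
def annulus_fine():
    """Annulus at 0.25 mm spacing for refinement-sensitive checks."""
    spec = cm.PhantomSpec(shape="annulus", r1=2.0, r2=3.5, height=6.0, spacing=0.25)
    ct, artery, truth = cm.make_annulus(spec)
    return spec, ct, artery, truth


@pytest.fixture(scope="session")
def ball_mask():
    """Voxelized ball of radius 10 mm at 0.5 mm spacing."""
    r, sp = 10.0, 0.5
    n = int(np.ceil(2 * (r + 2) / sp)) + 1
    idx = np.indices((n, n, n), dtype=float)
    c = (n - 1) / 2
    x, y, z = ((idx[a] - c) * sp for a in range(3))
    return cm.BinaryMask(x * x + y * y + z * z <= r * r, (sp, sp, sp)), r


def random_blob_mask(rng, shape=(14, 14, 14), spacing=0.5):
    """Small random blobby mask for oracle-equivalence tests."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), 2.0)
    mask = field > np.percentile(field, 72)
    labels, n = ndimage.label(mask)
    if n == 0:  # pragma: no cover - extremely unlikely
        mask[tuple(s // 2 for s in shape)] = True
        labels, n = ndimage.label(mask)
    biggest = 1 + np.argmax(np.bincount(labels.ravel())[1:])
    return cm.BinaryMask(labels == biggest, (spacing,) * 3)
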