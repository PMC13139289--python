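"""End-to-end evaluation harnesses on synthetic ground truth.

Each function regenerates its inputs from a seed, runs the pipeline and
measures the result against analytic truth, mirroring the validation
experiments a study would run before trusting the morphometry on real
scans: segmentation exactness on HU-realistic phantoms, surface-area
accuracy against closed-form areas, thickness recovery across wall
thicknesses and orientations, cross-resolution reproducibility of
segmented volumes, and parameter recovery of the regression stage.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import cohort as ch
from . import phantoms as ph
from . import segmentation as seg
from . import surface as surf
from . import thickness as th
from .volumes import BinaryMask, resample_volume


def ball_mask(radius: float = 10.0, spacing: float = 0.5) -> BinaryMask:
    n = 2 * (int(np.ceil((radius + 2) / spacing)) + 1)
    idx = np.indices((n, n, n), dtype=float)
    c = (n - 1) / 2
    x, y, z = ((idx[a] - c) * spacing - spacing / 3 for a in range(3))
    return BinaryMask(x * x + y * y + z * z <= radius * radius, (spacing,) * 3)


def segmentation_exactness(n_phantoms: int = 20, seed: int = 0) -> dict:
    """Fraction of phantoms whose HU-window segmentation equals truth.

    Every phantom carries an adjacent 1000 HU bone block outside the artery
    mask; any leak would break exactness.
    """
    specs = ph.make_cohort_fixture(n_phantoms, seed=seed, spacing=0.5)
    exact = 0
    for spec in specs:
        ct, artery, truth = ph.make_annulus(spec)
        calc = seg.threshold_calcification(ct, artery)
        if np.array_equal(calc.data, truth["calc_mask"].data):
            exact += 1
    return {"exact_rate": exact / n_phantoms, "n": n_phantoms}


def ball_area_error(radius: float = 10.0, spacing: float = 0.5) -> dict:
    mask = ball_mask(radius, spacing)
    mesh = surf.build_surface(mask)
    true = 4 * np.pi * radius * radius
    err = abs(surf.surface_area(mesh) - true) / true
    return {"rel_error": err, "n": len(mesh.faces)}


def annulus_area_errors(spacings=(1.0, 0.5, 0.25)) -> dict:
    """Relative area error of the default annulus shell per spacing."""
    errors = {}
    n = 0
    for sp in spacings:
        spec = ph.PhantomSpec(shape="annulus", spacing=sp)
        _, _, truth = ph.make_annulus(spec)
        mesh = surf.build_surface(truth["calc_mask"])
        errors[sp] = abs(surf.surface_area(mesh) - truth["area_mm2"]) / truth["area_mm2"]
        n = len(mesh.faces)
    return {"errors": errors, "n": n}


def plate_thickness_error(separation: float = 2.0) -> dict:
    """Max |T - d| over a parallel-plate mesh (closed-form case)."""
    mesh = ph.parallel_plates_mesh(separation, size=10.0, n=5)
    t = th.face_thickness(mesh)
    return {"max_abs_error": float(np.abs(t - separation).max()), "n": len(t)}


def thickness_recovery(n_phantoms: int = 40, seed: int = 0, spacing: float = 0.25) -> dict:
    """Share of phantoms whose representative T lands within one voxel.

    The ensemble alternates annulus and slab geometry over wall thicknesses
    {1.0, 1.5, 2.0, 3.0} mm, with varying radius/height/extent and a tilt
    applied to every fourth phantom.
    """
    rng = np.random.default_rng(seed)
    walls = (1.0, 1.5, 2.0, 3.0)
    hits, results = 0, []
    for i in range(n_phantoms):
        wall = walls[i % len(walls)]
        rotation = 30.0 if i % 4 == 3 else 0.0
        if (i // len(walls)) % 2 == 0:
            r1 = float(rng.uniform(1.6, 2.4))
            spec = ph.PhantomSpec(
                shape="annulus", r1=r1, r2=r1 + wall,
                height=float(rng.uniform(4.0, 6.0)), spacing=spacing,
                rotation_deg=rotation, rotation_axis=int(rng.integers(0, 3)),
            )
            ct, artery, truth = ph.make_annulus(spec)
        else:
            e = float(rng.uniform(7.0, 9.0))
            spec = ph.PhantomSpec(
                shape="slab", thickness=wall, extent=(e, e), spacing=spacing,
                rotation_deg=rotation, rotation_axis=int(rng.integers(0, 3)),
            )
            ct, artery, truth = ph.make_slab(spec)
        rep = th.morphometry(ct, artery).representative_thickness_mm
        err = abs(rep - truth["thickness_mm"])
        results.append(err)
        hits += err <= spacing
    return {
        "within_one_voxel_rate": hits / n_phantoms,
        "max_abs_error": float(max(results)),
        "n": n_phantoms,
    }


def resolution_reproducibility(n_phantoms: int = 50, seed: int = 0) -> dict:
    """Pearson r between segmented volumes at 0.625 mm and 1.25 mm.

    The fine CT is down-sampled with linear interpolation (mask with
    nearest-neighbor) and the identical segmentation procedure is rerun on
    the coarse grid, mirroring a two-resolution acquisition protocol.
    """
    specs = ph.make_cohort_fixture(n_phantoms, seed=seed, spacing=0.625)
    v_fine, v_coarse = [], []
    for spec in specs:
        ct, artery, _ = ph.make_annulus(spec)
        v_fine.append(seg.mask_volume_mm3(seg.threshold_calcification(ct, artery)))
        ct2 = resample_volume(ct, 1.25, method="linear")
        artery2 = resample_volume(artery, 1.25, method="nearest")
        v_coarse.append(seg.mask_volume_mm3(seg.threshold_calcification(ct2, artery2)))
    r = float(stats.pearsonr(v_fine, v_coarse).statistic)
    mean_abs = float(np.mean(np.abs(np.array(v_fine) - np.array(v_coarse))))
    return {
        "pearson": r,
        "mean_abs_diff_mm3": mean_abs,
        "mean_volume_mm3": float(np.mean(v_fine)),
        "n": n_phantoms,
    }


def bh_step_up_oracle(pvals: np.ndarray) -> np.ndarray:
    """Literal step-up definition, independent of the pipeline's backend."""
    pvals = np.asarray(pvals, dtype=float)
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


def stats_recovery(
    true_betas=(-0.15, -0.08, 0.0),
    n_replicates: int = 200,
    n: int = 1232,
    seed: int = 0,
) -> dict:
    """Bias and 95%-CI coverage of the standardized S effect.

    For each true β*_S, ``n_replicates`` synthetic cohorts are generated
    and Model 1 is fit; the CI uses the t critical value at the model's
    residual degrees of freedom.
    """
    out = {}
    rng = np.random.default_rng(seed)
    for true in true_betas:
        est, se = [], []
        for _ in range(n_replicates):
            spec = ch.SyntheticCohortSpec(
                n=n,
                seed=int(rng.integers(0, 2**31 - 1)),
                regions={"roi": ch.RegionEffects(beta_s=true)},
            )
            table = ch.synthesize_cohort(spec)
            e = ch.fit_model(table, 1, "roi").estimates["S"]
            est.append(e.beta_std)
            se.append(e.se_std)
        est, se = np.array(est), np.array(se)
        tcrit = stats.t.ppf(0.975, n - 7)
        out[true] = {
            "bias": float(est.mean() - true),
            "coverage": float(np.mean(np.abs(est - true) <= tcrit * se)),
        }
    # closed-form collinearity check: two predictors at r = 0.8
    z = rng.normal(size=(2000, 2))
    q, _ = np.linalg.qr(z - z.mean(0))
    design = np.column_stack([q[:, 0], 0.8 * q[:, 0] + 0.6 * q[:, 1]])
    vif_pair = float(ch.vif(design)[0])
    # BH agreement with the literal step-up definition
    diffs = []
    for _ in range(50):
        p = rng.uniform(0, 1, int(rng.integers(1, 12)))
        adj, _ = ch.bh_adjust(p)
        diffs.append(np.abs(adj - bh_step_up_oracle(p)).max())
    return {
        "per_beta": out,
        "vif_correlated_pair": vif_pair,
        "bh_max_abs_diff": float(max(diffs)),
        "n": n_replicates,
    }


def weighting_behavior() -> dict:
    """Weight-function limits and the axial-bias correction.

    The limits are checked on plate pairs at controlled angles; the bias
    correction on an idealized half-arc shell whose cap faces measure the
    phantom length (6 mm) instead of the 1.5 mm wall unless down-weighted.
    """
    import trimesh

    weights = {}
    for angle in (0.0, 60.0, 90.0):
        calc = ph.parallel_plates_mesh(1.0, size=4.0, n=2)
        artery = ph.parallel_plates_mesh(8.0, size=12.0, n=3)
        artery.apply_transform(
            trimesh.transformations.rotation_matrix(np.radians(angle), [1, 0, 0])
        )
        weights[angle] = float(th.direction_weights(calc, artery, k=5).mean())
    shell = ph.annulus_shell_mesh(2.0, 3.5, 6.0, arc_deg=180.0)
    artery = ph.tube_mesh(4.5, 16.0)
    t = th.face_thickness(shell)
    w = th.direction_weights(shell, artery)
    truth = 1.5
    weighted = th.representative_thickness(t, w)
    unweighted = th.representative_thickness(t)
    return {
        "weights": weights,
        "halfarc_weighted_error": abs(weighted - truth),
        "halfarc_unweighted_error": abs(unweighted - truth),
        "n": len(t),
    }
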