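"""Baseline serial-section aligners and transform re-application.

Three classic pairwise registration approaches are provided:

* **LS** — closed-form least-squares fit of a rigid (orthogonal Procrustes)
  or affine (linear least squares) transform to point correspondences.
* **OPT** — intensity-based registration minimizing the mean squared
  grayscale error over the overlap, optimized coarse-to-fine over an image
  pyramid with a deterministic derivative-free search.
* **Feature-based** — SIFT keypoints, ratio-test descriptor matching and a
  robust affine fit by RANSAC.

A whole stack is registered sequentially: pairwise transforms between
adjacent sections are composed outward from a chosen reference section, so
every section is mapped into the reference frame. The estimated alignment
can then be re-applied to the matching mask and landmark stacks, which is
how landmark-based evaluation of any aligner (including imported
third-party transforms) works.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform, rescale, warp

from .exceptions import DegenerateInputError, MatchFailureError
from .stack_io import SectionStack, to_gray
from .transform import PlanarTransform, StackAlignment

__all__ = [
    "fit_affine_ls",
    "register_pair_opt",
    "register_pair_features",
    "register_stack",
    "apply_alignment",
    "detect_failure",
    "ls_aligner",
    "opt_aligner",
    "feature_aligner",
    "alignment_to_csv",
    "alignment_from_csv",
]

FAILURE_DIMENSION_FACTOR = 5.0


# ---------------------------------------------------------------------------
# LS: least squares on point correspondences


def fit_affine_ls(
    src_points: np.ndarray,
    dst_points: np.ndarray,
    model: str = "affine",
) -> PlanarTransform:
    """Least-squares transform mapping ``src_points`` onto ``dst_points``.

    The affine model solves the 6-parameter linear least-squares problem and
    needs >= 3 non-collinear correspondences; the rigid model is the
    closed-form orthogonal Procrustes solution (rotation + translation, no
    scaling) and needs >= 2 distinct points.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (N, 2) arrays")
    n = len(src)
    if model == "affine":
        if n < 3:
            raise DegenerateInputError("affine fit needs >= 3 correspondences")
        centered = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
            raise DegenerateInputError("source points are collinear")
        design = np.hstack([src, np.ones((n, 1))])
        coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
        return PlanarTransform(coef.T, model="affine")
    if model == "rigid":
        if n < 2 or np.allclose(src, src[0]):
            raise DegenerateInputError("rigid fit needs >= 2 distinct points")
        mu_s = src.mean(axis=0)
        mu_d = dst.mean(axis=0)
        h = (src - mu_s).T @ (dst - mu_d)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, d]) @ u.T
        t = mu_d - rot @ mu_s
        return PlanarTransform(np.column_stack([rot, t]), model="rigid")
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# OPT: intensity-based pairwise registration


def _params_to_transform(p: np.ndarray, model: str, center: np.ndarray) -> PlanarTransform:
    if model == "translation":
        return PlanarTransform.from_params(p[0], p[1], model="rigid")
    if model == "rigid":
        return PlanarTransform.from_params(
            p[0], p[1], rotation_deg=p[2], center=tuple(center), model="rigid"
        )
    # affine: [tx, ty, rot_deg, log_sx, log_sy, shear]
    return PlanarTransform.from_params(
        p[0], p[1], rotation_deg=p[2],
        scale=(np.exp(p[3]), np.exp(p[4])), shear=p[5],
        center=tuple(center), model="affine",
    )


_N_PARAMS = {"translation": 2, "rigid": 3, "affine": 6}


def _mse_loss(fixed: np.ndarray, moving: np.ndarray, tform: PlanarTransform) -> float:
    """Mean squared intensity error over the overlap of fixed and warped moving."""
    inv = tform.inverse().as_skimage()
    warped = warp(moving, inv, output_shape=fixed.shape, order=1,
                  cval=np.nan, preserve_range=True)
    valid = ~np.isnan(warped)
    n_valid = int(valid.sum())
    min_overlap = 0.05 * fixed.size
    if n_valid < max(64, min_overlap):
        return 1e12  # lost overlap; steer the search back
    diff = warped[valid] - fixed[valid]
    return float(np.mean(diff * diff))


def register_pair_opt(
    fixed: np.ndarray,
    moving: np.ndarray,
    model: str = "rigid",
    pyramid_levels: int = 3,
    max_iter: int = 400,
    tolerance: float = 1e-4,
) -> PlanarTransform:
    """Estimate the transform mapping ``moving`` onto ``fixed`` by MSE descent.

    Grayscale mean squared error over the overlap is minimized coarse-to-
    fine: the images are downscaled by powers of two, a deterministic
    Nelder-Mead search (identity initialization at the coarsest level)
    refines the parameters at each level, and pixel-unit parameters are
    rescaled between levels. Returns the transform with a ``converged``
    attribute; non-convergence returns the best found.
    """
    f = to_gray(fixed)
    m = to_gray(moving)
    if model not in _N_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    params = np.zeros(_N_PARAMS[model])
    converged = True
    for level in range(pyramid_levels - 1, -1, -1):
        scale = 2.0**level
        if scale > 1:
            fl = rescale(f, 1 / scale, anti_aliasing=True, preserve_range=True)
            ml = rescale(m, 1 / scale, anti_aliasing=True, preserve_range=True)
        else:
            fl, ml = f, m
        center = np.array([(fl.shape[1] - 1) / 2, (fl.shape[0] - 1) / 2])
        # pixel-unit translations shrink with the level; angles/scales do not
        p0 = params.copy()
        p0[:2] /= scale

        def loss(p):
            return _mse_loss(fl, ml, _params_to_transform(p, model, center))

        # explicit simplex: large enough steps to escape the flat start
        steps = {"translation": [3.0, 3.0], "rigid": [3.0, 3.0, 2.0],
                 "affine": [3.0, 3.0, 2.0, 0.05, 0.05, 0.05]}[model]
        simplex = np.vstack([p0] + [p0 + np.eye(len(p0))[k] * steps[k]
                                    for k in range(len(p0))])
        res = minimize(
            loss, p0, method="Nelder-Mead",
            options=dict(initial_simplex=simplex, maxiter=max_iter,
                         xatol=tolerance, fatol=tolerance),
        )
        converged = converged and res.success
        params = res.x.copy()
        params[:2] *= scale
    center_full = np.array([(f.shape[1] - 1) / 2, (f.shape[0] - 1) / 2])
    tform = _params_to_transform(params, model, center_full)
    object.__setattr__(tform, "converged", bool(converged))
    return tform


# ---------------------------------------------------------------------------
# feature-based pairwise registration


def register_pair_features(
    fixed: np.ndarray,
    moving: np.ndarray,
    match_ratio: float = 0.8,
    ransac_threshold_px: float = 3.0,
    min_inliers: int = 6,
    max_trials: int = 2000,
    seed: int = 0,
    detector_kwargs: dict | None = None,
) -> PlanarTransform:
    """Affine transform from SIFT matches, fitted robustly by RANSAC.

    Scale/rotation-invariant keypoints with 128-d gradient descriptors are
    detected in both grayscale images, matched by nearest-neighbor with a
    ratio test, and an affine model is fitted by seeded random-sample
    consensus. Raises :class:`MatchFailureError` when keypoints, matches or
    inliers are too few; the returned transform carries ``n_inliers`` and
    ``inlier_residual`` attributes.
    """
    kp: list[np.ndarray] = []
    desc: list[np.ndarray] = []
    for img in (fixed, moving):
        g = to_gray(img)
        g = (g - g.min()) / (np.ptp(g) or 1.0)
        try:
            det_i = SIFT(**(detector_kwargs or {}))
            det_i.detect_and_extract(g)
        except RuntimeError as err:  # no keypoints found
            raise MatchFailureError(f"keypoint detection failed: {err}") from err
        kp.append(det_i.keypoints)
        desc.append(det_i.descriptors)
    if min(len(k) for k in kp) < 3:
        raise MatchFailureError("too few keypoints for an affine fit")
    matches = match_descriptors(desc[0], desc[1], cross_check=True,
                                max_ratio=match_ratio)
    if len(matches) < max(3, min_inliers):
        raise MatchFailureError(f"only {len(matches)} putative matches")
    # keypoints are (row, col); transforms work in (x, y)
    pts_fixed = kp[0][matches[:, 0]][:, ::-1].astype(float)
    pts_moving = kp[1][matches[:, 1]][:, ::-1].astype(float)
    model, inliers = ransac(
        (pts_moving, pts_fixed), AffineTransform, min_samples=3,
        residual_threshold=ransac_threshold_px, max_trials=max_trials,
        rng=seed,
    )
    if model is None or inliers is None or inliers.sum() < min_inliers:
        n = 0 if inliers is None else int(inliers.sum())
        raise MatchFailureError(f"only {n} inliers after consensus")
    tform = PlanarTransform.from_skimage(model)
    resid = np.linalg.norm(
        tform.apply(pts_moving[inliers]) - pts_fixed[inliers], axis=1
    )
    object.__setattr__(tform, "n_inliers", int(inliers.sum()))
    object.__setattr__(tform, "inlier_residual", float(resid.mean()))
    return tform


# ---------------------------------------------------------------------------
# aligner factories (uniform pairwise interface)


def ls_aligner(landmarks, model: str = "affine"):
    """Pair method fitting LS transforms to the landmarks of each pair.

    ``landmarks`` is a single-observer LandmarkSet; the returned callable
    ignores the images and fits moving-section points onto fixed-section
    points of the shared pair.
    """

    def method(fixed_img, moving_img, *, fixed_index: int, moving_index: int):
        lo = min(fixed_index, moving_index)
        if landmarks.is_pairwise:
            src = landmarks.points(moving_index, pair=lo)
            dst = landmarks.points(fixed_index, pair=lo)
        else:
            src = landmarks.points(moving_index)
            dst = landmarks.points(fixed_index)
        common = sorted(set(src) & set(dst))
        if len(common) < (3 if model == "affine" else 2):
            raise DegenerateInputError(
                f"pair ({fixed_index},{moving_index}): only {len(common)} "
                "matched landmarks"
            )
        return fit_affine_ls(
            np.array([src[j] for j in common]),
            np.array([dst[j] for j in common]),
            model=model,
        )

    return method


def opt_aligner(**params):
    """Pair method wrapping :func:`register_pair_opt`."""

    def method(fixed_img, moving_img, *, fixed_index: int, moving_index: int):
        return register_pair_opt(fixed_img, moving_img, **params)

    return method


def feature_aligner(**params):
    """Pair method wrapping :func:`register_pair_features`."""

    def method(fixed_img, moving_img, *, fixed_index: int, moving_index: int):
        return register_pair_features(fixed_img, moving_img, **params)

    return method


# ---------------------------------------------------------------------------
# stack registration and re-application


def register_stack(
    stack: SectionStack,
    pair_method,
    reference_index: int = 0,
    on_pair_failure: str = "identity",
) -> StackAlignment:
    """Sequentially register a stack outward from the reference section.

    For each adjacent pair moving away from the reference, ``pair_method``
    (signature ``f(fixed_img, moving_img, *, fixed_index, moving_index)``)
    estimates the transform mapping the outer (moving) section onto its
    inner (fixed) neighbor; global transforms are the compositions along the
    chain to the reference, whose own transform is the identity. A failing
    pair either falls back to the identity with a warning
    (``on_pair_failure="identity"``, default) or aborts (``"raise"``).
    """
    n = stack.n_sections
    if not 0 <= reference_index < n:
        raise ValueError("reference_index out of range")
    transforms: list[PlanarTransform | None] = [None] * n
    transforms[reference_index] = PlanarTransform.identity()
    failures: list[int] = []

    def pairwise(fixed_i: int, moving_i: int) -> PlanarTransform:
        try:
            return pair_method(
                stack[fixed_i], stack[moving_i],
                fixed_index=fixed_i, moving_index=moving_i,
            )
        except Exception as err:
            if on_pair_failure == "raise":
                raise
            warnings.warn(
                f"pair ({fixed_i},{moving_i}) failed ({err}); identity fallback",
                stacklevel=2,
            )
            failures.append(min(fixed_i, moving_i))
            return PlanarTransform.identity()

    for i in range(reference_index + 1, n):
        transforms[i] = transforms[i - 1] @ pairwise(i - 1, i)
    for i in range(reference_index - 1, -1, -1):
        transforms[i] = transforms[i + 1] @ pairwise(i + 1, i)
    alignment = StackAlignment(transforms, reference_index, pair_failures=failures)
    alignment.failure_flag = detect_failure(alignment, stack.shapes)
    return alignment


def detect_failure(alignment: StackAlignment, input_shape) -> bool:
    """Flag error-accumulation failures by runaway canvas growth.

    ``input_shape`` is one (rows, cols) shape or a per-section list. True
    iff either dimension of the common output canvas exceeds five times the
    corresponding maximum input dimension — strictly over fivefold, so an
    exactly fivefold canvas is not a failure.
    """
    shapes = input_shape
    if np.ndim(input_shape) == 1:
        shapes = [tuple(input_shape)] * len(alignment)
    canvas_shape, _ = alignment.canvas(list(shapes))
    max_h = max(s[0] for s in shapes)
    max_w = max(s[1] for s in shapes)
    return bool(
        canvas_shape[0] > FAILURE_DIMENSION_FACTOR * max_h
        or canvas_shape[1] > FAILURE_DIMENSION_FACTOR * max_w
    )


def apply_alignment(
    stack: SectionStack,
    alignment: StackAlignment,
    interpolation: str = "linear",
    is_mask: bool = False,
) -> SectionStack:
    """Resample every section onto the common reference-frame canvas.

    The canvas is the tight bounding box of all transformed section extents,
    shared across the stack; background fills with 0. ``interpolation`` is
    ``"linear"`` or ``"nearest"``; boolean masks warped linearly are
    re-thresholded at 0.5. Landmark images should use linear interpolation —
    the color decoder tolerates the blur.
    """
    if len(alignment) != stack.n_sections:
        raise ValueError("alignment does not cover all sections")
    order = {"linear": 1, "nearest": 0}[interpolation]
    canvas_shape, offset = alignment.canvas(stack.shapes)
    shift = PlanarTransform(
        np.column_stack([np.eye(2), -np.asarray(offset, float)])
    )
    images = []
    for img, tf in zip(stack.images, alignment.transforms):
        full = shift @ tf
        inv = full.inverse().as_skimage()
        was_bool = img.dtype == bool
        src = img.astype(float)
        out = warp(src, inv, output_shape=canvas_shape, order=order,
                   cval=0.0, preserve_range=True)
        if was_bool or is_mask:
            images.append(out > 0.5)
        elif np.issubdtype(img.dtype, np.integer):
            info = np.iinfo(img.dtype)
            images.append(np.clip(np.rint(out), info.min, info.max).astype(img.dtype))
        else:
            images.append(out.astype(img.dtype))
    return SectionStack(images, pixel_size=stack.pixel_size,
                        section_spacing=stack.section_spacing)


# ---------------------------------------------------------------------------
# serialization (the plugin surface for third-party transforms)

_COEF_COLS = ["m00", "m01", "m02", "m10", "m11", "m12"]


def alignment_to_csv(alignment: StackAlignment, path) -> None:
    """Write per-section affine coefficients (row-major 2x3) to CSV."""
    rows = []
    for i, tf in enumerate(alignment.transforms):
        row = {"section_index": i, "reference_index": alignment.reference_index}
        row.update(dict(zip(_COEF_COLS, tf.matrix.ravel())))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def alignment_from_csv(path) -> StackAlignment:
    """Read an alignment written by :func:`alignment_to_csv` (or any tool
    emitting the same section_index + 6-coefficient layout)."""
    df = pd.read_csv(path).sort_values("section_index")
    transforms = [
        PlanarTransform(np.array([[r.m00, r.m01, r.m02], [r.m10, r.m11, r.m12]]))
        for r in df.itertuples()
    ]
    ref = int(df["reference_index"].iloc[0])
    return StackAlignment(transforms, ref)


def alignment_to_json(alignment: StackAlignment, path) -> None:
    data = {
        "reference_index": alignment.reference_index,
        "transforms": [tf.matrix.ravel().tolist() for tf in alignment.transforms],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def alignment_from_json(path) -> StackAlignment:
    data = json.loads(Path(path).read_text())
    transforms = [
        PlanarTransform(np.array(coefs, float).reshape(2, 3))
        for coefs in data["transforms"]
    ]
    return StackAlignment(transforms, int(data["reference_index"]))
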