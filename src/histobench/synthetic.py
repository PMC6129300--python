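"""Ground-truthed synthetic serial-section datasets.

A smooth 3D tissue phantom — an elliptic-cylinder body whose axis drifts
along a curve through the stack (the classic "banana" geometry that
sequential registration tends to straighten) — is sliced into N sections.
Each section carries band-limited 3D texture, darker gland-like tubes and
small nucleus-like blobs, so intensity- and feature-based aligners both
have signal, and is perturbed by a known random rigid or affine transform
emulating the placement of physical sections on slides.

Two annotation designs are emulated:

* **pairwise** ("bisected nuclei" style): each adjacent section pair gets P
  corresponding points shared only by that pair, independently chosen per
  observer;
* **columns** ("laser holes" style): P fiducial columns run through the
  whole volume, following the tissue, and every observer marks the same
  physical columns on every section.

Observers annotate with small independent Gaussian jitter; observer 0 is
reserved for the exact ground truth. All true transforms, coordinates and
tissue areas are recorded, and generation is bit-deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import PhantomSpecError
from .stack_io import (
    LANDMARK_COLUMNS,
    LandmarkColorMap,
    LandmarkSet,
    SectionStack,
    encode_landmarks,
    encode_pairwise_landmarks,
)
from .transform import PlanarTransform

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "PhantomDataset",
    "generate_phantom",
    "emulate_study_design",
    "count_annotations",
]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic serial-section dataset.

    Geometry is in pixels at the working resolution; ``pixel_size`` and
    ``section_spacing`` are µm. ``curvature_amplitude`` is the in-plane
    drift of the tissue axis over the stack; perturbation ranges are the
    half-widths of the uniform distributions the per-section transforms are
    drawn from.
    """

    n_sections: int = 20
    image_size: tuple[int, int] = (256, 256)  # (rows, cols)
    pixel_size: float = 2.0
    section_spacing: float = 5.0
    # phantom body
    tissue_radii: tuple[float, float] = (95.0, 75.0)  # ellipse semi-axes (x, y)
    radius_variation: float = 0.03      # fractional smooth change along z
    curvature_amplitude: float = 8.0    # px drift of the axis ("banana")
    texture_scale: float = 14.0         # intensity std of band-limited texture
    n_glands: int = 10
    n_nuclei: int = 500
    # per-section perturbation
    perturbation: str = "rigid"         # "none" | "rigid" | "affine"
    max_translation: float = 10.0       # px
    max_rotation: float = 5.0           # deg
    max_log_scale: float = 0.03         # affine only
    max_shear: float = 0.02             # affine only
    # annotation design
    landmark_design: str = "pairwise"   # "pairwise" | "columns"
    points_per_section: int = 4
    n_observers: int = 2
    observer_jitter: float = 1.0        # px, truncated at 3 sigma
    disk_radius: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 3:
            raise PhantomSpecError("need at least 3 sections")
        if self.points_per_section < 1:
            raise PhantomSpecError("need at least one landmark point")
        if self.landmark_design not in ("pairwise", "columns"):
            raise PhantomSpecError(f"unknown design {self.landmark_design!r}")
        if self.perturbation not in ("none", "rigid", "affine"):
            raise PhantomSpecError(f"unknown perturbation {self.perturbation!r}")
        h, w = self.image_size
        reach = (
            max(self.tissue_radii) * (1 + self.radius_variation)
            + self.curvature_amplitude
            + self.max_translation * (self.perturbation != "none")
            + 8
        )
        if 2 * reach > min(h, w):
            raise PhantomSpecError(
                f"tissue (reach {reach:.0f} px) may leave the {h}x{w} canvas; "
                "use a larger image_size or smaller radii/perturbations"
            )

    # -- analytic geometry (shared with test oracles) ----------------------

    def axis(self, i) -> np.ndarray:
        """True tissue-axis center (x, y) on section(s) i, unperturbed frame."""
        t = np.asarray(i, dtype=float) / (self.n_sections - 1)
        h, w = self.image_size
        x = (w - 1) / 2 + self.curvature_amplitude * np.sin(np.pi * t)
        y = (h - 1) / 2 + 0.5 * self.curvature_amplitude * (1 - np.cos(np.pi * t))
        return np.stack([x, y], axis=-1)

    def radii(self, i) -> np.ndarray:
        t = np.asarray(i, dtype=float) / (self.n_sections - 1)
        rx, ry = self.tissue_radii
        f = 1.0 - self.radius_variation * np.sin(np.pi * t)
        return np.stack([rx * f, ry * f], axis=-1)

    def true_area_px(self, i) -> float:
        r = self.radii(i)
        return float(np.pi * r[..., 0] * r[..., 1])


@dataclass
class PhantomGroundTruth:
    """Everything needed to score a reconstruction of the phantom exactly."""

    transforms: list[PlanarTransform]          # unperturbed -> stored frame
    landmarks_true: LandmarkSet                # exact coords, stored frame
    landmarks_unperturbed: LandmarkSet         # exact coords, block frame
    true_areas_px: np.ndarray                  # analytic tissue area/section

    def inverse_alignment(self):
        """StackAlignment undoing the perturbations (perfect registration).

        The inverses are expressed relative to section 0 (t0 ∘ t_i^-1) so
        the reference transform is exactly the identity; this differs from
        the raw inverses only by one global affine map, which no metric in
        the panel is sensitive to.
        """
        from .transform import StackAlignment

        t0 = self.transforms[0]
        return StackAlignment(
            [t0 @ tf.inverse() for tf in self.transforms], reference_index=0
        )


@dataclass
class PhantomDataset:
    """A generated phantom: stacks, annotations and ground truth."""

    spec: PhantomSpec
    ground_truth: PhantomGroundTruth
    landmarks: LandmarkSet                     # observers >= 1, with jitter
    colormap: LandmarkColorMap
    tissue: SectionStack | None = None
    masks: SectionStack | None = None

    def landmark_stacks(self, observer: int) -> list[SectionStack]:
        """Encode one observer's annotations (0 = exact ground truth) as
        disk-image stacks: two stacks for the pairwise design, one for
        columns."""
        ls = (
            self.ground_truth.landmarks_true
            if observer == 0
            else self.landmarks.for_observer(observer)
        )
        shape = self.spec.image_size
        kw = dict(
            n_sections=self.spec.n_sections,
            pixel_size=self.spec.pixel_size,
            section_spacing=self.spec.section_spacing,
        )
        if self.spec.landmark_design == "pairwise":
            return list(
                encode_pairwise_landmarks(ls, shape, self.colormap, **kw)
            )
        return [encode_landmarks(ls, shape, self.colormap, **kw)]


# ---------------------------------------------------------------------------
# generation


def _sample_transform(spec: PhantomSpec, rng: np.random.Generator) -> PlanarTransform:
    if spec.perturbation == "none":
        return PlanarTransform.identity()
    h, w = spec.image_size
    center = ((w - 1) / 2, (h - 1) / 2)
    tx, ty = rng.uniform(-spec.max_translation, spec.max_translation, 2)
    rot = rng.uniform(-spec.max_rotation, spec.max_rotation)
    if spec.perturbation == "rigid":
        return PlanarTransform.from_params(tx, ty, rot, center=center, model="rigid")
    sx, sy = np.exp(rng.uniform(-spec.max_log_scale, spec.max_log_scale, 2))
    shear = rng.uniform(-spec.max_shear, spec.max_shear)
    return PlanarTransform.from_params(
        tx, ty, rot, scale=(sx, sy), shear=shear, center=center, model="affine"
    )


def _sample_points(
    spec: PhantomSpec,
    rng: np.random.Generator,
    sections: list[int],
    n_points: int,
    min_sep: float,
    margin: float = 0.75,
) -> np.ndarray:
    """Points inside the tissue ellipse of every listed section, separated."""
    centers = spec.axis(np.array(sections))
    radii = spec.radii(np.array(sections)) * margin
    pts: list[np.ndarray] = []
    for _ in range(n_points):
        for _try in range(500):
            u = rng.uniform(0, 1)
            th = rng.uniform(0, 2 * np.pi)
            unit = np.sqrt(u) * np.array([np.cos(th), np.sin(th)])
            cand_all = centers + unit * radii  # candidate on each section
            cand = cand_all[0]
            if not np.allclose(cand_all, cand, atol=1e-9):
                # use the section-0 candidate but require it inside every ellipse
                rel = (cand - centers) / radii
                if (np.linalg.norm(rel, axis=1) > 1).any():
                    continue
            if all(np.linalg.norm(cand - p) > min_sep for p in pts):
                pts.append(cand)
                break
        else:
            raise PhantomSpecError(
                "could not place separated landmarks; enlarge the tissue or "
                "reduce points_per_section/disk_radius"
            )
    return np.array(pts)


def _jitter(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    j = rng.normal(0.0, spec.observer_jitter, 2)
    return np.clip(j, -3 * spec.observer_jitter, 3 * spec.observer_jitter)


def _make_landmarks(spec: PhantomSpec, rng: np.random.Generator, transforms):
    """Ground-truth and per-observer annotated landmark tables."""
    min_sep = 2 * spec.disk_radius + 6 + 6 * spec.observer_jitter
    true_rows: list[dict] = []
    obs_rows: list[dict] = []
    if spec.landmark_design == "pairwise":
        for obs in range(1, spec.n_observers + 1):
            for i in range(spec.n_sections - 1):
                pts = _sample_points(
                    spec, rng, [i, i + 1], spec.points_per_section, min_sep
                )
                for j, u in enumerate(pts, start=1):
                    for sec in (i, i + 1):
                        x, y = transforms[sec].apply(u)
                        if obs == 1:  # ground truth follows observer 1's points
                            true_rows.append(dict(
                                section=sec, point_id=j, observer=0,
                                x=x, y=y, pair=i, ux=u[0], uy=u[1],
                            ))
                        jx, jy = _jitter(spec, rng)
                        obs_rows.append(dict(
                            section=sec, point_id=j, observer=obs,
                            x=x + jx, y=y + jy, pair=i,
                        ))
    else:  # columns: same physical holes for every observer
        offsets = _sample_points(
            spec, rng, list(range(spec.n_sections)), spec.points_per_section,
            min_sep,
        ) - spec.axis(0)
        for i in range(spec.n_sections):
            c = spec.axis(i)
            for j, off in enumerate(offsets, start=1):
                u = c + off
                x, y = transforms[i].apply(u)
                true_rows.append(dict(
                    section=i, point_id=j, observer=0,
                    x=x, y=y, pair=np.nan, ux=u[0], uy=u[1],
                ))
                for obs in range(1, spec.n_observers + 1):
                    jx, jy = _jitter(spec, rng)
                    obs_rows.append(dict(
                        section=i, point_id=j, observer=obs,
                        x=x + jx, y=y + jy, pair=np.nan,
                    ))
    true_df = pd.DataFrame(true_rows)
    landmarks_true = LandmarkSet(true_df[LANDMARK_COLUMNS].copy())
    unp = true_df.copy()
    unp["x"], unp["y"] = unp["ux"], unp["uy"]
    landmarks_unperturbed = LandmarkSet(unp[LANDMARK_COLUMNS].copy())
    landmarks = LandmarkSet(pd.DataFrame(obs_rows)[LANDMARK_COLUMNS])
    return landmarks_true, landmarks_unperturbed, landmarks


@dataclass
class _Volume:
    """Random 3D content of the phantom, evaluable at arbitrary coords."""

    waves: np.ndarray      # (K, 6): amp, fx, fy, fz, phase, _
    glands: np.ndarray     # (G, 5): off_x, off_y, radius, z0, z1
    nuclei: np.ndarray     # (M, 4): x, y, z, radius

    @classmethod
    def sample(cls, spec: PhantomSpec, rng: np.random.Generator) -> "_Volume":
        k = 36
        waves = np.column_stack([
            rng.normal(1.0, 0.3, k),                       # amplitude
            rng.uniform(-0.03, 0.03, (k, 2)),              # fx, fy (cycles/px)
            rng.uniform(-0.08, 0.08, k),                   # fz (cycles/section)
            rng.uniform(0, 2 * np.pi, k),
            np.zeros(k),
        ])
        rx, ry = spec.tissue_radii
        glands = np.column_stack([
            rng.uniform(-0.6 * rx, 0.6 * rx, spec.n_glands),
            rng.uniform(-0.6 * ry, 0.6 * ry, spec.n_glands),
            rng.uniform(8, 18, spec.n_glands),
            rng.uniform(0, spec.n_sections * 0.7, spec.n_glands),
        ])
        glands = np.column_stack([
            glands, glands[:, 3] + rng.uniform(3, spec.n_sections, spec.n_glands)
        ])
        nuclei = np.column_stack([
            rng.uniform(-0.85 * rx, 0.85 * rx, spec.n_nuclei),
            rng.uniform(-0.85 * ry, 0.85 * ry, spec.n_nuclei),
            rng.uniform(-1, spec.n_sections, spec.n_nuclei),
            rng.uniform(2.0, 4.0, spec.n_nuclei),
        ])
        return cls(waves, glands, nuclei)


def _render_section(
    spec: PhantomSpec, vol: _Volume, i: int, tform: PlanarTransform
) -> tuple[np.ndarray, np.ndarray]:
    """Analytically render section i in its perturbed (stored) frame.

    Every output pixel is mapped through the inverse perturbation into the
    block frame and the phantom is evaluated there, so no interpolation is
    involved and the stored image is exact for any affine perturbation.
    """
    h, w = spec.image_size
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    inv = tform.inverse()
    ux = inv.linear[0, 0] * xs + inv.linear[0, 1] * ys + inv.translation[0]
    uy = inv.linear[1, 0] * xs + inv.linear[1, 1] * ys + inv.translation[1]

    cx, cy = spec.axis(i)
    rx, ry = spec.radii(i)
    e = np.sqrt(((ux - cx) / rx) ** 2 + ((uy - cy) / ry) ** 2)
    mask = e <= 1.0
    alpha = np.clip((1.0 - e) * rx, 0.0, 1.0)  # ~1 px anti-aliased edge

    tex = np.zeros_like(ux)
    for amp, fx, fy, fz, ph, _ in vol.waves:
        tex += amp * np.cos(2 * np.pi * (fx * ux + fy * uy + fz * i) + ph)
    tex /= np.sqrt(len(vol.waves) / 2)  # unit-ish variance

    gland = np.zeros_like(ux)
    for gx, gy, gr, z0, z1 in vol.glands:
        if not (z0 <= i <= z1):
            continue
        d2 = (ux - (cx + gx)) ** 2 + (uy - (cy + gy)) ** 2
        gland += np.exp(-d2 / (2 * gr**2))
    gland = np.clip(gland, 0, 1)

    nuc = np.zeros_like(ux)
    zdist = np.abs(vol.nuclei[:, 2] - i)
    for nx, ny, _, nr in vol.nuclei[zdist < 1.5]:
        d2 = (ux - (cx + nx)) ** 2 + (uy - (cy + ny)) ** 2
        near = d2 < (4 * nr) ** 2
        if near.any():
            nuc[near] += np.exp(-d2[near] / (2 * nr**2))
    nuc = np.clip(nuc, 0, 1)

    t = spec.texture_scale * tex
    base = np.stack([
        225 + 0.9 * t - 95 * nuc - 35 * gland,
        160 + 0.7 * t - 100 * nuc - 45 * gland,
        200 + 0.9 * t - 55 * nuc - 15 * gland,
    ], axis=-1)
    bg = 245.0
    rgb = bg * (1 - alpha[..., None]) + alpha[..., None] * base
    return np.clip(rgb, 0, 255).astype(np.uint8), mask


def generate_phantom(spec: PhantomSpec, images: bool = True) -> PhantomDataset:
    """Generate a phantom dataset; with ``images=False`` only transforms,
    landmark tables and ground truth are produced (fast, for large stacks).

    The random draw order is fixed so the geometry, transforms and
    annotations are identical whether or not images are rendered; the whole
    generation is bit-deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    vol = _Volume.sample(spec, rng)
    transforms = [_sample_transform(spec, rng) for _ in range(spec.n_sections)]
    lm_true, lm_unp, lm_obs = _make_landmarks(spec, rng, transforms)
    truth = PhantomGroundTruth(
        transforms=transforms,
        landmarks_true=lm_true,
        landmarks_unperturbed=lm_unp,
        true_areas_px=np.array(
            [spec.true_area_px(i) for i in range(spec.n_sections)]
        ),
    )
    cm = LandmarkColorMap(disk_radius=spec.disk_radius)
    dataset = PhantomDataset(
        spec=spec, ground_truth=truth, landmarks=lm_obs, colormap=cm
    )
    if images:
        tissue, masks = [], []
        for i in range(spec.n_sections):
            rgb, mask = _render_section(spec, vol, i, transforms[i])
            tissue.append(rgb)
            masks.append(mask)
        meta = dict(pixel_size=spec.pixel_size,
                    section_spacing=spec.section_spacing)
        dataset.tissue = SectionStack(tissue, **meta)
        dataset.masks = SectionStack(masks, **meta)
    return dataset


# ---------------------------------------------------------------------------
# study-design emulation


def emulate_study_design(
    study: str,
    image_size: tuple[int, int] = (192, 192),
    n_sections: int | None = None,
    seed: int = 0,
    observer_jitter: float = 1.0,
) -> PhantomSpec:
    """A spec mirroring one of the two study designs at desk scale.

    ``"prostate"``: 260 sections with four pairwise "bisected nuclei" points
    per adjacent pair, two observers. ``"liver"``: 47 sections with four
    through-stack fiducial columns ("laser holes"), two observers. Section
    spacing is 5 µm and the pixel size matches the low-resolution analysis
    scale (7.36 µm); the image extent is reduced for desk-scale runs.
    """
    scale = min(image_size) / 256.0
    common = dict(
        image_size=image_size,
        pixel_size=7.36,
        section_spacing=5.0,
        tissue_radii=(88.0 * scale, 70.0 * scale),
        curvature_amplitude=8.0 * scale,
        max_translation=10.0 * scale,
        points_per_section=4,
        n_observers=2,
        observer_jitter=observer_jitter,
        disk_radius=max(3, int(round(5 * scale))),
        seed=seed,
    )
    if study == "prostate":
        return PhantomSpec(
            n_sections=n_sections or 260, landmark_design="pairwise", **common
        )
    if study == "liver":
        return PhantomSpec(
            n_sections=n_sections or 47, landmark_design="columns", **common
        )
    raise ValueError(f"unknown study {study!r}")


def count_annotations(landmarks: LandmarkSet) -> int:
    """Number of manually annotated landmarks, counted as in the studies.

    A pairwise-style landmark is one correspondence per (section pair,
    point, observer); a column-style landmark is one mark per (section,
    point, observer). Ground-truth records (observer 0) are not counted.
    """
    df = landmarks.df[landmarks.df["observer"] >= 1]
    pairwise = df[df["pair"].notna()]
    columns = df[df["pair"].isna()]
    n = 0
    if len(pairwise):
        n += len(pairwise.groupby(["pair", "point_id", "observer"]))
    if len(columns):
        n += len(columns.groupby(["section", "point_id", "observer"]))
    return n
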