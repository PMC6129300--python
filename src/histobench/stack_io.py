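"""Section-stack I/O, tissue segmentation and landmark image coding.

A *section stack* is an ordered series of 2D images (RGB tissue sections,
binary tissue masks, or RGB landmark images) cut from one sample, together
with the pixel size (µm/pixel) and the physical spacing between sections
(µm). Landmark positions can be represented either as coordinate tables or
as images carrying one colored disk per landmark; because color survives
resampling, landmark images let transforms estimated by any registration
tool be evaluated even when the tool cannot map coordinates directly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.color import rgb2hsv
from skimage.draw import disk as draw_disk
from skimage.filters import threshold_otsu
from skimage.measure import block_reduce
from skimage.morphology import closing, disk, remove_small_holes, remove_small_objects

from .exceptions import EncodingError, OrderingError

__all__ = [
    "SectionStack",
    "LandmarkSet",
    "LandmarkColorMap",
    "read_stack",
    "write_stack",
    "to_gray",
    "segment_tissue",
    "downsample_stack",
    "encode_landmarks",
    "decode_landmarks",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SectionStack:
    """Ordered series of 2D section images with physical metadata.

    ``images`` may differ in shape between sections but must share dtype and
    channel layout. ``pixel_size`` is µm/pixel in-plane, ``section_spacing``
    the µm step between adjacent sections (section thickness).
    """

    images: list[np.ndarray]
    pixel_size: float = 1.0
    section_spacing: float = 1.0

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise ValueError("a section stack needs at least 2 sections")
        if self.pixel_size <= 0 or self.section_spacing <= 0:
            raise ValueError("pixel_size and section_spacing must be positive")
        first = self.images[0]
        for im in self.images[1:]:
            if im.dtype != first.dtype or im.ndim != first.ndim:
                raise ValueError("all sections must share dtype and channel layout")

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.images[i]

    @property
    def n_sections(self) -> int:
        return len(self.images)

    @property
    def shapes(self) -> list[tuple[int, int]]:
        return [im.shape[:2] for im in self.images]

    def map(self, fn) -> "SectionStack":
        return SectionStack(
            [fn(im) for im in self.images],
            pixel_size=self.pixel_size,
            section_spacing=self.section_spacing,
        )


LANDMARK_COLUMNS = ["section", "point_id", "observer", "x", "y", "pair"]


@dataclass
class LandmarkSet:
    """Per-section 2D landmark records.

    Backed by a DataFrame with columns ``section`` (0-based section index),
    ``point_id``, ``observer``, ``x``, ``y`` (pixels) and ``pair``: for
    pairwise-style annotations (bisected-nuclei design) ``pair`` is the index
    of the lower section of the adjacent pair sharing the correspondence and
    each (pair, point_id, observer) appears on exactly the two consecutive
    sections; for column-style annotations (fiducial-hole design) ``pair`` is
    NaN and each point_id appears on every section.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LANDMARK_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"landmark table missing columns {missing}")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[dict]) -> "LandmarkSet":
        df = pd.DataFrame.from_records(records)
        if "pair" not in df.columns:
            df["pair"] = np.nan
        if "observer" not in df.columns:
            df["observer"] = 1
        return cls(df[LANDMARK_COLUMNS])

    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_pairwise(self) -> bool:
        return bool(self.df["pair"].notna().any())

    @property
    def observers(self) -> list[int]:
        return sorted(self.df["observer"].unique())

    def for_observer(self, observer: int) -> "LandmarkSet":
        return LandmarkSet(self.df[self.df["observer"] == observer].copy())

    def for_section(self, section: int) -> pd.DataFrame:
        return self.df[self.df["section"] == section]

    def points(self, section: int, pair: int | None = None) -> dict[int, np.ndarray]:
        """point_id -> (x, y) on one section, optionally one pair only."""
        sub = self.for_section(section)
        if pair is not None:
            sub = sub[sub["pair"] == pair]
        return {int(r.point_id): np.array([r.x, r.y]) for r in sub.itertuples()}

    def transformed(self, transforms) -> "LandmarkSet":
        """Map coordinates through per-section transforms (list or dict)."""
        df = self.df.copy()
        for sec, grp in df.groupby("section"):
            tf = transforms[int(sec)]
            xy = tf.apply(grp[["x", "y"]].to_numpy(float))
            df.loc[grp.index, ["x", "y"]] = np.atleast_2d(xy)
        return LandmarkSet(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        if "pair" not in df.columns:
            df["pair"] = np.nan
        if "observer" not in df.columns:
            df["observer"] = 1
        return cls(df[LANDMARK_COLUMNS])


_DEFAULT_COLORS = {
    1: (255, 0, 0),       # red
    2: (0, 255, 0),       # green
    3: (0, 0, 255),       # blue
    4: (255, 255, 0),     # yellow
}


@dataclass
class LandmarkColorMap:
    """Assignment of point ids to disk colors for landmark images."""

    colors: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_COLORS)
    )
    disk_radius: int = 5
    # accepted pixel-to-color distance, as a fraction of the minimum pairwise
    # inter-color distance; blurred disk borders fall outside this ball
    tolerance_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.disk_radius < 1:
            raise ValueError("disk_radius must be >= 1")
        arr = np.array(list(self.colors.values()), dtype=float)
        if len(arr) >= 2:
            d = np.linalg.norm(arr[:, None] - arr[None, :], axis=-1)
            self._min_dist = float(d[d > 0].min())
            if self._min_dist < 1.0:
                raise ValueError("colormap colors must be pairwise distinct")
        else:
            self._min_dist = 255.0

    @property
    def tolerance(self) -> float:
        return self.tolerance_fraction * self._min_dist


# ---------------------------------------------------------------------------
# reading / writing

_TRAILING_INT = re.compile(r"(\d+)$")


def _section_index(path: Path) -> int:
    m = _TRAILING_INT.search(path.stem)
    if m is None:
        raise OrderingError(f"no trailing section number in {path.name!r}")
    return int(m.group(1))


def read_stack(
    path_pattern,
    pixel_size: float = 1.0,
    section_spacing: float = 1.0,
) -> SectionStack:
    """Read per-section TIFFs into a stack, ordered by trailing file number.

    ``path_pattern`` is a directory (all .tif/.tiff inside) or a glob.
    Section numbers must be unique and gap-free; anything else raises
    :class:`OrderingError` rather than silently reordering.
    """
    p = Path(path_pattern)
    if p.is_dir():
        files = sorted(list(p.glob("*.tif")) + list(p.glob("*.tiff")))
    else:
        files = sorted(p.parent.glob(p.name))
    if not files:
        raise OrderingError(f"no section files match {path_pattern!r}")
    indexed = sorted((_section_index(f), f) for f in files)
    indices = [i for i, _ in indexed]
    if len(set(indices)) != len(indices):
        raise OrderingError(f"duplicate section numbers in {path_pattern!r}")
    lo, hi = indices[0], indices[-1]
    if indices != list(range(lo, hi + 1)):
        missing = sorted(set(range(lo, hi + 1)) - set(indices))
        raise OrderingError(f"missing section numbers {missing}")
    images = [tifffile.imread(f) for _, f in indexed]
    return SectionStack(images, pixel_size=pixel_size, section_spacing=section_spacing)


def write_stack(stack: SectionStack, directory, prefix: str = "sec") -> list[Path]:
    """Write one TIFF per section with zero-padded numeric suffixes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(stack.n_sections)))
    paths = []
    for i, im in enumerate(stack.images, start=1):
        out = im.astype(np.uint8) * 255 if im.dtype == bool else im
        path = directory / f"{prefix}_{i:0{width}d}.tif"
        tifffile.imwrite(path, out)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# preprocessing

# ITU-R 601 luma weights; every module converts RGB to gray through here
_LUMA = np.array([0.299, 0.587, 0.114])


def to_gray(image: np.ndarray) -> np.ndarray:
    """RGB -> float grayscale via ITU-R 601 luma; grayscale passes through."""
    if image.ndim == 2:
        return image.astype(float)
    return image[..., :3].astype(float) @ _LUMA


def segment_tissue(
    image: np.ndarray,
    min_object_area: int = 64,
    max_hole_area: int = 64,
    closing_radius: int = 2,
) -> np.ndarray:
    """Segment tissue (foreground) from a bright background.

    HE-style sections on a white background are segmented by combining an
    Otsu threshold on the HSV saturation channel with an inverted-luminance
    Otsu threshold, then tidied by morphological closing, small-object
    removal and pinhole filling. Binary input is treated as an
    already-thresholded intensity image (nonzero = tissue), making the
    operation idempotent on its own output.
    """
    if image.ndim == 2:
        raw = image > 0 if image.dtype == bool else image > (image.max() / 2 if image.max() else 0)
    else:
        img = image[..., :3]
        sat = rgb2hsv(img)[..., 1]
        gray = to_gray(img)
        try:
            raw = (sat > threshold_otsu(sat)) | (gray < threshold_otsu(gray))
        except ValueError:  # constant image, no threshold exists
            warnings.warn("blank image: no foreground found", stacklevel=2)
            return np.zeros(image.shape[:2], dtype=bool)
    if not raw.any():
        warnings.warn("empty tissue mask after thresholding", stacklevel=2)
        return np.zeros(image.shape[:2], dtype=bool)
    mask = closing(raw, disk(closing_radius))
    mask = remove_small_objects(mask, max_size=min_object_area - 1)
    mask = remove_small_holes(mask, max_size=max_hole_area - 1)
    if not mask.any():
        warnings.warn("empty tissue mask after cleanup", stacklevel=2)
    return mask


def downsample_stack(stack: SectionStack, factor: int) -> SectionStack:
    """Downsample every section by an integer factor.

    Intensity images are reduced by block averaging (anti-aliasing for
    integer factors); binary masks by block area-majority voting. The pixel
    size is multiplied by the factor; section spacing is unchanged.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return SectionStack(
            [im.copy() for im in stack.images],
            pixel_size=stack.pixel_size,
            section_spacing=stack.section_spacing,
        )
    for h, w in stack.shapes:
        if factor > min(h, w):
            raise ValueError(
                f"factor {factor} exceeds image extent {min(h, w)}"
            )

    def _reduce(im: np.ndarray) -> np.ndarray:
        if im.dtype == bool:
            return block_reduce(im.astype(float), (factor, factor), np.mean) > 0.5
        block = (factor, factor) + (1,) * (im.ndim - 2)
        mean = block_reduce(im.astype(float), block, np.mean)
        if np.issubdtype(im.dtype, np.integer):
            return np.clip(np.rint(mean), 0, np.iinfo(im.dtype).max).astype(im.dtype)
        return mean.astype(im.dtype)

    return SectionStack(
        [_reduce(im) for im in stack.images],
        pixel_size=stack.pixel_size * factor,
        section_spacing=stack.section_spacing,
    )


# ---------------------------------------------------------------------------
# landmark image coding


def encode_landmarks(
    landmarks: LandmarkSet,
    image_shape: tuple[int, int],
    colormap: LandmarkColorMap | None = None,
    n_sections: int | None = None,
    pixel_size: float = 1.0,
    section_spacing: float = 1.0,
) -> SectionStack:
    """Rasterize landmarks as solid colored disks on black RGB sections.

    One disk per (section, point_id), colored by the colormap. Raises
    :class:`EncodingError` if two disks on a section would overlap (their
    centroids could merge after decoding) or if a disk extends outside the
    image, and ValueError on a point_id without a color.
    """
    cm = colormap or LandmarkColorMap()
    h, w = image_shape
    if n_sections is None:
        n_sections = int(landmarks.df["section"].max()) + 1 if len(landmarks) else 0
    images = []
    for sec in range(n_sections):
        img = np.zeros((h, w, 3), dtype=np.uint8)
        rows = landmarks.for_section(sec)
        if rows["point_id"].duplicated().any():
            raise EncodingError(f"duplicate point_id on section {sec}")
        pts = rows[["x", "y"]].to_numpy(float)
        if len(pts) >= 2:
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() <= 2 * cm.disk_radius:
                raise EncodingError(
                    f"landmark disks overlap on section {sec} "
                    f"(min center distance {d.min():.1f} px, radius {cm.disk_radius})"
                )
        for r in rows.itertuples():
            pid = int(r.point_id)
            if pid not in cm.colors:
                raise ValueError(f"no color for point_id {pid}")
            if not (
                cm.disk_radius <= r.x <= w - 1 - cm.disk_radius
                and cm.disk_radius <= r.y <= h - 1 - cm.disk_radius
            ):
                raise EncodingError(
                    f"disk for point {pid} on section {sec} exceeds image bounds"
                )
            rr, cc = draw_disk((r.y, r.x), cm.disk_radius + 0.5, shape=(h, w))
            img[rr, cc] = cm.colors[pid]
        images.append(img)
    return SectionStack(images, pixel_size=pixel_size, section_spacing=section_spacing)


def decode_landmarks(
    landmark_stack: SectionStack,
    colormap: LandmarkColorMap | None = None,
    observer: int = 1,
    min_pixels: int = 5,
) -> LandmarkSet:
    """Recover landmark coordinates as centroids of color-classified pixels.

    Each non-background pixel is assigned to the nearest colormap color if
    its RGB distance is below the colormap tolerance; interpolation-blurred
    disk borders fall outside every tolerance ball and are ignored. A color
    with fewer than ``min_pixels`` accepted pixels is reported missing (with
    a warning), not as a zero coordinate.
    """
    cm = colormap or LandmarkColorMap()
    palette = np.array(list(cm.colors.values()), dtype=float)
    ids = list(cm.colors.keys())
    records = []
    for sec, img in enumerate(landmark_stack.images):
        rgb = img[..., :3].astype(float)
        candidate = rgb.sum(axis=-1) > 30  # skip near-black background fast
        ys, xs = np.nonzero(candidate)
        if len(xs) == 0:
            continue
        pix = rgb[ys, xs]
        dists = np.linalg.norm(pix[:, None, :] - palette[None, :, :], axis=-1)
        nearest = dists.argmin(axis=1)
        accepted = dists[np.arange(len(pix)), nearest] < cm.tolerance
        for k, pid in enumerate(ids):
            sel = accepted & (nearest == k)
            if sel.sum() < min_pixels:
                if sel.sum() > 0:
                    warnings.warn(
                        f"landmark {pid} on section {sec}: only {int(sel.sum())} "
                        f"pixels classified, reported missing",
                        stacklevel=2,
                    )
                continue
            records.append(
                dict(
                    section=sec,
                    point_id=pid,
                    observer=observer,
                    x=float(xs[sel].mean()),
                    y=float(ys[sel].mean()),
                    pair=np.nan,
                )
            )
    if not records:
        return LandmarkSet(pd.DataFrame(columns=LANDMARK_COLUMNS))
    return LandmarkSet.from_records(records)


def encode_pairwise_landmarks(
    landmarks: LandmarkSet,
    image_shape: tuple[int, int],
    colormap: LandmarkColorMap | None = None,
    n_sections: int | None = None,
    **kwargs,
) -> tuple[SectionStack, SectionStack]:
    """Encode pairwise-linked landmarks as two disk-image stacks.

    With four colors but up to eight points per section (a section shares
    correspondences with both neighbors), pairwise annotations are split into
    a *lower* stack, where section i carries the points it shares with
    section i+1 (pair == i), and an *upper* stack, where section i carries
    the points shared with section i-1 (pair == i-1).
    """
    if n_sections is None:
        n_sections = int(landmarks.df["section"].max()) + 1
    df = landmarks.df
    lower = LandmarkSet(df[df["pair"] == df["section"]].copy())
    upper = LandmarkSet(df[df["pair"] == df["section"] - 1].copy())
    enc = lambda ls: encode_landmarks(
        ls, image_shape, colormap, n_sections=n_sections, **kwargs
    )
    return enc(lower), enc(upper)


def decode_pairwise_landmarks(
    lower_stack: SectionStack,
    upper_stack: SectionStack,
    colormap: LandmarkColorMap | None = None,
    observer: int = 1,
    **kwargs,
) -> LandmarkSet:
    """Inverse of :func:`encode_pairwise_landmarks`, restoring pair linkage."""
    lo = decode_landmarks(lower_stack, colormap, observer=observer, **kwargs).df
    up = decode_landmarks(upper_stack, colormap, observer=observer, **kwargs).df
    lo["pair"] = lo["section"]
    up["pair"] = up["section"] - 1
    return LandmarkSet(pd.concat([lo, up], ignore_index=True))
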