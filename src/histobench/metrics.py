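"""Reconstruction-accuracy metrics for registered serial-section stacks.

The panel combines direct landmark-based errors with indirect image-based
measures:

* **TRE** — pairwise target registration error: the Euclidean distance, in
  µm, between corresponding landmarks on adjacent sections.
* **ATRE** — accumulated TRE, quantifying low-frequency drift ("the banana
  problem") in two variants: the norm of the cumulative sum of per-pair mean
  displacement vectors (for pairwise annotations), and the in-plane
  deviation of through-stack fiducial trajectories from 3D lines fitted by
  least squares (for fiducial-column annotations).
* **Jaccard** and **ΔA-%** — tissue-mask overlap per pair, and relative
  change in tissue area per section introduced by resampling.
* **Pixel-wise similarity** — RMSE, NCC (Pearson), MI and NMI of grayscale
  intensities over the overlapping tissue pixels of each pair.
* **GLCM smoothness** — Haralick contrast (f2) and correlation (f3) of a
  single gray-level co-occurrence matrix summed over all section pairs,
  pairing the intensity at each overlap pixel with the intensity at the same
  position on the next section. Low f2 / high f3 indicate a smooth volume.

TRE and ATRE are reported in physical units so they are comparable across
image resolutions; pixel-wise and GLCM metrics are resolution- and
content-dependent by nature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CanvasError, DegenerateInputError
from .stack_io import LandmarkSet

__all__ = [
    "MetricSeries",
    "GlcmAccumulator",
    "tre_pair",
    "pairwise_tre",
    "atre_cumulative",
    "atre_linefit",
    "jaccard",
    "delta_area",
    "pixel_similarity",
    "glcm_accumulate",
    "glcm_features",
    "summarize",
]


@dataclass
class MetricSeries:
    """A named per-pair or per-section metric series with µ/max/σ summary."""

    name: str
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values.size else np.nan

    @property
    def max(self) -> float:
        return float(np.max(self.values)) if self.values.size else np.nan

    @property
    def std(self) -> float:
        # sample standard deviation; a single observation has no spread
        if self.values.size == 0:
            return np.nan
        if self.values.size == 1:
            return 0.0
        return float(np.std(self.values, ddof=1))

    def summary(self) -> dict[str, float]:
        return {"mean": self.mean, "max": self.max, "std": self.std}


# ---------------------------------------------------------------------------
# landmark-based errors


def tre_pair(
    points_a: dict[int, np.ndarray],
    points_b: dict[int, np.ndarray],
    pixel_size: float = 1.0,
) -> dict[int, float]:
    """Distances (µm) between matching point ids of one section pair."""
    common = sorted(set(points_a) & set(points_b))
    if not common:
        raise DegenerateInputError("no matched landmarks on this section pair")
    return {
        j: float(np.linalg.norm(points_a[j] - points_b[j])) * pixel_size
        for j in common
    }


def _pair_points(landmarks: LandmarkSet, i: int):
    """Matched points of pair (i, i+1): pair-linked if present, else by id."""
    if landmarks.is_pairwise:
        a = landmarks.points(i, pair=i)
        b = landmarks.points(i + 1, pair=i)
    else:
        a = landmarks.points(i)
        b = landmarks.points(i + 1)
    return a, b


def pairwise_tre(
    landmarks: LandmarkSet,
    pixel_size: float = 1.0,
    n_sections: int | None = None,
) -> tuple[pd.DataFrame, MetricSeries]:
    """Pairwise TRE for every adjacent section pair of a single-observer set.

    Returns a long table (pair, point_id, tre_um) and a MetricSeries over all
    (pair, point) values. Points missing on either section are skipped; pairs
    with no matched points at all are skipped with a warning.
    """
    if len(landmarks.observers) > 1:
        raise ValueError("pass a single-observer LandmarkSet (use for_observer)")
    if n_sections is None:
        n_sections = int(landmarks.df["section"].max()) + 1
    rows = []
    for i in range(n_sections - 1):
        a, b = _pair_points(landmarks, i)
        common = set(a) & set(b)
        if not common:
            warnings.warn(f"no matched landmarks on pair {i}", stacklevel=2)
            continue
        for j, d in tre_pair(a, b, pixel_size).items():
            rows.append(dict(pair=i, point_id=j, tre_um=d))
    df = pd.DataFrame(rows)
    return df, MetricSeries("TRE", df["tre_um"].to_numpy() if len(df) else [], "um")


def atre_cumulative(
    landmarks: LandmarkSet,
    pixel_size: float = 1.0,
    n_sections: int | None = None,
) -> MetricSeries:
    """Cumulative-drift ATRE for pairwise-style annotations.

    For each pair i the displacement vectors X_{j,i} - X_{j,i+1} of the
    matched landmarks are averaged into one mean displacement per section
    pair; ATRE_k is the Euclidean norm (µm) of the running sum of these mean
    vectors from pair 1 to k. Consistent drift accumulates linearly while
    independent errors cancel.
    """
    if len(landmarks.observers) > 1:
        raise ValueError("pass a single-observer LandmarkSet")
    if n_sections is None:
        n_sections = int(landmarks.df["section"].max()) + 1
    means = []
    for i in range(n_sections - 1):
        a, b = _pair_points(landmarks, i)
        common = sorted(set(a) & set(b))
        if not common:
            raise DegenerateInputError(
                f"pair {i} has no matched landmarks; cumulative series breaks"
            )
        disp = np.array([a[j] - b[j] for j in common], dtype=float)
        means.append(disp.mean(axis=0))
    cumulative = np.cumsum(np.array(means), axis=0)
    atre = np.linalg.norm(cumulative, axis=1) * pixel_size
    return MetricSeries("ATRE", atre, "um")


def atre_linefit(
    landmarks: LandmarkSet,
    pixel_size: float = 1.0,
) -> tuple[pd.DataFrame, MetricSeries]:
    """Line-fit ATRE for through-stack fiducial columns.

    For each landmark id, x and y are regressed on section index by ordinary
    least squares — for equally spaced sections this is the 3D line
    minimizing mean squared in-plane error — and ATRE_{j,i} is the in-plane
    distance (µm) between the observed point and the fitted line at that
    section. Landmarks observed on fewer than 3 sections are excluded.
    """
    if len(landmarks.observers) > 1:
        raise ValueError("pass a single-observer LandmarkSet")
    rows = []
    for pid, grp in landmarks.df.groupby("point_id"):
        if len(grp) < 3:
            warnings.warn(
                f"landmark {pid} on only {len(grp)} sections; excluded",
                stacklevel=2,
            )
            continue
        z = grp["section"].to_numpy(float)
        fitted = np.empty((len(grp), 2))
        for k, col in enumerate(("x", "y")):
            coef = np.polyfit(z, grp[col].to_numpy(float), 1)
            fitted[:, k] = np.polyval(coef, z)
        resid = grp[["x", "y"]].to_numpy(float) - fitted
        dist = np.linalg.norm(resid, axis=1) * pixel_size
        for sec, d in zip(grp["section"], dist):
            rows.append(dict(section=int(sec), point_id=int(pid), atre_um=float(d)))
    df = pd.DataFrame(rows)
    return df, MetricSeries(
        "ATRE", df["atre_um"].to_numpy() if len(df) else [], "um"
    )


# ---------------------------------------------------------------------------
# mask-based metrics


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two equal-shape binary masks."""
    if mask_a.shape != mask_b.shape:
        raise CanvasError(
            f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}"
        )
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("both masks empty; Jaccard defined as 0", stacklevel=2)
        return 0.0
    return np.count_nonzero(a & b) / union


def delta_area(
    mask_original: np.ndarray,
    mask_registered: np.ndarray,
    pixel_size_original: float = 1.0,
    pixel_size_registered: float | None = None,
) -> float:
    """Relative change in tissue area, percent, in physical units.

    Areas are pixel counts times pixel area so the measure is comparable
    across resolutions. Returns NaN (reported missing) for an empty
    original mask.
    """
    if pixel_size_registered is None:
        pixel_size_registered = pixel_size_original
    a0 = np.count_nonzero(mask_original) * pixel_size_original**2
    a1 = np.count_nonzero(mask_registered) * pixel_size_registered**2
    if a0 == 0:
        warnings.warn("empty original mask; delta-area undefined", stacklevel=2)
        return np.nan
    return (a1 - a0) / a0 * 100.0


# ---------------------------------------------------------------------------
# pixel-wise similarity


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def pixel_similarity(
    gray_a: np.ndarray,
    gray_b: np.ndarray,
    overlap_mask: np.ndarray,
    bins: int = 64,
) -> dict[str, float]:
    """RMSE, NCC, MI and NMI of two grayscale sections over their overlap.

    MI and NMI use a joint histogram with ``bins`` equal-width bins spanning
    the shared intensity range of the two overlap samples; MI is in bits and
    NMI is Studholme's (H(a)+H(b))/H(a,b) in [1, 2]. An empty overlap leaves
    all four undefined (NaN) — pixel-wise similarity of barely overlapping
    sections is not meaningful.
    """
    if not (gray_a.shape == gray_b.shape == overlap_mask.shape):
        raise CanvasError("images and overlap mask must share one canvas")
    sel = overlap_mask.astype(bool)
    if not sel.any():
        warnings.warn("empty overlap; pixel-wise metrics undefined", stacklevel=2)
        return {"RMSE": np.nan, "NCC": np.nan, "MI": np.nan, "NMI": np.nan}
    a = gray_a[sel].astype(float)
    b = gray_b[sel].astype(float)
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if a.std() == 0 or b.std() == 0:
        ncc = np.nan
    else:
        ncc = float(np.corrcoef(a, b)[0, 1])
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    pj = joint / joint.sum()
    ha = _entropy(pj.sum(axis=1))
    hb = _entropy(pj.sum(axis=0))
    hab = _entropy(pj.ravel())
    mi = ha + hb - hab
    nmi = (ha + hb) / hab if hab > 0 else np.nan
    return {"RMSE": rmse, "NCC": ncc, "MI": float(mi), "NMI": float(nmi)}


# ---------------------------------------------------------------------------
# GLCM smoothness


@dataclass
class GlcmAccumulator:
    """Gray-level co-occurrence counts summed over all section pairs.

    The co-occurring pair is (level at pixel p on section i, level at the
    same pixel on section i+1) over the overlapping tissue pixels — an
    across-section offset that probes smoothness of the reconstructed
    volume. ``value_range`` fixes the quantization so every pair contributes
    on the same level grid.
    """

    levels: int = 32
    value_range: tuple[float, float] = (0.0, 255.0)
    counts: np.ndarray = field(default=None)
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros((self.levels, self.levels), dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def quantize(self, gray: np.ndarray) -> np.ndarray:
        lo, hi = self.value_range
        q = np.floor((np.asarray(gray, float) - lo) / (hi - lo) * self.levels)
        return np.clip(q, 0, self.levels - 1).astype(np.intp)


def glcm_accumulate(
    gray_a: np.ndarray,
    gray_b: np.ndarray,
    overlap_mask: np.ndarray,
    accumulator: GlcmAccumulator | None = None,
) -> GlcmAccumulator:
    """Add one section pair's co-occurrence counts to the accumulator."""
    if accumulator is None:
        accumulator = GlcmAccumulator()
    if not (gray_a.shape == gray_b.shape == overlap_mask.shape):
        raise CanvasError("images and overlap mask must share one canvas")
    sel = overlap_mask.astype(bool)
    la = accumulator.quantize(gray_a[sel])
    lb = accumulator.quantize(gray_b[sel])
    np.add.at(accumulator.counts, (la, lb), 1)
    accumulator.n_pairs += 1
    return accumulator


def glcm_features(accumulator: GlcmAccumulator) -> dict[str, float]:
    """Haralick contrast f2 and correlation f3 of the accumulated GLCM."""
    if accumulator.total == 0:
        raise DegenerateInputError("empty GLCM accumulator")
    p = accumulator.counts / accumulator.total
    idx = np.arange(accumulator.levels, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    f2 = float(((i - j) ** 2 * p).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i == 0 or var_j == 0:
        warnings.warn("zero-variance GLCM marginal; f3 undefined", stacklevel=2)
        f3 = np.nan
    else:
        f3 = float((((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j))
    return {"f2": f2, "f3": f3}


# ---------------------------------------------------------------------------
# summary tables


def summarize(reports: list[dict]) -> pd.DataFrame:
    """Build a benchmark summary table, one row per method x resolution.

    Each report is a dict with keys ``method``, ``resolution`` (or any other
    identifying fields), MetricSeries values (expanded to mean/max/std
    columns) and plain scalars (kept as-is).
    """
    rows = []
    for rep in reports:
        row: dict = {}
        for key, val in rep.items():
            if isinstance(val, MetricSeries):
                s = val.summary()
                row[f"{key}_mean"] = s["mean"]
                row[f"{key}_max"] = s["max"]
                row[f"{key}_std"] = s["std"]
            else:
                row[key] = val
        rows.append(row)
    return pd.DataFrame(rows)
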