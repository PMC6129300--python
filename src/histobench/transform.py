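"""2D planar transforms and stack alignments.

Coordinate convention (shared by every module): points are (x, y) with
x = column, y = row, 0-based, pixel centers at integer coordinates.
A transform maps points from a source frame into a destination frame via
``p' = A p + t`` where ``A`` is the 2x2 linear part and ``t`` the translation
in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform

__all__ = ["PlanarTransform", "StackAlignment"]

_DET_EPS = 1e-8
_RIGID_TOL = 1e-6


@dataclass(frozen=True)
class PlanarTransform:
    """A 2D affine map stored as a 2x3 matrix (linear part | translation).

    ``model`` is either ``"affine"`` or ``"rigid"``; a rigid transform must
    have an orthogonal linear part with determinant +1 (rotation, no
    reflection or scaling).
    """

    matrix: np.ndarray
    model: str = "affine"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"transform matrix must be 2x3, got {m.shape}")
        object.__setattr__(self, "matrix", m)
        det = np.linalg.det(m[:, :2])
        if abs(det) < _DET_EPS:
            raise ValueError(f"singular linear part (|det| = {abs(det):.2e})")
        if self.model == "rigid":
            a = m[:, :2]
            if not np.allclose(a.T @ a, np.eye(2), atol=_RIGID_TOL) or det < 0:
                raise ValueError("rigid model requires an orthogonal linear "
                                 "part with determinant +1")
        elif self.model != "affine":
            raise ValueError(f"unknown transform model {self.model!r}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls, model: str = "affine") -> "PlanarTransform":
        return cls(np.hstack([np.eye(2), np.zeros((2, 1))]), model=model)

    @classmethod
    def from_params(
        cls,
        tx: float = 0.0,
        ty: float = 0.0,
        rotation_deg: float = 0.0,
        scale: tuple[float, float] = (1.0, 1.0),
        shear: float = 0.0,
        center: tuple[float, float] = (0.0, 0.0),
        model: str | None = None,
    ) -> "PlanarTransform":
        """Build rotation/scale/shear about ``center`` plus translation.

        The linear part is ``R(rotation) @ [[sx, shear], [0, sy]]`` applied
        about ``center``; (tx, ty) is added afterwards.
        """
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lin = rot @ np.array([[scale[0], shear], [0.0, scale[1]]])
        c = np.asarray(center, dtype=float)
        t = c - lin @ c + np.array([tx, ty], dtype=float)
        if model is None:
            pure_rigid = scale == (1.0, 1.0) and shear == 0.0
            model = "rigid" if pure_rigid else "affine"
        return cls(np.column_stack([lin, t]), model=model)

    @classmethod
    def from_skimage(cls, tform: AffineTransform) -> "PlanarTransform":
        return cls(np.asarray(tform.params)[:2, :])

    # -- algebra -----------------------------------------------------------

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points (a single point is fine)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + self.translation
        return out[0] if np.ndim(points) == 1 else out

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        lin = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        model = "rigid" if self.model == other.model == "rigid" else "affine"
        return PlanarTransform(np.column_stack([lin, t]), model=model)

    def __matmul__(self, other: "PlanarTransform") -> "PlanarTransform":
        return self.compose(other)

    def inverse(self) -> "PlanarTransform":
        inv = np.linalg.inv(self.linear)
        return PlanarTransform(
            np.column_stack([inv, -inv @ self.translation]), model=self.model
        )

    def as_skimage(self) -> AffineTransform:
        params = np.vstack([self.matrix, [0.0, 0.0, 1.0]])
        return AffineTransform(matrix=params)

    def almost_equals(self, other: "PlanarTransform", atol: float = 1e-9) -> bool:
        return np.allclose(self.matrix, other.matrix, atol=atol)


@dataclass
class StackAlignment:
    """Per-section transforms mapping each section into a reference frame.

    ``transforms[i]`` maps coordinates of section ``i`` into the frame of the
    reference section; the transform at ``reference_index`` is the identity.
    ``pair_failures`` records indices of adjacent pairs whose pairwise
    estimation failed (and fell back to identity).
    """

    transforms: list[PlanarTransform]
    reference_index: int = 0
    pair_failures: list[int] = field(default_factory=list)
    failure_flag: bool = False

    def __post_init__(self) -> None:
        n = len(self.transforms)
        if n < 1:
            raise ValueError("alignment needs at least one transform")
        if not 0 <= self.reference_index < n:
            raise ValueError("reference_index out of range")
        ref = self.transforms[self.reference_index]
        if not ref.almost_equals(PlanarTransform.identity(), atol=1e-6):
            raise ValueError("transform at reference_index must be identity")

    def __len__(self) -> int:
        return len(self.transforms)

    def canvas(self, shapes: list[tuple[int, int]]) -> tuple[tuple[int, int], np.ndarray]:
        """Tight common bounding box of all transformed section extents.

        ``shapes`` are (rows, cols) per section. Returns ``(canvas_shape,
        offset)`` where ``offset`` is the (x, y) of the canvas origin in the
        reference frame, so canvas coords = reference coords - offset.
        """
        lo = np.array([np.inf, np.inf])
        hi = np.array([-np.inf, -np.inf])
        for (h, w), tf in zip(shapes, self.transforms, strict=True):
            corners = np.array(
                [[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float
            )
            mapped = tf.apply(corners)
            lo = np.minimum(lo, mapped.min(axis=0))
            hi = np.maximum(hi, mapped.max(axis=0))
        offset = np.floor(lo)
        extent = np.ceil(hi) - offset + 1
        return (int(extent[1]), int(extent[0])), offset
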