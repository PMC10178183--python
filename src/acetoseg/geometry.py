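"""Projective alignment of before/after colposcopic image pairs.

The before-acetic-acid image is related to the after-acetic-acid image by a
plane projective transformation (homography): the cervix is treated as
approximately planar and only the camera pose changes between the two
exposures.  The homography is estimated from >= 4 manually (or, for synthetic
data, programmatically) identified corresponding points by the normalized
direct linear transform (DLT), and the before-image is then warped into the
after-image frame by inverse mapping.

Coordinate convention: 0-based, x rightward (column), y downward (row),
pixel centers at integer coordinates.  Homographies map before -> after.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import skimage.transform

from .errors import DegeneracyError, ParseError, ValidationError

__all__ = [
    "PointPair",
    "CorrespondenceSet",
    "ProjectiveTransform",
    "estimate_homography",
    "reprojection_residuals",
    "apply_transform",
    "warp_image",
    "read_correspondences",
    "write_correspondences",
]

#: |w| below this in a homogeneous perspective divide is treated as the
#: vanishing line.
_W_EPS = 1e-12


@dataclass(frozen=True)
class PointPair:
    """One corresponding point: the same anatomical location in both images."""

    before_xy: tuple[float, float]
    after_xy: tuple[float, float]
    label: int = 0

    def __post_init__(self):
        for name in ("before_xy", "after_xy"):
            xy = getattr(self, name)
            if len(xy) != 2 or not all(np.isfinite(v) for v in xy):
                raise ValidationError(f"{name} must be two finite numbers, got {xy!r}")
        object.__setattr__(self, "before_xy", (float(self.before_xy[0]), float(self.before_xy[1])))
        object.__setattr__(self, "after_xy", (float(self.after_xy[0]), float(self.after_xy[1])))


def _collinear(p: np.ndarray, q: np.ndarray, r: np.ndarray, tol: float = 1e-9) -> bool:
    # area of the triangle relative to its squared extent
    area2 = abs((q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0]))
    scale = max(np.abs(np.stack([q - p, r - p])).max(), 1.0)
    return area2 <= tol * scale * scale


@dataclass(frozen=True)
class CorrespondenceSet:
    """An ordered set of >= 4 point pairs for one case."""

    pairs: tuple[PointPair, ...]
    case_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if len(self.pairs) < 4:
            raise ValidationError(
                f"need at least 4 point pairs, got {len(self.pairs)}"
            )
        for name in ("before_xy", "after_xy"):
            seen: dict[tuple[float, float], int] = {}
            for pair in self.pairs:
                xy = getattr(pair, name)
                if xy in seen:
                    raise ValidationError(
                        f"duplicate {name} point {xy} (labels {seen[xy]} and {pair.label})"
                    )
                seen[xy] = pair.label
        first4 = np.array([p.after_xy for p in self.pairs[:4]])
        labels4 = [p.label for p in self.pairs[:4]]
        for i in range(4):
            for j in range(i + 1, 4):
                for k in range(j + 1, 4):
                    if _collinear(first4[i], first4[j], first4[k]):
                        raise DegeneracyError(
                            "three of the first four after-image points are "
                            f"collinear (labels {labels4[i]}, {labels4[j]}, {labels4[k]})"
                        )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def before_points(self) -> np.ndarray:
        return np.array([p.before_xy for p in self.pairs], dtype=float)

    @property
    def after_points(self) -> np.ndarray:
        return np.array([p.after_xy for p in self.pairs], dtype=float)


def _normalize_matrix(matrix: np.ndarray) -> np.ndarray:
    """Canonical form: h33 = 1 when |h33| > 1e-8, else unit Frobenius norm."""
    matrix = np.asarray(matrix, dtype=float)
    if abs(matrix[2, 2]) > 1e-8:
        return matrix / matrix[2, 2]
    return matrix / np.linalg.norm(matrix)


@dataclass(frozen=True)
class ProjectiveTransform:
    """A 3x3 homogeneous homography mapping before-image -> after-image."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or not np.all(np.isfinite(m)):
            raise ValidationError("homography must be a finite 3x3 matrix")
        if abs(np.linalg.det(m)) <= 1e-12 * max(np.linalg.norm(m) ** 3, 1e-30):
            raise DegeneracyError("homography matrix is singular")
        object.__setattr__(self, "matrix", _normalize_matrix(m))
        self.matrix.setflags(write=False)

    @classmethod
    def identity(cls) -> "ProjectiveTransform":
        return cls(np.eye(3))

    @classmethod
    def from_translation(cls, tx: float, ty: float) -> "ProjectiveTransform":
        m = np.eye(3)
        m[0, 2], m[1, 2] = tx, ty
        return cls(m)

    def inverse(self) -> "ProjectiveTransform":
        return ProjectiveTransform(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "ProjectiveTransform") -> "ProjectiveTransform":
        return ProjectiveTransform(self.matrix @ other.matrix)


def _hartley_normalization(points: np.ndarray) -> np.ndarray:
    """Similarity transform taking the centroid to the origin and the mean
    distance from it to sqrt(2)."""
    centroid = points.mean(axis=0)
    mean_dist = np.mean(np.linalg.norm(points - centroid, axis=1))
    scale = np.sqrt(2) / mean_dist if mean_dist > 0 else 1.0
    T = np.array(
        [[scale, 0, -scale * centroid[0]],
         [0, scale, -scale * centroid[1]],
         [0, 0, 1.0]]
    )
    return T


def estimate_homography(correspondences: CorrespondenceSet) -> ProjectiveTransform:
    """Estimate the before->after homography by normalized DLT.

    Both point sets are Hartley-normalized, the 2N x 9 design matrix is
    assembled, and its least-squares null vector (smallest right singular
    vector) gives the homography; with exactly 4 nondegenerate noiseless
    pairs this is the exact interpolant.

    Raises
    ------
    ValidationError
        Fewer than 4 pairs (raised when the set is built).
    DegeneracyError
        Rank-deficient design matrix (degenerate point geometry).
    """
    src = correspondences.before_points
    dst = correspondences.after_points
    T_src = _hartley_normalization(src)
    T_dst = _hartley_normalization(dst)
    src_h = np.column_stack([src, np.ones(len(src))]) @ T_src.T
    dst_h = np.column_stack([dst, np.ones(len(dst))]) @ T_dst.T

    n = len(src)
    A = np.zeros((2 * n, 9))
    x, y = src_h[:, 0], src_h[:, 1]
    u, v = dst_h[:, 0], dst_h[:, 1]
    A[0::2, 0], A[0::2, 1], A[0::2, 2] = -x, -y, -1.0
    A[0::2, 6], A[0::2, 7], A[0::2, 8] = u * x, u * y, u
    A[1::2, 3], A[1::2, 4], A[1::2, 5] = -x, -y, -1.0
    A[1::2, 6], A[1::2, 7], A[1::2, 8] = v * x, v * y, v

    _, s, vt = np.linalg.svd(A)
    # with n >= 4 the design matrix must have rank 8 for a unique solution
    if s[7] <= 1e-9 * s[0]:
        labels = [p.label for p in correspondences.pairs]
        raise DegeneracyError(
            f"degenerate correspondence geometry (design-matrix rank < 8) "
            f"for points with labels {labels}"
        )
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(T_dst) @ Hn @ T_src
    return ProjectiveTransform(H)


def reprojection_residuals(
    correspondences: CorrespondenceSet, transform: ProjectiveTransform
) -> np.ndarray:
    """Euclidean distance, per pair, between the mapped before-point and the
    observed after-point (pixels)."""
    mapped = apply_transform(correspondences.before_points, transform)
    return np.linalg.norm(mapped - correspondences.after_points, axis=1)


def apply_transform(
    points: Sequence[tuple[float, float]] | np.ndarray,
    transform: ProjectiveTransform,
) -> np.ndarray:
    """Map (x, y) points through the homography (homogeneous multiply then
    perspective divide).  Points on the vanishing line raise DegeneracyError."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"points must have shape (n, 2), got {pts.shape}")
    homog = np.column_stack([pts, np.ones(len(pts))]) @ transform.matrix.T
    w = homog[:, 2]
    bad = np.abs(w) < _W_EPS
    if bad.any():
        raise DegeneracyError(
            f"{int(bad.sum())} point(s) map to the vanishing line (|w| < {_W_EPS})"
        )
    return homog[:, :2] / w[:, None]


def warp_image(
    image: np.ndarray,
    transform: ProjectiveTransform,
    out_shape: tuple[int, int] | None = None,
    interpolation: str = "bilinear",
    fill: float = 0,
) -> np.ndarray:
    """Warp `image` (before-frame) into the after-frame of `transform`.

    Inverse mapping: output pixel (x, y) is sampled from the input at
    H^-1 (x, y); samples outside the input get `fill`.  Use
    ``interpolation="nearest"`` for masks so they stay binary.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValidationError("cannot warp an empty image")
    if interpolation not in ("bilinear", "nearest"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "bilinear" else 0
    if out_shape is None:
        out_shape = image.shape[:2]
    # skimage's warp uses (x, y) = (col, row) homogeneous coordinates with
    # pixel centers at integers, matching this package's convention; the
    # transform passed to `warp` is the output->input map.
    inv = skimage.transform.ProjectiveTransform(
        matrix=np.linalg.inv(transform.matrix)
    )
    warped = skimage.transform.warp(
        image.astype(float),
        inv,
        output_shape=out_shape,
        order=order,
        cval=fill,
        preserve_range=True,
        mode="constant",
    )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        warped = np.clip(np.rint(warped), info.min, info.max).astype(image.dtype)
    else:
        warped = warped.astype(image.dtype)
    return warped


def read_correspondences(path: str | Path) -> CorrespondenceSet:
    """Read a plain-text correspondence file.

    One pair per line: ``label x_before y_before x_after y_after``; blank
    lines and ``#`` comments are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"correspondence file not found: {path}")
    pairs = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ParseError(
                f"expected 'label x_before y_before x_after y_after', got {raw!r}",
                lineno,
            )
        try:
            label = int(fields[0])
            xb, yb, xa, ya = (float(v) for v in fields[1:])
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
        pairs.append(PointPair(before_xy=(xb, yb), after_xy=(xa, ya), label=label))
    return CorrespondenceSet(pairs=tuple(pairs), case_id=path.parent.name)


def write_correspondences(correspondences: CorrespondenceSet, path: str | Path) -> None:
    path = Path(path)
    lines = ["# label x_before y_before x_after y_after"]
    for p in correspondences.pairs:
        lines.append(
            f"{p.label} {p.before_xy[0]:.6f} {p.before_xy[1]:.6f} "
            f"{p.after_xy[0]:.6f} {p.after_xy[1]:.6f}"
        )
    path.write_text("\n".join(lines) + "\n")
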