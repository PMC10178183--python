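"""Case packaging: downscaling, cropping, and on-disk layout.

A *case* is one colposcopy examination: the after-acetic-acid image, the
before-acetic-acid image (raw and projectively aligned to the after frame),
and a binary lesion mask (1 = acetowhite epithelium) drawn on the after
image.  On disk a case is a directory::

    <case>/after.png       RGB, after acetic acid
    <case>/before.png      RGB, before acetic acid (unaligned)
    <case>/mask.png        8-bit, values {0, 255}
    <case>/points.txt      >= 4 corresponding points (geometry module format)
    <case>/crop.txt        optional crop rectangle "x0 y0 h w"

Loading runs the alignment; masks are stored 0/255 on disk and {0, 1} in
memory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import skimage.transform

from . import geometry
from .errors import ValidationError

__all__ = [
    "CasePair",
    "downscale",
    "crop",
    "crop_case",
    "load_case",
    "save_case",
    "read_manifest",
    "write_manifest",
]


@dataclass
class CasePair:
    """One co-registered case ready for training or evaluation."""

    case_id: str
    after_img: np.ndarray
    before_img_raw: np.ndarray
    before_img_aligned: np.ndarray
    mask: np.ndarray
    crop_rect: tuple[int, int, int, int] | None = None
    points: geometry.CorrespondenceSet | None = None

    def __post_init__(self):
        a, b, m = self.after_img, self.before_img_aligned, self.mask
        if not (a.shape[:2] == b.shape[:2] == m.shape[:2]):
            raise ValidationError(
                f"after {a.shape}, aligned-before {b.shape} and mask {m.shape} "
                "must share height/width"
            )
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"mask values must be in {{0,1}}, got {vals[:10]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.after_img.shape[:2]


def downscale(image: np.ndarray, target_shape: tuple[int, int],
              is_mask: bool = False) -> np.ndarray:
    """Anti-aliased area downscaling to ``target_shape`` (h, w).

    The aspect ratio must be preserved within 1%.  Masks are resampled by
    nearest neighbour and re-binarized.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    th, tw = target_shape
    if th > h or tw > w:
        raise ValidationError(f"target {target_shape} exceeds source ({h}, {w})")
    if abs((th / h) / (tw / w) - 1.0) > 0.01:
        raise ValidationError(
            f"downscale would change aspect ratio beyond 1%: ({h},{w}) -> ({th},{tw})"
        )
    if (th, tw) == (h, w):
        return image.copy()
    if is_mask:
        out = skimage.transform.resize(
            image, (th, tw), order=0, anti_aliasing=False, preserve_range=True
        )
        return (out > 0.5).astype(image.dtype)
    out = skimage.transform.resize(
        image, (th, tw), order=1, anti_aliasing=True, preserve_range=True
    )
    if np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.rint(out), 0, np.iinfo(image.dtype).max).astype(image.dtype)
    return out


def crop(image: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    """Exact sub-raster; ``rect`` is (x0, y0, h, w) with x rightward."""
    x0, y0, h, w = rect
    H, W = image.shape[:2]
    if x0 < 0 or y0 < 0 or h < 1 or w < 1 or y0 + h > H or x0 + w > W:
        raise ValidationError(f"crop rect {rect} out of bounds for image ({H}, {W})")
    return image[y0:y0 + h, x0:x0 + w].copy()


def crop_case(case: CasePair, rect: tuple[int, int, int, int]) -> CasePair:
    """Apply the same crop rectangle to the after image, the aligned before
    image, and the mask (they share one coordinate frame)."""
    return replace(
        case,
        after_img=crop(case.after_img, rect),
        before_img_aligned=crop(case.before_img_aligned, rect),
        mask=crop(case.mask, rect),
        crop_rect=rect,
    )


def _read_image(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing case file: {path}")
    return np.asarray(iio.imread(path))


def load_case(case_dir: str | Path, align: bool = True) -> CasePair:
    """Load a case directory and run alignment of the before image."""
    case_dir = Path(case_dir)
    after = _read_image(case_dir / "after.png")
    before = _read_image(case_dir / "before.png")
    mask_raw = _read_image(case_dir / "mask.png")
    if mask_raw.ndim == 3:
        mask_raw = mask_raw[..., 0]
    bad = ~np.isin(mask_raw, (0, 255))
    if bad.any():
        raise ValidationError(
            f"{case_dir / 'mask.png'}: mask must contain only 0 and 255, "
            f"found {np.unique(mask_raw[bad])[:10]}"
        )
    mask = (mask_raw == 255).astype(np.uint8)
    points_path = case_dir / "points.txt"
    if not points_path.exists():
        raise FileNotFoundError(f"missing case file: {points_path}")
    points = geometry.read_correspondences(points_path)
    if align:
        transform = geometry.estimate_homography(points)
        aligned = geometry.warp_image(
            before, transform, out_shape=after.shape[:2], interpolation="bilinear"
        )
    else:
        aligned = before.copy()
    crop_rect = None
    crop_path = case_dir / "crop.txt"
    if crop_path.exists():
        vals = crop_path.read_text().split()
        crop_rect = tuple(int(v) for v in vals[:4])
    return CasePair(
        case_id=case_dir.name,
        after_img=after,
        before_img_raw=before,
        before_img_aligned=aligned,
        mask=mask,
        crop_rect=crop_rect,
        points=points,
    )


def save_case(case: CasePair, case_dir: str | Path) -> Path:
    """Write the case-directory layout (lossless PNG; mask as 0/255)."""
    if case.points is None:
        raise ValidationError("cannot save a case without correspondence points")
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(case_dir / "after.png", case.after_img)
    iio.imwrite(case_dir / "before.png", case.before_img_raw)
    iio.imwrite(case_dir / "mask.png", (case.mask * 255).astype(np.uint8))
    geometry.write_correspondences(case.points, case_dir / "points.txt")
    if case.crop_rect is not None:
        (case_dir / "crop.txt").write_text(" ".join(str(v) for v in case.crop_rect) + "\n")
    return case_dir


def save_probability_map(prob: np.ndarray, path: str | Path) -> None:
    """Write a [0,1] probability map losslessly as 16-bit PNG."""
    prob = np.asarray(prob, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValidationError("probability map must lie in [0, 1]")
    iio.imwrite(Path(path), np.rint(prob * 65535).astype(np.uint16))


def load_probability_map(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.float32) / 65535.0


def read_manifest(path: str | Path) -> list[Path]:
    """Dataset manifest: one case directory per line, relative to the
    manifest's own directory."""
    path = Path(path)
    base = path.parent
    dirs = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            dirs.append(base / line)
    return dirs


def write_manifest(case_dirs: list[str | Path], path: str | Path) -> None:
    path = Path(path)
    base = path.parent
    lines = [str(Path(d).relative_to(base)) for d in case_dirs]
    path.write_text("\n".join(lines) + "\n")
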