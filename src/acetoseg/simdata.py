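"""Synthetic paired colposcopic images with exact ground truth.

Each case emulates the appearance changes that make acetowhite segmentation
hard from a single image:

* an elliptical "cervix" of pale-pink squamous epithelium on a dark
  background, with a reddish central os (columnar epithelium) that barely
  changes with acetic acid;
* *confuser* patches — near-white squamous epithelium that looks identical
  in the before- and after-images, and is therefore indistinguishable from
  acetowhite epithelium in the after-image alone;
* *lesion* blobs near the os boundary (the squamous-columnar junction) that
  are pink before and shift toward white after acetic acid — exactly the
  change signal the dual-input network can exploit;
* a random projective camera perturbation between the two exposures (the
  before-image is rendered through the inverse of a known homography), plus
  independent per-image Gaussian noise and optional specular highlights.

The true homography and >= 4 noise-free landmark correspondences are
emitted with every case, closing the loop with the geometry module.
Everything is deterministic given (params, case_seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage

from . import geometry, preprocess
from .errors import ValidationError

__all__ = [
    "SimParams",
    "SimCase",
    "generate_case",
    "generate_dataset",
    "change_classifier",
    "whiteness_classifier",
]

# color anchors (RGB, unit scale); jittered per case
BACKGROUND_RGB = (0.10, 0.08, 0.09)
PINK_RGB = (0.85, 0.55, 0.60)    # squamous epithelium
RED_RGB = (0.72, 0.28, 0.30)     # columnar epithelium / os
WHITE_RGB = (0.95, 0.93, 0.92)   # acetowhite / near-white squamous


@dataclass
class SimParams:
    """Generator settings.

    ``lesion_whitening`` is the blend fraction toward the near-white anchor
    applied to lesion pixels in the after-image (0 = no change, 1 = fully
    white); ``confuser_whiteness`` the baseline intensity of the patches
    present in both images.  ``perturbation_scale`` displaces each image
    corner by up to that fraction of min(h, w) to build the true homography.
    """

    image_size: tuple[int, int] = (64, 64)
    n_cases: int = 30
    n_lesions_range: tuple[int, int] = (1, 3)
    n_confusers_range: tuple[int, int] = (1, 3)
    lesion_whitening: float = 0.85
    confuser_whiteness: float = 0.92
    perturbation_scale: float = 0.05
    noise_sd: float = 0.01
    specular_prob: float = 0.0
    seed: int = 0
    mask_frac_band: tuple[float, float] = (0.05, 0.30)
    max_retries: int = 50

    def __post_init__(self):
        for name in ("n_lesions_range", "n_confusers_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValidationError(f"{name} must be a nonempty range")
        if self.n_lesions_range[0] < 1:
            raise ValidationError("every case needs at least one lesion")
        if self.perturbation_scale < 0 or self.noise_sd < 0:
            raise ValidationError("perturbation_scale and noise_sd must be >= 0")


@dataclass
class SimCase(preprocess.CasePair):
    """A generated case plus its exact ground-truth geometry."""

    true_transform: geometry.ProjectiveTransform | None = None
    confuser_mask: np.ndarray | None = None

    @property
    def landmark_points(self) -> geometry.CorrespondenceSet:
        return self.points


# ------------------------------------------------------------ scene pieces

def _ellipse_mask(shape, center, axes, angle=0.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def _blob_mask(shape, center, radius, rng, wobble=0.25):
    """Irregular blob: an ellipse whose radius is modulated by a few
    low-order angular harmonics."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - center[0]).astype(float)
    dx = (xx - center[1]).astype(float)
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    mod = np.ones_like(theta)
    for k in range(2, 5):
        amp = rng.normal(0.0, wobble / 3)
        phase = rng.uniform(0, 2 * np.pi)
        mod += amp * np.cos(k * theta + phase)
    stretch = rng.uniform(0.7, 1.3)
    r_eff = np.hypot(dy / stretch, dx * stretch)
    return r_eff <= radius * np.clip(mod, 0.4, 1.6)


def _jitter_color(rng, anchor, sd=0.02):
    return np.clip(np.asarray(anchor) + rng.normal(0.0, sd, 3), 0.0, 1.0)


def _corner_homography(shape, scale, rng) -> geometry.ProjectiveTransform:
    """Random projective map built by displacing the four image corners by
    up to ``scale * min(h, w)`` pixels; identity when scale == 0."""
    h, w = shape
    corners = np.array([[0, 0], [w - 1.0, 0], [w - 1.0, h - 1.0], [0, h - 1.0]])
    if scale == 0:
        return geometry.ProjectiveTransform.identity()
    d = rng.uniform(-scale * min(h, w), scale * min(h, w), size=(4, 2))
    pairs = [
        geometry.PointPair(before_xy=tuple(corners[i] + d[i]),
                           after_xy=tuple(corners[i]), label=i + 1)
        for i in range(4)
    ]
    return geometry.estimate_homography(
        geometry.CorrespondenceSet(pairs=tuple(pairs), case_id="corners")
    )


def _to_uint8(img):
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


# ------------------------------------------------------------- generation

def generate_case(params: SimParams, case_seed: int) -> SimCase:
    """Render one before/after pair with mask, true homography and
    landmarks.  Deterministic in (params, case_seed)."""
    rng = np.random.default_rng(case_seed)
    h, w = params.image_size
    scale_len = min(h, w)

    for _attempt in range(params.max_retries):
        # --- base scene (after-image frame) -----------------------------
        cy = h / 2 + rng.uniform(-0.05, 0.05) * h
        cx = w / 2 + rng.uniform(-0.05, 0.05) * w
        cerv_axes = (rng.uniform(0.33, 0.42) * h, rng.uniform(0.35, 0.44) * w)
        cervix = _ellipse_mask((h, w), (cy, cx), cerv_axes, rng.uniform(-0.4, 0.4))
        os_axes = (rng.uniform(0.10, 0.16) * h, rng.uniform(0.10, 0.16) * w)
        os_cy = cy + rng.uniform(-0.04, 0.04) * h
        os_cx = cx + rng.uniform(-0.04, 0.04) * w
        os_region = _ellipse_mask((h, w), (os_cy, os_cx), os_axes) & cervix

        scene = np.empty((h, w, 3), float)
        scene[:] = _jitter_color(rng, BACKGROUND_RGB, 0.01)
        pink = _jitter_color(rng, PINK_RGB)
        scene[cervix] = pink
        scene[os_region] = _jitter_color(rng, RED_RGB)
        # smooth texture over the cervix
        texture = scipy.ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, (h, w)), sigma=3.0
        )
        scene += 0.04 * texture[..., None] * cervix[..., None]

        # --- lesions at the squamous-columnar junction -------------------
        n_lesions = int(rng.integers(params.n_lesions_range[0],
                                     params.n_lesions_range[1] + 1))
        lesion_mask = np.zeros((h, w), bool)
        os_r = float(np.mean(os_axes))
        for _ in range(n_lesions):
            theta = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(1.0, 1.8) * os_r
            ly = os_cy + rad * np.sin(theta)
            lx = os_cx + rad * np.cos(theta)
            blob = _blob_mask((h, w), (ly, lx), rng.uniform(0.10, 0.18) * scale_len, rng)
            lesion_mask |= blob & cervix

        # --- confusers: near-white in BOTH images ------------------------
        n_conf = int(rng.integers(params.n_confusers_range[0],
                                  params.n_confusers_range[1] + 1))
        confuser_mask = np.zeros((h, w), bool)
        ok = True
        for _ in range(n_conf):
            for _try in range(params.max_retries):
                theta = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0.9, 2.4) * os_r
                ky = os_cy + rad * np.sin(theta)
                kx = os_cx + rad * np.cos(theta)
                blob = _blob_mask((h, w), (ky, kx),
                                  rng.uniform(0.08, 0.14) * scale_len, rng)
                blob &= cervix
                overlap = (blob & lesion_mask).sum()
                if blob.sum() > 0 and overlap <= 0.05 * max(blob.sum(), 1):
                    confuser_mask |= blob & ~lesion_mask
                    break
            else:
                ok = False
                break
        if not ok:
            continue

        # lesion coverage must keep the task learnable
        frac = lesion_mask.sum() / max(cervix.sum(), 1)
        if not (params.mask_frac_band[0] <= frac <= params.mask_frac_band[1]):
            continue

        white = _jitter_color(rng, WHITE_RGB, 0.01)
        conf_color = np.clip(
            white * params.confuser_whiteness / max(np.mean(WHITE_RGB), 1e-9), 0, 1
        )
        scene[confuser_mask] = conf_color

        before_scene = scene.copy()
        after_scene = scene.copy()
        wf = params.lesion_whitening
        after_scene[lesion_mask] = (
            (1 - wf) * after_scene[lesion_mask] + wf * white[None, :]
        )

        # --- camera perturbation, landmarks, noise -----------------------
        true_tf = _corner_homography((h, w), params.perturbation_scale, rng)
        before_u8 = _to_uint8(before_scene)
        if params.perturbation_scale > 0:
            before_raw = geometry.warp_image(
                before_u8, true_tf.inverse(), out_shape=(h, w)
            )
        else:
            before_raw = before_u8.copy()

        angles = np.deg2rad([0, 90, 180, 270, 45, 135, 225, 315])
        anchors = np.column_stack([
            cx + 0.85 * cerv_axes[1] * np.cos(angles),
            cy + 0.85 * cerv_axes[0] * np.sin(angles),
        ])
        before_pts = geometry.apply_transform(anchors, true_tf.inverse())
        pairs = tuple(
            geometry.PointPair(before_xy=tuple(before_pts[i]),
                               after_xy=tuple(anchors[i]), label=i + 1)
            for i in range(len(anchors))
        )
        landmarks = geometry.CorrespondenceSet(pairs=pairs, case_id=f"case_{case_seed}")

        after = after_scene.copy()
        before_img = before_raw.astype(float) / 255.0
        if params.specular_prob > 0:
            for img in (after, before_img):
                if rng.random() < params.specular_prob:
                    n_spots = int(rng.integers(1, 4))
                    for _ in range(n_spots):
                        sy = rng.uniform(0.25, 0.75) * h
                        sx = rng.uniform(0.25, 0.75) * w
                        spot = _ellipse_mask((h, w), (sy, sx),
                                             (rng.uniform(1, 3), rng.uniform(1, 3)))
                        img[spot] = 0.99
        if params.noise_sd > 0:
            after = after + rng.normal(0.0, params.noise_sd, after.shape)
            before_img = before_img + rng.normal(0.0, params.noise_sd, before_img.shape)
        after_u8 = _to_uint8(np.clip(after, 0, 1))
        before_raw_u8 = _to_uint8(np.clip(before_img, 0, 1))

        aligned = geometry.warp_image(before_raw_u8, true_tf, out_shape=(h, w))
        return SimCase(
            case_id=f"case_{case_seed:04d}",
            after_img=after_u8,
            before_img_raw=before_raw_u8,
            before_img_aligned=aligned,
            mask=lesion_mask.astype(np.uint8),
            points=landmarks,
            true_transform=true_tf,
            confuser_mask=confuser_mask.astype(np.uint8),
        )
    raise ValidationError(
        f"could not place lesions/confusers within {params.max_retries} attempts "
        f"(seed {case_seed}); loosen SimParams"
    )


def generate_dataset(
    params: SimParams, out_dir: str | Path | None = None
) -> list[SimCase]:
    """Generate ``params.n_cases`` cases (case i uses seed ``params.seed + i``)
    and optionally write the on-disk case layout plus a manifest."""
    if params.n_cases < 1:
        raise ValidationError("n_cases must be >= 1")
    cases = [generate_case(params, params.seed + i) for i in range(params.n_cases)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dirs = []
        for case in cases:
            d = out_dir / case.case_id
            preprocess.save_case(case, d)
            np.savetxt(d / "truth_transform.txt", case.true_transform.matrix)
            dirs.append(d)
        preprocess.write_manifest(dirs, out_dir / "manifest.txt")
    return cases


# ------------------------------------------------- oracle pixel classifiers

def change_classifier(case: preprocess.CasePair, threshold: float = 0.15) -> np.ndarray:
    """Label a pixel lesion when the before->after color change exceeds
    ``threshold`` (max over channels, unit scale).  On noiseless, perfectly
    aligned pairs this recovers the mask exactly — the signal the dual-input
    arm can learn."""
    after = case.after_img.astype(float) / 255.0
    before = case.before_img_aligned.astype(float) / 255.0
    change = np.abs(after - before).max(axis=-1)
    return (change > threshold).astype(np.uint8)


def whiteness_classifier(case: preprocess.CasePair, threshold: float = 0.75) -> np.ndarray:
    """Label a pixel lesion when the after-image is near-white (min channel
    above ``threshold``).  This is the best a single-image rule can do, and
    it necessarily fires on every confuser pixel."""
    after = case.after_img.astype(float) / 255.0
    return (after.min(axis=-1) > threshold).astype(np.uint8)
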