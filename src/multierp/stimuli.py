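"""Programmatic two-tone stimulus generation and luminance equalization.

The original degraded-face photographs are not redistributable, so the face
stimuli here are synthetic two-tone stand-ins: thresholded smooth random
blob fields with enforced bilateral symmetry and dark upper-half features.
Their "distorted" counterparts are block-scrambled versions of the same
image (identical ink).  Kanizsa figures are built from three notched discs;
the distorted variant rotates the notches away from the centroid so the
illusory triangle disappears while the total disc area is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EqualizationError, ParameterError
from .config import ImageKind

DEFAULT_PX = 256


@dataclass
class StimulusImage:
    pixels: np.ndarray          # 2-D, values in [0, 1]
    kind: str                   # an ImageKind value or "mask"
    variant_id: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ParameterError("stimulus raster must be 2-D")
        if p.min() < 0 or p.max() > 1:
            raise ParameterError("pixel values must lie in [0, 1]")
        self.pixels = p

    @property
    def mean_luminance(self) -> float:
        return float(self.pixels.mean())


@dataclass
class StimulusSet:
    images: dict[str, list[StimulusImage]]

    @property
    def mean_luminances(self) -> dict[str, list[float]]:
        return {k: [im.mean_luminance for im in v]
                for k, v in self.images.items()}

    def all_images(self) -> list[StimulusImage]:
        return [im for v in self.images.values() for im in v]


def make_checkerboard(tiles_per_side: int, px: int) -> StimulusImage:
    """Alternating black/white tiles; mean luminance exactly 0.5."""
    if tiles_per_side % 2:
        raise ParameterError("tiles_per_side must be even")
    if px % tiles_per_side:
        raise ParameterError("px must be divisible by tiles_per_side")
    t = px // tiles_per_side
    i, j = np.indices((px, px))
    board = ((i // t + j // t) % 2).astype(float)
    return StimulusImage(board, "mask", 0,
                         {"tiles": tiles_per_side, "px": px})


def _disc_with_notch(px: int, center: tuple[float, float], radius: float,
                     notch_angle_rad: float, notch_width_rad: float) -> np.ndarray:
    """Dark disc with a wedge of fixed angular width removed."""
    i, j = np.indices((px, px), dtype=float)
    dy, dx = i - center[0], j - center[1]
    inside = dy ** 2 + dx ** 2 <= radius ** 2
    ang = np.arctan2(dy, dx)
    delta = np.angle(np.exp(1j * (ang - notch_angle_rad)))
    wedge = np.abs(delta) <= notch_width_rad / 2
    return inside & ~wedge


def make_kanizsa(variant: str = "canonical", px: int = DEFAULT_PX,
                 rotation_seed: int = 0) -> StimulusImage:
    """Illusory-triangle inducers: three inward-notched discs.

    ``distorted`` keeps the same components but rotates each notch outward
    (randomly, seeded) so no illusory surface forms; disc ink is identical
    because the wedge width is fixed.
    """
    if px < 64:
        raise ParameterError("px must be >= 64")
    rng = np.random.default_rng(rotation_seed)
    cx, cy = px / 2, px / 2
    r_tri = px * 0.30
    r_disc = px * 0.12
    notch_w = np.pi / 3
    canvas = np.zeros((px, px), dtype=bool)
    for k in range(3):
        theta = -np.pi / 2 + k * 2 * np.pi / 3
        center = (cy + r_tri * np.sin(theta), cx + r_tri * np.cos(theta))
        inward = np.arctan2(cy - center[0], cx - center[1])
        if variant == "canonical":
            notch = inward
        elif variant == "distorted":
            # anywhere in the outward half-plane, away from the centroid
            notch = inward + np.pi + rng.uniform(-np.pi / 3, np.pi / 3)
        else:
            raise ParameterError(f"unknown variant {variant!r}")
        canvas |= _disc_with_notch(px, center, r_disc, notch, notch_w)
    img = 1.0 - canvas.astype(float)   # dark discs on white ground
    return StimulusImage(img, ImageKind.KANIZSA.value if variant == "canonical"
                         else ImageKind.KANIZSA_DISTORTED.value,
                         rotation_seed, {"variant": variant, "px": px})


def make_two_tone_pattern(kind: str = "face_proxy", seed: int = 0,
                          px: int = DEFAULT_PX) -> StimulusImage:
    """Binary two-tone pattern from a thresholded smooth random field.

    ``face_proxy`` enforces mirror symmetry plus two dark upper-half blobs;
    ``scrambled`` permutes 32x32 blocks of the face_proxy built from the
    same seed, so the histogram (ink) is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    fieldv = ndimage.gaussian_filter(rng.standard_normal((px, px)), px / 16)
    fieldv = (fieldv + fieldv[:, ::-1]) / 2          # bilateral symmetry
    # dark "eye" features in the upper half
    i, j = np.indices((px, px), dtype=float)
    for ex in (0.35, 0.65):
        d2 = ((i - 0.38 * px) ** 2 + (j - ex * px) ** 2)
        fieldv -= 1.5 * np.exp(-d2 / (2 * (px * 0.06) ** 2))
    img = (fieldv > np.median(fieldv)).astype(float)
    if kind == "face_proxy":
        pass
    elif kind == "scrambled":
        bs = px // 8
        blocks = [img[r:r + bs, c:c + bs]
                  for r in range(0, px, bs) for c in range(0, px, bs)]
        perm = rng.permutation(len(blocks))
        out = np.empty_like(img)
        k = 0
        for r in range(0, px, bs):
            for c in range(0, px, bs):
                out[r:r + bs, c:c + bs] = blocks[perm[k]]
                k += 1
        img = out
    else:
        raise ParameterError(f"unknown kind {kind!r}")
    return StimulusImage(img, ImageKind.MOONEY_FACE.value if kind == "face_proxy"
                         else ImageKind.MOONEY_DISTORTED.value,
                         seed, {"kind": kind, "px": px})


def build_stimulus_set(seed: int = 0, px: int = DEFAULT_PX,
                       n_faces: int = 30, n_kanizsa: int = 2) -> StimulusSet:
    """The full bank: 30 face stand-ins + 30 scrambled, 2 Kanizsa + 2
    distorted, and a checkerboard mask."""
    images = {
        ImageKind.MOONEY_FACE.value: [
            make_two_tone_pattern("face_proxy", seed + i, px)
            for i in range(n_faces)],
        ImageKind.MOONEY_DISTORTED.value: [
            make_two_tone_pattern("scrambled", seed + i, px)
            for i in range(n_faces)],
        ImageKind.KANIZSA.value: [
            make_kanizsa("canonical", px, seed + i) for i in range(n_kanizsa)],
        ImageKind.KANIZSA_DISTORTED.value: [
            make_kanizsa("distorted", px, seed + i) for i in range(n_kanizsa)],
        "mask": [make_checkerboard(8, px)],
    }
    return StimulusSet(images)


def equalize_mean_luminance(stim_set: StimulusSet, tolerance: float = 0.01,
                            seed: int = 0) -> tuple[StimulusSet, dict]:
    """Flip randomly chosen pixels until every image's mean luminance is
    within ``tolerance`` of the set's grand mean.

    Only binary images are adjusted (values flipped 0<->1); a report maps
    each image to (before, after) means.
    """
    imgs = stim_set.all_images()
    if not imgs:
        raise EqualizationError("empty stimulus set")
    rng = np.random.default_rng(seed)
    grand = float(np.mean([im.mean_luminance for im in imgs]))
    report: dict[str, list] = {"grand_mean": grand, "images": []}
    for im in imgs:
        before = im.mean_luminance
        px = im.pixels
        n = px.size
        # number of pixels to flip toward the grand mean
        delta = grand - before
        need = int(round(abs(delta) * n))
        if need:
            src_val = 0.0 if delta > 0 else 1.0
            cand = np.flatnonzero(px.ravel() == src_val)
            if len(cand) < need:
                raise EqualizationError(
                    f"cannot reach tolerance for {im.kind}/{im.variant_id}: "
                    "image saturated")
            pick = rng.choice(cand, size=need, replace=False)
            flat = px.ravel()
            flat[pick] = 1.0 - src_val
            im.pixels = flat.reshape(px.shape)
        after = im.mean_luminance
        if abs(after - grand) > tolerance:
            raise EqualizationError(
                f"residual {abs(after - grand):.4f} above tolerance for "
                f"{im.kind}/{im.variant_id}")
        report["images"].append({"kind": im.kind, "variant": im.variant_id,
                                 "before": before, "after": after})
    return stim_set, report
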