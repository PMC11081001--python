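"""Image augmentation and contrast enhancement for staged-dementia MRI scans.

Augmentation balances class counts with lossless geometric ops (flips and
90-degree rotations), the standard recipe for bringing a 64-image minority
class up to parity with a 3,200-image majority. Enhancement is a two-stage
contrast chain: an edge-aware Laplacian-pyramid detail boost followed by a
combined top-hat/bottom-hat morphological filter that lifts small bright
structures and suppresses small dark ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color, morphology
from skimage.transform import resize

from .synthetic import ImageGrid

AUGMENT_OPS = ("hflip", "vflip", "rot90", "rot180", "rot270")


@dataclass
class AugmentPlan:
    """How to bring one class up to a target count.

    ``ops`` is the pool of lossless operators sampled (with a seeded RNG)
    to create the extra images; originals are always retained.
    """

    target_count_per_class: int
    ops: list[str] = field(default_factory=lambda: list(AUGMENT_OPS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ops:
            raise ValueError("ops must be non-empty")
        unknown = set(self.ops) - set(AUGMENT_OPS)
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")


def hflip(img: ImageGrid) -> ImageGrid:
    """Mirror across the vertical axis: column order reversed."""
    return ImageGrid(img.intensities[:, ::-1].copy())


def vflip(img: ImageGrid) -> ImageGrid:
    """Mirror across the horizontal axis: row order reversed."""
    return ImageGrid(img.intensities[::-1, :].copy())


def rotate90(img: ImageGrid, quarter_turns: int) -> ImageGrid:
    """Rotate counterclockwise by 90 * quarter_turns degrees about the center.

    Only quarter turns are supported: they permute pixels losslessly, so the
    intensity histogram is preserved exactly.
    """
    if quarter_turns not in (1, 2, 3):
        raise ValueError("quarter_turns must be 1, 2 or 3")
    return ImageGrid(np.rot90(img.intensities, k=quarter_turns, axes=(0, 1)).copy())


_OP_FUNCS = {
    "hflip": hflip,
    "vflip": vflip,
    "rot90": lambda im: rotate90(im, 1),
    "rot180": lambda im: rotate90(im, 2),
    "rot270": lambda im: rotate90(im, 3),
}


def apply_op(img: ImageGrid, op: str) -> ImageGrid:
    try:
        return _OP_FUNCS[op](img)
    except KeyError:
        raise ValueError(f"unknown augmentation op {op!r}") from None


def augment_to_count(images: list[ImageGrid], plan: AugmentPlan) -> list[ImageGrid]:
    """Pad a class to ``target_count_per_class`` images.

    Originals come first; extras are produced by a seeded random choice of
    (source image, operator) so repeated runs with the same plan give the
    identical sequence.
    """
    if not images:
        raise ValueError("need at least one input image")
    if plan.target_count_per_class < len(images):
        raise ValueError("target count below existing count")
    out = list(images)
    rng = np.random.default_rng(plan.seed)
    while len(out) < plan.target_count_per_class:
        src = images[int(rng.integers(len(images)))]
        op = plan.ops[int(rng.integers(len(plan.ops)))]
        out.append(apply_op(src, op))
    return out


def _per_channel(img: np.ndarray, fn) -> np.ndarray:
    if img.ndim == 2:
        return fn(img)
    return np.dstack([fn(img[:, :, c]) for c in range(img.shape[2])])


def tophat_bottomhat_enhance(img: ImageGrid, selem_radius: int = 5) -> ImageGrid:
    """Combined morphological contrast boost with a disc structuring element.

    Adds the white top-hat (small bright structures on a darker backdrop)
    and subtracts the black bottom-hat (small dark structures), then clips
    back to [0, 1]:  I + (I - opening(I)) - (closing(I) - I).
    """
    if selem_radius < 1:
        raise ValueError("selem_radius must be >= 1")
    footprint = morphology.disk(selem_radius)

    def enhance(channel: np.ndarray) -> np.ndarray:
        top = morphology.white_tophat(channel, footprint)
        bottom = morphology.black_tophat(channel, footprint)
        return channel + top - bottom

    out = _per_channel(img.intensities, enhance)
    return ImageGrid(np.clip(out, 0.0, 1.0))


def _reduce(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma=1.0, mode="nearest")[::2, ::2]


def _expand(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return resize(img, shape, order=1, mode="edge", anti_aliasing=False)


def local_laplacian_enhance(
    img: ImageGrid, levels: int = 3, sigma: float = 0.1, alpha: float = 2.0
) -> ImageGrid:
    """Laplacian-pyramid detail remap boosting boundary detail.

    Band-pass coefficients with magnitude below ``sigma`` are scaled by
    ``alpha`` (detail boost for alpha > 1); the pyramid is then collapsed
    and clipped to [0, 1]. Reconstruction uses the same expand operator as
    analysis, so alpha = 1 is an exact identity up to float error. Color
    images are taken to YUV and only the luma channel is enhanced.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if sigma <= 0 or alpha <= 0:
        raise ValueError("sigma and alpha must be positive")
    h, w = img.intensities.shape[:2]
    if h < 2**levels or w < 2**levels:
        raise ValueError("image smaller than 2**levels in one dimension")

    def enhance(channel: np.ndarray) -> np.ndarray:
        gaussians = [channel]
        for _ in range(levels - 1):
            gaussians.append(_reduce(gaussians[-1]))
        laplacians = []
        for lo, hi in zip(gaussians[1:], gaussians[:-1]):
            band = hi - _expand(lo, hi.shape)
            band = np.where(np.abs(band) < sigma, alpha * band, band)
            laplacians.append(band)
        out = gaussians[-1]
        for band in reversed(laplacians):
            out = band + _expand(out, band.shape)
        return out

    arr = img.intensities
    if arr.ndim == 3:
        yuv = color.rgb2yuv(arr)
        yuv[:, :, 0] = enhance(yuv[:, :, 0])
        out = color.yuv2rgb(yuv)
    else:
        out = enhance(arr)
    return ImageGrid(np.clip(out, 0.0, 1.0))


def enhance_chain(
    img: ImageGrid,
    levels: int = 3,
    sigma: float = 0.1,
    alpha: float = 2.0,
    selem_radius: int = 5,
) -> ImageGrid:
    """Full enhancement: local-Laplacian detail boost, then top/bottom-hat."""
    return tophat_bottomhat_enhance(
        local_laplacian_enhance(img, levels=levels, sigma=sigma, alpha=alpha),
        selem_radius=selem_radius,
    )
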