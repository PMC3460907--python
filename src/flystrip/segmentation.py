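"""Embryo mask generation from 10x DIC micrographs.

The mask pipeline turns a colour DIC image of a single embryo into a binary
foreground mask through a fixed sequence of classical image operations:
grayscale conversion, strong gamma compression, inversion, Sobel edge
detection, low thresholding, dilations interleaved with border-blob removal,
hole filling, size-based blob cleaning, Gaussian edge smoothing and a final
re-threshold.  Every intermediate is recorded so that a failed mask can be
diagnosed stage by stage.

Images are plain ``numpy`` arrays: RGB images are ``(H, W, 3)`` uint8, gray
and binary images are ``(H, W)``.  Binary images use the values {0, 255};
pixels at 255 form 8-connected "blobs".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.special import erfcinv

from .errors import FormatError, NoEmbryoError, ParameterError

__all__ = [
    "SegmentationParams",
    "EmbryoMask",
    "to_gray8",
    "gamma_correct",
    "invert",
    "sobel_edges",
    "binarize",
    "dilate",
    "kill_border_blobs",
    "fill_holes",
    "remove_small_blobs",
    "gaussian_smooth",
    "make_mask",
    "MASK_STAGES",
]

# 8-connected blobs, 3x3 square structuring element (desktop-imaging default)
_STRUCT8 = np.ones((3, 3), dtype=bool)
# holes are background components 4-connected to each other (dual of the above)
_STRUCT4 = ndi.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the mask pipeline.

    Attributes
    ----------
    gamma : float
        Exponent of the contrast (gamma) correction.  The default 0.08
        compresses almost the whole intensity range towards white, leaving
        only near-black pixels dark; this makes the subsequent edge
        detection respond to the embryo rim rather than to illumination
        gradients.
    edge_threshold : int
        Cutoff applied to the Sobel gradient magnitude: values <= the
        threshold become background.
    beta : float
        Image-area divisor defining the minimum blob size.  Blobs smaller
        than ``H*W/beta`` are removed when more than one blob is present;
        1/beta is the largest area fraction still considered "non-embryo".
        Increase for small embryos, decrease to clean bigger artefacts.
    blur_sigma : float
        Standard deviation, in pixels, of the Gaussian used to smooth the
        mask edge before the final threshold.
    blur_accuracy : float
        Per-axis Gaussian tail mass allowed to fall outside the truncated
        kernel.
    post_blur_threshold : int
        Cutoff re-binarising the smoothed mask.
    """

    gamma: float = 0.08
    edge_threshold: int = 6
    beta: float = 13.0
    blur_sigma: float = 31.0
    blur_accuracy: float = 1e-3
    post_blur_threshold: int = 145

    def __post_init__(self):
        if self.gamma <= 0:
            raise ParameterError("gamma must be > 0")
        if self.beta <= 0:
            raise ParameterError("beta must be > 0")
        if not (0 <= self.edge_threshold <= 255 and 0 <= self.post_blur_threshold <= 255):
            raise ParameterError("thresholds must lie in [0, 255]")
        if self.blur_sigma <= 0:
            raise ParameterError("blur_sigma must be > 0")


#: Stage names of the mask pipeline, in execution order.
MASK_STAGES = (
    "gray",
    "gamma",
    "invert",
    "edges",
    "binarize",
    "dilate_1",
    "kill_border_1",
    "dilate_2",
    "fill_holes",
    "kill_border_2",
    "remove_small_blobs",
    "gaussian_smooth",
    "binarize_final",
    "remove_small_blobs_final",
)


@dataclass
class EmbryoMask:
    """Binary embryo mask together with its provenance.

    ``intermediates`` maps each stage name of :data:`MASK_STAGES` to the
    image produced by that stage; ``quality`` follows the manual rating
    vocabulary ('good', 'ok', 'not good').
    """

    mask: np.ndarray
    intermediates: dict[str, np.ndarray]
    params_used: SegmentationParams
    quality: str = "good"
    warnings: list[str] = field(default_factory=list)

    @property
    def blob_count(self) -> int:
        return int(ndi.label(self.mask > 0, structure=_STRUCT8)[1])


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise FormatError(f"expected a 2-D gray image, got shape {img.shape}")
    return img


def to_gray8(rgb: np.ndarray, weights=None) -> np.ndarray:
    """Collapse an 8-bit RGB image to a single gray channel.

    By default the three channels are averaged with equal weight and rounded
    to the nearest integer; pass ``weights`` (length 3, summing to 1) for a
    luminance-style conversion.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError(f"expected an (H, W, 3) RGB image, got shape {rgb.shape}")
    if weights is None:
        weights = np.full(3, 1.0 / 3.0)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (3,):
            raise ParameterError("weights must have length 3")
    gray = rgb.astype(float) @ weights
    return np.rint(gray).clip(0, 255).astype(np.uint8)


def gamma_correct(img: np.ndarray, gamma: float = 0.08) -> np.ndarray:
    """Apply ``out = 255 * (in/255)**gamma``, rounded; 0 and 255 are fixed."""
    if gamma <= 0:
        raise ParameterError("gamma must be > 0")
    img = _check_gray(img)
    out = 255.0 * (img.astype(float) / 255.0) ** gamma
    return np.rint(out).clip(0, 255).astype(np.uint8)


def invert(img: np.ndarray) -> np.ndarray:
    """Return ``255 - img`` (dark background becomes light and vice versa)."""
    return (255 - _check_gray(img).astype(np.int16)).astype(np.uint8)


def sobel_edges(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, clipped to [0, 255].

    Uses the standard 3x3 Sobel kernels with edge replication at the image
    border, so a flat border produces no spurious edge response.
    """
    img = _check_gray(img).astype(float)
    gx = ndi.sobel(img, axis=1, mode="nearest")
    gy = ndi.sobel(img, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    return np.rint(mag).clip(0, 255).astype(np.uint8)


def binarize(img: np.ndarray, t: int) -> np.ndarray:
    """Threshold to {0, 255}: values <= ``t`` become 0, the rest 255."""
    if not 0 <= t <= 255:
        raise ParameterError("threshold must lie in [0, 255]")
    img = _check_gray(np.asarray(img))
    return np.where(img <= t, 0, 255).astype(np.uint8)


def dilate(img: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Iterated binary dilation with a 3x3 square structuring element."""
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    img = _check_gray(img)
    if iterations == 0:
        return img.copy()
    fg = ndi.binary_dilation(img > 0, structure=_STRUCT8, iterations=iterations)
    return np.where(fg, 255, 0).astype(np.uint8)


def kill_border_blobs(img: np.ndarray) -> np.ndarray:
    """Remove every 8-connected blob that contains an image-border pixel."""
    img = _check_gray(img)
    labels, n = ndi.label(img > 0, structure=_STRUCT8)
    if n == 0:
        return img.copy()
    border = np.zeros(img.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & (labels > 0)])
    out = img.copy()
    if touching.size:
        out[np.isin(labels, touching)] = 0
    return out


def fill_holes(img: np.ndarray) -> np.ndarray:
    """Set enclosed background regions to foreground.

    A hole is a 4-connected background component that cannot reach the image
    border; 4-connectivity is the topological dual of the 8-connected blobs.
    """
    img = _check_gray(img)
    filled = ndi.binary_fill_holes(img > 0, structure=_STRUCT4)
    return np.where(filled, 255, 0).astype(np.uint8)


def remove_small_blobs(img: np.ndarray, beta: float = 13.0) -> tuple[np.ndarray, list[str]]:
    """Remove supernumerary blobs smaller than ``H*W/beta`` pixels.

    Removal only triggers when more than one blob is present; a lone blob is
    never removed no matter how small.  If several blobs survive the size
    cut they are all kept and a warning is returned.

    Returns
    -------
    (image, warnings)

    Raises
    ------
    NoEmbryoError
        If no blob remains after removal.
    """
    if beta <= 0:
        raise ParameterError("beta must be > 0")
    img = _check_gray(img)
    labels, n = ndi.label(img > 0, structure=_STRUCT8)
    warnings: list[str] = []
    if n <= 1:
        if n == 0:
            raise NoEmbryoError("remove_small_blobs", "image contains no blobs")
        return img.copy(), warnings
    threshold = img.shape[0] * img.shape[1] / beta
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= threshold) + 1
    if keep.size == 0:
        raise NoEmbryoError(
            "remove_small_blobs",
            f"all {n} blobs are smaller than the area cutoff {threshold:.0f} px",
        )
    out = np.where(np.isin(labels, keep), 255, 0).astype(np.uint8)
    if keep.size > 1:
        warnings.append(
            f"{keep.size} blobs above the size cutoff survive; expected a single embryo"
        )
    return out, warnings


def _gaussian_truncate(sigma: float, accuracy: float) -> float:
    # kernel radius r = truncate*sigma chosen so the omitted two-sided tail
    # mass 2*(1 - Phi(r/sigma)) stays below `accuracy` per axis
    return float(math.sqrt(2.0) * erfcinv(accuracy))


def gaussian_smooth(img: np.ndarray, sigma: float = 31.0, accuracy: float = 1e-3) -> np.ndarray:
    """Separable Gaussian smoothing; returns a float image in [0, 255].

    The kernel is truncated where the omitted tail mass per axis falls below
    ``accuracy``.  The output is kept at float precision so the following
    threshold operates on the exact smoothed values.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    img = _check_gray(img).astype(float)
    return ndi.gaussian_filter(
        img, sigma=sigma, mode="nearest", truncate=_gaussian_truncate(sigma, accuracy)
    )


def make_mask(dic: np.ndarray, params: SegmentationParams | None = None) -> EmbryoMask:
    """Run the full mask pipeline on a 10x DIC image.

    The stages run in the fixed order of :data:`MASK_STAGES`; each result is
    stored in :attr:`EmbryoMask.intermediates`.  The input must contain one
    complete embryo not touching the border (other embryos may appear but
    only if they touch the border, where they are discarded).

    Raises
    ------
    NoEmbryoError
        If the foreground vanishes at any stage; the error names the stage.
    """
    params = params or SegmentationParams()
    dic = np.asarray(dic)
    if dic.ndim != 3 or dic.shape[2] != 3:
        raise FormatError(f"expected an (H, W, 3) RGB DIC image, got shape {dic.shape}")
    if dic.shape[0] < 3 or dic.shape[1] < 3:
        raise FormatError("image smaller than 3x3 pixels")

    intermediates: dict[str, np.ndarray] = {}
    warnings: list[str] = []

    def record(stage, image):
        intermediates[stage] = image
        if stage != "gaussian_smooth" and not np.any(np.asarray(image) > 0):
            raise NoEmbryoError(stage)
        return image

    img = record("gray", to_gray8(dic))
    img = record("gamma", gamma_correct(img, params.gamma))
    img = record("invert", invert(img))
    img = record("edges", sobel_edges(img))
    img = record("binarize", binarize(img, params.edge_threshold))
    img = record("dilate_1", dilate(img, 2))
    img = record("kill_border_1", kill_border_blobs(img))
    img = record("dilate_2", dilate(img, 2))
    img = record("fill_holes", fill_holes(img))
    img = record("kill_border_2", kill_border_blobs(img))
    img, w = remove_small_blobs(img, params.beta)
    warnings.extend(w)
    record("remove_small_blobs", img)
    img = record(
        "gaussian_smooth", gaussian_smooth(img, params.blur_sigma, params.blur_accuracy)
    )
    img = record("binarize_final", binarize(img, params.post_blur_threshold))
    img, w = remove_small_blobs(img, params.beta)
    warnings.extend(w)
    record("remove_small_blobs_final", img)

    n_blobs = ndi.label(img > 0, structure=_STRUCT8)[1]
    if n_blobs > 1:
        quality = "not good"
    elif warnings:
        quality = "ok"
    else:
        quality = "good"
    return EmbryoMask(
        mask=img,
        intermediates=intermediates,
        params_used=params,
        quality=quality,
        warnings=warnings,
    )
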