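"""Rotate the embryo so the A-P (major) axis is horizontal, then crop.

The principal axis is found from the central second moments of the
foreground pixel distribution.  Angles follow the visual convention (y up,
counter-clockwise positive), in degrees within (-90, 90].  Rotation is
about the image centre with bilinear interpolation; after rotation all
registered images are cropped to the tight bounding box of the mask.
Anterior-left / dorsal-up orientation cannot be determined automatically,
so horizontal/vertical flips are user-supplied inputs.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import FlyStripError

__all__ = [
    "OrientationResult",
    "principal_axis_angle",
    "rotate_and_crop",
    "apply_flips",
    "orient_embryo",
]

# moment anisotropy below which the mask is treated as isotropic (no axis)
_DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class OrientationResult:
    """Rotation angle, flips and crop box applied to one embryo.

    ``crop_box`` is ``(row0, col0, height, width)`` in 0-based pixel
    coordinates of the rotated frame, half-open.
    """

    angle: float
    hflip: bool
    vflip: bool
    crop_box: tuple[int, int, int, int]


def principal_axis_angle(mask: np.ndarray) -> float:
    """Angle of the major principal axis relative to the horizontal.

    Computed from the central second moments of the foreground pixels,
    returned in degrees within (-90, 90].  An isotropic mask (e.g. a disk)
    has no defined major axis: 0 is returned with a warning.
    """
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size < 2:
        raise FlyStripError("mask needs at least 2 foreground pixels")
    x = cols - cols.mean()
    y = -(rows - rows.mean())  # y axis pointing up
    mu20 = float(np.mean(x * x))
    mu02 = float(np.mean(y * y))
    mu11 = float(np.mean(x * y))
    scale = mu20 + mu02
    if scale <= 0:
        raise FlyStripError("mask foreground is a single point or collinear along no axis")
    if abs(mu20 - mu02) / scale < _DEGENERATE_TOL and abs(mu11) / scale < _DEGENERATE_TOL:
        _warnings.warn("isotropic mask: principal axis undefined, returning 0 degrees")
        return 0.0
    angle = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    if angle <= -90.0:
        angle += 180.0
    return float(angle)


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise FlyStripError("rotated mask is empty")
    return (
        int(rows.min()),
        int(cols.min()),
        int(rows.max() - rows.min() + 1),
        int(cols.max() - cols.min() + 1),
    )


def rotate_and_crop(
    mask: np.ndarray, images: list[np.ndarray], angle: float
) -> tuple[np.ndarray, list[np.ndarray], tuple[int, int, int, int]]:
    """Rotate mask and registered images by ``-angle`` and crop to the mask.

    All images are rotated about the image centre with bilinear
    interpolation; the mask is re-binarised at 128 afterwards to stay a
    {0, 255} image.  The crop box is the tight bounding box of the rotated
    mask and is applied to every image.

    Returns ``(mask, images, crop_box)``.
    """
    mask = np.asarray(mask)
    rot_mask = ndi.rotate(mask.astype(float), -angle, reshape=True, order=1, mode="constant")
    rot_mask = np.where(rot_mask >= 128, 255, 0).astype(np.uint8)
    r0, c0, h, w = box = _bbox(rot_mask)
    out_mask = rot_mask[r0 : r0 + h, c0 : c0 + w]
    out_images = []
    for img in images:
        img = np.asarray(img)
        rot = ndi.rotate(
            img.astype(float), -angle, reshape=True, order=1, mode="constant", axes=(1, 0)
        )
        # reshape=True keeps all rotations of equal canvas size for a given
        # angle, so the mask's crop box registers with the image
        rot = np.rint(rot).clip(0, 255).astype(np.uint8)
        out_images.append(rot[r0 : r0 + h, c0 : c0 + w])
    return out_mask, out_images, box


def apply_flips(images: list[np.ndarray], hflip: bool, vflip: bool) -> list[np.ndarray]:
    """Mirror images about the vertical (hflip) / horizontal (vflip) midline.

    Applying the same flips twice restores the input exactly.
    """
    out = []
    for img in images:
        img = np.asarray(img)
        if hflip:
            img = img[:, ::-1]
        if vflip:
            img = img[::-1, :]
        out.append(np.ascontiguousarray(img))
    return out


def orient_embryo(
    mask: np.ndarray,
    images: list[np.ndarray],
    angle: float | None = None,
    hflip: bool = False,
    vflip: bool = False,
) -> tuple[np.ndarray, list[np.ndarray], OrientationResult]:
    """Full orientation step: auto (or given) angle, rotate, crop, flip."""
    if angle is None:
        angle = principal_axis_angle(mask)
    out_mask, out_images, box = rotate_and_crop(mask, images, angle)
    flipped = apply_flips([out_mask, *out_images], hflip, vflip)
    result = OrientationResult(angle=float(angle), hflip=hflip, vflip=vflip, crop_box=box)
    return flipped[0], flipped[1:], result
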