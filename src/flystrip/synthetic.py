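"""Synthetic four-image embryo sets with exact ground truth.

Real WMISH data consist, per embryo, of a 10x DIC image (segmentation
source), a 10x bright-field image (expression source), a 10x nuclear
counterstain and a 40x membrane-detail image.  This module renders
emulations of all four with known ground truth (binary mask, rotation
angle, midline, domain boundary positions), so every pipeline stage can be
tested quantitatively without real micrographs.

The embryo body is an ellipse.  The DIC emulation combines interior
texture with a dark rim band just inside the ellipse boundary; the rim
produces the closed Sobel edge ring the mask pipeline relies on, and its
outer edge coincides with the ground-truth ellipse so that the pipeline's
dilation growth and Gaussian-smoothing shrinkage roughly cancel.  It is
sufficient for the segmentation algorithm, not photorealistic.

Expression domains are graded: a domain on (a, b) percent egg length with
steepness s contributes ``plateau * (sigmoid((u-a)/s) - sigmoid((u-b)/s))``
to the stained channel, so the half-maximum crossings of the rendered
signal sit at a and b.  NBT/BCIP domains are written into the red channel
and FastRed domains as green-over-red excess, matching the extraction
formulas (nbt = red, fastred = green - red).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError

__all__ = ["Domain", "SyntheticEmbryoSpec", "GroundTruth", "render_embryo", "render_batch", "write_image_set"]


@dataclass(frozen=True)
class Domain:
    """One graded expression domain.

    Boundaries are in percent egg length; ``steepness`` is the logistic
    scale of the boundary ramps (about 4.4 steepness units span the
    10-90% rise).  ``stain`` is 'NBT_BCIP' or 'FastRed'.
    """

    stain: str
    anterior: float
    posterior: float
    steepness: float = 2.0
    plateau: float = 120.0

    def __post_init__(self):
        if not (0.0 < self.anterior < self.posterior < 100.0):
            raise ParameterError("need 0 < anterior < posterior < 100 percent EL")
        if not (0.0 < self.plateau <= 255.0):
            raise ParameterError("plateau must lie in (0, 255]")


@dataclass(frozen=True)
class SyntheticEmbryoSpec:
    """Parameters of one synthetic embryo image set.

    Defaults emulate a lateral-view blastoderm embryo in a 10x wide-field
    frame: semi-axes 500 x 190 px (a ~2.6:1 aspect-ratio egg spanning most
    of the field) on a 1360 x 1036 px canvas, moderate background level and
    texture, so the embryo fits the frame at any rotation.  ``rotation``
    is the visually counter-clockwise angle of the A-P axis against the
    horizontal.

    ``noise_sd`` is the total Gaussian noise SD added to the DIC and
    bright-field images.  The noise is a mixture of a small per-pixel
    sensor component (20% of the SD) and smooth illumination mottle
    (correlation length ~6 px) carrying the rest, emulating well-exposed
    wide-field images where uneven illumination dominates over shot noise.
    """

    canvas: tuple[int, int] = (1036, 1360)  # (height, width)
    semi_major: float = 500.0
    semi_minor: float = 190.0
    rotation: float = 0.0
    centre_offset: tuple[float, float] = (0.0, 0.0)  # (row, col)
    domains: tuple[Domain, ...] = ()
    background: float = 140.0
    noise_sd: float = 0.0
    nucleus_count: int = 80
    neighbor_at_border: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (self.semi_major > self.semi_minor > 0):
            raise ParameterError("need semi_major > semi_minor > 0")


@dataclass
class GroundTruth:
    """Exact truth for one rendered embryo."""

    mask: np.ndarray
    angle: float
    midline: np.ndarray  # (N, 2) (row, col) points along the major axis
    boundaries: list[dict]  # stain, anterior, posterior, plateau


@dataclass
class RawImageSet:
    """The four registered RGB images of one embryo."""

    brightfield: np.ndarray
    dic: np.ndarray
    nuclear: np.ndarray
    membrane: np.ndarray


def _embryo_frame(spec: SyntheticEmbryoSpec):
    """Per-pixel embryo-frame coordinates (u along major, v along minor)."""
    h, w = spec.canvas
    phi = np.deg2rad(spec.rotation)
    r, c = np.indices((h, w), dtype=float)
    cy = (h - 1) / 2.0 + spec.centre_offset[0]
    cx = (w - 1) / 2.0 + spec.centre_offset[1]
    x = c - cx
    y = -(r - cy)  # y up, so positive rotation is visually counter-clockwise
    u = x * np.cos(phi) + y * np.sin(phi)
    v = -x * np.sin(phi) + y * np.cos(phi)
    return u, v, (cy, cx)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


# fraction of the noise SD carried by the per-pixel sensor component; the
# rest is smooth illumination mottle with this Gaussian correlation length
_NOISE_PIXEL_FRACTION = 0.2
_NOISE_CORRELATION_PX = 6.0


def _noise_field(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    if sd <= 0:
        return np.zeros(shape)
    sd_pixel = _NOISE_PIXEL_FRACTION * sd
    sd_mottle = float(np.sqrt(sd**2 - sd_pixel**2))
    mottle = ndi.gaussian_filter(rng.normal(0.0, 1.0, shape), _NOISE_CORRELATION_PX)
    mottle *= sd_mottle / max(mottle.std(), 1e-12)
    return sd_pixel * rng.normal(0.0, 1.0, shape) + mottle


def render_embryo(spec: SyntheticEmbryoSpec) -> tuple[RawImageSet, GroundTruth]:
    """Render one synthetic four-image set plus its ground truth.

    Deterministic for a fixed spec (byte-identical output on re-run).
    """
    h, w = spec.canvas
    a, b = spec.semi_major, spec.semi_minor
    u, v, (cy, cx) = _embryo_frame(spec)
    phi = np.deg2rad(spec.rotation)
    # embryo must fit the canvas with margin for the rim and the pipeline's
    # dilations (which must not reach the image border)
    reach = np.hypot(a * np.cos(phi), b * np.sin(phi)), np.hypot(a * np.sin(phi), b * np.cos(phi))
    margin = 12
    if cx - reach[0] < margin or cx + reach[0] > w - 1 - margin or cy - reach[1] < margin or cy + reach[1] > h - 1 - margin:
        raise ParameterError("embryo (plus margin) exceeds the canvas")

    rng = np.random.default_rng(spec.seed)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    inside = rho <= 1.0
    mask = np.where(inside, 255, 0).astype(np.uint8)

    # --- DIC: background + interior texture + dark rim just inside the edge
    # approximate signed distance to the ellipse via the local gradient of rho
    grad_scale = np.sqrt((u / a**2) ** 2 + (v / b**2) ** 2)
    dist = (rho - 1.0) / np.maximum(grad_scale, 1e-9)  # px, negative inside
    rim_width = 4.0
    rim = (dist <= 0) & (dist >= -rim_width)
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 2.0)
    texture *= 18.0 / max(texture.std(), 1e-9)
    dic_gray = np.full((h, w), spec.background, dtype=float)
    dic_gray[inside] += texture[inside]
    dic_gray[rim] = 45.0
    if spec.neighbor_at_border:
        # partial neighbour embryo clipped by the border, with its own rim
        rr, cc = np.indices((h, w), dtype=float)
        nb = (cc - (w - 1)) ** 2 / (0.25 * a) ** 2 + (rr - 0.15 * h) ** 2 / (
            0.2 * b + 20.0
        ) ** 2
        dic_gray[nb <= 1.0] = spec.background + 10.0
        dic_gray[(nb <= 1.0) & (nb >= 0.7)] = 45.0
    dic_gray += _noise_field(rng, (h, w), spec.noise_sd)
    dic = np.repeat(np.rint(dic_gray).clip(0, 255).astype(np.uint8)[..., None], 3, axis=2)

    # --- bright-field: flat background, graded stain in the domain channels
    el = (u / a + 1.0) * 50.0  # percent egg length, 0 at anterior (left) pole
    red = np.full((h, w), 60.0)
    green = np.full((h, w), 60.0)
    blue = np.full((h, w), 60.0)
    for dom in spec.domains:
        ramp = dom.plateau * (
            _sigmoid((el - dom.anterior) / dom.steepness)
            - _sigmoid((el - dom.posterior) / dom.steepness)
        )
        ramp = np.where(inside, ramp, 0.0)
        stain = dom.stain.lower().replace("/", "_")
        if stain in ("nbt_bcip", "nbt", "purple"):
            red += ramp
        elif stain in ("fastred", "fast_red", "red"):
            green += ramp
        else:
            raise ParameterError(f"unknown stain {dom.stain!r}")
    bf = np.stack([red, green, blue], axis=2)
    if spec.noise_sd > 0:
        bf = bf + np.stack(
            [_noise_field(rng, (h, w), spec.noise_sd) for _ in range(3)], axis=2
        )
    brightfield = np.rint(bf).clip(0, 255).astype(np.uint8)

    # --- nuclear counterstain: Gaussian dots in the blue channel
    nuc = np.zeros((h, w))
    n = max(int(spec.nucleus_count), 0)
    if n:
        # rejection-free placement in embryo-frame polar coordinates
        t = rng.uniform(0.0, 2 * np.pi, n)
        r_frac = np.sqrt(rng.uniform(0.0, 1.0, n)) * 0.92
        uu, vv = r_frac * a * np.cos(t), r_frac * b * np.sin(t)
        rr = cy - (uu * np.sin(phi) + vv * np.cos(phi))
        cc = cx + (uu * np.cos(phi) - vv * np.sin(phi))
        for ri, ci in zip(rr, cc):
            nuc[int(round(ri)), int(round(ci))] += 255.0
        nuc = ndi.gaussian_filter(nuc, 2.5)
        if nuc.max() > 0:
            nuc *= 220.0 / nuc.max()
    nuclear = np.zeros((h, w, 3), dtype=np.uint8)
    nuclear[..., 2] = np.rint(nuc).clip(0, 255).astype(np.uint8)

    # --- 40x membrane detail: plain texture patch
    memb_gray = 128.0 + ndi.gaussian_filter(rng.normal(0.0, 30.0, (256, 256)), 1.5)
    membrane = np.repeat(np.rint(memb_gray).clip(0, 255).astype(np.uint8)[..., None], 3, axis=2)

    # ground-truth midline: major axis segment in canvas coordinates
    t = np.linspace(-a, a, 201)
    midline = np.stack([cy - t * np.sin(phi), cx + t * np.cos(phi)], axis=1)
    truth = GroundTruth(
        mask=mask,
        angle=spec.rotation,
        midline=midline,
        boundaries=[
            {
                "stain": d.stain,
                "anterior": d.anterior,
                "posterior": d.posterior,
                "plateau": d.plateau,
            }
            for d in spec.domains
        ],
    )
    return RawImageSet(brightfield=brightfield, dic=dic, nuclear=nuclear, membrane=membrane), truth


def render_batch(
    specs: list[SyntheticEmbryoSpec], seed: int = 0
) -> tuple[list[tuple[RawImageSet, GroundTruth]], list[dict]]:
    """Render one set per spec with per-embryo seeds derived from ``seed``.

    Returns the rendered sets and a manifest (one dict per embryo with the
    ground-truth values, suitable for a CSV).
    """
    if not specs:
        raise ParameterError("need at least one spec")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(specs)) % (2**31)
    sets, manifest = [], []
    for i, (spec, s) in enumerate(zip(specs, child_seeds)):
        spec_i = replace(spec, seed=int(s))
        rendered = render_embryo(spec_i)
        sets.append(rendered)
        row = {
            "embryo_id": f"{i + 1:03d}",
            "seed": int(s),
            "angle": spec_i.rotation,
            "semi_major": spec_i.semi_major,
            "semi_minor": spec_i.semi_minor,
            "noise_sd": spec_i.noise_sd,
        }
        for j, d in enumerate(spec_i.domains):
            row[f"domain{j}_stain"] = d.stain
            row[f"domain{j}_anterior"] = d.anterior
            row[f"domain{j}_posterior"] = d.posterior
        manifest.append(row)
    return sets, manifest


def write_image_set(images: RawImageSet, directory: str | Path, embryo_id: str) -> dict[str, Path]:
    """Write the four images as PNG using the NNN / NNN_dic / NNN_nuc /
    NNN_memb naming convention; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "brightfield": directory / f"{embryo_id}.png",
        "dic": directory / f"{embryo_id}_dic.png",
        "nuclear": directory / f"{embryo_id}_nuc.png",
        "membrane": directory / f"{embryo_id}_memb.png",
    }
    iio.imwrite(paths["brightfield"], images.brightfield)
    iio.imwrite(paths["dic"], images.dic)
    iio.imwrite(paths["nuclear"], images.nuclear)
    iio.imwrite(paths["membrane"], images.membrane)
    return paths


def write_manifest(manifest: list[dict], path: str | Path) -> Path:
    """Write the ground-truth manifest of :func:`render_batch` as CSV."""
    path = Path(path)
    keys: list[str] = []
    for row in manifest:
        keys.extend(k for k in row if k not in keys)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(manifest)
    return path
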