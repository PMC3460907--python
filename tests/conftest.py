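import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def ellipse_mask(shape=(240, 420), a=180.0, b=60.0, angle_deg=0.0):
    """Direct analytic ellipse mask (no generator) for geometry tests."""
    h, w = shape
    phi = np.deg2rad(angle_deg)
    r, c = np.indices(shape, dtype=float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    x = c - cx
    y = -(r - cy)
    u = x * np.cos(phi) + y * np.sin(phi)
    v = -x * np.sin(phi) + y * np.cos(phi)
    return np.where((u / a) ** 2 + (v / b) ** 2 <= 1.0, 255, 0).astype(np.uint8)


def iou(a, b):
    a, b = np.asarray(a) > 0, np.asarray(b) > 0
    return (a & b).sum() / (a | b).sum()


@pytest.fixture(scope="session")
def domain_embryo():
    """One noiseless rotated embryo with an NBT and a FastRed domain,
    processed through mask -> orient -> profile; shared across tests."""
    from flystrip.orientation import orient_embryo
    from flystrip.profiles import extract_from_oriented
    from flystrip.segmentation import make_mask
    from flystrip.synthetic import Domain, SyntheticEmbryoSpec, render_embryo

    spec = SyntheticEmbryoSpec(
        seed=7,
        rotation=18.0,
        domains=(
            Domain("NBT_BCIP", 40.0, 60.0, steepness=2.0, plateau=120.0),
            Domain("FastRed", 70.0, 85.0, steepness=2.0, plateau=120.0),
        ),
    )
    images, truth = render_embryo(spec)
    em = make_mask(images.dic)
    mask, (bf,), ores = orient_embryo(em.mask, [images.brightfield])
    profile, strip, spline = extract_from_oriented(mask, bf)
    return {
        "spec": spec,
        "images": images,
        "truth": truth,
        "embryo_mask": em,
        "oriented_mask": mask,
        "oriented_bf": bf,
        "orientation": ores,
        "profile": profile,
        "strip": strip,
        "spline": spline,
    }


def half_max_crossings(positions, signal, background=None):
    """Linear-interpolated half-maximum crossing positions of a signal."""
    signal = np.asarray(signal, dtype=float)
    if background is None:
        background = np.partition(signal, signal.size // 4)[: signal.size // 4].mean()
    s = signal - background
    half = s.max() / 2.0
    above = s >= half
    out = []
    for i in np.flatnonzero(np.diff(above.astype(int))):
        x0, x1 = positions[i], positions[i + 1]
        y0, y1 = s[i], s[i + 1]
        out.append(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
    return out
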