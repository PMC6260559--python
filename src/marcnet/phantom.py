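"""Synthetic pelvis-like CT slices and brachytherapy-applicator metal masks.

The generators here stand in for a clinical image source: seeded, purely
elliptical compositions (Shepp-Logan style) so that analytic projection
oracles stay available to the test suite.  Tissue classes use conventional
Hounsfield ranges: air -1000 HU, soft tissue 0-80 HU, trabecular/cortical
bone 700-1500 HU.  Metal is *not* part of the phantom; implants are
described separately by :class:`MetalMask` and inserted by the artifact
simulator.

Coordinate convention (used by every module): row-major arrays, 0-based
indices, pixel centers at integer coordinates, ``values[i, j]`` = row i,
column j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "MetalMask",
    "generate_phantom",
    "generate_metal_mask",
    "body_ellipse",
    "APPLICATORS",
]

#: Default display window in Hounsfield units.
DEFAULT_HU_WINDOW = (-1000.0, 3000.0)

#: Known applicator geometries for :func:`generate_metal_mask`.
APPLICATORS = ("tandem", "ovoid-pair", "needle-set")

MIN_SIZE = 16
MIN_PHANTOM_SIZE = 32


@dataclass
class ImageGrid:
    """A real-valued 2-D grid of attenuation values on an HU-like scale.

    Parameters
    ----------
    values:
        ``(H, W)`` float array of HU values.
    spacing_mm:
        Physical pixel spacing ``(row, col)`` in millimetres.
    hu_window:
        The ``(hu_min, hu_max)`` window the values are expected to lie in.
        Images that legitimately contain metal carry a widened window.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ImageGrid values must be 2-D")
        h, w = self.values.shape
        if h < MIN_SIZE or w < MIN_SIZE:
            raise ValueError(f"ImageGrid must be at least {MIN_SIZE}x{MIN_SIZE}, got {h}x{w}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageGrid values must be finite")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        lo, hi = self.hu_window
        if self.values.min() < lo - 1e-9 or self.values.max() > hi + 1e-9:
            raise ValueError(
                f"values [{self.values.min():.1f}, {self.values.max():.1f}] "
                f"outside HU window [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy_with(self, values: np.ndarray, hu_window: tuple[float, float] | None = None) -> "ImageGrid":
        return ImageGrid(values, self.spacing_mm, hu_window or self.hu_window)


@dataclass
class MetalMask:
    """Binary implant mask paired with an :class:`ImageGrid` of equal shape."""

    mask: np.ndarray
    applicator: str = "tandem"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("MetalMask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


def body_ellipse(size: tuple[int, int]) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fixed body-outline ellipse for a given image size.

    Returns ``(center_rc, semi_axes_rc)``.  The outline is a deterministic
    function of the size alone so that implant masks generated for any seed
    are guaranteed to lie inside the body support of any phantom of the
    same size.
    """
    h, w = size
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    semi = (0.40 * h, 0.46 * w)
    return center, semi


def _ellipse(shape, center, semi, angle_deg=0.0, rho=1.0):
    """Boolean mask of a (rotated) filled ellipse; pixel-center sampling."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy = yy - center[0]
    dx = xx - center[1]
    if angle_deg:
        t = np.deg2rad(angle_deg)
        dy, dx = dy * np.cos(t) + dx * np.sin(t), -dy * np.sin(t) + dx * np.cos(t)
    a, b = semi
    return (dy / a) ** 2 + (dx / b) ** 2 <= rho**2


def generate_phantom(seed: int, size: tuple[int, int], complexity: int = 3) -> ImageGrid:
    """Generate a seeded pelvis-like artifact-free slice.

    The slice is an air background (-1000 HU) with a soft-tissue body
    ellipse (0-80 HU, with low-contrast internal structure), and 2-6 bone
    ellipses (700-1500 HU) arranged in a girdle-like ring so the central
    region stays soft tissue (where applicators sit clinically).

    Parameters
    ----------
    seed:
        RNG seed; identical seeds reproduce the grid bit-for-bit.
    size:
        ``(H, W)``, each at least 32.
    complexity:
        Small integer scaling the number of low-contrast soft-tissue
        inserts (default 3).
    """
    h, w = size
    if h < MIN_PHANTOM_SIZE or w < MIN_PHANTOM_SIZE:
        raise ValueError(f"phantom size must be at least {MIN_PHANTOM_SIZE}, got {size}")
    rng = np.random.default_rng(seed)
    center, semi = body_ellipse(size)
    body = _ellipse(size, center, semi)

    values = np.full(size, -1000.0)
    base = rng.uniform(20.0, 55.0)
    values[body] = base

    # Low-contrast soft-tissue inserts (bladder/bowel-like), kept inside the body.
    n_soft = max(1, int(complexity)) + rng.integers(0, 3)
    for _ in range(n_soft):
        rho = rng.uniform(0.0, 0.55)
        phi = rng.uniform(0, 2 * np.pi)
        c = (center[0] + rho * semi[0] * np.sin(phi), center[1] + rho * semi[1] * np.cos(phi))
        ax = (rng.uniform(0.06, 0.22) * semi[0], rng.uniform(0.06, 0.22) * semi[1])
        delta = rng.uniform(-45.0, 30.0)
        e = _ellipse(size, c, ax, angle_deg=rng.uniform(0, 180)) & body
        values[e] = np.clip(values[e] + delta, 0.0, 80.0)

    # Bone girdle: 2-6 ellipses on a ring around the center.
    n_bone = int(rng.integers(2, 7))
    s = min(h, w)
    phis = rng.uniform(0, 2 * np.pi) + np.linspace(0, 2 * np.pi, n_bone, endpoint=False)
    for phi in phis:
        rho = rng.uniform(0.55, 0.75)
        c = (center[0] + rho * semi[0] * np.sin(phi), center[1] + rho * semi[1] * np.cos(phi))
        ax = (rng.uniform(0.045, 0.095) * s, rng.uniform(0.045, 0.095) * s)
        hu = rng.uniform(700.0, 1500.0)
        e = _ellipse(size, c, ax, angle_deg=rng.uniform(0, 180)) & body
        values[e] = hu

    # Partial-volume/detector blur: clinical slices are band-limited by the
    # reconstruction kernel; a small Gaussian keeps the phantom consistent
    # with what a real scan of this geometry would contain.
    values = ndimage.gaussian_filter(values, sigma=0.8)
    np.clip(values, -1000.0, DEFAULT_HU_WINDOW[1], out=values)
    return ImageGrid(values, hu_window=DEFAULT_HU_WINDOW)


def _rod(shape, center, length, width, angle_deg):
    """Filled rod (rectangle with semicircular caps) as a boolean mask."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy = yy - center[0]
    dx = xx - center[1]
    t = np.deg2rad(angle_deg)
    # u along the rod axis, v across it
    u = dy * np.cos(t) + dx * np.sin(t)
    v = -dy * np.sin(t) + dx * np.cos(t)
    half = length / 2.0
    r = width / 2.0
    body = (np.abs(u) <= half) & (np.abs(v) <= r)
    caps = ((np.abs(u) - half) ** 2 + v**2 <= r**2) & (np.abs(u) > half)
    return body | caps


def generate_metal_mask(seed: int, size: tuple[int, int], applicator: str) -> MetalMask:
    """Generate a seeded binary implant mask for one applicator type.

    ``tandem`` is a single intrauterine rod with a rounded tip;
    ``ovoid-pair`` two colpostat disks; ``needle-set`` 3-8 thin parallel
    interstitial rods.  All geometry is placed well inside the fixed body
    ellipse of :func:`body_ellipse`, so the mask never touches air for any
    phantom of the same size.
    """
    if applicator not in APPLICATORS:
        raise ValueError(f"unknown applicator {applicator!r}; expected one of {APPLICATORS}")
    h, w = size
    if h < MIN_PHANTOM_SIZE or w < MIN_PHANTOM_SIZE:
        raise ValueError(f"mask size must be at least {MIN_PHANTOM_SIZE}, got {size}")
    rng = np.random.default_rng(seed)
    center, semi = body_ellipse(size)
    s = min(h, w)
    mask = np.zeros(size, dtype=bool)

    def jitter(scale=0.15):
        return (
            center[0] + rng.uniform(-scale, scale) * semi[0],
            center[1] + rng.uniform(-scale, scale) * semi[1],
        )

    if applicator == "tandem":
        length = rng.uniform(0.18, 0.30) * s
        width = max(2.0, rng.uniform(0.025, 0.045) * s)
        angle = 90.0 + rng.uniform(-20.0, 20.0)  # near-vertical rod
        mask |= _rod(size, jitter(), length, width, angle)
    elif applicator == "ovoid-pair":
        r = max(1.6, rng.uniform(0.035, 0.06) * s)
        sep = rng.uniform(2.6, 3.6) * r
        c = jitter(0.10)
        for sgn in (-1.0, 1.0):
            mask |= _ellipse(size, (c[0], c[1] + sgn * sep / 2.0), (r, r))
    else:  # needle-set
        n = int(rng.integers(3, 9))
        length = rng.uniform(0.14, 0.24) * s
        width = max(1.2, rng.uniform(0.012, 0.02) * s)
        angle = 90.0 + rng.uniform(-10.0, 10.0)
        span = rng.uniform(0.25, 0.45) * semi[1]
        c = jitter(0.08)
        offsets = np.linspace(-span / 2.0, span / 2.0, n)
        for off in offsets:
            mask |= _rod(size, (c[0], c[1] + off), length, width, angle)

    # Belt and braces: never leave the inner body region.
    mask &= _ellipse(size, center, semi, rho=0.90)
    if not mask.any():
        raise RuntimeError("generated mask is empty; size too small for applicator geometry")
    return MetalMask(mask, applicator=applicator)
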