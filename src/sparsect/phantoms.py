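"""Synthetic ground-truth phantoms.

Ground-truth images are square 2D arrays with values in [0, 1] (pixel size
1 length unit).  Three families are provided:

* ``chest-like`` — the in-domain training family: a soft-tissue body
  ellipse containing lung-like low-intensity regions, a spine-like dense
  object and random soft-tissue blobs, plus mild zero-mean Gaussian texture
  inside the object support.  The texture emulates the fact that measured
  clinical ground truths are never noise-free.
* ``flat-sharp`` — the out-of-domain family: completely noise-free, flat
  regions containing small, sharp, high-contrast objects.
* ``shepp-logan`` — the canonical head phantom (modified intensities, so
  values already lie in [0, 1]); mainly used for analytic projector checks.

Ellipse parameters live in normalized coordinates: centers and semi-axes
are fractions of the half image side, rotation angles in degrees CCW.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Ellipse", "PhantomSpec", "generate_phantom", "generate_dataset",
           "scale_to_unit", "render_ellipses", "SHEPP_LOGAN"]

FAMILIES = ("chest-like", "flat-sharp", "shepp-logan")


@dataclass(frozen=True)
class Ellipse:
    """(cx, cy) center, (a, b) semi-axes — all fractions of the half-side —
    rotation angle in degrees CCW, and additive intensity."""
    cx: float
    cy: float
    a: float
    b: float
    angle: float
    intensity: float

    def contains(self, x: float | np.ndarray, y: float | np.ndarray):
        t = np.deg2rad(self.angle)
        xr = (x - self.cx) * np.cos(t) + (y - self.cy) * np.sin(t)
        yr = -(x - self.cx) * np.sin(t) + (y - self.cy) * np.cos(t)
        return (xr / self.a) ** 2 + (yr / self.b) ** 2 <= 1.0


# Modified Shepp-Logan intensities (summed image lies in [0, 1]).
SHEPP_LOGAN: tuple[Ellipse, ...] = (
    Ellipse(0.0, 0.0, 0.69, 0.92, 0.0, 1.0),
    Ellipse(0.0, -0.0184, 0.6624, 0.874, 0.0, -0.8),
    Ellipse(0.22, 0.0, 0.11, 0.31, -18.0, -0.2),
    Ellipse(-0.22, 0.0, 0.16, 0.41, 18.0, -0.2),
    Ellipse(0.0, 0.35, 0.21, 0.25, 0.0, 0.1),
    Ellipse(0.0, 0.1, 0.046, 0.046, 0.0, 0.1),
    Ellipse(0.0, -0.1, 0.046, 0.046, 0.0, 0.1),
    Ellipse(-0.08, -0.605, 0.046, 0.023, 0.0, 0.1),
    Ellipse(0.0, -0.606, 0.023, 0.023, 0.0, 0.1),
    Ellipse(0.06, -0.605, 0.023, 0.046, 0.0, 0.1),
)


@dataclass
class PhantomSpec:
    """Recipe for one phantom image.

    If ``ellipses`` is None the family's randomized generator draws them
    from ``seed``; otherwise the given list is rendered as-is.
    ``texture_sigma`` is the std-dev of the intra-object Gaussian texture
    (chest-like family only; the flat-sharp family is noise-free by
    contract).
    """
    family: str = "chest-like"
    size: int = 128
    ellipses: list | None = None
    texture_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {FAMILIES}")
        if self.size < 16:
            raise ValueError("size must be >= 16")
        if self.family == "flat-sharp" and self.texture_sigma != 0:
            self.texture_sigma = 0.0


def _grid(size: int):
    c = (np.arange(size) + 0.5) / size * 2.0 - 1.0
    return np.meshgrid(c, c)   # x (columns), y (rows)


def render_ellipses(ellipses, size: int, supersample: int = 4) -> np.ndarray:
    """Sum of ellipse intensities on a size x size grid (no rescaling).

    Pixels are area-weighted by ``supersample`` x ``supersample``
    subsampling, the correct discretization of the continuous phantom:
    binary-edged rasterization would put spurious energy above the band
    limit of any scanner model.  Interior pixels carry the exact summed
    intensities either way.
    """
    ss = max(1, int(supersample))
    x, y = _grid(size * ss)
    img = np.zeros((size * ss, size * ss))
    for e in ellipses:
        img[e.contains(x, y)] += e.intensity
    if ss == 1:
        return img
    return img.reshape(size, ss, size, ss).mean(axis=(1, 3))


def _chest_ellipses(rng: np.random.Generator) -> list[Ellipse]:
    es = []
    body_a = rng.uniform(0.75, 0.9)
    body_b = rng.uniform(0.55, 0.7)
    ang = rng.uniform(-8, 8)
    es.append(Ellipse(rng.uniform(-0.04, 0.04), rng.uniform(-0.04, 0.04),
                      body_a, body_b, ang, rng.uniform(0.3, 0.4)))
    # two lung-like hypodense regions, roughly mirrored
    for sgn in (-1, 1):
        es.append(Ellipse(sgn * rng.uniform(0.3, 0.42),
                          rng.uniform(-0.08, 0.08),
                          rng.uniform(0.18, 0.28), rng.uniform(0.3, 0.42),
                          sgn * rng.uniform(5, 20),
                          -rng.uniform(0.18, 0.26)))
    # spine-like dense object near the posterior midline
    es.append(Ellipse(rng.uniform(-0.05, 0.05), rng.uniform(-0.55, -0.4),
                      rng.uniform(0.08, 0.12), rng.uniform(0.06, 0.1),
                      0.0, rng.uniform(0.35, 0.5)))
    # random soft-tissue blobs
    for _ in range(rng.integers(3, 7)):
        es.append(Ellipse(rng.uniform(-0.4, 0.4), rng.uniform(-0.35, 0.35),
                          rng.uniform(0.04, 0.2), rng.uniform(0.04, 0.2),
                          rng.uniform(0, 180), rng.uniform(0.05, 0.2)))
    return es


def _flat_sharp_ellipses(rng: np.random.Generator) -> list[Ellipse]:
    es = [Ellipse(0.0, 0.0, rng.uniform(0.78, 0.88), rng.uniform(0.78, 0.88),
                  0.0, rng.uniform(0.45, 0.55))]
    for _ in range(rng.integers(5, 10)):
        r = rng.uniform(0.0, 0.6)
        phi = rng.uniform(0, 2 * np.pi)
        size = rng.uniform(0.015, 0.06)
        bright = rng.random() < 0.6
        es.append(Ellipse(r * np.cos(phi), r * np.sin(phi),
                          size, size * rng.uniform(0.6, 1.0),
                          rng.uniform(0, 180),
                          rng.uniform(0.3, 0.45) if bright
                          else -rng.uniform(0.25, 0.4)))
    return es


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom; deterministic in (spec, spec.seed).

    Values are guaranteed in [0, 1]: if the summed ellipse intensities
    leave that range the image is affinely rescaled (a log record is
    emitted — intensities are never silently clipped).
    """
    rng = np.random.default_rng(spec.seed)
    ellipses = spec.ellipses
    if ellipses is None:
        if spec.family == "chest-like":
            ellipses = _chest_ellipses(rng)
        elif spec.family == "flat-sharp":
            ellipses = _flat_sharp_ellipses(rng)
        else:
            ellipses = list(SHEPP_LOGAN)
    img = render_ellipses(ellipses, spec.size)
    if spec.family == "chest-like" and spec.texture_sigma > 0 and ellipses:
        x, y = _grid(spec.size)
        support = np.zeros((spec.size, spec.size), bool)
        for e in ellipses:
            support |= np.asarray(e.contains(x, y))
        tex = rng.normal(0.0, spec.texture_sigma, img.shape)
        img = img + np.where(support, tex, 0.0)
    lo, hi = float(img.min()), float(img.max())
    if lo < 0.0 or hi > 1.0:
        logger.info("phantom (family=%s seed=%s) range [%.3f, %.3f] exceeds "
                    "[0, 1]; rescaling affinely", spec.family, spec.seed,
                    lo, hi)
        img = scale_to_unit(img)
    return img


def generate_dataset(n: int, spec_template: PhantomSpec, seed: int,
                     split: str = "train") -> list[np.ndarray]:
    """n phantoms with randomized parameters around the template family.

    Train and test splits use disjoint seed streams derived from ``seed``,
    so the two sets never share an image.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if split not in ("train", "test"):
        raise ValueError("split must be 'train' or 'test'")
    ss = np.random.SeedSequence((int(seed), 0 if split == "train" else 1))
    children = ss.spawn(n)
    out = []
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(generate_phantom(replace(spec_template, ellipses=None,
                                            seed=child_seed)))
    return out


def scale_to_unit(img: np.ndarray) -> np.ndarray:
    """Affine rescale so min -> 0 and max -> 1; a constant image maps to
    all zeros (documented degenerate rule)."""
    img = np.asarray(img, float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)
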