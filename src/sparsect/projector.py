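"""Forward projection (sinogram simulation) and measurement noise.

Two beam geometries are supported:

* ``parallel`` — classic Radon geometry; used for analytic unit checks
  (chord lengths, mass conservation, rotational symmetry).
* ``fan-flat`` — fan beam with a flat detector; the sparse-view study
  presets use it because only a divergent beam distinguishes a 360-view
  full-circle scan from a 180-view half-circle scan informationally.

Detector offsets are measured on a virtual flat detector through the
rotation axis, perpendicular to the central ray, in pixel-length units.
Angles are degrees CCW from the +x axis of the image grid.  Line integrals
are evaluated by marching each ray at half-pixel steps with bilinear
interpolation, which is linear in the image by construction.

The two named acquisition protocols:

* ``full-range``  — 360 views, 1° spacing over [0°, 360°).
* ``half-range``  — 180 views over [0°, 180°) (limited-angle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba
import numpy as np

__all__ = ["ScanGeometry", "Sinogram", "make_geometry", "forward_project",
           "add_noise", "default_n_detectors"]

PROTOCOLS = ("full-range", "half-range", "custom")


@dataclass(frozen=True)
class ScanGeometry:
    beam: str                      # "parallel" | "fan-flat"
    angle_start: float             # degrees, inclusive
    angle_end: float               # degrees, exclusive
    n_views: int
    n_detectors: int
    detector_spacing: float = 1.0  # pixel lengths, on the virtual detector
    source_axis_distance: float = 0.0   # fan only
    axis_detector_distance: float = 0.0  # fan only (records the physical set-up)
    protocol_tag: str = "custom"

    def __post_init__(self):
        if self.beam not in ("parallel", "fan-flat"):
            raise ValueError(f"unknown beam {self.beam!r}")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.angle_end <= self.angle_start:
            raise ValueError("angles must be strictly increasing")
        if self.protocol_tag not in PROTOCOLS:
            raise ValueError(f"unknown protocol tag {self.protocol_tag!r}")
        if self.beam == "fan-flat" and self.source_axis_distance <= 0:
            raise ValueError("fan-flat beam needs source_axis_distance > 0")

    @property
    def angles_deg(self) -> np.ndarray:
        step = (self.angle_end - self.angle_start) / self.n_views
        return self.angle_start + step * np.arange(self.n_views)

    @property
    def angular_span_rad(self) -> float:
        return math.radians(self.angle_end - self.angle_start)

    @property
    def detector_offsets(self) -> np.ndarray:
        return (np.arange(self.n_detectors)
                - (self.n_detectors - 1) / 2) * self.detector_spacing


@dataclass
class Sinogram:
    values: np.ndarray             # (n_views, n_detectors)
    geometry: ScanGeometry
    noise_level: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.geometry.n_views,
                                 self.geometry.n_detectors):
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"({self.geometry.n_views} x {self.geometry.n_detectors})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")


def default_n_detectors(image_size: int) -> int:
    """ceil(sqrt(2) * size) rounded up to even: covers the image diagonal."""
    n = math.ceil(math.sqrt(2.0) * image_size)
    return n + (n % 2)


def make_geometry(protocol_tag: str, image_size: int, beam: str | None = None,
                  n_views: int | None = None, angle_start: float = 0.0,
                  angle_end: float | None = None,
                  n_detectors: int | None = None) -> ScanGeometry:
    """Build a scan geometry for one of the named protocols.

    The study presets (``full-range``, ``half-range``) default to the
    fan-flat beam with source–axis and axis–detector distances both equal
    to twice the image width; ``custom`` requires ``n_views`` (and takes
    any of the optional overrides).
    """
    if protocol_tag not in PROTOCOLS:
        raise ValueError(f"unknown protocol tag {protocol_tag!r}; "
                         f"choose from {PROTOCOLS}")
    nd = n_detectors if n_detectors is not None else default_n_detectors(image_size)
    if protocol_tag == "full-range":
        beam = beam or "fan-flat"
        n_views, angle_start, angle_end = 360, 0.0, 360.0
    elif protocol_tag == "half-range":
        beam = beam or "fan-flat"
        n_views, angle_start, angle_end = 180, 0.0, 180.0
    else:
        beam = beam or "parallel"
        if n_views is None:
            raise ValueError("custom protocol requires n_views")
        if angle_end is None:
            angle_end = 180.0
    dso = dod = 2.0 * image_size if beam == "fan-flat" else 0.0
    return ScanGeometry(beam=beam, angle_start=angle_start,
                        angle_end=angle_end, n_views=n_views, n_detectors=nd,
                        detector_spacing=1.0, source_axis_distance=dso,
                        axis_detector_distance=dod, protocol_tag=protocol_tag)


# ---------------------------------------------------------------------------
# ray marching
# ---------------------------------------------------------------------------

@numba.njit(cache=True, fastmath=True)
def _bilinear(img, r, c):
    H, W = img.shape
    if r < -1.0 or r > H or c < -1.0 or c > W:
        return 0.0
    r0 = int(math.floor(r))
    c0 = int(math.floor(c))
    fr = r - r0
    fc = c - c0
    v = 0.0
    for dr in range(2):
        rr = r0 + dr
        if rr < 0 or rr >= H:
            continue
        wr = fr if dr == 1 else 1.0 - fr
        for dc in range(2):
            cc = c0 + dc
            if cc < 0 or cc >= W:
                continue
            wc = fc if dc == 1 else 1.0 - fc
            v += wr * wc * img[rr, cc]
    return v


@numba.njit(cache=True, fastmath=True)
def _project_kernel(img, angles_rad, offsets, fan, dso, step):
    n_views = angles_rad.shape[0]
    n_det = offsets.shape[0]
    H, W = img.shape
    cy = (H - 1) / 2.0
    cx = (W - 1) / 2.0
    radius = math.hypot(H, W) / 2.0 + 1.0
    sino = np.zeros((n_views, n_det), np.float64)
    for v in range(n_views):
        ca = math.cos(angles_rad[v])
        sa = math.sin(angles_rad[v])
        # unit vectors: n = (ca, sa) toward the source, e = (-sa, ca) along
        # the virtual detector
        for d in range(n_det):
            u = offsets[d]
            if fan:
                sx = dso * ca
                sy = dso * sa
                px = -u * sa
                py = u * ca
                dx = px - sx
                dy = py - sy
                norm = math.hypot(dx, dy)
                dx /= norm
                dy /= norm
                ox, oy = sx, sy
            else:
                # parallel limit of the fan: direction -n, through u*e
                dx = -ca
                dy = -sa
                ox = -u * sa
                oy = u * ca
            # clip ray o + t*d to the circle of given radius
            b = ox * dx + oy * dy
            cc = ox * ox + oy * oy - radius * radius
            disc = b * b - cc
            if disc <= 0.0:
                continue
            sq = math.sqrt(disc)
            t0 = -b - sq
            t1 = -b + sq
            n_steps = int(math.ceil((t1 - t0) / step))
            acc = 0.0
            for i in range(n_steps):
                t = t0 + (i + 0.5) * step
                if t >= t1:
                    break
                x = ox + t * dx
                y = oy + t * dy
                acc += _bilinear(img, y + cy, x + cx)
            sino[v, d] = acc * step
    return sino


def forward_project(img: np.ndarray, geom: ScanGeometry,
                    step: float = 0.5) -> Sinogram:
    """Discretized line integrals of ``img`` along every (view, detector)
    ray.  Linear in the image; rays missing the support give zeros."""
    img = np.ascontiguousarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be square 2D")
    vals = _project_kernel(img, np.deg2rad(geom.angles_deg),
                           geom.detector_offsets.astype(np.float64),
                           geom.beam == "fan-flat",
                           float(geom.source_axis_distance), float(step))
    return Sinogram(vals, geom)


def add_noise(sino: Sinogram, level: float, seed: int) -> Sinogram:
    """Additive white Gaussian noise at a relative-energy ``level``.

    e = level * (||b||_2 / sqrt(m)) * xi  with xi ~ N(0, I) over all m
    entries, so E ||e||_2 / ||b||_2 = level.  Deterministic given ``seed``.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return Sinogram(sino.values.copy(), sino.geometry, 0.0, seed)
    rng = np.random.default_rng(seed)
    b = sino.values
    sigma = level * np.linalg.norm(b) / math.sqrt(b.size)
    return Sinogram(b + rng.normal(0.0, sigma, b.shape), sino.geometry,
                    float(level), int(seed))
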