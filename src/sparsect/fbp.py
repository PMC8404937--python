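"""Filtered back-projection.

Produces the artefact-corrupted images y that the learned post-processing
networks are trained to correct.  The filter is the standard band-limited
ramp obtained by FFT of the discrete spatial-domain ramp kernel (sample the
kernel, not |f|, to avoid the DC-bias cupping of a frequency-sampled ramp);
the sampled kernel's small positive DC term is kept, because it is exactly
what compensates the low-frequency deficit of the truncated ramp (zeroing
it biases flat regions down by ~1%).  Constant detector rows are therefore
suppressed to ~1e-3 of their mean rather than exactly to zero.
Optional Hann / cosine apodization windows and a fractional
Nyquist cutoff are available; the default is the plain ramp at full cutoff.

Fan-flat sinograms are cosine pre-weighted before filtering and
back-projected with the usual inverse-square distance weight.  A half-range
(180°) fan scan is *less* than a short scan, and no Parker-style weighting
is applied: the resulting limited-angle artefacts are exactly the degraded
inputs the post-processing study is about.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba
import numpy as np

from .projector import Sinogram

__all__ = ["FilterSpec", "ramp_filter", "ramp_frequency_response",
           "fbp_reconstruct"]

WINDOWS = ("ram-lak", "hann", "cosine")


@dataclass(frozen=True)
class FilterSpec:
    window: str = "ram-lak"
    cutoff: float = 1.0            # fraction of Nyquist in (0, 1]

    def __post_init__(self):
        if self.window not in WINDOWS:
            raise ValueError(f"unknown window {self.window!r}")
        if not 0.0 < self.cutoff <= 1.0:
            raise ValueError("cutoff must be in (0, 1]")


def _next_pow2(n: int) -> int:
    return 1 << max(0, (n - 1).bit_length())


def ramp_frequency_response(n_detectors: int, filt: FilterSpec,
                            spacing: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """(frequencies, response) of the discrete ramp filter actually applied.

    The response is the FFT of the sampled spatial ramp kernel over the
    zero-padded window, windowed and cut off per ``filt``.  For the plain
    ramp it approximates |f| up to the cutoff; the residual DC term of the
    truncated kernel is retained deliberately (see module docstring).
    """
    nfft = _next_pow2(2 * n_detectors)
    h = np.zeros(nfft)
    h[0] = 1.0 / (4.0 * spacing ** 2)
    k = np.arange(1, nfft // 2 + 1)
    odd = k[k % 2 == 1]
    h[odd] = -1.0 / (np.pi * odd * spacing) ** 2
    h[-odd] = -1.0 / (np.pi * odd * spacing) ** 2
    H = np.real(np.fft.rfft(h))
    f = np.fft.rfftfreq(nfft, d=spacing)
    f_nyq = 1.0 / (2.0 * spacing)
    fc = filt.cutoff * f_nyq
    if filt.window == "hann":
        w = np.where(f <= fc, 0.5 * (1.0 + np.cos(np.pi * f / fc)), 0.0)
    elif filt.window == "cosine":
        w = np.where(f <= fc, np.cos(np.pi * f / (2.0 * fc)), 0.0)
    else:
        w = (f <= fc).astype(float)
    return f, H * w


def ramp_filter(sino: Sinogram, filt: FilterSpec = FilterSpec()) -> Sinogram:
    """Convolve every view row with the windowed ramp kernel (linear op).

    Fan-flat rows are cosine pre-weighted (D/sqrt(D^2+u^2)) first, as
    required by the flat-detector fan inversion formula.
    """
    geom = sino.geometry
    nd = geom.n_detectors
    if nd < 2:
        raise ValueError("need at least 2 detector bins to filter")
    ds = geom.detector_spacing
    rows = sino.values
    if geom.beam == "fan-flat":
        u = geom.detector_offsets
        dso = geom.source_axis_distance
        rows = rows * (dso / np.sqrt(dso ** 2 + u ** 2))
    nfft = _next_pow2(2 * nd)
    _, H = ramp_frequency_response(nd, filt, ds)
    spec = np.fft.rfft(rows, n=nfft, axis=1)
    filtered = np.fft.irfft(spec * H, n=nfft, axis=1)[:, :nd] * ds
    return Sinogram(filtered, geom, sino.noise_level, sino.seed)


@numba.njit(cache=True, fastmath=True)
def _backproject_parallel(q, angles_rad, spacing, out_size, scale):
    n_views, nd = q.shape
    img = np.zeros((out_size, out_size))
    c = (out_size - 1) / 2.0
    off0 = (nd - 1) / 2.0
    for v in range(n_views):
        ca = math.cos(angles_rad[v])
        sa = math.sin(angles_rad[v])
        for r in range(out_size):
            y = r - c
            for cc in range(out_size):
                x = cc - c
                u = (-x * sa + y * ca) / spacing + off0
                i0 = int(math.floor(u))
                if i0 < -1 or i0 > nd - 1:
                    continue
                fu = u - i0
                v0 = q[v, i0] if i0 >= 0 else 0.0
                v1 = q[v, i0 + 1] if i0 + 1 < nd else 0.0
                img[r, cc] += (1.0 - fu) * v0 + fu * v1
    return img * scale


@numba.njit(cache=True, fastmath=True)
def _backproject_fan(q, angles_rad, spacing, dso, out_size, scale):
    n_views, nd = q.shape
    img = np.zeros((out_size, out_size))
    c = (out_size - 1) / 2.0
    off0 = (nd - 1) / 2.0
    for v in range(n_views):
        ca = math.cos(angles_rad[v])
        sa = math.sin(angles_rad[v])
        for r in range(out_size):
            y = r - c
            for cc in range(out_size):
                x = cc - c
                U = dso - (x * ca + y * sa)
                if U <= 1e-6:
                    continue
                t = -x * sa + y * ca
                u = (dso * t / U) / spacing + off0
                i0 = int(math.floor(u))
                if i0 < -1 or i0 > nd - 1:
                    continue
                fu = u - i0
                v0 = q[v, i0] if i0 >= 0 else 0.0
                v1 = q[v, i0 + 1] if i0 + 1 < nd else 0.0
                w = dso * dso / (U * U)
                img[r, cc] += w * ((1.0 - fu) * v0 + fu * v1)
    return img * scale


def fbp_reconstruct(sino: Sinogram, filt: FilterSpec = FilterSpec(),
                    out_size: int | None = None) -> np.ndarray:
    """Filter, then back-project; returns the reconstructed image.

    The angular scale is the view spacing in radians, halved when the scan
    spans more than 180° (every line integral is then measured twice).  A
    single-view sinogram back-projects to a valid, heavily streaked image.
    """
    geom = sino.geometry
    if out_size is None:
        out_size = int(round(geom.n_detectors / math.sqrt(2.0)))
    if out_size < 16:
        raise ValueError("out_size must be >= 16")
    filtered = ramp_filter(sino, filt)
    span = geom.angular_span_rad
    dtheta = span / geom.n_views
    scale = dtheta * (0.5 if span > math.pi + 1e-9 else 1.0)
    angles = np.deg2rad(geom.angles_deg)
    q = np.ascontiguousarray(filtered.values)
    if geom.beam == "fan-flat":
        return _backproject_fan(q, angles, geom.detector_spacing,
                                float(geom.source_axis_distance),
                                int(out_size), scale)
    return _backproject_parallel(q, angles, geom.detector_spacing,
                                 int(out_size), scale)
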