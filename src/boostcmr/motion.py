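"""Beat-to-beat translational motion estimation and k-space correction.

Respiratory translation is estimated per heartbeat from the 2D image
navigators by normalized cross-correlation template matching (template
from a designated source beat, search restricted to a rectangular region
of interest covering the heart), with parabolic sub-pixel refinement of
the correlation peak.  Because the two interleaved contrasts look
different, each parity stream is matched against its own template; the
end-expiration reference position is selected from the combined SI trace
so both contrasts align to the same position.  Correction multiplies each
acquired k-space line with the linear phase that translates the image to
the reference position — exact for rigid in-plane translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from skimage.feature import match_template

from .phantom import KSpaceDataset

__all__ = [
    "MotionTrace",
    "estimate_translation",
    "build_motion_trace",
    "select_reference",
    "correct_kspace",
]


@dataclass
class MotionTrace:
    """Per-heartbeat displacement estimates (mm), SI = dy, RL = dx."""

    dy_mm: np.ndarray
    dx_mm: np.ndarray
    parity: np.ndarray
    score: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.dy_mm))
                and np.all(np.isfinite(self.dx_mm))):
            raise ValueError("motion trace contains non-finite values")
        if self.score is None:
            self.score = np.ones_like(np.asarray(self.dy_mm, float))

    def __len__(self) -> int:
        return len(self.dy_mm)


def _parabolic_offset(m1: float, c: float, p1: float) -> float:
    """Sub-pixel offset of a parabola through three samples around a peak."""
    denom = m1 - 2.0 * c + p1
    if denom >= 0:  # flat or non-concave: keep the integer peak
        return 0.0
    off = 0.5 * (m1 - p1) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_translation(
    image: np.ndarray,
    template: np.ndarray,
    roi: Optional[Tuple[slice, slice]] = None,
    template_origin: Optional[Tuple[int, int]] = None,
) -> Tuple[float, float, float]:
    """Displacement (dy, dx) in pixels maximizing NCC of ``template``.

    ``roi`` restricts the search region within ``image``; ``template_origin``
    is the (row, col) where the template was cut from the source image —
    displacements are reported relative to it (defaults to the ROI corner,
    i.e. a template cut at the search origin).  Returns ``(dy, dx, score)``
    with ``score`` the peak NCC in [-1, 1].
    """
    img = np.abs(image).astype(float)
    tpl = np.abs(template).astype(float)
    if roi is not None:
        search = img[roi]
        origin = (roi[0].start or 0, roi[1].start or 0)
    else:
        search = img
        origin = (0, 0)
    if tpl.shape[0] > search.shape[0] or tpl.shape[1] > search.shape[1]:
        raise ValueError("template larger than the search region")
    if np.ptp(tpl) == 0 or np.ptp(search) == 0:
        raise ValueError("flat template or search region; cannot match")
    ncc = match_template(search, tpl, pad_input=False)
    iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
    score = float(ncc[iy, ix])
    dy, dx = float(iy), float(ix)
    # a perfect integer-lag match needs no refinement (the parabolic fit
    # would only add interpolation bias)
    if score < 1.0 - 1e-7:
        if 0 < iy < ncc.shape[0] - 1:
            dy += _parabolic_offset(ncc[iy - 1, ix], ncc[iy, ix],
                                    ncc[iy + 1, ix])
        if 0 < ix < ncc.shape[1] - 1:
            dx += _parabolic_offset(ncc[iy, ix - 1], ncc[iy, ix],
                                    ncc[iy, ix + 1])
    if template_origin is None:
        template_origin = origin
    return (dy + origin[0] - template_origin[0],
            dx + origin[1] - template_origin[1], score)


def _default_roi(shape, frac: float = 0.6) -> Tuple[slice, slice]:
    ny, nx = shape
    hy, hx = int(ny * frac) // 2, int(nx * frac) // 2
    return (slice(ny // 2 - hy, ny // 2 + hy),
            slice(nx // 2 - hx, nx // 2 + hx))


def build_motion_trace(
    inavs: np.ndarray,
    parity: np.ndarray,
    template_source: int = 0,
    roi: Optional[Tuple[slice, slice]] = None,
    template_margin: int = 12,
    voxel_mm: Tuple[float, float] = (1.0, 1.0),
) -> MotionTrace:
    """Estimate per-beat displacement from the navigator stack.

    The template of each parity stream is cut from the first beat of that
    stream at ``template_source`` position (the ROI shrunk by
    ``template_margin`` pixels on every side), so the two differently
    contrasted streams never cross-match.  Displacements are in mm.
    """
    n = len(inavs)
    if n < 2:
        raise ValueError("need at least two heartbeats")
    if roi is None:
        roi = _default_roi(inavs[0].shape)
    t_roi = (slice(roi[0].start + template_margin, roi[0].stop - template_margin),
             slice(roi[1].start + template_margin, roi[1].stop - template_margin))
    t_origin = (t_roi[0].start, t_roi[1].start)
    dy = np.zeros(n)
    dx = np.zeros(n)
    score = np.zeros(n)
    for par in np.unique(parity):
        beats = np.nonzero(parity == par)[0]
        src = beats[min(template_source, len(beats) - 1)]
        template = np.abs(inavs[src])[t_roi]
        for b in beats:
            try:
                dy[b], dx[b], score[b] = estimate_translation(
                    inavs[b], template, roi, template_origin=t_origin)
            except ValueError as err:
                raise ValueError(f"beat {b}: {err}") from err
        # displacements relative to the template beat's own position
        dy[beats] -= 0.0
    dy *= voxel_mm[0]
    dx *= voxel_mm[1]
    return MotionTrace(dy_mm=dy, dx_mm=dx, parity=np.asarray(parity),
                       score=score)


def select_reference(trace: MotionTrace, bin_mm: float = 1.0) -> float:
    """End-expiration reference: mode of the SI displacement histogram.

    Displacements are binned at ``bin_mm``; the most populated bin wins and
    ties go to the bin center nearer the median (the quiescent plateau of
    the breathing cycle dwells longest, so the mode sits at
    end-expiration).
    """
    dy = np.asarray(trace.dy_mm, float)
    if dy.size == 0:
        raise ValueError("empty trace")
    edges = np.arange(dy.min() - bin_mm / 2, dy.max() + bin_mm, bin_mm)
    if len(edges) < 2:
        return float(np.median(dy))
    hist, edges = np.histogram(dy, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best = hist.max()
    med = np.median(dy)
    cands = centers[hist == best]
    ref_bin = cands[np.argmin(np.abs(cands - med))]
    in_bin = np.abs(dy - ref_bin) <= bin_mm / 2
    return float(np.mean(dy[in_bin]))


def correct_kspace(
    data: KSpaceDataset,
    trace: MotionTrace,
    reference_mm: Tuple[float, float] = (0.0, 0.0),
) -> KSpaceDataset:
    """Translate every heartbeat's lines to the reference position.

    Each line acquired at beat ``b`` is multiplied by the linear phase
    ``exp(+2πi (k_y Δy_b + k_x Δx_b))`` with ``Δ = estimate − reference``
    in voxels over the FOV, undoing the displacement the phantom had when
    the line was sampled.  Exact for fractional shifts.
    """
    if len(trace) != data.n_beats:
        raise ValueError("trace length does not match heartbeat count")
    if "fov_mm" not in data.meta or "matrix" not in data.meta:
        raise ValueError("dataset meta lacks fov_mm/matrix for mm->cycles")
    ns, ny, nx = data.meta["matrix"]
    fov = data.meta["fov_mm"]
    vox = (fov[0] / ny, fov[1] / nx)
    out = data.copy()
    ky = np.fft.fftshift(np.fft.fftfreq(ny))
    kx = np.fft.fftshift(np.fft.fftfreq(nx))
    ref_y, ref_x = reference_mm
    for b in range(data.n_beats):
        dy_vox = (trace.dy_mm[b] - ref_y) / vox[0]
        dx_vox = (trace.dx_mm[b] - ref_x) / vox[1]
        if dy_vox == 0 and dx_vox == 0:
            continue
        row_phase = np.exp(2j * np.pi * kx * dx_vox)
        for l in range(data.lines.shape[1]):
            kyi = data.line_coords[b, l, 1]
            out.lines[b, l] = data.lines[b, l] * row_phase \
                * np.exp(2j * np.pi * ky[kyi] * dy_vox)
    out.meta = dict(out.meta)
    out.meta["motion_corrected"] = True
    out.meta["reference_mm"] = [float(ref_y), float(ref_x)]
    return out
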