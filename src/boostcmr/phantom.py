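"""Digital phantom, respiratory motion and Cartesian k-space acquisition.

The phantom is a multi-slice stack of 2D images (axes ordered ``(slice,
SI, RL)``) containing circular vials of the simulated tissue compartments
on a uniform background.  Acquisition is segmented over heartbeats: every
heartbeat contributes ``n_lines_per_beat`` phase-encode lines of one
contrast (determined by its parity), displaced by the respiratory position
of that beat (an exact k-space linear phase), using the line-resolved
transient signal of the running sequence simulation, plus complex Gaussian
noise.  Each heartbeat also yields a low-resolution image navigator (iNAV)
formed from the central k-space block of that beat's bright view.

Conventions: lengths in mm, positive SI displacement = superior; voxel
indices 0-based; k-space stored FFT-shifted (DC at ``n // 2``); the
unitary FFT convention is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np
import warnings

from .epg_engine import TissueParams
from .sequences import SequenceParams, SimulationResult, simulate_sequence

__all__ = [
    "PhantomSpec",
    "Vial",
    "RespiratoryModel",
    "KSpaceDataset",
    "make_label_map",
    "render_contrast",
    "sample_respiration",
    "simulate_acquisition",
    "spiral_interleaved_order",
    "default_phantom",
]

BACKGROUND = 0


@dataclass(frozen=True)
class Vial:
    """Circular vial: center (SI, RL) in mm from FOV center, radius mm."""

    center_mm: tuple
    radius_mm: float
    label: int


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the digital vial phantom.

    ``matrix`` is ``(n_slices, n_si, n_rl)``; ``fov_mm`` is the in-plane
    field of view ``(si, rl)``.  Labels index into a tissue table kept by
    the caller; label 0 is background (no signal).
    """

    matrix: tuple = (3, 192, 192)
    fov_mm: tuple = (320.0, 320.0)
    vials: tuple = ()
    slice_thickness_mm: float = 2.0

    @property
    def voxel_mm(self) -> tuple:
        return (self.fov_mm[0] / self.matrix[1],
                self.fov_mm[1] / self.matrix[2])

    def validate(self) -> None:
        for v in self.vials:
            for c, half in zip(v.center_mm, (f / 2 for f in self.fov_mm)):
                if abs(c) + v.radius_mm > half:
                    raise ValueError(f"vial {v.label} extends outside the FOV")


def default_phantom(radius_mm: float = 30.0) -> PhantomSpec:
    """Three-vial phantom: myocardium (1), scar (2), blood (3)."""
    return PhantomSpec(vials=(
        Vial((-60.0, -60.0), radius_mm, 1),
        Vial((-60.0, 60.0), radius_mm, 2),
        Vial((60.0, 0.0), radius_mm, 3),
    ))


def make_label_map(spec: PhantomSpec) -> np.ndarray:
    """Integer label image; ties go to the earliest-listed vial."""
    spec.validate()
    ns, ny, nx = spec.matrix
    dy, dx = spec.voxel_mm
    y = (np.arange(ny) - ny / 2.0) * dy
    x = (np.arange(nx) - nx / 2.0) * dx
    yy, xx = np.meshgrid(y, x, indexing="ij")
    labels = np.full((ny, nx), BACKGROUND, dtype=np.int16)
    claimed = np.zeros((ny, nx), dtype=bool)
    overlap = False
    for v in spec.vials:
        inside = (yy - v.center_mm[0]) ** 2 + (xx - v.center_mm[1]) ** 2 \
            <= v.radius_mm ** 2
        overlap = overlap or bool(np.any(inside & claimed))
        labels[inside & ~claimed] = v.label
        claimed |= inside
    if overlap:
        warnings.warn("overlapping vials; earliest-listed vial wins")
    return np.broadcast_to(labels, (ns, ny, nx)).copy()


def render_contrast(labels: np.ndarray, signal_per_label: Dict[int, complex]
                    ) -> np.ndarray:
    """Voxelwise label -> complex signal lookup (signs/phases preserved)."""
    present = set(np.unique(labels).tolist()) - {BACKGROUND}
    missing = present - set(signal_per_label)
    if missing:
        raise KeyError(f"no signal for labels {sorted(missing)}")
    out = np.zeros(labels.shape, complex)
    for lab, sig in signal_per_label.items():
        out[labels == lab] = sig
    return out


@dataclass(frozen=True)
class RespiratoryModel:
    """Rigid breathing trace generator.

    ``sinusoid`` gives plain harmonic motion; ``asymmetric`` uses
    ``d(t) = A * (1 - cos(pi t / T) ** 6)``, which dwells ~47% of the
    cycle within 10% of the end-expiration extreme ``A`` — the quiescent
    plateau real breathing shows.  A linear drift and a seeded per-beat
    jitter can be added.
    """

    amplitude_si_mm: float = 5.0
    amplitude_rl_mm: float = 2.0
    period_s: float = 4.0
    drift_mm_per_min: float = 0.0
    waveform: str = "asymmetric"
    jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_si_mm < 0 or self.amplitude_rl_mm < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if self.waveform not in ("sinusoid", "asymmetric"):
            raise ValueError(f"unknown waveform {self.waveform!r}")


def sample_respiration(model: RespiratoryModel, n_beats: int, rr_s: float):
    """Per-heartbeat (dy_si_mm, dx_rl_mm) displacement arrays."""
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    t = np.arange(n_beats) * rr_s
    phase = t / model.period_s
    if model.waveform == "sinusoid":
        shape = np.sin(2 * np.pi * phase)
    else:
        shape = 1.0 - np.cos(np.pi * phase) ** 6
    drift = model.drift_mm_per_min * t / 60.0
    rng = np.random.default_rng(model.seed)
    jit = rng.normal(0.0, model.jitter_mm, (2, n_beats)) \
        if model.jitter_mm > 0 else np.zeros((2, n_beats))
    dy = model.amplitude_si_mm * shape + drift + jit[0]
    dx = model.amplitude_rl_mm * shape + jit[1]
    return dy, dx


def spiral_interleaved_order(n_y: int, n_slices: int, n_lines: int,
                             n_segments: int) -> np.ndarray:
    """Center-out segmented phase-encode ordering.

    Approximates a spiral profile order on the Cartesian ``(ky, slice)``
    plane: encodes are sorted by distance from the k-space center and dealt
    round-robin into ``n_segments`` arms (one heartbeat each), so every
    heartbeat acquires a center-out interleave and the k-space center is
    sampled first in each beat (centric contrast weighting).

    Returns an ``(n_segments, n_lines, 2)`` int array of ``(slice, ky)``.
    """
    ky, sl = np.meshgrid(np.arange(n_y), np.arange(n_slices), indexing="ij")
    ky, sl = ky.ravel(), sl.ravel()
    cy, cs = n_y // 2, n_slices // 2
    r = ((ky - cy) / n_y) ** 2 + ((sl - cs) / max(n_slices, 1)) ** 2
    ang = np.arctan2(sl - cs, ky - cy)
    order = np.lexsort((ang, r))  # center-out, angle breaks ties
    total = n_segments * n_lines
    if order.size != total:
        raise ValueError(
            f"encode count {order.size} != segments*lines {total}")
    coords = np.stack([sl[order], ky[order]], axis=-1)
    # deal: line l of segment s is the (l*n_segments + s)-th closest encode
    return coords.reshape(n_lines, n_segments, 2).transpose(1, 0, 2)


def linear_order(n_y: int, n_slices: int, n_lines: int,
                 n_segments: int) -> np.ndarray:
    """Sequential ky/slice ordering (comparison mode)."""
    ky, sl = np.meshgrid(np.arange(n_y), np.arange(n_slices), indexing="ij")
    coords = np.stack([sl.ravel(), ky.ravel()], axis=-1)
    total = n_segments * n_lines
    if coords.shape[0] != total:
        raise ValueError("encode count mismatch")
    return coords.reshape(n_segments, n_lines, 2)


@dataclass
class KSpaceDataset:
    """Segmented Cartesian k-space with per-beat navigators.

    ``lines[b, l]`` is the complex readout (length ``n_rl``) of line ``l``
    of heartbeat ``b``; ``line_coords[b, l] = (slice, ky)``;
    ``parity[b]`` is 0 for odd (first-contrast) beats, 1 for even.
    ``inavs[b]`` is the complex low-resolution navigator image.
    """

    lines: np.ndarray
    line_coords: np.ndarray
    parity: np.ndarray
    inavs: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return self.lines.shape[0]

    def copy(self) -> "KSpaceDataset":
        return KSpaceDataset(self.lines.copy(), self.line_coords.copy(),
                             self.parity.copy(), self.inavs.copy(),
                             dict(self.meta))


def _kspace_of_masks(labels: np.ndarray) -> Dict[int, np.ndarray]:
    """Unitary FFT of each label's indicator image, per slice."""
    out = {}
    for lab in np.unique(labels):
        if lab == BACKGROUND:
            continue
        mask = (labels == lab).astype(float)
        out[int(lab)] = np.fft.fftshift(
            np.fft.fft2(np.fft.ifftshift(mask, axes=(-2, -1)),
                        norm="ortho"), axes=(-2, -1))
    return out


def _shift_phase(ny: int, nx: int, dy_vox: float, dx_vox: float) -> np.ndarray:
    """k-space linear phase that translates an image by (dy, dx) voxels."""
    ky = np.fft.fftshift(np.fft.fftfreq(ny))[:, None]
    kx = np.fft.fftshift(np.fft.fftfreq(nx))[None, :]
    return np.exp(-2j * np.pi * (ky * dy_vox + kx * dx_vox))


def simulate_acquisition(
    spec: PhantomSpec,
    params: SequenceParams,
    tissues: Iterable[TissueParams],
    resp: Optional[RespiratoryModel] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_beats_per_contrast: Optional[int] = None,
    ordering: str = "spiral",
    sim_result: Optional[SimulationResult] = None,
    inav_block: tuple = (14, 32),
    noise_scale: Optional[float] = None,
) -> KSpaceDataset:
    """Acquire the phantom through the full segmented schedule.

    The label->signal table of beat ``b``, line ``l`` comes from the
    steady-state transient of the sequence simulation (line ``l`` of the
    steady beat of that parity), so centric contrast weighting and
    through-readout signal decay are both present.  ``noise_sigma`` is the
    per-channel complex-Gaussian standard deviation as a fraction of this
    dataset's peak noiseless bright-contrast image magnitude (the unitary
    FFT maps white k-space noise to image noise of the same standard
    deviation).  ``noise_scale`` overrides it with an absolute image-domain
    sigma — used to impose one scanner noise level across sequences.
    """
    tissues = tuple(tissues)
    labels = make_label_map(spec)
    ns, ny, nx = spec.matrix
    n_lines = params.n_lines_per_beat
    if n_beats_per_contrast is None:
        n_beats_per_contrast = ns * ny // n_lines
    if n_beats_per_contrast * n_lines != ns * ny:
        raise ValueError("phase encodes per contrast must equal "
                         "n_beats_per_contrast * n_lines_per_beat")
    single = params.kind == "cmra"
    n_contrasts = 1 if single else 2
    n_beats = n_contrasts * n_beats_per_contrast

    if sim_result is None:
        sim_result = simulate_sequence(params, tissues)
    label_of = {i + 1: t.name for i, t in enumerate(tissues)}
    steady = {
        0: sim_result.steady_beat("odd"),
        1: sim_result.steady_beat("odd" if single else "even"),
    }

    if ordering == "spiral":
        order = spiral_interleaved_order(ny, ns, n_lines, n_beats_per_contrast)
    elif ordering == "linear":
        order = linear_order(ny, ns, n_lines, n_beats_per_contrast)
    else:
        raise ValueError(f"unknown ordering {ordering!r}")

    if resp is None:
        resp = RespiratoryModel(amplitude_si_mm=0.0, amplitude_rl_mm=0.0)
    dy_mm, dx_mm = sample_respiration(resp, n_beats, params.rr_ms / 1000.0)
    dy_vox = dy_mm / spec.voxel_mm[0]
    dx_vox = dx_mm / spec.voxel_mm[1]

    masks_k = _kspace_of_masks(labels)  # {label: (ns, ny, nx)}
    rng = np.random.default_rng(seed)

    # bright-contrast image peak: vials are disjoint indicator masks, so
    # the peak magnitude is the largest per-label signal at the k-center
    bright_beat = steady[1 if not single else 0]
    peak = max((abs(sim_result.signal[name][bright_beat, 0])
                for name in label_of.values()), default=1.0)

    lines = np.zeros((n_beats, n_lines, nx), complex)
    coords = np.zeros((n_beats, n_lines, 2), np.int32)
    parities = np.zeros(n_beats, np.int8)
    nav_ny, nav_nx = inav_block
    inavs = np.zeros((n_beats, ny, nx), complex)

    for b in range(n_beats):
        par = 0 if single else b % 2
        parities[b] = par
        seg = b if single else b // 2
        coords[b] = order[seg]
        phase = _shift_phase(ny, nx, dy_vox[b], dx_vox[b])
        sbeat = steady[par]
        for l in range(n_lines):
            sl, kyi = coords[b, l]
            row = np.zeros(nx, complex)
            for lab, kmask in masks_k.items():
                s = sim_result.signal[label_of[lab]][sbeat, l]
                row = row + s * kmask[sl, kyi, :] * phase[kyi, :]
            lines[b, l] = row
        # iNAV: central low-res block of the mid-slice at this position,
        # first-line contrast of this beat's parity
        kfull = sum(sim_result.signal[label_of[lab]][sbeat, 0]
                    * masks_k[lab][ns // 2] for lab in masks_k) * phase
        block = np.zeros_like(kfull)
        y0, x0 = ny // 2 - nav_ny // 2, nx // 2 - nav_nx // 2
        block[y0:y0 + nav_ny, x0:x0 + nav_nx] = \
            kfull[y0:y0 + nav_ny, x0:x0 + nav_nx]
        inavs[b] = np.fft.fftshift(
            np.fft.ifft2(np.fft.ifftshift(block), norm="ortho"))
    scale = noise_scale if noise_scale is not None else noise_sigma * peak
    if scale > 0:
        lines = lines + scale * (
            rng.standard_normal(lines.shape)
            + 1j * rng.standard_normal(lines.shape))
        inavs = inavs + scale / np.sqrt(ny * nx / (nav_ny * nav_nx)) * (
            rng.standard_normal(inavs.shape)
            + 1j * rng.standard_normal(inavs.shape))

    meta = {
        "matrix": list(spec.matrix),
        "fov_mm": list(spec.fov_mm),
        "noise_sigma": float(noise_sigma),
        "noise_scale": float(scale),
        "seed": int(seed),
        "ordering": ordering,
        "n_beats_per_contrast": int(n_beats_per_contrast),
        "kind": params.kind,
        "tr_ms": params.tr_ms,
        "n_lines_per_beat": n_lines,
        "true_dy_mm": dy_mm.tolist(),
        "true_dx_mm": dx_mm.tolist(),
    }
    return KSpaceDataset(lines, coords, parities, inavs, meta)
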