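"""Whole-sequence schedulers and summary extractors.

Three ECG-triggered segmented bSSFP sequences are scheduled over a train of
heartbeats, each heartbeat containing (depending on the sequence and the
beat parity) magnetization preparations, recovery gaps, a catalyzation ramp
and an imaging readout, with free relaxation filling the rest of the RR
interval:

``boost``
    Odd beats: T2Prep followed immediately by an inversion (T2Prep-IR,
    black-blood magnitude image); the readout starts TI after the
    inversion.  Even beats: T2Prep only, bright-blood reference image at
    the same high flip angle.
``conventional_psir``
    Odd beats: inversion + TI recovery, high-flip magnitude image.  Even
    beats: low-flip proton-density reference, no preparation.
``cmra``
    Every beat: T2Prep + bright-blood readout (dedicated coronary
    angiography comparator).

Timing conventions (frozen against the printed magnetization values):

* TI runs from the inversion pulse to the *first imaging line*; with
  centric ordering that line is the k-space center, so TI nulls the target
  tissue where it matters.  The ramp occupies the last ``n_ramp * tr`` of
  the TI interval.
* Readouts of both parities sit at the same trigger delay, so only
  inter-event gaps enter the on-resonance simulation.
* Bright-blood beats (BOOST even beats and every CMRA beat) include a
  spectral fat-saturation interval ``fat_sat_gap_ms`` between the T2Prep
  and the ramp, mirroring the SPIR pulse those acquisitions carry; on
  T2Prep-IR beats fat suppression is STIR-like (a property of the
  inversion) and costs no extra time.  No fat compartment is simulated —
  only the timing matters on resonance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .epg_engine import (
    TissueParams,
    bssfp_readout,
    equilibrium_state,
    invert,
    relax,
    t2prep,
)

__all__ = [
    "SequenceParams",
    "SimulationResult",
    "simulate_sequence",
    "mz_interval",
    "signal_difference",
    "blood_myo_ratio",
    "tissue_signal_table",
    "boost_defaults",
    "conventional_psir_defaults",
    "cmra_defaults",
]

KINDS = ("boost", "conventional_psir", "cmra")


@dataclass(frozen=True)
class SequenceParams:
    """Timing and flip-angle description of one simulated sequence.

    All times in ms, angles in degrees.  ``ti_ms`` is the inversion time of
    odd heartbeats (ignored for ``cmra``); ``flip_reference_deg`` is the
    even-beat flip of the conventional PSIR sequence and unused otherwise.
    """

    kind: str = "boost"
    ti_ms: float = 150.0
    t2prep_ms: float = 40.0
    flip_imaging_deg: float = 90.0
    flip_reference_deg: float = 8.0
    n_lines_per_beat: int = 33
    tr_ms: float = 3.6
    te_ms: float = 1.56  # metadata only; on-resonance Mz is TE-independent
    n_ramp: int = 14
    heart_rate_bpm: float = 60.0
    n_heartbeats: int = 50
    n_dummy: int = 2
    ordering: str = "centric"
    inversion_efficiency: float = 1.0
    fat_sat_gap_ms: float = 25.0
    t2prep_mode: str = "pure-decay"
    max_order: int = 32

    @property
    def rr_ms(self) -> float:
        return 60000.0 / self.heart_rate_bpm

    @property
    def ramp_ms(self) -> float:
        return self.n_ramp * self.tr_ms

    @property
    def readout_ms(self) -> float:
        return self.n_lines_per_beat * self.tr_ms

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        if self.ordering not in ("centric", "linear"):
            raise ValueError(f"unknown ordering {self.ordering!r}")
        if self.n_dummy >= self.n_heartbeats:
            raise ValueError("n_dummy must be smaller than n_heartbeats")
        if self.kind != "cmra" and self.ti_ms < self.ramp_ms:
            raise ValueError("TI shorter than the catalyzation ramp")
        budget = self.ti_ms + self.readout_ms + (
            self.t2prep_ms if self.kind == "boost" else 0.0)
        if budget >= self.rr_ms:
            raise ValueError("schedule does not fit in the RR interval")


def boost_defaults(**overrides) -> SequenceParams:
    """BOOST parameters as used in the reference simulations."""
    overrides = {"kind": "boost", "ti_ms": 150.0, **overrides}
    return SequenceParams(**overrides)


def conventional_psir_defaults(**overrides) -> SequenceParams:
    overrides = {"kind": "conventional_psir", "ti_ms": 350.0, **overrides}
    return SequenceParams(**overrides)


def cmra_defaults(**overrides) -> SequenceParams:
    overrides = {"kind": "cmra", "ti_ms": 150.0, **overrides}
    return SequenceParams(**overrides)


@dataclass
class SimulationResult:
    """Per-heartbeat, per-line record of one multi-tissue simulation."""

    params: SequenceParams
    tissues: tuple
    #: Mz/M0 immediately before each imaging pulse, per tissue label.
    z_before_line: dict
    #: complex echo amplitude per imaging line, per tissue label.
    signal: dict
    #: 'odd' / 'even' per heartbeat (1-based beat 1 is odd).
    beat_parity: np.ndarray = field(default=None)
    #: True for dummy (discarded) heartbeats.
    is_dummy: np.ndarray = field(default=None)

    @property
    def tissue_names(self):
        return tuple(t.name for t in self.tissues)

    def steady_beat(self, parity: str) -> int:
        """Index of the steady-state (last full) beat of a parity."""
        ok = (self.beat_parity == parity) & ~self.is_dummy
        idx = np.nonzero(ok)[0]
        if idx.size == 0:
            raise ValueError(f"no non-dummy {parity!r} heartbeat in result")
        return int(idx[-1])

    @property
    def steady_window(self):
        """(odd beat index, even beat index) of the final full pair."""
        return self.steady_beat("odd"), self.steady_beat("even")


def _tissue_schedule(params: SequenceParams, tissue: TissueParams):
    """Run the per-heartbeat event schedule for a single tissue."""
    p = params
    state = equilibrium_state(tissue, p.max_order)
    n_beats, n_lines = p.n_heartbeats, p.n_lines_per_beat
    z = np.zeros((n_beats, n_lines))
    sig = np.zeros((n_beats, n_lines), complex)
    parity = np.array(["odd" if b % 2 == 0 else "even" for b in range(n_beats)])
    ti_gap = p.ti_ms - p.ramp_ms  # inversion -> first ramp pulse

    def read(s):
        return bssfp_readout(
            s, tissue, p.n_ramp, n_lines, p.tr_ms, p.flip_imaging_deg)

    for b in range(n_beats):
        odd = parity[b] == "odd"
        if p.kind == "boost":
            if odd:
                state = t2prep(state, p.t2prep_ms, tissue, p.t2prep_mode)
                state = invert(state, p.inversion_efficiency)
                state = relax(state, ti_gap, tissue)
                state, sig[b], z[b] = read(state)
                used = p.t2prep_ms + p.ti_ms + p.readout_ms
            else:
                # matched trigger delay: first line at TI into the beat
                pre = p.ti_ms - p.ramp_ms - p.fat_sat_gap_ms - p.t2prep_ms
                pre = max(pre, 0.0)
                state = relax(state, pre, tissue)
                state = t2prep(state, p.t2prep_ms, tissue, p.t2prep_mode)
                state = relax(state, p.fat_sat_gap_ms, tissue)
                state, sig[b], z[b] = read(state)
                used = pre + p.t2prep_ms + p.fat_sat_gap_ms + p.ramp_ms \
                    + p.readout_ms
        elif p.kind == "conventional_psir":
            if odd:
                state = invert(state, p.inversion_efficiency)
                state = relax(state, ti_gap, tissue)
                state, sig[b], z[b] = read(state)
                used = p.ti_ms + p.readout_ms
            else:
                pre = max(p.ti_ms - p.ramp_ms, 0.0)
                state = relax(state, pre, tissue)
                state, sig[b], z[b] = bssfp_readout(
                    state, tissue, p.n_ramp, n_lines, p.tr_ms,
                    p.flip_reference_deg)
                used = pre + p.ramp_ms + p.readout_ms
        else:  # cmra: identical every heartbeat
            pre = p.ti_ms - p.ramp_ms - p.fat_sat_gap_ms - p.t2prep_ms
            pre = max(pre, 0.0)
            state = relax(state, pre, tissue)
            state = t2prep(state, p.t2prep_ms, tissue, p.t2prep_mode)
            state = relax(state, p.fat_sat_gap_ms, tissue)
            state, sig[b], z[b] = read(state)
            used = pre + p.t2prep_ms + p.fat_sat_gap_ms + p.ramp_ms \
                + p.readout_ms
        state = relax(state, p.rr_ms - used, tissue)
    return z / tissue.m0, sig, parity


def simulate_sequence(
    params: SequenceParams, tissues: Iterable[TissueParams]
) -> SimulationResult:
    """Simulate one sequence for each tissue independently.

    Tissues are non-interacting isochromats; each is scheduled through the
    identical event train and its per-line longitudinal magnetization
    (``Mz/M0``) and echo signal recorded.
    """
    params.validate()
    tissues = tuple(tissues)
    if not tissues:
        raise ValueError("at least one tissue required")
    z_rec, s_rec = {}, {}
    parity = None
    for t in tissues:
        z, sig, parity = _tissue_schedule(params, t)
        z_rec[t.name] = z
        s_rec[t.name] = sig
    dummy = np.zeros(params.n_heartbeats, bool)
    dummy[: params.n_dummy] = True
    return SimulationResult(
        params=params, tissues=tissues, z_before_line=z_rec, signal=s_rec,
        beat_parity=parity, is_dummy=dummy,
    )


def _first_line_mz(result: SimulationResult, tissue: str, parity: str) -> float:
    if tissue not in result.z_before_line:
        raise KeyError(f"unknown tissue label {tissue!r}")
    beat = result.steady_beat(parity)
    return float(result.z_before_line[tissue][beat, 0])


def mz_interval(result: SimulationResult, tissue: str, parity: str):
    """(first-line, last-line) Mz/M0 of the steady-state beat of a parity."""
    if tissue not in result.z_before_line:
        raise KeyError(f"unknown tissue label {tissue!r}")
    beat = result.steady_beat(parity)
    row = result.z_before_line[tissue][beat]
    return float(row[0]), float(row[-1])


def signal_difference(
    result: SimulationResult, tissue_a: str, tissue_b: str, parity: str = "odd"
) -> float:
    """Signed Mz/M0 difference (a minus b) at the first imaging line of the
    steady-state beat.  Meaningful for centric ordering, where the first
    line is the k-space center and sets the image contrast."""
    if result.params.ordering != "centric":
        raise ValueError("signal differences are defined for centric ordering")
    return _first_line_mz(result, tissue_a, parity) - _first_line_mz(
        result, tissue_b, parity)


def blood_myo_ratio(result: SimulationResult, parity: str = "even") -> float:
    """Blood-to-myocardium Mz/M0 ratio at the first imaging line."""
    myo = _first_line_mz(result, "myocardium", parity)
    blood = _first_line_mz(result, "blood", parity)
    if myo <= 0:
        raise ValueError("myocardium Mz is non-positive; ratio undefined")
    return blood / myo


def tissue_signal_table(result: SimulationResult) -> pd.DataFrame:
    """Deterministic per-tissue summary, one row per tissue x parity.

    Columns: steady-beat index, first/last-line Mz/M0 and the first-line
    echo magnitude.  CMRA collapses to a single parity row per tissue.
    """
    parities = ("odd",) if result.params.kind == "cmra" else ("odd", "even")
    rows = []
    for t in result.tissue_names:
        for par in parities:
            beat = result.steady_beat(par)
            start, end = mz_interval(result, t, par)
            rows.append({
                "tissue": t,
                "parity": par,
                "steady_beat": beat,
                "mz_first_line": start,
                "mz_last_line": end,
                "signal_first_line": float(
                    np.abs(result.signal[t][beat, 0])),
            })
    return pd.DataFrame(rows)


def sequence_metadata(params: SequenceParams) -> dict:
    """Flat dict of the sequence parameters (for file headers)."""
    return asdict(params)
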