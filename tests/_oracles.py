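"""Independent oracles for the test suite.

A 3-vector Bloch integrator (rotation matrices + exponential relaxation)
serves as the reference for every on-resonance balanced pulse train; it
shares no code with the configuration-state engine it checks.
"""

import numpy as np


def bloch_rot(flip_deg: float, phase_deg: float) -> np.ndarray:
    """Rotation by ``flip`` about an in-plane axis at ``phase`` from x."""
    a = np.deg2rad(flip_deg)
    p = np.deg2rad(phase_deg)

    def rz(t):
        return np.array([[np.cos(t), -np.sin(t), 0.0],
                         [np.sin(t), np.cos(t), 0.0],
                         [0.0, 0.0, 1.0]])

    rx = np.array([[1.0, 0.0, 0.0],
                   [0.0, np.cos(a), -np.sin(a)],
                   [0.0, np.sin(a), np.cos(a)]])
    return rz(p) @ rx @ rz(-p)


def bloch_relax(m: np.ndarray, dt: float, t1: float, t2: float,
                m0: float = 1.0) -> np.ndarray:
    e1, e2 = np.exp(-dt / t1), np.exp(-dt / t2)
    out = m * np.array([e2, e2, e1])
    out[2] += m0 * (1.0 - e1)
    return out


def bloch_train(m, events, t1, t2, m0=1.0):
    """Apply a list of ('rf', flip, phase) / ('relax', dt) events."""
    m = np.asarray(m, float).copy()
    for ev in events:
        if ev[0] == "rf":
            m = bloch_rot(ev[1], ev[2]) @ m
        elif ev[0] == "relax":
            m = bloch_relax(m, ev[1], t1, t2, m0)
        else:
            raise ValueError(ev)
    return m


def bssfp_fixed_point(flip_deg: float, tr: float, t1: float, t2: float,
                      m0: float = 1.0) -> float:
    """Mz immediately before an imaging pulse in the alternating-phase
    bSSFP steady state, from the affine two-pulse recursion.

    The map over two TRs is affine, ``m -> A m + b``; its fixed point is
    solved linearly from two evaluations.
    """

    def two_tr(m):
        m = bloch_rot(flip_deg, 0.0) @ m
        m = bloch_relax(m, tr, t1, t2, m0)
        m = bloch_rot(flip_deg, 180.0) @ m
        return bloch_relax(m, tr, t1, t2, m0)

    b = two_tr(np.zeros(3))
    cols = [two_tr(e) - b for e in np.eye(3)]
    A = np.stack(cols, axis=1)
    fixed = np.linalg.solve(np.eye(3) - A, b)
    return float(fixed[2])


def brute_force_ncc(search: np.ndarray, template: np.ndarray):
    """Integer-lag normalized cross-correlation by direct looping."""
    sh = (search.shape[0] - template.shape[0] + 1,
          search.shape[1] - template.shape[1] + 1)
    out = np.zeros(sh)
    t = template - template.mean()
    tn = np.sqrt((t ** 2).sum())
    for i in range(sh[0]):
        for j in range(sh[1]):
            w = search[i:i + template.shape[0], j:j + template.shape[1]]
            w = w - w.mean()
            denom = tn * np.sqrt((w ** 2).sum())
            out[i, j] = (w * t).sum() / denom if denom > 0 else 0.0
    return out
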