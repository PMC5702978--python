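# boostcmr

A desk-scale simulation and reconstruction toolkit for **interleaved
bright-blood / black-blood whole-heart cardiac MR** (the "BOOST"
acquisition scheme): a free-breathing 3D bSSFP sequence that alternates a
T2-prepared inversion-recovery (T2Prep-IR) magnitude volume on odd
heartbeats with a T2-prepared bright-blood reference volume on even
heartbeats, corrects respiratory motion beat-to-beat with image
navigators (iNAVs), and combines the two co-registered volumes in a
phase-sensitive (PSIR-like) reconstruction that renders post-contrast
blood black and scar bright — simultaneous late-gadolinium-enhancement
assessment and coronary angiography from a single scan.

The package is for MR physicists and methods researchers who want to
study this sequence family quantitatively without a scanner: everything a
phantom experiment needs is simulated, end to end.

## What it computes

* **EPG engine** (`boostcmr.epg_engine`) — extended-phase-graph operators
  (RF mixing, relaxation, dephasing shift, spoiling, inversion, T2Prep)
  for arbitrary pulse schedules, validated against a 3-vector Bloch
  integrator to < 1e-6 per step.
* **Sequence schedulers** (`boostcmr.sequences`) — heartbeat-by-heartbeat
  simulation of BOOST, a conventional PSIR LGE sequence and a dedicated
  T2-prepared coronary MRA (CMRA), with the published protocol as
  defaults: myocardium T1/T2 = 550/45 ms, scar 300/45 ms, post-contrast
  blood 450/200 ms; TI = 150 ms (BOOST) / 350 ms (PSIR); T2Prep 40 ms;
  flip 90° (8° PSIR reference); 33 lines at TR 3.6 ms behind 14 linear
  ramp-up pulses; 60 bpm, 50 heartbeats (2 dummy).
* **Digital phantom + k-space acquisition** (`boostcmr.phantom`) —
  three-vial phantom, segmented Cartesian sampling with center-out spiral
  profile order, per-heartbeat respiratory translation applied as exact
  k-space phase, complex Gaussian noise, and per-beat low-resolution
  iNAVs.
* **Motion correction** (`boostcmr.motion`) — per-beat translation from
  the iNAVs by normalized-cross-correlation template matching with
  sub-pixel refinement, end-expiration reference selection, and k-space
  linear-phase correction.
* **Reconstruction** (`boostcmr.recon`) — unitary FFT reconstruction,
  rigid co-registration of the two contrasts, and the signed PSIR
  combination `Re{IR · exp(-i φ_ref)}` with optional intensity
  normalization (off by default, which preserves tissue contrast).
* **Quantification** (`boostcmr.metrics`) — SNR/CNR from ROI means and a
  background noise estimate taken after removal of low-spatial-frequency
  signal, with the residual-filter variance bias corrected.

## Worked example

```python
from boostcmr.epg_engine import MYOCARDIUM, SCAR, BLOOD
from boostcmr.sequences import (boost_defaults, simulate_sequence,
                                signal_difference, blood_myo_ratio,
                                tissue_signal_table)

res = simulate_sequence(boost_defaults(), (MYOCARDIUM, SCAR, BLOOD))
print(tissue_signal_table(res).to_string(index=False,
                                         float_format=lambda v: f"{v:.3f}"))
print("scar - myocardium (odd):",
      round(signal_difference(res, "scar", "myocardium", "odd"), 3))
print("blood/myocardium (even):", round(blood_myo_ratio(res, "even"), 2))
```

prints

```
    tissue parity  steady_beat  mz_first_line  mz_last_line  signal_first_line
myocardium    odd           48         -0.003         0.058              0.003
myocardium   even           49          0.223         0.115              0.214
      scar    odd           48          0.089         0.125              0.085
      scar   even           49          0.293         0.172              0.282
     blood    odd           48         -0.170        -0.007              0.169
     blood   even           49          0.478         0.421              0.473

scar - myocardium (odd): 0.092
blood/myocardium (even): 2.15
```

Read it as the physics of the method: on the steady-state odd (T2Prep-IR)
heartbeat the inversion time nulls healthy myocardium at the k-space
center (`Mz/M0 = -0.003`), blood is still strongly negative (`-0.170`)
and scar already positive (`+0.089`) — after phase-sensitive
reconstruction blood turns black while scar stays bright.  On even
heartbeats the T2Prep weighting gives blood more than twice the
myocardial magnetization (`ratio 2.15`), the bright-blood contrast used
for coronary visualization.

The same experiment at image level, from the shell:

```sh
boost-cmr simulate                       # magnetization tables + plots
boost-cmr phantom --out results/boost.h5 # segmented k-space + iNAVs
boost-cmr recon results/boost.h5 --out results/recon
boost-cmr metrics results/recon/*.nii.gz --out results/metrics.csv
```

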