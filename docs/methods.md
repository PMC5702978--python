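# Methods

## Magnetization model

All simulations use the extended-phase-graph (EPG) formalism: the state
of one tissue is the ladder of configuration amplitudes `(F_k, F*_{-k},
Z_k)` up to a maximum order (default 32).  RF pulses mix each order with
the standard 3×3 rotation matrix; free relaxation scales `F` by
`exp(-dt/T2)` and `Z` by `exp(-dt/T1)` with `Z_0` regrowing toward `m0`;
crushers zero the transverse ladder.  The sequences simulated here are
balanced (no net gradient moment per TR) and on-resonance, so the engine
never shifts the ladder during readouts and is then exactly equivalent to
a single 3-vector Bloch isochromat — an equivalence the test suite
asserts to 1e-6 per step on random pulse trains.  The shift operator
exists for crushed preparations and for experimentation; states pushed
past the ladder edge are dropped and tallied in a truncation diagnostic.

Preparation modules are idealized: the T2-preparation is a hard 90°
tip-down, pure T2 decay over its duration τ, a −90° tip-up and a crusher,
so a longitudinal state `M` maps to `M·exp(-τ/T2)` ("pure-decay" mode; a
"composite" mode running full relaxation inside τ exists for sensitivity
checks and differs only through the crushed regrowth term).  Inversion is
instantaneous with efficiency 1.0 (an `efficiency` argument exists).
Neither slice profiles, B1 inhomogeneity, off-resonance, flow nor
magnetization transfer are modeled.

## Sequence timing conventions

The published protocol leaves several scheduling details open; the ones
chosen here were fixed by requiring the simulated steady-state
magnetization to reproduce the published values, and are:

* **TI reference.** TI runs from the inversion pulse to the *first
  imaging line*.  Under centric (center-out) ordering that line is the
  k-space center, so nulling is enforced where image contrast is set.
  The 14 ramp-up pulses occupy the final `14·TR` of the TI interval.
* **Catalyzation.** Linear ramp `flip·k/14` (k = 1..14) with RF phase
  alternating 0°/180°, the alternation continuing into the imaging
  pulses.  Echoes are sampled mid-TR; the longitudinal magnetization is
  recorded immediately before each imaging pulse.
* **Trigger delays.** Readouts of both heartbeat parities sit at the same
  delay after the R-wave; on resonance only inter-event gaps matter, and
  free relaxation fills the remainder of each RR interval.
* **Fat-saturation interval.** Bright-blood acquisitions (even BOOST
  heartbeats and every CMRA heartbeat) carry a spectral fat-saturation
  pulse between the T2Prep and the readout in the pulse-sequence diagram;
  its duration is modeled as a 25 ms free-relaxation gap (a typical SPIR
  pulse plus crusher).  No fat compartment is simulated — on resonance
  the pulse itself does nothing to water and only the time it occupies
  matters.  Odd (T2Prep-IR) heartbeats obtain fat suppression from the
  inversion itself (STIR-like) and carry no extra delay.
* **Post-readout.** Transverse magnetization is crushed after the last
  imaging pulse of each heartbeat (the conventional segmented-bSSFP
  assumption); `Mz` then relaxes freely to the next preparation.
* **Steady state.** 50 heartbeats at 60 bpm converge far beyond need (the
  last four same-parity beats agree to < 1e-3); reported quantities come
  from the final odd/even pair.  The two dummy heartbeats are flagged and
  excluded, though their presence changes nothing at steady state.

With these conventions the simulation reproduces the published
magnetization endpoints within ±0.02 (ratios ±0.05) for the BOOST
sequence itself and for most comparator endpoints.  Two comparator
values cannot be reached by any schedule consistent with the rest of the
published numbers, and are deliberately left failing in the acceptance
suite rather than patched:

* *Conventional-PSIR scar-minus-myocardium (+0.208).*  The published
  reference-beat values pin the pre-inversion myocardium magnetization
  near 0.94 of `M0`, which at TI = 350 ms cannot fall to the published
  −0.002 at the first line (that would require ≈ 0.89, i.e. a reference
  readout placed so late in the cycle that the also-published
  reference-beat value 0.807 would be violated by > 0.1).  The engine
  yields +0.231.
* *CMRA blood magnetization (0.498).*  With RR = 1000 ms, τ = 40 ms and
  169 ms of ramp + readout, blood recovery is bounded below by the
  schedule; the minimum attainable first-line value over all prep
  placements is 0.519 (0.525 with the fat-saturation gap that the
  blood/myocardium ratio 2.26 requires).
* The published interval endpoints are also mutually inconsistent at the
  0.01–0.02 level (e.g. the even-beat and CMRA myocardium curves, which
  share one tissue and one readout, would need a readout decay factor
  greater than 1 to agree), which is the scale of the residuals above.

## Digital phantom and acquisition

The phantom is a stack of 2D slices (default 3 × 192 × 192 voxels over a
320 × 320 mm² field of view) containing three circular vials with the
myocardium, scar and blood relaxation times.  Acquisition is segmented:
each heartbeat samples `n_lines` phase-encode lines (default 32, so the
576 encodes per contrast divide evenly into 18 heartbeats per contrast)
of one contrast in center-out order along round-robin-dealt interleaves
(encodes ranked by distance from the k-space center with angular
tie-breaks and dealt across heartbeats — a Cartesian stand-in for spiral
profile ordering; a plain linear order is available and reconstructs
identically for static objects).  Line `ℓ` of
a beat uses the `ℓ`-th transient signal of the steady-state beat of that
parity, so centric contrast weighting and through-readout decay are in
the data.  Respiratory displacement of the beat is applied as an exact
k-space linear phase; complex white Gaussian noise is added per sample.
The noise level is quoted as a fraction of the bright-contrast image
peak; when sequences are compared, one absolute level (derived from the
BOOST bright-blood contrast, default 5%) is imposed on all of them, as a
scanner would.  Each beat also yields an iNAV: the central 14 × 32
k-space block of the mid-slice at that beat's position and contrast,
zero-padded and reconstructed — deliberately low resolution in the
phase-encode direction, like a ramp-pulse navigator.

The breathing trace is sinusoidal or "asymmetric"
(`A·(1 − cos⁶(πt/T))`), the latter dwelling ≈ 47% of the cycle within
10% of the end-expiratory extreme, with optional drift and seeded
jitter.  It emulates quiet periodic breathing only: no bulk motion, no
hysteresis, no intra-beat (cardiac) motion, and rigid in-plane
translation only — so passing tests show the translational correction
machinery is exact, not that the method handles real respiratory
deformation.

## Motion estimation and correction

Each parity stream is matched against its own template (the two
contrasts look different), cut from the first beat of the stream inside
the search ROI; displacement is the argmax of normalized
cross-correlation over integer lags with separable parabolic refinement
of the 3 × 3 peak neighbourhood.  When the integer-lag peak is a perfect
match (score ≥ 1 − 1e-7, the noiseless case with on-grid motion) the
refinement is skipped — it would only add interpolation bias.  The
end-expiration reference is the mode of the 1 mm-binned SI displacement
histogram (tie → bin nearer the median), computed on the combined trace
so both contrasts align to one position; the residual constant offset
between the streams (each stream's estimates are relative to its own
template beat) is absorbed by the later volume co-registration.
Correction multiplies each line with `exp(+2πi(k·Δ))`, exact for
fractional shifts.  Accuracy is limited by the parabolic interpolation
(~0.02–0.1 px on the low-resolution iNAVs), which is why the exact-
restoration guarantee is stated for on-grid motion and the noisy-case
guarantee as an RMSE bound of half a pixel.

## Reconstruction and the phase-sensitive combination

Volumes are unitary inverse FFTs of the fully sampled per-contrast
grids.  The even (reference) volume is rigidly aligned to the odd volume
by phase correlation on the mid-slice magnitudes (sub-pixel via Fourier
upsampling; residual < 0.25 px on synthetic pairs) and shifted with the
exact Fourier phase.  The background phase is the argument of the
Gaussian-smoothed complex reference (FWHM 12 mm; below a 5% magnitude
floor the nearest valid phase is used) — a deliberate simplification of
region-growing phase estimators, adequate for the smooth synthetic phase
fields here and noted as such.  The signed output is
`Re{IR·exp(-iφ_ref)}`; intensity normalization (division by
`|reference| + 1e-3·max`) is optional and off by default: dividing by
the low-magnitude reference amplifies background noise and compresses
tissue contrast, which is exactly the published argument for omitting
it.  Display offsetting to non-negative values happens only in the CLI
export, never in stored volumes.

## Quantification

Noise is estimated in a uniform background ROI from the residual of a
wide Gaussian smooth (FWHM 25 mm, a parameter), with the estimator
divided by the analytic residual-filter factor `sqrt(1 − 2g(0) + Σg²)`
so it is unbiased for white noise.  SNR is the ROI mean over sigma; CNR
the absolute ROI-mean difference over sigma.  Signed PSIR images use the
plain real-image estimator; magnitude images inherit the
Rayleigh-background statistics naturally, which is what makes the
magnitude T2Prep-IR volume the highest scar–myocardium-contrast dataset
at realistic noise levels.  ROIs on synthetic data come from the phantom
label map eroded by 2 voxels.

## Problem sizes

Defaults were chosen so a full experiment is interactive: the sequence
simulations run in well under a second, a complete phantom pipeline
(two acquisitions, motion correction, reconstruction, PSIR, metrics) in
a few seconds, and the entire test suite in tens of seconds.

## Known limitations

Single uniform coil (no parallel imaging, no surface-coil shading);
rigid in-plane translation only; no fat compartment (only the
fat-saturation timing is modeled); idealized preparations; phase errors
at tissue interfaces are handled only by smoothing; published in-vivo
contrast magnitudes are patient-data dependent and are not reproduced —
only the directional phantom claims are asserted.
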