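# socimotor

Digital biometrics of **socio-motor agency** for dyadic wearable
recordings: a Python library (plus a thin CLI) that turns triaxial
angular-velocity streams from body-worn gyroscopes — six sensors, one
child and one clinician, sampled synchronously at 128 Hz — into
personalized indexes of **motor control**, **motor autonomy** and
**dyadic causal influence**, and screens subjects with a
sex-stratified leave-one-person-out classifier.  It is aimed at
movement-neuroscience and digital-biomarker researchers studying
social interactions (for example ADOS-style child–clinician sessions)
who need objective, anatomy-independent measures of how two bodies
exchange control during an interaction.

## The method

1. **Micro-movement spikes (MMS).**  The scalar angular speed
   `V = sqrt(Vx² + Vy² + Vz²)` is reduced to its local peaks; each
   peak is expressed as an absolute deviation from the empirically
   estimated Gamma mean of the whole series and scaled by its two
   flanking minima:

   `NormPeak = PeakDev / (PeakDev + AvgMinDev)  ∈ [0, 1]`

   Because numerator and denominator scale together, anatomical
   (allometric) amplitude differences cancel: the series is
   comparable across ages and body sizes.

2. **Motor control (Gamma process).**  MMS amplitudes are fit by
   maximum likelihood with the continuous Gamma family (shape `k`,
   scale `θ`; moments `μ = kθ`, `σ² = kθ²`).  The noise-to-signal
   ratio reduces algebraically to the scale, `NSR = σ²/μ = θ`, and
   the control index is `−log₂ NSR = log₂ SNR`.  Across sessions the
   fitted pairs follow a scaling power law `log k = a + b·log θ`
   with `b < 0` — the maturation line from memoryless-exponential
   (k ≈ 1, noisy) toward Gaussian-like (high k, predictable) regimes.

3. **Motor autonomy (entropy rate).**  MMS peaks are binarized into
   spike trains and cut into ~7.8-s windows (1000 samples at 128 Hz);
   the approximate entropy ApEn(m, r, N) of each window — template
   length m set to the mean inter-spike interval, exact-symbol
   matching on binary data — estimates the entropy rate in bits.
   Random spiking (high ApEn) means the agent is hard to predict and
   control: autonomous.  Clock-like spiking means controllable.

4. **Dyadic causality (transfer entropy).**  The plug-in transfer
   entropy `T_{Y→X}(k, l) = E[log p(x_{n+1}|x_k, y_l) −
   log p(x_{n+1}|x_k)]` with embedded histories of length 20 (word
   counts pooled across a session's windows) quantifies who leads the
   interaction, assembled into a 6×6 sensor matrix whose
   child↔clinician blocks are the shared dyadic space.  It decomposes
   exactly as `T = h_X − h_{X,Y}` (conditional minus generalized
   entropy rate).  Earth Mover's Distances between per-sensor MMS
   histograms give a companion 6×6 similarity matrix.

5. **Screening.**  Per-window feature vectors (autonomy, NSR, spike
   rate, clinician→child TE, embedding delay from the first minimum
   of average mutual information) feed an RBF-kernel SVM trained
   separately per sex under leave-one-person-out cross-validation;
   the fraction of a held-out subject's windows labelled positive is
   their screening score, validated by ROC/AUC.

A seed-deterministic synthetic dyad generator (`socimotor.synthetic_dyad`)
produces six-sensor sessions with known ground truth — Gamma amplitude
laws, renewal spiking with a controllable regularity (autonomy) knob and
directional lagged coupling — so the entire pipeline is testable without
any recordings.

## Worked example

```bash
python examples/02_gamma_control.py
```

prints (seeded, deterministic):

```
Gamma fit on 566 MMS amplitudes: k = 4.429 (95% CI 3.931..4.927), theta = 0.1478
moments: mu = 0.6547, var = 0.09677, skew = 0.950
NSR = var/mu = 0.1478 (equals theta); control index = -log2(NSR) = 2.758 bits
power law across sessions: log k = -0.46 -1.05 * log theta (R^2 = 1.00)
```

The fitted scale 0.148 *is* the noise-to-signal ratio of this child's
normalized movement amplitudes; its negative log (2.76 bits) is the
control index — higher means smoother, more predictable motor output.
The last line refits sessions of increasing programmed noise and
recovers the negative-exponent power law linking shape and scale.

The other examples follow the same pattern, one capability each:
`01` MMS extraction, `03` windowed autonomy and the agency ratio,
`04` the 6×6 transfer-entropy matrix of a clinician-led session
(the planted clinician→child entry, 0.049 bits, dominates a ~0.002-bit
noise floor and the reverse direction stays at 0.0007), `05` the EMD
similarity matrix, `06` LOOCV screening of a 26-subject cohort.

A thin CLI mirrors the library:
`socimotor simulate|mms|gamma|entropy|te|agency|screen --help`.

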