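# Model and methods

`corticalpitch` implements a mesoscopic model of how early auditory cortex
extracts pitch — and, through the same machinery, why consonant two-tone
combinations (dyads) are processed faster than dissonant ones.  The model
chain is: stimulus synthesis → simplified auditory-nerve front end → summary
autocorrelation (SACF) periodicity detection → two coupled mean-field
cortical networks (*decoder* and *sustainer*) → evoked-field observables
(equivalent dipole moment, pitch-onset-response latency, decoded pitch).

## Stimuli

Iterated rippled noise (IRN) is built by a delay-and-add filter,
`s(t) = Σ_{n=0}^{its−1} g^n s0(t − nT)`, applied to a white-noise token
`s0`; a dyad uses two delayed copies of the *same* token at delays `T0` and
`T1 = T0 / ratio` (just intonation; `2^(−semitones/12) T0` under equal
temperament).  Default conditions are those of the neuromagnetic
experiments being modelled: 750 ms IRN segments at 80 dB SPL, 48 kHz
sampling, preceded by a 750 ms energy-balanced bandpass noise precursor and
joined by a 10 ms equal-power cross-fade; single-tone experiments use 16
iterations and an 0.8–3.2 kHz band, dyad experiments 8 iterations and
125–2000 Hz with a 160 Hz (6.25 ms) lower note.  The stimulus bandpass is a
zero-phase 4th-order Butterworth so filtering adds no group delay to
latency estimates.  Level calibration fixes 1.0 full scale ≡ 1 Pa, so 80 dB
SPL corresponds to an RMS of 0.2 Pa; absolute level is immaterial
downstream because the periphery normalises its output.

## Auditory-nerve front end

The front end is a deliberately simple, pluggable phenomenological chain on
a bank of 40 gammatone channels log-spaced between 125 Hz and 10 kHz:

1. complex one-pole-cascade 4th-order gammatone filter (unconditionally
   stable at any CF/sample-rate combination), with 85 % of the filter's
   envelope group delay compensated so channel responses are approximately
   time-aligned at the noise→pitch transition;
2. half-wave rectification and power-law compression (exponent 0.3);
3. Gaussian low-pass at the channel's phase-locking cutoff,
   `min(1 kHz, CF)` (never below 250 Hz).  A Gaussian is used instead of an
   IIR low-pass because IIR ringing side lobes masquerade as periodicity at
   ~1/cutoff lags; tying the cutoff to CF expresses the progressive loss of
   phase locking, so periodicity information is carried by envelope beats
   rather than resolved fine structure;
4. decimation to a 10 kHz internal rate and normalisation of the whole
   response matrix into [0, 1] by its global maximum (this, not the level
   calibration, provides level invariance).

The chain is deterministic — no spontaneous firing or synaptic noise.  What
it does *not* capture: adaptation and synaptic fatigue, middle-ear
filtering, spontaneous-rate fibre classes, two-tone suppression, and the
full synchrony-capture behaviour of biophysical periphery models.  The two
consequences that matter here are (a) the harmonic amplitude profile of the
periodicity representation is flatter than a biophysical periphery would
produce, and (b) pitches conveyed *only* by resolved fine structure (e.g. a
2 ms period in an 0.8–3.2 kHz band, where the envelope beat spacing exceeds
the channel bandwidth) are weak; see *Known limitations*.

## Periodicity detection (SACF)

One leaky integrator per candidate period accumulates the channel-summed
product of the nerve activity with its delayed copy,

    τ_n dA_n/dt = −A_n + Σ_m p(t)_m p(t − δt_n)_m ,

over N = 250 lags uniformly spaced from 0.5 ms (phase-locking limit) to
30 ms (lower limit of melodic pitch).  Lag time constants grow with lag,
τ_n = max(1 ms, 0.3 δt_n), calibrated once (together with the group-delay
compensation) so that the lag-T detector first reaches half of its steady
response ≈ 1.25 T after pitch onset for a reference T = 5 ms IRN — the
activation-time scaling that makes longer periods take proportionally
longer to detect, and ultimately makes the pitch-onset-response latency
grow with period.  Integration uses the exact exponential update for
piecewise-constant drive at the 10 kHz periphery rate, then decimates to
the 1 ms cortical step (verified against a 10× finer brute-force integrator
to < 1 % RMS).

### Regularization into the cortical input

The raw SACF rides on a large lag-unspecific baseline (the product of
non-negative signals) and scales with stimulus statistics.  The
regularization `A → Â` used here is built from neuronal normalization
principles, in four stages, each with a concrete job:

1. **Divisive normalisation** across the lag axis,
   `z_n = A_n / (k + mean_n A_n)` with semi-saturation `k = 1` (of the
   order of the steady lag-mean, which damps the transient at sound onset
   when the lag-mean is still near zero);
2. **Lag-axis contrast enhancement**: subtract a local baseline pool (31
   columns ≈ 3.7 ms, uniform, reflected at the grid edges).  Narrow
   harmonic peaks (3–5 columns) pass; broad envelope-correlation humps —
   which otherwise drive spurious winners near 0.5 ms and 10–13 ms during
   the noise precursor — are removed;
3. **Temporal adaptation**: subtract a slow exponential average (τ = 0.5 s)
   of the residual.  Stationary structure of the noise precursor fades
   before pitch onset while the harmonic pattern appearing at the
   noise→pitch transition passes at full strength; this also makes the
   aggregated cortical response decay after the decision, giving the
   dipole moment a single dominant post-onset peak;
4. **Sensitivity taper and rescale**: detector gain ramps from 0.1 at the
   0.5 ms grid edge to 1 at 2.3 ms (detectors near the phase-locking limit
   respond weakly; this suppresses the band-edge periodicity of bandpass
   noise), and the result is scaled by a fixed mode-specific factor
   (R = 4000 for single tones, R = 1500 for dyads) onto the current range
   the decoder expects.  The two rescale factors compensate for the
   different peak-to-baseline statistics of the two stimulus bands.

All constants were calibrated once, against four qualitative targets —
no false decisions on noise-only input, prompt three-harmonic decisions,
eventual two-harmonic decisions, a decodable range bounded at 15 ms — and
then frozen.

## Cortical networks

Both networks have 250 columns, one per lag-grid period; each column holds
an excitatory and an inhibitory mean-field ensemble with rate dynamics

    τ_pop(H) dH/dt = −H + φ(I),    φ(I) = (aI − b) / (1 − e^{−d(aI − b)}),

with the standard parameter sets for excitatory (a = 310 /V·nC,
b = 125 Hz, d = 0.16 s) and inhibitory (615, 177, 0.087) populations.  The
population time constant adapts with activity,
τ_pop = τ0 Δ_T φ′(I)/H (τ0 = 10 ms, Δ_T = 1 mV), clamped to [1, 10] ms; the
formula diverges as H → 0 and the clamp maximum effectively paces every
lift-off from silence.  A 10 ms ceiling (equal to τ0, and inside the
empirical 11.9 ± 6.5 ms range for cortical populations) is required for the
sustainer to latch a decision before the decoder's transient inhibitory
phase collapses; with a 100 ms ceiling the network re-enters a
decode–collapse–re-decode limit cycle.  φ′ is implemented as the exact
analytic derivative (removable singularity handled by series expansion) and
verified against central finite differences to 10⁻⁶ relative error.

Synaptic gating follows the standard kinetic reduction: AMPA and GABA pools
relax with τ = 2 and 5 ms driven by the presynaptic rate; NMDA saturates,
dS/dt = −S/30 ms + γ(1 − S)H with γ = 0.641.  Independent Gaussian noise
(σ = 0.0007 nA, scaled by √dt) perturbs every gating variable every step.
Integration is forward Euler at 1 ms (agreement with a 0.1 ms integration
is ≤ 5 % RMS on driven rate trajectories).

### Connectivity and the decision mechanism

Within the decoder, `C^ee` is the identity and
`C^ii = (1 − c0)δ + c0` with c0 = 0.1 (specific plus global inhibition).
The harmonic matrices implement the pitch computation:

- `C^ei`: the inhibitory ensemble at period T collects excitation from the
  columns at {T, 2T, 3T}.  Each harmonic contributes a narrow Gaussian bump
  (σ = 1 grid step) normalised to unit *mass* against the untruncated
  Gaussian — so a single broad activation cannot impersonate several
  harmonics, and bumps truncated at the grid edge genuinely lose their
  off-grid weight.  An overall gain of 1.2 sets the working point at which
  **three simultaneously active harmonic locations are necessary** to
  ignite the ensemble.  Columns whose third harmonic falls beyond the
  30 ms grid (T > 10 ms) carry a 1.3× compensating weight — partial row
  renormalisation — so periods up to half the grid limit remain decodable
  from two harmonics; columns with a single on-grid harmonic (T > 15 ms)
  are de-weighted to 0.5×, making the 15 ms decoding bound structural.
- `C^ie`: the inhibitory ensemble at T projects peak-normalised Gaussian
  inhibition onto the excitatory columns at the lower harmonics
  {2T, 3T, …} up to the grid edge, sparing the fundamental.

A decision therefore unfolds as: the periodicity detectors at T, 2T, 3T
activate sequentially (≈ 1.25 T, 2.5 T, 3.75 T after onset); their decoder
excitatory columns rise; when all three are active the inhibitory ensemble
at T ignites and progressively silences the lower-harmonic columns; the
resulting drop in aggregated excitatory activity is the falling flank of
the simulated pitch-onset response.  The sustainer — a second, block-local
network receiving bottom-up input from the decoder (AMPA from excitatory,
GABA from inhibitory counterparts) and returning top-down NMDA drive to the
decoder's inhibitory ensembles — latches the winner: at rest its inhibitory
populations are tonically active (≈ 80 Hz) and its excitatory populations
silent; a strongly active decoder-inhibitory ensemble silences its
sustainer-inhibitory counterpart, the released sustainer-excitatory
ensemble ignites on bottom-up drive plus self-NMDA, and its top-down
projection keeps the decoder's winner inhibited-column active after the
shunted harmonics can no longer drive it.  All conductances are the
published cortical parameter set and are never varied between experiments.

## Observables

The equivalent dipole moment is the column sum of decoder excitatory rates
shifted by a fixed subcortical delay (50 ms single tones, 75 ms dyads);
the POR latency is its argmax within 0–350 ms after pitch onset (ties to
the earliest sample; runs whose peak does not exceed the pre-onset baseline
by 10 % of the window's dynamic range are flagged "no decision" and
excluded from averages).  Decoded pitches are the prominent local maxima
(≥ 10 % of the profile's dynamic range, and above a 30 Hz absolute
activation floor separating ignited winners at 80–170 Hz from sub-threshold
hum below ~25 Hz) of the decoder-inhibitory profile time-averaged 250–300
ms after onset; one pitch is read out for single tones, two for dyads.

## Why consonance is faster

A dyad's two harmonic series {T0, 2T0, 3T0} and {T1, 2T1, 3T1} share lags
exactly when the frequency ratio is simple (the perfect fifth shares
3T1 = 2T0; the unison shares everything).  Shared lags receive summed
drive from both notes, so the corresponding detectors rise faster and the
three-harmonic ignition condition for both fundamentals completes earlier.
Dissonant ratios spread the same stimulus energy over more, weaker,
near-coincident peaks, which also depress one another through the divisive
and contrast normalisation — decisions arrive later.  In the model this
produces pooled {P1, P5} latencies well below pooled {m2, TT, m7}
latencies (one-tailed rank-sum, p < 0.01 with 10 runs per interval), with
no parameter changed between the single-tone and dyad experiments except
the documented input rescale and subcortical delay.

## Problem sizes and reproducibility

Experiments simulate the full noise precursor and the first 450 ms of the
pitch segment (the analysis windows end at 350 ms post onset); trajectories
are recorded at 1 ms in float32.  Batch experiments default to 10 runs per
condition; the full reproduction profile uses 60.  A single master seed
spawns independent per-run streams (`numpy.random.SeedSequence`), so adding
conditions never shifts other conditions' draws, and every experiment
replays bit-identically from its recorded seeds.

## Known limitations

- **T = 2 ms pitches are unreliable.**  In the 0.8–3.2 kHz band a 500 Hz
  comb is resolved by the gammatone bank (line spacing exceeds channel
  bandwidths), so the period is carried almost entirely by fine structure,
  which this front end deliberately attenuates.  Roughly half the runs
  decode 2 ms correctly; the rest fail to ignite or ignite an octave high.
- **Latency is not monotone in period at the short end.**  For T = 4 ms
  the columns at 4, 8 and 12 ms *all* receive complete harmonic trios of
  near-equal strength (the normalised input profile is flat across
  harmonics), and the winner-take-all competition among them outlasts the
  15 ms activation head start of the fundamental: mean latency at 4 ms
  (~170–200 ms) exceeds that at 8 ms (~120–135 ms).  A periphery with a
  decaying harmonic profile (as biophysical models produce) would break the
  tie in favour of the fundamental; within this simplified front end the
  inversion is an honest emergent property.  For delays beyond the 15 ms
  decoding bound no decision occurs at all, so the latency-versus-period
  trend is cleanly observed only between roughly 5 and 15 ms.
- **No binaural integration, no plasticity, no attention/expectation
  biases**; pitch changes and sustained-field behaviour beyond the offset
  relaxation asymmetry are not analysed.
- Synthetic-data caveat: all validation uses the model's own synthesized
  stimuli.  Passing tests show that the mechanism behaves as designed under
  the stated stimulus statistics; they do not establish quantitative
  agreement with neuromagnetic recordings beyond the structural/calibration
  quantities explicitly tested.
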