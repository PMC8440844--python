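# Methods

`voxphys` estimates four vocal-function measures — mean subglottal pressure
(Ps), vocal fold collision pressure (Pc), and normalized cricothyroid (a_CT)
and thyroarytenoid (a_TA) activation — from seven aerodynamic/acoustic
features of the glottal airflow.  The estimator is a feed-forward regression
network trained **only on synthetic phonation** produced by a
muscle-controlled voice synthesizer; an impedance-based inverse filter (IBIF)
recovers the glottal airflow from a neck-surface accelerometer so the same
features can be computed from wearable recordings.

This note documents the model, its parameters and the numerical and design
choices, in the package's own words.

## 1. Voice production model

### 1.1 Muscle posturing

Each intrinsic laryngeal muscle (LCA, IA, PCA, CT, TA) and the connective
tissues (vocal ligament, mucosa) is a one-dimensional fibrous tissue with a
modified Kelvin (standard-linear-solid) law

    tau_s ds/dt + s = sigma_p(eps) + a sigma_am f_act(eps) + tau_e d(sigma_p)/dt,

with passive stress `sigma_p(eps) = sigma0 (exp(B eps) − 1)` (zero at rest by
construction) and a parabolic active length-tension shape
`f_act = max(0, 1 − b (eps − eps_m)^2)` scaled by the activation `a ∈ [0, 1]`
and the maximum isometric stress `sigma_am`.  Connective tissues have
`sigma_am = 0`.  The quasi-static call path is the `tau_s → 0` limit; a
stiff-ODE path integrates the full law for time-varying strain.

Posturing reduces to a scalar force balance along the fold axis: CT tension
acting through a lever gain (`g_ct`) elongates the fold against the passive
tension of the TA + ligament + mucosa assembly and a fraction (`g_ta_active`)
of the active TA stress, with the kinematic coupling `eps_CT = −kappa_ct eps`.
The balance is monotone in the fold strain, so it is solved with a bracketed
root-finder (`brentq`, tolerance 1e−12) over the physiologic band
[−0.3, 0.6] and clipped at the band edges for extreme co-activations.  (A
damped fixed-point iteration would serve too; the bracketed solve is
unconditionally convergent on a monotone residual, which is why it is used.)

Adduction follows an empirical rule: the effective adductor level
`a_LC = (a_LCA + a_IA)/2 − 0.25 a_PCA` maps linearly to the prephonatory
glottal half-width at the vocal processes, `xi_02 = xi_max (1 − 2 a_LC)`
(`xi_max` = 1.5 mm), negative values meaning a pressed configuration.  The
posterior cartilaginous gap area is `0.7 · 3 mm · max(xi_02, 0)`.

Antagonistic co-contraction effects beyond this balance are not modeled,
and left/right folds are identical (one side computed).

The numeric constants (rest lengths, cross-sections, maximum stresses,
passive curve coefficients, lever gains) are not primary literature values
of record; they ship as a versioned YAML parameter file
(`assets/params_default.yaml`) with defaults chosen from the lineage of
Kelvin-type laryngeal muscle models and calibrated **once** so the
synthesizer phonates across the sampled control lattice with female-range
fundamental frequency and airflow.  Every constant is overridable.

### 1.2 Triangular body-cover fold model

Three masses per side (lower/upper cover on a body mass) with nonlinear
springs `k x (1 + eta x^2)` (`eta` = 1e6 m⁻²), viscous damping
(zeta = 0.1/0.1/0.15), and a cover-cover coupling spring.  Empirical rules
regenerate the lumped parameters from the posture: geometry scales with
strain at conserved tissue volume (`L = L0(1+eps)`, `T = T0/(1+0.8 eps)`,
depth from volume conservation); cover stiffness carries the
area-weighted ligament+mucosa fiber stress and body stiffness the total TA
stress through a string-tension term `pi^2 sigma T D / L` added to a shear
term `2 mu L T / D`.  At zero strain and zero activation the rules return
the reference parameters exactly.

The prephonatory glottis is triangular: the local half-width of cover mass
*i* is `h_i(y) = x_i + x_i0 + (y/L) xi_02`.  Because both profiles share the
slope, the flow-limiting profile is the one with the smaller offset, and all
area/contact integrals have closed forms.  Collision is zipper-like: where
`h_i < 0` a penalty spring (3× the mass spring, per unit length) acts over
the contacting anterior portion, with added damping (zeta_col = 0.4) scaled
by the contact fraction.  The collision pressure sample is the integrated
collision force over the contact area; the scalar regression target is the
per-cycle peak averaged over the analysis window (config-switchable to the
contact-phase mean).  The per-cycle peak is the quantity discussed
clinically, which is why it is the default.

Time stepping is a fixed-step truncated-Taylor update
(`x += v dt + a dt²/2; v += a dt`) at the simulation rate (44.1 kHz
default), the conventional scheme for body-cover models; with the default
damping the discrete energy balance is non-increasing to O(dt²) per step.

### 1.3 Glottal flow

The effective glottal area is the membranous open integral (doubled for the
two folds) plus the posterior gap.  The flow solves the transglottal
pressure balance with a lumped kinetic loss `kt ρ U²/(2 A_g²)` (kt = 1.0,
config-exposed) against the characteristic wave impedances of the adjacent
tract sections; the admissible root has a closed form, is continuous in all
arguments, and reduces to the quasi-steady Bernoulli orifice flow as the
impedances vanish.  Driving pressures on the cover masses follow the
standard body-cover convention: the lower mass sees
`Ps − (Ps − Pe)(a_min/a_l)²` over its open fraction and Ps over its
contacted fraction; the upper mass sees Pe over its open fraction.

### 1.4 Wave-reflection tracts

Subglottal and supraglottal tracts are concatenations of uniform cylinders
of length `c·dt/2` (two propagation/scattering passes per sample), with
junction reflection coefficients `(A_i − A_{i+1})/(A_i + A_{i+1})` and an
exponential per-section attenuation (0.996 at 44.1 kHz, config-exposed —
propagation loss is a known sensitivity of this model family and can be
swept).  The discrete ladder's effective acoustic length is (n−1) sections;
the loader adds one section so the anatomical length is preserved.

The lip end carries a first-order inertive radiation load (piston-in-baffle
R‖M network, bilinear-discretized; DC reflection exactly −1; radiated
pressure rising ≈ +6 dB/octave at low frequency).  The lung end is an
absorbing termination with reflection −0.8: the sign is the pressure-release
convention — the lungs approximate a soft termination — and the magnitude is
config-exposed.  Because the per-section attenuation would otherwise damp
the travelling waves that carry the static head (steady tracheal flow sees
almost no viscous drop), the injected lung source is normalized so the
zero-flow steady subglottal pressure equals the lung pressure exactly; the
AC loss behavior is untouched.

Area functions for the male/female /æ/ and /ɑ/ tracts and a representative
trachea are packaged as CSV assets.  They are smooth parametric
approximations of published MRI-based shapes, not digitizations of any
single table (so labelled in their headers); the male /ɑ/ formants fall at
F1 ≈ 810 Hz, F2 ≈ 1320 Hz and the female /æ/ at ≈ 840/2200 Hz, verified by
an independent chain-matrix calculation and by the packaged wave-reflection
machinery itself.  Area-preserving resampling maps them to the section
length implied by the simulation rate.

## 2. Monte Carlo training data

Controls are drawn uniformly at random on the discrete sustained-phonation
lattice: a_CT, a_TA ∈ {0, 0.1, …, 1}, a_LCA, a_IA ∈ {0.2, …, 0.8},
a_PCA ∈ {0, 0.1}, lung pressure 500–2,000 Pa in 150 Pa steps.  (The lattice
is sampled, not enumerated — the full factorial is ~1.3 M points.  The
printed a_PCA range/step implies exactly two levels.)  Each simulation runs
800 ms; all scalar features and targets use only the final 50 ms to avoid
onset transients.  The default tract is the female /æ/, matching the
validation population of the estimation task.

The glottal flow is conditioned exactly as laboratory recordings: 10th-order
Chebyshev-II low-pass at 1,100 Hz (60 dB stopband — the ripple spec is a
design choice, only order and cutoff being given), polyphase decimation to
8,192 Hz, 4th-order Butterworth high-pass at 60 Hz, all zero-phase.  Rows
whose features do not occur in the laboratory population are discarded
(ACFL < 30 mL/s or fo outside 120–400 Hz, inclusive bounds).  Two fixed
corrections align scales with the laboratory conditions: SPL −28.5 dB (lip
output referred to a 10 cm microphone) and Ps −3.37 cm H2O.  The Ps offset
derives from a clinical corpus that is not recomputable here; it ships as a
documented constant, and `recalibrate_ps_offset` recomputes it against any
user-supplied reference table.  Feature and target columns are min-max
normalized on the (seed-reproducible) 80% training split, applied to both
splits; the split is drawn after filtering.

With the default parameter file roughly 80% of lattice draws phonate and
survive the filters — a higher yield than a broader exploration would give,
because the sampled adduction range is already restricted to
oscillation-friendly configurations.

## 3. Regression networks

Fully connected ReLU stacks with 10% inverted dropout after every hidden
layer, linear 4-unit output, trained with Adam (lr 0.001, β = 0.9/0.999) for
100 epochs on the MSE of the four normalized outputs, batch size 64 (not
specified by the protocol; 64 is a conventional default).  Targets share the
feature normalization scheme, which balances the four-output loss.  Case I
uses the six aerodynamic features (ACFL, MFDR, OQ, SQ, H1−H2, fo); Case II
adds SPL.  The implementation is plain numpy — dropout and per-epoch
train/validation traces are explicit requirements, and the network sizes
involved (≤ 4×128) train in seconds — with He initialization and
seed-deterministic batching.  Metrics are computed in denormalized physical
units: MAE, RMSE, R², MAE as % of the observed target range, MAPE.

## 4. Feature extraction

Cycle segmentation finds flow minima on a lightly smoothed copy (kernel =
period/8) after an autocorrelation period estimate (normalized peak ≥ 0.5
required for voicing); landmarks are measured on the raw signal with
sub-sample threshold crossings and parabolic peak refinement.  OQ uses a
threshold at 10% of the cycle's peak-to-peak amplitude above the minimum
(the conventional criterion; the upstream definition is not reproduced in
the source protocol), and fo comes from the refined autocorrelation period —
per-cycle boundary jitter would otherwise alias into OQ and fo.  H1−H2 picks
harmonic magnitudes from a Hann-windowed DFT within ±20 Hz of fo and 2fo.
ACFL/MFDR are per-cycle means (window extrema are a config switch).  SPL is
`20 log10(RMS/20 µPa)` of the acoustic channel.

The intraoral-pressure reference conditions the IOP record (5th-order
Butterworth low-pass at 80 Hz, zero-phase, decimation to 256 Hz), segments
occlusion plateaus by a threshold at half the 98th percentile with a minimum
30 ms duration, trims plateau edges, averages the two plateaus flanking each
vowel, and averages the three middle syllables (≥ 5 syllables required).

## 5. IBIF

The forward model is a lossy uniform tracheal transmission line (area
2.5 cm², wall loss 1 m⁻¹, lung reflection −0.8) driven by the glottal flow
at the top, with a per-area mass-spring-damper skin patch at the sensor
depth; the accelerometer output is the skin surface acceleration times the
sensor sensitivity.  The model is LTI and applied in the frequency domain.
The inverse applies the conjugate transfer function with a Tikhonov floor of
1e−4 relative to the **peak magnitude** of H and is restricted to the
conditioning band (60–1,100 Hz, smooth half-cosine transitions): the
acceleration response falls as 1/ω² toward DC, so an unrestricted inverse
would amplify out-of-band leakage that carries no physical information.

Calibration is global-best PSO (inertia 0.72, cognitive/social 1.49, swarm
24, 40 iterations — hyper-parameters are implementation choices, none being
printed in the source protocol) over ±50% bounds around nominal adult
values, minimizing the relative band-RMS waveform error between the
inverse-filtered acceleration and the reference airflow over the interior of
the synchronized overlap (the outer 10% per side carries finite-window edge
effects).  A derivative-free Powell polish (≤ 2,500 evaluations) refines the
swarm best: the cost surface has long, shallow valleys (skin mass and
stiffness trade off at fixed resonance) in which the swarm alone stalls.
Identifiability depends on the reference's spectral support: a harmonic comb
that misses the skin-resonance region leaves the skin parameters weakly
constrained, which is visible in the calibration tests.

The oral-airflow reference uses a single-notch FIR (conjugate zero pair,
unity DC gain) at the first vocal tract resonance.  The center frequency is
located on the cepstrally smoothed spectral envelope (liftering below 60% of
the glottal period removes the harmonic comb), with parabolic sub-bin
refinement — an automatic stand-in for the interactive ripple-minimization
procedure used with laboratory mask recordings.

## 6. Problem sizes and reproducibility

The full recomputation (`scripts/acceptance.py`) simulates 9,000 lattice
draws (typically ≈ 7,300 surviving rows), then trains the 2×4 and 4×128
networks for both cases; it completes in roughly ten minutes on one core.
The in-suite acceptance tests use 1,500 draws.  These sizes were chosen so
the held-out metrics are stable against split/seed noise at a few percent
while the whole pipeline remains desk-scale; all randomness flows from a
single root seed split per stage, and identical seeds reproduce datasets
bit-for-bit and metrics to 1e−6.

## 7. What the synthetic data does and does not show

The generator emulates sustained, symmetric, non-pathological female
phonation of a single "anatomy" across a wide control range.  It does not
emulate inter-subject anatomical variability, asymmetric or lesioned folds,
pitch glides or syllable gestures, supraglottal noise sources, or sensor
noise.  Consequently, held-out synthetic accuracy shows that the feature →
measure mapping is learnable and stable under the stated protocol — it does
not certify accuracy on real recordings, where model mismatch and
measurement error dominate.  Two further caveats: the collision-pressure
scalar depends on the chosen per-cycle-peak summary, and the muscle
activations are more identifiable from this synthesizer's features than the
printed reference values suggest for theirs (our a_CT/a_TA R² run slightly
high), consistent with a cleaner, lower-variance synthetic corpus.

## 8. Known limitations

- The posturing balance is scalar (strain only); rotation/translation of the
  cricothyroid joint is folded into two lever constants.
- Collision pressure uses a linear penalty integrated over the contact zone;
  no Hertzian or poroelastic contact.
- The trachea in the IBIF forward model is uniform and independent of the
  wave-reflection subglottal tract used for synthesis (one acoustics engine
  serves synthesis; the IBIF line is analytic for invertibility).
- PSO identifiability of skin mass/stiffness requires reference content near
  the skin resonance.
- Formant accuracy of the packaged area functions is approximate (§1.4);
  vowel identity, not acoustic fidelity to a specific speaker, is the goal.
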