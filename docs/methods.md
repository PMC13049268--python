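# Methods

`grapetx` designs calibration-free ("universal"), spectrally selective
parallel-transmit (pTx) excitation pulses by unparameterized optimal control
(GRAPE), and evaluates them with hard-pulse Bloch and extended-phase-graph
(EPG) simulation. This note records the model, the numerical choices, and
what the synthetic data do and do not establish.

## Physical model and conventions

RF is represented as complex per-channel voltages V_c(t) (volts) on a
uniform midpoint time grid; gradients as G(t) in mT/m on the same grid.
Channel sensitivities s_c(r) carry Hz/V, so the rotating-frame transverse
field is gamma*B1(r,t)/2pi = sum_c s_c(r) V_c(t) (Hz, complex) and no
separate volts-to-tesla map is needed. The longitudinal rate of a spin is
dB0(r) + f + gamma_bar * G(t).r with the injected offset f and
gamma_bar = 42.577 Hz/(mT/m * mm). Each sample applies the exact axis-angle
rotation of the instantaneous field (hard-pulse approximation); relaxation
is neglected during the few-millisecond pulses (T2 >> T). Handedness:
positive offsets precess Mxy clockwise, i.e. free precession at f for a
time tau accrues phase -2*pi*f*tau; the flip angle is extracted as
atan2(|Mxy|, Mz), which stays monotone past 90 degrees.

The volts-to-field calibration is a property of the (synthetic) coil: the
generator normalizes each subject so the mean CP-mode magnitude over the
brain equals 47 Hz/V. This coil efficiency was chosen so that a 90-degree,
3 ms Hann-apodized sinc respects a 1 W per-channel time-average power limit
with about 2x margin; an appreciably less efficient coil would make any
selective 90-degree pulse of this duration power-infeasible under the
limits the designer enforces (power here is averaged over the pulse
duration at 50 ohm, not over a TR duty cycle, so the package's absolute
millijoule figures are a convention, not a claim).

## Design target and cost

The target is a rectangular spectral flip-angle profile, FA_T for
|f| <= BW_T/2 and zero outside, identical in every voxel of every subject;
a constant selection gradient then maps the spectral passband to a slice or
slab. The cost is a magnitude-least-squares term over per-voxel random
frequency samples plus a phase-consistency term: within the passband the
response phase must satisfy phi(f) - phi(f+df) = pi*df*T, the relation a
linear-phase pulse of duration T obeys (free precession over T/2). The
phase difference formulation fixes the phase *slope* without prescribing
any per-voxel phase intercept, which leaves static phase shimming available
to the optimizer. Residuals are wrapped to (-pi, pi] before squaring and
normalized by pi*df*T; df defaults to 100 Hz ("slightly shifted" is all the
physics requires — small against the passband, large enough that the
difference is well-conditioned).

Weights: w_profile(f) is 1 deep in the passband, falls to exactly zero at
+-BW_T/2 over a raised-cosine flank (default width 0.3*BW_T), and rises to
a configurable stopband plateau (default 0.5) — the transition band is
unavoidable for a finite-duration pulse and must not dominate the quadratic
cost. The voxel weight multiplies by (1 + lambda_b0 * |dB0| in Hz); the
absolute value keeps the weight admissible for either sign of off-resonance.
The phase term is gated by w_ph(FA) = (1 + tanh(k*(FA - 0.2*FA_T)))/2 with
k = 10/FA_T, suppressing phase residuals where the flip angle (hence the
transverse phase) is ill-defined; at FA zeros the phase genuinely jumps by
pi. The total cost is the square root of the weighted sum normalized by the
number of (subject, voxel, frequency) terms, which makes lambda_ph
comparable across problem sizes. Frequency samples (5 Gaussian sigma =
6.6 kHz draws per voxel for slice designs; 3 uniform draws in
[-6.25, 6.25] kHz for slab designs) are drawn once per design from
per-subject streams and held fixed, so the objective is deterministic for
the optimizer.

## Optimizer

SLSQP on the half-parameter vector of a time-symmetric pulse (element-wise
mirror of complex RF and gradients; the symmetry halves the search space).
Two symmetry conventions are implemented: plain mirroring, used by the
designer, admits static per-channel phase shims (a complex weight on a
shared real envelope), which are the dominant B1+ homogenization mechanism —
but linear spectral phase is then a property the phase term must enforce,
not a theorem. Conjugate (Hermitian) mirroring guarantees a real spectrum
and hence exactly linear phase, but forces a spatially uniform phase
intercept and therefore forbids phase shimming; it is available for
constructing reference pulses.

Gradients of the cost are computed by adjoint-state differentiation through
the rotation chain: a forward sweep stores the magnetization trajectory, a
backward sweep propagates the adjoint with transposed rotations, and the
per-sample gradient w.r.t. the rotation vector is J_l(theta)^T (M x lambda)
with J_l the left Jacobian of SO(3) (series expansions guard small angles).
This is validated against central finite differences to a relative error
below 1e-5. Crucially, the coarse design grid (30 us; 20 us in the paper's
slab setting) is only a *parameterization*: the cost always simulates the
linearly interpolated fine-grid (10 us) waveform — the pulse the scanner
would play — with the gradient chained through the interpolation operator.
Optimizing the coarse-grid discretization directly was observed to overfit
it badly (a design whose coarse-grid cost was 0.031 scored 0.084 after
interpolation).

Hardware constraints (peak voltage, gradient amplitude, slew rate including
the edge ramps from and to zero, per-channel and total time-average power)
enter as smooth aggregated inequalities: exact sums for the powers,
log-sum-exp soft maxima for the per-sample quantities (the soft max
over-estimates the true max by at most 5% of the squared limit, so it is
conservative). The slew constraint is evaluated on the fine playout grid,
where the edge ramps are steepest. The limits handed to the optimizer are
tightened by 0.2% so SLSQP's transient constraint violations still satisfy
the true limits; the best true-feasible iterate is tracked during the run,
candidates are projected to exact feasibility (rescaling) and re-scored,
and the returned pulse is never worse than the initialization and always
passes the exact per-sample limit check. The initialization is a CP-mode
Hann-apodized sinc with TBW = BW_T * T whose envelope bandwidth is
numerically calibrated so its small-tip FWHM equals TBW/T (apodization
alone would widen it ~1-2%).

ROI (slice-specific) designs multiply every voxel's contribution by
exp(-d/10 mm) with d the distance from the slice center along the selection
axis, warm-start from the whole-volume pulse, optimize only every second
slice position and reuse each result for the adjacent slice. The B1+-shim
baseline is magnitude least squares via alternating phase update and linear
solve, with a few seeded random-phase restarts (alternating projections are
prone to the CP fixed point).

## Synthetic field maps

Measured multi-subject field-map databases for head arrays are not
redistributable, so the cohort is synthetic: an ellipsoidal head on a
default 24 x 20 x 20 grid at 5 mm (about 3-4k brain voxels), eight loop-like
sources on a ring whose magnitude decays with distance and whose phase
advances with an RF propagation term (k ~ 0.048 rad/mm, a ~13 cm in-tissue
wavelength at 7T), so the CP combination is constructively bright at the
head center and destructively dark peripherally — the hallmark 7T pattern.
Maps are expressed in the CP-aligned frame (the azimuthal phase rotation of
the physical array is absorbed into the channels, as CP-calibrated relative
maps are in practice), so equal drive is the CP mode. dB0 is a smooth
low-order polynomial (+-150 Hz) plus Gaussian hotspots up to +-600 Hz near
the anterior-inferior and lateral-inferior mask boundary (frontal sinuses,
ear canals). Per-subject jitter (head size +-5%, position +-4 mm, tilt
+-5 degrees, coil loading +-10%, hotspot strength) is driven by a
deterministic (master seed, subject index) stream; the default cohort has
20 subjects. Generated cohorts have CP-mode coefficient of variation around
35% and center-to-periphery ratios above 3, so the design problem is
non-trivial.

What the generator does *not* emulate: realistic anatomy, electromagnetic
(FDTD) field solutions, receive sensitivities, SAR hot spots beyond the
stated power limits, or measured inter-subject covariance. Passing tests
therefore demonstrate that the method recovers its design targets under
plausible 7T-like inhomogeneity, not performance on any real scanner.

## Evaluation

Slice profiles are simulated with 3000 spins equidistant on a 6 mm segment,
B0/B1+ linearly interpolated across the segment, the selection gradient
mapping position to frequency, and the pulse's own gradients acting on the
absolute spin positions; the slice integral is the magnitude of the complex
sum (phase dispersion across the slice reduces it). The sequence's
slice-refocusing lobe is modeled by rewinding half the selection-gradient
area (configurable); without it the linear across-slice phase of any
selective pulse annihilates the integral. The EPG module maps per-voxel
excitation FA/phase to vFA-TSE echo amplitudes with the standard
configuration-state evolution (unit crusher dephasing per half echo
spacing, relaxation over the actual durations, instantaneous RF); it agrees
with a 512-spin dephased-isochromat ensemble to machine precision on short
trains, and reproduces unit echoes for the ideal CPMG 90/180 train. The
default refocusing train (107 echoes, 6.65 ms spacing, 12.5 ms first
spacing, 120 -> 55 -> 110 degree vFA ramp, T1/T2 = 1500/60 ms) is a generic
plausible setting, configurable via a plain-text train file, not a claim
about any particular protocol.

## Problem sizes and determinism

Desk-scale defaults keep a design run in tens of seconds: one to three
subjects, 70-200 randomly subsampled voxels per subject, 2-3 frequency
offsets per voxel, 300 SLSQP iterations. These sizes are the package's
validation conditions; the method itself scales linearly in (subjects x
voxels x offsets x time samples). Every random choice (cohort, voxel
subsets, frequency draws) derives from explicit seeds, so a design is a
pure function of (cohort config, design config), and repeated runs are
bit-identical.

## Known limitations

- The hard-pulse integrator is exact for piecewise-constant waveforms but
  the played pulse is piecewise-linear; at 10 us and < 7 kHz offsets the
  discrepancy is negligible, and design and evaluation share the same
  fine-grid model.
- SLSQP with ~1000 parameters typically hits the iteration budget before
  its convergence test; the returned-best contract makes this safe, but
  under-converged universal designs can be beaten by longer runs.
- The MLS shim and the GRAPE designs are local optimizations; different
  seeds give slightly different (equally valid) pulses.
- Slab designs regularly ride the per-channel power and slew limits; with a
  less efficient coil calibration the 90-degree target becomes infeasible
  and the optimizer trades flip angle for feasibility.
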