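# Methods

This note documents the models and procedures `dsgckit` implements, the
defaults it ships, the numerical choices behind them, and what the synthetic
generators do and do not emulate.

## Sweep preprocessing

A `SweepSet` holds trial-replicated traces for each of the stimulus
directions (canonically 8 at 45° spacing, three trials each, sampled at
10 kHz). Traces are averaged across trials per direction, then the mean of
the first 500 ms (the pre-stimulus baseline) is subtracted; baseline
subtraction is idempotent. ON (bar entry) and OFF (bar exit) responses are
analyzed independently inside two disjoint 1.5 s windows, defaulting to
0.5–2.0 s and 2.5–4.0 s of a 4.5 s sweep; window placement is configurable
because it depends on stimulus geometry (bar entry time = field offset /
speed).

Peak currents are the window maximum for IPSCs (outward, recorded at the
cation reversal 0 mV) and the window minimum for EPSCs (inward, recorded at
the chloride reversal −60 mV); ties go to the earliest sample. Spikes in
cell-attached sweeps are detected on a zero-phase band-passed copy
(0.08–2 kHz Butterworth, forward–backward so event times are not shifted) by
threshold crossing with a refractory merge (default 2 ms). The threshold
default is 5× the median absolute deviation of the filtered trace — an
automated surrogate for per-cell manual threshold choice, with a manual
override in the configuration. Maximum firing rate is a sliding count
(default 100 ms slide) restricted to the response window; the search is
event-driven (a candidate interval starts at each spike, half-open
counting), which attains the supremum over all continuous placements.
Subthreshold peak depolarizations come from a zero-phase low-pass (default
50 Hz) that removes brief action potentials while passing the synaptic
envelope. Low-pass spike removal relies on spikes being brief and roughly
charge-balanced (depolarization followed by afterhyperpolarization); a wide
unipolar transient would leave a residual of roughly area × bandwidth.

## Directional statistics

The vector sum of a tuning curve r(θ) is Σ r_d·(cos θ_d, sin θ_d). Its angle
(mapped to [0, 360)) is the response-weighted direction; its length
normalized by r_max = max r quantifies tuning strength. Normalization by
r_max rather than Σr follows the field convention for these cells; for
broad bimodal curves the normalized value can exceed 1, which is a property
of the statistic and is left as-is. A numerically vanishing sum (|Σ| below
1e−9·r_max, e.g. any symmetric curve) leaves the angle undefined and the
result flagged rather than fabricated.

For inhibitory curves the null direction is either the argmax of the IPSC
curve or the vector-sum angle (both conventions are implemented and the
output records which was used); the preferred direction is 180° away,
snapped to the nearest sampled angle because responses exist only on the
grid. Argmax ties break toward the angle nearest the vector-sum angle, then
toward the smallest angle. Spiking and subthreshold-Vm curves give the PD
directly as the vector-sum angle. DSI = (PD − ND)/(PD + ND) is bounded in
[−1, 1] for non-negative responses; asymmetric inhibition is the signed
difference ND − PD of peak IPSCs. Circular alignment offsets are reported
in (−180°, 180°], antipodal mapping to +180°.

## Parallel-conductance model

The membrane is a single RC compartment with three branches:

    dV/dt = −[G_exc(t)(V − E_exc) + G_inh(t)(V − E_inh) + G_leak(V − E_leak)] / C_m

integrated by forward Euler, V(t+Δt) = V(t) + (dV/dt)·Δt. Units are nS, mV,
pF and ms, which make the expression conversion-free (nS·mV/pF = mV/ms).
The minus sign and grouping are the physically consistent reading
(each branch relaxes V toward its own reversal); this reproduces the stated
rest E_leak = −55 mV with zero synaptic input. Defaults: C_m = 80 pF,
G_leak = 3.3 nS, E_leak = −55 mV, E_exc = 0 mV, E_inh = −60 mV — typical
empirical passive constants for these cells, each overridable per cell.

Δt defaults to 0.1 ms, more than 20× inside the stability bound
Δt < C_m/(G_leak + max ΣG_syn) at default parameters; integration aborts
with the required bound in the message if |V| exceeds 200 mV. For
non-negative conductances and stable Δt, V stays inside the reversal
envelope, piecewise-constant inputs settle to the weighted-reversal closed
form ΣG_iE_i/ΣG_i (verified to 0.01 mV), and the dt = 0.1 ms peak
depolarization agrees with a dt/100 reference to better than 0.1%.

Conductance extraction divides baseline-subtracted, trial-averaged currents
by the driving force at the recording hold: g_inh = I_ipsc/(V_hold,inh −
E_inh) at hold 0 mV, g_exc = I_epsc/(V_hold,exc − E_exc) at hold −60 mV.
Negative values — wrong-sign noise — are rectified to zero after averaging;
rectifying before averaging differs only at noise level. The extraction
holds reuse the model reversals so extraction and simulation are mutually
consistent.

## Paired recordings

IV curves are assembled from per-hold sweep blocks: trials averaged,
pre-stimulation baseline subtracted, and the evoked peak taken as the
maximal absolute deflection (sign preserved) inside the depolarization
epoch, which comes from stimulus metadata because no universal search
window exists. Commanded holds are shifted by the liquid-junction correction
(−10 mV default for the dual-recording solutions; note the single-cell
voltage-clamp solutions have a −12 mV correction — the value is a config
field, not a constant). An OLS line through the points gives the connection
conductance (slope, pA/mV = nS) and reversal (x-intercept); fits with
R² ≤ 0.80 fail quality control ("above 0.80" is read strictly). A slope
below numerical epsilon leaves the reversal undefined (NaN) rather than
reporting a wild intercept.

Dendritic fields are convex hulls of traced point sets (Qhull); overlap is
the convex-polygon intersection area (shapely), symmetric and bounded by the
smaller hull. The conductance–overlap relation is the squared Pearson
correlation of raw values (not a regression through the origin), the default
reading when a plain R² is reported for such scatter.

## OKR quantification

Pupil centers are fitted per frame to the 8 pupil-border markers with
likelihood ≥ 0.9 (the pose-network cutoff is not standardized; 0.9 is the
config default) using the Coope linearization x² + y² = 2ax + 2by + c,
solved in one least-squares step — exact on noiseless circles and O(σ/√n)
in center error for small isotropic noise. Frames with fewer than three
usable markers (three being the minimum that determines a circle) carry the
last good center forward and are flagged low-confidence; frames before the
first good fit are back-filled from it. Centers are referenced to the
centroid of the high-confidence corneal reflections, making the coordinate
translation-invariant.

Calibration converts pixels to degrees using the 12° angular separation of
the two cameras: the cornea-referenced pupil centers in the two views sit a
fixed pixel distance apart, so scale = 12° / mean paired distance, computed
per presentation (session mean over frames that are high-confidence in both
cameras). The camera with more high-confidence frames is analyzed
(overridable).

Positions are smoothed with a Gaussian of σ = 2 frames (20 ms at 100 fps;
applied to position, not velocity), differentiated by central differences
(one-sided at edges) and scaled by fps to °/s. Frames with total velocity
above 30 °/s are saccades/fast movements; imputed frames are
low-confidence; the rest are slow pursuit.

Cumulative slow pursuit sums per-frame displacements over slow frames,
projected on the stimulus direction unit vector (positive with the
stimulus). Two deliberate numerical choices here:

- Displacements are **backward differences of the unsmoothed position**
  (velocity for classification still comes from the smoothed position).
  With carry-forward imputation, the position catches up in one jump on the
  first good frame after a gap; backward differencing assigns that jump to
  the good, slow-labeled frame, so pursuit that happened during dropout
  stays in the integral. Central differencing instead splits the jump onto
  the excluded frame and biases gain low by roughly the dropout fraction.
  Using raw rather than smoothed displacement also keeps saccadic
  displacement, which smoothing smears over ±4σ frames, out of neighboring
  slow frames.
- Frames within 1 frame of a saccade label are excluded from the integral
  as a margin against boundary leakage.

Gain is cumulative slow-pursuit displacement divided by total stimulus
displacement (velocity × duration; 2 °/s × 45 s = 90° at defaults), signed:
negative gain means net slow movement opposite the stimulus. Pursuit during
excluded (saccadic) frames is unmeasurable under this definition, so the
estimate is biased low by about the excluded-time fraction times the gain
(~0.03 at gain 1 under the default saccade statistics); this is inherent to
slow-frame integration, not corrected for.

## Synthetic generators

Every generator is deterministic given (spec, seed) and returns its latent
parameters, so downstream stages are tested as parameter recovery.

- **Tuning law**: peak(θ) = peak_ND + (peak_PD − peak_ND)·f(θ − PD) with a
  von-Mises-shaped kernel rescaled to f(0) = 1, f(180°) = 0 and
  parameterized by its half-width at half maximum (90° gives the cosine
  kernel). Chosen for smooth unimodality with two-parameter control; the
  shape of real tuning curves is not standardized.
- **PSC waveform**: alpha function (t/τ)e^(1−t/τ) (default τ = 80 ms) in
  each response window, polarity +1 for IPSC-like, −1 for EPSC-like, plus
  white trial noise. Trial-to-trial noise magnitudes in real recordings are
  not published; the default (10 pA) is a free parameter exposed in config.
- **Spike trains**: homogeneous Poisson within each response window at the
  tuned rate, zero outside, rendered as 1 ms biphasic waveforms; an optional
  absolute refractory period (`min_isi`) thins the train so waveforms never
  overlap (used when exact count recovery is the point; the default 0 keeps
  the window-mean rate exactly the tuning law).
- **IV data**: peaks on I = g(V − E_rev) + noise, and optionally full sweep
  traces whose evoked alpha transient peaks on that line.
- **Eye streams**: latent position gain·v·t along the stimulus axis,
  reset by minimum-jerk saccades opposite the stimulus (default 10°,
  700 °/s peak — mouse-like resetting saccades, 2–3 frames at 100 fps),
  rendered orthographically at a configurable °/px scale into two camera
  frames whose centers differ by the separation-implied pixel offset; 8
  pupil markers exactly on a circle, 3 fixed corneal reflections, white
  center noise (default 0.05°), and Bernoulli frame dropout (default 5%)
  via sub-threshold likelihoods.
- **Dendritic fields**: rectangles of known area with corner points
  included, shifted for an exact prescribed hull overlap.

What the generators do **not** emulate: photoreal eye images, pupil-size or
torsional dynamics, biophysical spike shapes, series-resistance or space-
clamp artifacts, correlated (non-white) noise, and slow drift. Passing
recovery tests therefore demonstrates correctness of the quantification
chain under the stated noise model, not robustness to every artifact of
real recordings.

## Problem sizes and defaults used in the shipped checks

The test suite and `scripts/acceptance.py` run the membrane model for
0.4–0.5 s of simulated time (dt 0.1 ms; the fine-dt reference uses 1 µs),
IV recovery over 500 seeds at 5 holds, OKR gain recovery over 100 seeded
45 s presentations at the default noise/saccade/dropout statistics,
Monte-Carlo geometry checks at 10⁵ samples, and vector-sum oracle
comparisons over 1,000 random curves. Reduced sweep durations (1.8 s at
2 kHz) with proportionally shifted windows are used where only the
windowing logic, not the default geometry, is under test.
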