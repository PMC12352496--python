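# dsgckit

Quantification toolkit for retinal direction selectivity and optokinetic-reflex
(OKR) behavior, aimed at cellular neurophysiologists analyzing
direction-selective ganglion cell (DSGC) recordings and marker-based eye
tracking.

Direction-selective ganglion cells fire preferentially for one direction of
visual motion, a computation shaped by asymmetric GABAergic inhibition from
starburst amacrine cells (SACs): inhibition is strongest for null-direction
(ND) motion. `dsgckit` implements the standard quantification chain for this
system, end to end, on plain-text data:

- **Sweep preprocessing** (`dsgckit.traces`) — trial averaging, baseline
  subtraction over the first 500 ms, spike detection (band-pass 0.08–2 kHz +
  threshold), sliding-window maximum firing rates, and peak IPSC/EPSC or
  subthreshold-ΔV<sub>m</sub> extraction inside separate 1.5 s ON and OFF
  response windows.
- **Directional statistics** (`dsgckit.tuning`) — the vector sum
  VS = |Σ<sub>d</sub> r<sub>d</sub> e<sup>iθ<sub>d</sub></sup>| / r<sub>max</sub>,
  preferred/null directions by either the argmax-IPSC or vector-sum
  convention (PD = ND + 180°), the direction selectivity index
  DSI = (PD − ND)/(PD + ND), asymmetric inhibition (ND − PD peak IPSC), and
  signed circular alignment offsets.
- **Parallel-conductance model** (`dsgckit.conductance`) — synaptic
  conductances from voltage-clamp currents
  (g = I / (V<sub>hold</sub> − E<sub>rev</sub>), rectified), integrated by
  forward Euler:
  dV/dt = −[G<sub>Exc</sub>(t)(V−E<sub>Exc</sub>) + G<sub>Inh</sub>(t)(V−E<sub>Inh</sub>) + G<sub>Leak</sub>(V−E<sub>Leak</sub>)]/C<sub>m</sub>,
  with C<sub>m</sub> = 80 pF, G<sub>Leak</sub> = 3.3 nS, E<sub>Leak</sub> = −55 mV,
  E<sub>Exc</sub> = 0 mV, E<sub>Inh</sub> = −60 mV by default.
- **Paired-recording analysis** (`dsgckit.paired`) — IV curves across
  junction-corrected holding potentials, ordinary-least-squares conductance
  and reversal-potential fits gated at R² > 0.80, convex-hull dendritic
  fields and their intersection area.
- **OKR quantification** (`dsgckit.okr`) — Coope least-squares pupil-circle
  fits from 8 pose markers, corneal-reflection referencing, °/px calibration
  from the 12° inter-camera separation, Gaussian position smoothing,
  30 °/s saccade classification, and gain = signed cumulative slow-pursuit
  displacement / total stimulus displacement.
- **Synthetic data** (`dsgckit.synth`) — generators with known ground truth
  for every stream above (tuned PSCs, Poisson spike trains, linear IV data,
  dual-camera marker streams, dendritic point clouds), so the whole pipeline
  is testable as parameter recovery.

## Worked example

The `demo` subcommand builds two synthetic cohorts — one with intact
ND-biased inhibition and full visual tracking, one with near-symmetric
(degraded) inhibition, reduced excitation, and no horizontal tracking — and
runs every stage on both:

```
$ dsgckit demo --seed 7 --out scratch/demo_report.json
intact: mean IPSC DSI -0.577, mean simulated-Vm DSI 0.423, asymmetric inhibition 449.2 pA, OKR gain H 0.689 / V 0.669
degraded: mean IPSC DSI -0.012, mean simulated-Vm DSI 0.137, asymmetric inhibition 9.1 pA, OKR gain H -0.000 / V 0.678
```

Reading the numbers: the intact cohort's inhibitory DSI is strongly negative
(IPSCs are much larger in the ND than the PD — asymmetric inhibition of
~450 pA), which the conductance model converts into direction-tuned
subthreshold depolarization (simulated-V<sub>m</sub> DSI 0.42) and which
supports horizontal and vertical OKR gains near 0.7. The degraded cohort's
inhibition is symmetric (DSI ≈ 0, asymmetry ≈ 9 pA), its simulated tuning
collapses, and its horizontal gain drops to ~0 while vertical tracking is
retained.

Stage-by-stage use (each subcommand also takes `--config` with a JSON/YAML
`RunConfig`):

```bash
dsgckit simulate --seed 1 --out run/            # synthetic dataset + ground truth
dsgckit traces --inp run/cell01_ipsc.csv --metric IPSC --out run/
dsgckit tuning --inp run/peaks.csv --out run/
dsgckit okr --cam-a run/eye_camA.csv --cam-b run/eye_camB.csv \
            --stim run/eye_ground_truth.json --out run/
```

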