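# Methods

## The simulated apparatus

The generator is a kinematic digital twin of a two-axis stepper gimbal
holding a rigid artificial eye in front of a monitor, tracked by a
video eye tracker at 1000 Hz.

**Geometry.** The eye sits on the screen-centre normal at 927 mm from a
531.36 × 298.89 mm, 1920 × 1080 display (square pixels, 0.27675 mm/px;
the horizontal pitch is applied to both axes). Screen coordinates are
0-based pixels, origin top-left, x rightward, y downward. Visual angles
are computed per axis as `atan(offset_mm / distance_mm)` of the linear
offset from the screen centre — the same conversion chain used for the
reported tables, deliberately chosen over great-circle angles so that
pixel↔degree arithmetic matches the metrology convention of desktop
tracker reports (1° ≈ 58.6 px at centre).

**Motors.** Each axis is a 1.8° stepper in 16× microstepping mode:
0.1125°/microstep. The drive ramps the pulse rate at 80,000 pps²
(9000°/s²) to at most 3200 pps (360°/s), giving a trapezoidal velocity
profile that degenerates to a triangle for moves shorter than
v²/a = 14.4°, with peak speed √(a·d). The continuous-time profile is
sampled on the 1 kHz tracker clock rather than emitting discrete pulse
events, because every downstream consumer sees only 1 kHz samples.
Commanded positions are quantized to the microstep lattice; an integer
positioning error uniform in ±2 microsteps (±0.225°, the estimated bound
for the drive train including the hinge potentiometers) is added per
commanded target. Both axes start simultaneously for oblique targets and
superpose without mutual influence (the orthogonal-hinge assumption);
the shorter axis holds its terminal value while the longer finishes.

In repeated trials of a *fixed pattern* the positioning error is seeded
once per pattern, not per trial: a stepper drive repositions repeatably,
so the error manifests as a systematic per-coordinate bias (visible in
the accuracy table, of the same order as the printed deviations of a
real rig) rather than trial-to-trial jitter. Trial-to-trial dispersion —
precision — is therefore governed by tracker noise alone, which is what
puts it in the 0.005–0.04° decade that real systems report. Modelling
the error as per-trial noise instead would inflate precision to ≈ 0.16°
(the SD of a ±2-microstep uniform draw), contradicting that observation.

**Tracker model.** Gaze angles are projected to screen pixels and i.i.d.
Gaussian position noise of SD 0.02° per axis (default; ≈ 1.2 px) is
added — chosen to land the simulated precision inside the reported
0.3–2.6 px range. The apparent pupil area is `A₀ · cos γ`, where γ is
the angle between the gaze direction and the eye→camera direction: the
rigid circular pupil images as an ellipse whose area shrinks with the
cosine of the viewing obliquity (Lambert foreshortening). A₀ defaults to
2888.94 tracker units, declared equivalent to the 5 mm artificial pupil;
this single declaration fixes the a.u.↔mm scale used when percent
deviations are converted to millimetres. Additive pupil noise defaults
to 10 a.u. (≈ 0.35%).

**Camera position.** Only qualitative placement is available for the
reference setup ("slightly left and down" of the eye, 530 mm away). The
cosine model orders left gaze above centre gaze only if the camera's
azimuth exceeds half the eccentricity of the leftmost grid target
(14.16°/2 ≈ 7.1°); a 30 mm offset (3.2°) cannot, so the default is
(−100, +120, 530) mm — azimuth 10.7° left, elevation 12.8° down — the
minimal "left and down" placement that reproduces the observed ordering
(largest pupil for leftward and downward gaze) on the 13-point grid.

**Experiment designs.** The calibration grid is the standard 13-point
pattern (centre, axis extremes, corners, inner diamond). Random-saccade
plans draw directions uniformly on the circle and amplitudes uniformly
in 4.5–14.1° (the linear regime of the main sequence), with targets
confined to the screen shrunk by 10% per side; fixations last 300 ms.
The brightness experiment replays each participant's plan identically
under all three conditions — motion, plans and positioning errors are
condition-independent, so brightness is a pure label (the null model).
Measurement noise is drawn fresh per recording (as it would be for a
physically re-run condition); a `shared_noise` switch makes the three
streams of a participant bit-identical instead. Recordings after the
first participant begin with a flagged transition move from the previous
participant's final position, giving the exclusion filter its intended
prey.

## Analysis chain

**Velocity** is the first derivative of position (converted to degrees
first) from a 3rd-order Savitzky–Golay filter with a seven-sample
window, which is exact for polynomial trajectories up to cubic.

**Noise estimate.** Per axis, starting from a 100°/s threshold: σ is the
SD of sub-threshold |velocity| samples and the threshold is updated to
mean + 6σ of those samples until it moves by < 1°/s (an all-zero signal
is floored at σ = 10⁻⁶ °/s). The iteration constants come from the
cited adaptive-threshold literature rather than being uniquely fixed by
the reference report; they are exposed as arguments. The detector
thresholds the *combined* speed against η = 3·max(σx, σy) — the report
gives per-axis σ but no combination rule, and the conservative maximum
keeps the per-axis false-positive guarantee.

**Saccades** are maximal runs of ≥ 6 consecutive supra-threshold
samples; onset/offset are the first/last sample of the run (no
sub-threshold refinement). Amplitude is the Euclidean norm of the
per-axis angular displacement between onset and offset; peak velocity
the maximum combined speed inside the event. Fixation windows are the
between-event stretches, trimmed by a 20 ms guard on each side so
transients do not bias fixation means.

**Exclusions** drop transition saccades, fragment-flagged events (offset
at the stream edge or < 20 ms from a neighbour — the stand-in for
saccades split by momentary tracking loss), and amplitudes outside
4.0–14.6° (the planned range widened by the tracker's acknowledged 0.5°
tolerance). On clean simulated data ≥ 99% of planned saccades survive;
the few drops are amplitude outliers produced by the positioning error.

**Precision** is reported (default) as the SD of all raw fixation
samples of a coordinate around their grand mean, pooled over trials —
reconstructable from per-window summaries via
`SS = Σ[(nᵢ−1)sdᵢ² + nᵢ(meanᵢ − grand)²]`; the SD of per-trial means is
available as an alternative (`method="trial_means"`).

**Main sequence / v10.** OLS of peak velocity on raw amplitude (the
amplitude filter guarantees the linear regime; no log–log transform).
Both per-participant fits (feeding the rm ANOVA) and grand pooled fits
per condition are emitted, since either pooling convention is defensible.
Participants with < 3 retained saccades in any condition are excluded.

**rm ANOVA.** One-way within-subject decomposition from sums of squares:
F = MS_level/MS_(subject×level), partial η² = SS_level/(SS_level+SS_error),
Mauchly's W with the chi-square approximation, Greenhouse–Geisser ε from
the orthonormal-contrast covariance and the Huynh–Feldt correction capped
at 1 (falling back to 1 when n is too small for the HF formula). The
implementation is deliberately self-contained and is cross-checked in the
tests against a brute-force two-way decomposition and against pingouin.
The brightness–pupil ANOVA uses per-fixation rows (participant ×
fixation), the v10 ANOVA per-participant rows, mirroring the two
granularities a real report mixes.

**Pupil-direction analysis** uses the outer-medial and centre grid
coordinates: left/middle/right (horizontal factor) and up/middle/down
(vertical factor). Trials are split evenly and at random (seeded)
between the two ANOVAs so the shared centre point never enters both.
Per-direction means are expressed as percent deviation from each
ANOVA's grand mean; a range in millimetres follows from the 5 mm pupil
declaration.

## Numerical and design choices

- **Laser projection.** The rig-planning convention computes the
  reflected-spot displacement as 2·D·tan θ (doubling applied to the
  tangent displacement), which reproduces the printed planning figure of
  33.6 cm for 13.5°; exact specular reflection would give D·tan 2θ
  (35.7 cm). Both are implemented; `doubled_tangent` is the default and
  the discrepancy is deliberately left visible rather than resolved.
- Sub-half-microstep moves are empty; profile end samples are pinned to
  the quantized command so displacement integrals close exactly.
- Degenerate inputs: zero-variance contrast covariance ⇒ sphericity
  trivially satisfied (W = 1, ε = 1); zero-length saccade displacement ⇒
  amplitude 0 with direction flagged undefined; missing grid coordinates
  abort the pupil-direction analysis.
- Backlash is modelled as an optional per-axis dead band, default 0: the
  reference mechanics acknowledge hinge backlash but give no magnitude.

## Problem sizes

The canonical scaled experiment is 20 participants × 50 saccades × 3
conditions (one replicate ≈ 1.1 M samples, ≈ 2 s of compute); the
null-calibration check runs 100 replicate seeds. Accuracy/precision and
pupil-direction analyses use 100 trials of the 13-point grid. The
generator accepts the full-scale design (200 × 200 × 3) through the same
interface.

## What the synthetic data does and does not show

The generator reproduces the *structure* of a robotic-eye evaluation:
exact trapezoidal kinematics, lattice quantization, a brightness factor
that cannot influence motion, and a purely geometric pupil bias. It does
not model drive-train resonance or missed steps, hinge backlash
magnitudes, camera image formation, corneal-reflection processing,
tracking loss near screen corners, or post-saccadic oscillation of a
deformable pupil. Consequently passing tests validate the analysis
chain's correctness and calibration on a system whose ground truth is
known — they do not certify any particular hardware's absolute numbers.
In particular the absolute fitted v10 (≈ 313°/s here, determined by the
triangular profile and SG smoothing) is a property of the modelled
drive, not a prediction of any physical rig's ≈ 358°/s, which depends on
unmodelled drive behaviour; only the null/ordering structure and the
conversion arithmetic transfer.
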