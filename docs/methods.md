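# Methods

## The scientific question and the quantities computed

In a visuomotor rotation experiment, cursor feedback is rotated 45°
clockwise relative to the unseen hand. Participants counter the rotation
through two channels: an *explicit* re-aiming strategy, reported each trial
as a numbered landmark on a ring (landmarks spaced 5.625°, landmark angle =
landmark × −5.625°, CCW positive), and *implicit* recalibration, estimated
as

    calculated implicit = reach angle − reported aim angle.

Implicit learning can also be measured directly: on a *catch trial* the
feedback and landmarks are removed, the participant is told to aim straight
at a probe target at direction θ, and the residual deviation of the reach
(reach − θ) reads out the implicit field at θ. The package's central
statistic relates the two measurements. For catch trial *i*,

    φ_i = catch-trial magnitude_i / mean(calculated implicit)_{i−4:i−1},

the denominator being the mean calculated implicit over the four rotation
trials immediately preceding the probe. φ = 1 means the directly measured
implicit learning at the probe equals the inferred implicit learning at the
aim — complete generalization; φ < 1 means learning did not carry to the
probe direction. Seven probes (after rotation trials 40, 80, …, 280) ×
70 subjects give 490 φ values per cohort. φ values outside (−2.3, 2.3) are
discarded as outliers (strict inequalities: boundary values are kept), and
a φ value whose denominator is within ε = 0.5° of zero is undefined and
excluded with a logged reason — early-learning bins can be near zero and
the ratio is then meaningless. The ε guard is a package choice; the
outlier bounds are part of the analysis definition.

The seven groups differ only in where the catch and aftereffect probes are
placed relative to the trained target (CCW positive): target (0°/0°),
aim (30°/30°), extreme CCW (60°/60°), extreme CW (−90°/−90°), cursor
(−30°/−30°), hand (45°/45°), and aim/target (catch 30°, aftereffect 0°).
Because the aim and aim/target groups are identical until the aftereffect
block, their φ values are pooled, so the 30° location has 20 subjects and
every other location 10 — hence the (5, 64) degrees of freedom of the
φ-by-location ANOVA and the df = 19 one-sample t at 30°.

## The synthetic cohort generator

No trial-level data are distributed with this package, so a generative
learner produces cohorts with the statistical structure the analysis
assumes. It is an artifact of this package — a device for exercising and
validating the pipeline, not a model fitted to any participant.

Each simulated subject carries an implicit field described by a scalar
amplitude *a* and a Gaussian tuning kernel

    K(d) = exp(−d² / 2w²),   K(0) = 1,

centered on `kernel_center`. The implicit contribution to a reach at
direction θ is a·K(θ − center). On every feedback trial:

* the amplitude follows a single-rate state-space update
  `a ← A·a − B·SPE`, where the sensory prediction error
  SPE = cursor − aim is negative under the CW rotation (so learning accrues
  CCW) and positive during washout (so learning unwinds);
* the kernel center relaxes toward the current aim direction,
  `center ← center + λ(aim − center)` — this operationalizes aim-centered
  generalization, which is the structure the analysis is designed to
  detect;
* with probability `p_reaim` the explicit aim moves by the whole number of
  landmarks nearest to the current target error, capped at 2 landmarks per
  trial. The policy needs no free asymptote: aiming settles wherever the
  cursor lands inside the half-landmark deadband, i.e. near
  45° − a·K ≈ 27° at plateau, while the reach plateaus near 45°.

Catch, aftereffect, and washout trials force the aim to the displayed
target (as instructed in the task); catch and aftereffect trials give no
feedback and therefore leave the learner state untouched.

### Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| A (`retention_a`) | 0.98 | per-trial retention of the implicit amplitude |
| B (`learning_rate_b`) | 0.0133 ± 0.003 (per subject, truncated ≥ 0.004) | error sensitivity; the noiseless fixed point of the amplitude recursion is a\* = 45·B/(1−A+B), and B = 0.0133 puts a\* ≈ 18° so reach ≈ 45° splits into aim ≈ 27° + implicit ≈ 18°, the split the analysis operates on; learning time constant ≈ 30 trials |
| w (`kernel_width`) | 35° ± 5° (truncated ≥ 15°) | Gaussian tuning width; a smooth unimodal generalization profile |
| λ (`center_rate`) | 0.1 | kernel-center tracking of the aim |
| motor noise SD | 3° | per-trial reach execution noise |
| `p_reaim` | 0.2 | per-trial probability of an explicit aim adjustment |
| report noise | none | the reported landmark is the aimed landmark |
| subjects | 10 per group × 7 groups | the cohort size of the experimental design |

A master seed expands into per-subject substreams by a SHA-256 hash of
(seed, group, subject index), so adding or removing a group never perturbs
the other groups' draws, and a fixed seed reproduces the cohort
bit-identically.

### What the generator emulates, and what it does not

It reproduces: the block structure (48 baseline / 8 baseline+report / 320
rotation with 7 inserted probes / 40 aftereffect / 40 washout), the
reach ≈ 45°, aim ≈ 25–30°, implicit ≈ 15–20° plateau split, aim-centered
generalization probed at the seven group locations, and aim reports that
wander over several landmarks early in learning (which is what makes
within-subject generalization curves estimable at all).

It does not reproduce: use-dependent plasticity, so the simulated
generalization profile is symmetric around the aim while human catch
magnitudes are biased toward the repeated 45° movement; as a result the
simulated group-mean φ at the hand (45°), cursor (−30°) and extreme (−90°)
probes differs in level from the human values even though the *ordering*
(maximal at 30°, lower everywhere else) is preserved. It also models no
within-reach kinematics, no trial timing, and no report errors. Passing
tests therefore certify the pipeline's correctness and the recoverability
of aim-centered structure, not the numerical φ levels of human subjects.

## Analysis conventions and numerical choices

* **Angles** are degrees, CCW positive, 0° at the trained target, stored in
  (−180, 180] and normalized on ingest. The CW rotation is −45°.
* **Trajectory reach angle** is the direction at the first crossing of the
  70 mm target radius, with the angle interpolated linearly in radius
  between the bracketing samples.
* **Binning** uses non-overlapping 4-trial bins; a trailing partial bin is
  averaged over its available trials (320 is divisible by 4, so the
  standard block is unaffected). Missing values are excluded from bin
  means rather than treated as zeros.
* **Plateau** is the mean over the final 100 rotation trials.
* **φ bins are anchored at the probe**: each probe uses the four rotation
  trials immediately before it, never straddling another probe, and not
  necessarily aligned with the display bins.
* **Modal aim** ties are broken toward the landmark whose angle is closest
  to the subject's mean aim angle, then toward the more CCW landmark.
* **Curve pooling** keeps offsets where more than 10 of the subjects
  contribute (≥ 11) and restricts to 40° CCW to 35° CW of the modal aim
  (offsets in [−35°, +40°]).
* **Cosine fit**: y = A·cos(2π(θ−c)/T) + d. A and d are linear given
  (c, T) and are solved in closed form (separable least squares); (c, T)
  are found by a coarse grid over landmark-spaced centers and candidate
  periods followed by Nelder–Mead polishing of the best starts. T is
  either fixed by the caller (e.g. 360°) or fitted within [90°, 720°];
  within the narrow analysis window the period is weakly identified and
  may sit at a bound — the center c is the scientific readout, and the
  fitted amplitude is sign-normalized (A ≥ 0, phase shifted by T/2).
  Noiseless model-generated curves are recovered to ≤ 1e−6.
* **Folded correlation**: offsets are collapsed to |offset|, means sharing
  an |offset| are averaged weighted by subject counts (the unweighted
  variant differs only when counts differ across the fold), and Pearson r
  with a two-sided t-transform p is reported along with the least-squares
  line.
* **Angle-distribution fits** histogram pooled rotation-block cursor, aim,
  and hand angles into landmark-aligned 5.625° bins and fit a
  three-parameter Gaussian to bin heights by least squares; peak
  normalization is display-only and never affects fitted parameters.
* **Statistics**: all tests are two-sided at α = 0.05. Fisher's LSD uses
  the pooled one-way MSE with N−k df and, by definition, unadjusted p
  values (a Welch fallback per pair is available for unequal variances).
  The mixed-design repeated-measures ANOVA has one within factor with two
  levels (plateau catch = mean of the last two catch trials; early
  aftereffect = mean of the first four aftereffect trials), so sphericity
  is not at issue; subjects missing a level are dropped with a warning.
  t and F machinery is delegated to scipy/pingouin; the test suite checks
  every statistic against independent brute-force sums-of-squares oracles.

## Validation problem sizes

The test suite validates statistics on hundreds of random instances with
n ≤ 12 per cell, runs one frozen-field noiseless cohort for exact kernel
oracles (learning disabled, preset 18° amplitude, deterministic aiming —
the configuration in which φ at a probe equals K(θ − center) to machine
precision), and 20 default-config cohorts of 70 subjects for parameter
recovery (fitted cosine center within one landmark of the true center,
folded correlation negative) and for the qualitative φ ordering across
probe locations. The acceptance script analyzes one 70-subject cohort.

## Known limitations

* The learner is a convenience generator: single-rate, no forgetting
  between blocks, no use-dependent plasticity, symmetric kernel. Group φ
  levels at probes far from the aim are not calibrated to human data.
* The washout block unwinds learning through the signed-error update but
  is not otherwise analyzed.
* The mixed-ANOVA oracle identity used in tests assumes balanced groups;
  the implementation (pingouin) handles the unbalanced case.
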