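# Methods

## Patient–ventilator model

The simulator integrates the single-compartment equation of motion of the
respiratory system on a fixed 200-Hz grid:

```
Paw(t) + Pmus(t) = Rrs·V'(t) + Ers·V(t) + PEEP + PEEPi
```

with volume referenced to the end-expiratory lung volume and clamped at
V ≥ 0: expiratory flow stops at V = 0 while the intrinsic-PEEP recoil
offset stays trapped, which is the minimal mechanism needed to exercise the
dynamic PEEPi measurement (effort spent before flow starts). Dynamic
hyperinflation proper — volume-dependent PEEPi — is out of scope.
Esophageal pressure follows the chest wall, `Pes = Pes_ee + Ecw·V − Pmus`.

The ventilator pressurizes the circuit to PEEP + PS with a first-order rise
(default time constant 0.08 s) once patient flow exceeds the trigger
threshold (default 0.05 L/s), and cycles off when inspiratory flow decays
to a set fraction of its peak (default 0.25). Expiratory-valve opening uses
a fast 0.06-s constant. A timed backup trigger delivers machine breaths
when the muscle-pressure amplitude is exactly zero (passive simulations).

Each effort rises as a half-sine over `rise_time` (default 0.8 s; a linear
ramp is available) and releases exponentially with time constant
`release_time/3` (default release 0.6 s), repeating at the set respiratory
rate. Fixed-step explicit integration at the sample rate is used
throughout: the system is non-stiff at physiologic parameters and exact
reproducibility across platforms is worth more than adaptive accuracy.

Occlusions freeze volume and force zero flow. The occluded Paw then reads
the alveolar pressure `PEEP + PEEPi + Ers·V − Pmus`, which is what makes
the three indices measurable at the airway opening. End-expiratory holds
close the valve 0.2 s before a scheduled effort onset; end-inspiratory
holds close it at cycle-off, and the patient pauses during an
end-inspiratory hold (clean-plateau condition; extra efforts during the
hold are supplied by the artifact injector instead). Ground truth recorded
per maneuver: P0.1 as the true Pmus 100 ms after the occluded onset, ΔPocc
as the maximal occluded Pmus, PMI as occluded plateau minus the actual
pre-hold peak Paw.

### Artifact injection

The four discard classes are injected into a clean end-inspiratory hold:
`short_hold` splices out the middle of the hold (default residual 1.2 s,
below the 1.5-s QC minimum); `air_leak` adds a monotone Paw ramp (default
−2 cmH2O/s after a 0.2-s delay) with Pes untouched; `extra_insp_effort` /
`extra_exp_effort` add a simultaneous sin²-shaped dip/bump (default 2
cmH2O over 0.5 s, centred at 65% of the hold) to both Paw and Pes. The
magnitudes are configurable; the defaults are large enough to be clinically
meaningful and small enough not to caricature the class.

## Default titration cohort

The cohort generator emulates a downward PS titration, 20 → 2 cmH2O in
2-cmH2O steps at PEEP 5, 28 patients by default. Per-patient mechanics are
drawn once around published ICU cohort medians: Ers ~ N(16.1, 3²) cmH2O/L
(floor 8), Ecw = clip(N(0.70, 0.06²), 0.5–0.85)·Ers, Rrs ~ N(10, 2²)
cmH2O·s/L (floor 4), PEEPi ∈ {0, 1, 2} with probabilities (0.50, 0.35,
0.15), Pes baseline ~ N(8, 1²) cmH2O, effort rise time ~ N(0.8, 0.12²) s.

Effort follows the support level: `pmus_max = c0 + c1·(20 − PS)` with
c0 ~ N(1.5, 0.5²) and c1 ~ N(0.55, 0.15²) per patient, so effort is
minimal at PS 20 and spreads across both class boundaries at low PS. The
intercept is floored at the trigger load (PEEPi + Rrs·trigger flow + 0.6
cmH2O) — a spontaneously breathing patient must clear that threshold on
every breath. The respiratory rate is drawn at 16–24/min and slowed under
generous support (`rr·(0.65 + 0.35·(20 − PS)/18)`), the drive response
that also gives the large assisted breaths time to empty. Remaining
high-support levels with incomplete emptying produce ineffective efforts
and 2:1 entrainment — deliberately left in, as the over-assistance
asynchrony regime.

Each level holds ~30 s of free breathing followed by three end-expiratory
(1.2 s) and three end-inspiratory (2.5 s) occlusions two breaths apart — a
desk-scale compression of a bedside protocol that would hold each level
for many minutes with occlusions a minute apart. The effort-averaging
window is therefore the available ~30-s pre-occlusion window. Sensor noise
defaults to 0.2 cmH2O (pressures) and 0.01 L/s (flow), with 5%
breath-to-breath effort jitter; unit-level simulations default to zero
noise.

Ground truth per level reports what the offline analysis can measure:
per-effort PTP integrates true Pmus from onset to the end of the
insufflation that effort triggered (ineffective efforts carry no PTP), and
the true respiratory rate is the realized breath rate in the window.

## Measurement pipeline

**Segmentation** bounds insufflation by positive- and negative-going
zero-crossings of flow smoothed with a 50-ms centred moving average, each
crossing snapped to the nearest raw-flow crossing (±30 ms) because the
moving average leads the true crossing when flow hovers near zero.
Insufflations shorter than 150 ms or peaking below 0.1 L/s are rejected as
noise. Tidal volume is the flow integral over the insufflation.

**Effort onset** is found on the smoothed Pes derivative: the latest
sustained run below −2 cmH2O/s (40-ms persistence) before the insufflation.
Within a window from 0.5 s before the run start up to the insufflation,
the onset is the last sample within 1 cmH2O/s of the derivative's local
peak — the slope break where the flattening expiratory decay turns into
the effort plunge. This handles both a flat pre-effort baseline and an
effort that merges with a still-active expiratory decay; the onset is
additionally clamped to at most 1 s before the insufflation. Breaths with
less than 300 ms of pre-insufflation signal raise a window error.

**Occlusion detection** looks for sustained near-zero-flow windows
(|flow| < 0.02 L/s for ≥ 200 ms). A window is end-inspiratory when the flow
just before it is still inspiratory and the volume accumulated since the
last insufflation start reaches half the preceding tidal volume; otherwise
it is reported as end-expiratory only when Paw falls ≥ 0.5 cmH2O below its
within-window running maximum — the signature of an occluded effort.
Quiet late-expiratory flow also sits under the zero-flow threshold and must
not be reported; the flip side is that an end-expiratory hold against a
near-zero effort is genuinely undetectable from the airway signal.

**Effort metrics.** `Pes_ee` is the mean Pes over the 100 ms before the
effort onset; the chest-wall recoil line is re-anchored per breath with
volume integrated from the insufflation start, removing flow-sensor drift.
Pmus is recoil − Pes (smoothed, 50 ms), its peak taken over onset →
insufflation end, PTP by trapezoidal integration over the same span.
Chest-wall elastance comes from the occluded Pes plateau at the patient's
highest support level, `(Pes plateau − Pes_ee)/VT`; respiratory-system
elastance from the Paw plateau, `(Paw plateau − PEEP − PEEPi)/VT`; dynamic
PEEPi as |Pes(onset) − Pes(insufflation start)|. The level summary averages
eligible breaths (Pes excursion within ±40 cmH2O, VT > 10 mL) in the
minute before the first occlusion and takes the rate from mean inter-breath
intervals.

**Occlusion indices.** The occluded effort onset is located where smoothed
Paw falls 0.5 cmH2O below its within-window running maximum, backtracked to
within 0.15 cmH2O of that plateau; referencing the running maximum (rather
than the pre-hold circuit pressure) makes the measurement read the occluded
muscle swing itself even when trapped recoil elevates the plateau. P0.1 is
read on the raw trace (3-sample means) because the moving average biases
the onset kink low. ΔPocc is the fall from the pre-effort occluded plateau
(median of the 150 ms before onset) to the occluded minimum. PMI is the
mean Paw in a 50-ms window centred 1.0 s after the hold start minus the
mean over the 50 ms before the refined zero-flow onset, sign preserved.
QC checks run in order: plateau < 1.5 s → short; simultaneous Paw+Pes
excursion beyond ±1 cmH2O (relative to post-relaxation reference levels at
0.5–0.8 s) → extra inspiratory/expiratory effort; Paw slope over the second
half below −1 cmH2O/s with Pes within ±0.5 cmH2O → air leak; else accepted.
Per level, the mean of accepted maneuvers is used even when fewer than
three were accepted; a level with none is reported missing.

## Diagnostics

AUC uses the Mann–Whitney construction with midranks (ties count half);
its standard error and the paired two-index test use DeLong structural
components; CIs are normal-approximation, clipped to [0, 1]. Youden
cutoffs scan midpoints between adjacent distinct scores plus open ends —
these realize every achievable confusion matrix under the ≥ rule — with
ties broken toward the more specific cutoff. Proportion CIs are exact
Clopper–Pearson. Cross-validation is stratified tenfold (seeded), cutoff
fitted per training fold, test predictions pooled; folds losing a class
are flagged and excluded. Reference intervals are nonparametric 10th/90th
percentiles (linear interpolation) with seeded-bootstrap CIs (2000
resamples); the grey zone is literally the fraction of observations
outside [lower, upper] — by construction ≈ 0.2 of the sample the limits
were fitted on, so the evaluation fits limits on the acceptable-effort
(intermediate) band and reads the grey-zone share over all classified
levels. The association summary replaces a mixed-effects likelihood with a
deterministic decomposition: between-patient R² on patient means,
within-patient R² on observations after subtracting patient means from
both variables. Exact REML equivalence is a non-goal.

Classification maps boundary values (exactly 5, 10, 50, 200) to
intermediate, matching the strict inequalities that define low and high.
Cross-validation treats the PS level as the observation unit; repeated
measures within patients violate independence, which is why the
between/within decomposition is reported alongside.

## What the simulator does and does not establish

Passing tests show the pipeline recovers known ground truth under the
model's assumptions: linear single-compartment mechanics, a stereotyped
effort shape, additive Gaussian sensor noise, and clean maneuver execution
apart from the injected artifact classes. Real recordings add cardiac
artifacts on Pes, esophageal spasm, swallow events, nonlinear resistance,
leak dynamics, and far messier asynchrony; performance there is not
established by these tests. Reference intervals and AUCs computed on the
simulated cohort characterize the method under the stated study
conditions, not any patient population.

## Numerical choices and known limitations

- Sizes are desk-scale by design: ~80-s level recordings, 28 × 10 levels
  by default; the full cohort simulates and analyzes in well under a
  minute on one CPU.
- Measured dynamic PEEPi includes genuinely trapped recoil from incomplete
  exhalation on top of the static PEEPi parameter, and onset-detection lag
  biases it slightly low at higher noise; the cohort-median absolute error
  is < 0.1 cmH2O at zero noise.
- P0.1 is insensitive below ~0.5 cmH2O of occluded drop (the onset
  threshold); such maneuvers read 0. This mirrors the bedside situation —
  a hold against minimal drive shows no measurable deflection.
- Under heavy entrainment (very compliant patients at high support),
  trapped recoil can mask the occluded effort and ΔPocc/P0.1 read low;
  these levels are low-effort levels, so the bias is concordant with the
  classification task but the index-versus-truth error there is large.
- The high-effort class by the PTPmus/min criterion is rare under the
  default effort shape (effective inspiratory time ≈ 0.65 s caps
  PTP/min ≈ 0.65·Pmus·RR), so high-effort diagnostics by that criterion
  rest on a handful of positives — analogous to the caution required for
  sparse high-effort cohorts in practice.
- The cohort draw floors the effort intercept at the per-patient trigger
  load; a fully apneic patient at high support is therefore not in the
  default cohort (the backup-trigger path covers passive ventilation in
  unit simulations).
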