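# respeffort

Inspiratory-effort measurement from ventilator waveforms during
pressure-support (PS) ventilation: esophageal-pressure reference metrics,
airway-occlusion indices with plateau quality control, diagnostic-accuracy
statistics, and a patient–ventilator simulator that provides ground truth
for all of it.

## The problem

During assisted ventilation, both under-assistance (vigorous effort, risk of
self-inflicted lung injury) and over-assistance (low effort, diaphragm
disuse) are harmful, but effort is invisible on routine monitoring. The
reference standard is esophageal manometry: from the esophageal pressure
(Pes), the inspiratory muscle pressure is

```
Pmus(t) = [Pes_ee + Ecw · V(t)] − Pes(t)
```

the gap between the quasi-static chest-wall recoil line and measured Pes,
and the per-minute pressure–time product is

```
PTPmus/min = mean over breaths of ∫ Pmus dt  (effort onset → end of insufflation) × RR .
```

Low, intermediate and high effort are defined as Pmus < 5 / 5–10 / > 10
cmH2O, or PTPmus/min < 50 / 50–200 / > 200 cmH2O·s/min.

Pes is invasive, so three indices readable from airway pressure (Paw) alone
via simple occlusion maneuvers stand in for it:

- **P0.1** — Paw drop over the first 100 ms of an occluded inspiratory
  effort (end-expiratory hold); a respiratory-drive index.
- **ΔPocc** — maximal Paw swing during the whole occluded effort; tracks
  peak Pmus through the zero-flow identity Paw + Pmus = const.
- **PMI** — plateau-minus-peak Paw after an end-inspiratory hold
  (= Ers·VT + PEEPi − PS); positive when the patient still contributed
  pressure at end-insufflation, negative under over-assistance. PMI is only
  valid on a clean plateau: holds shorter than 1.5 s, air leaks, and extra
  inspiratory/expiratory efforts during the hold are discarded by a QC
  screen, and triplicate maneuvers are averaged.

The package measures all of the above from raw flow/Paw/Pes channels,
classifies effort, and quantifies each index's diagnostic accuracy (ROC
AUC with DeLong confidence intervals and paired tests, Youden cutoffs,
sensitivity/specificity/PPV/NPV with exact CIs, stratified tenfold
cross-validation, nonparametric 10th/90th-percentile reference intervals
with bootstrap CIs, between/within-patient R²). Because bedside recordings
of this kind are not publicly deposited, a single-compartment
patient–ventilator simulator generates PS breathing with known effort,
occlusion maneuvers, and injectable plateau artifacts, so every stage is
testable against ground truth. It is aimed at respiratory-physiology and
ventilation researchers working in Python.

## Worked example

`examples/03_occlusion_indices.py` simulates one occlusion of each kind
for a patient with Ers 18, Ecw 12 cmH2O/L, Rrs 9 cmH2O·s/L, effort
amplitude 8 cmH2O at PS 8 / PEEP 5 cmH2O, measures the indices from Paw
alone, and exercises the QC screen:

```
end-expiratory occlusion:
  P0.1  = 1.56 cmH2O (truth 1.56)   -- drive: Paw drop over the first 100 ms of the occluded effort
  dPocc = 7.99 cmH2O (truth 8.00)   -- maximal occluded swing, tracks peak Pmus
end-inspiratory occlusion:
  QC accepted; PMI = 3.38 cmH2O (truth 3.41)  -- plateau minus peak Paw; ...
artifact injection -> QC label:
  short_hold         -> short_plateau
  air_leak           -> air_leak
  extra_insp_effort  -> extra_insp_effort
  extra_exp_effort   -> extra_exp_effort
```

ΔPocc reads the peak muscle pressure (8 cmH2O) almost exactly; P0.1 reads
the effort 100 ms in; PMI reads the end-inspiratory muscle pressure
remaining above the support level. The other examples cover free-breathing
simulation and file I/O (`01`), Pes-derived effort metrics (`02`), and the
full titration-cohort evaluation (`04`), which prints a diagnostics table
such as

```
task criterion index  auc  cutoff  sensitivity  specificity  ppv  npv
 low      pmus dpocc 1.00    5.07         0.97         1.00 1.00 0.98
 low      pmus   p01 0.94    0.96         0.94         0.84 0.78 0.95
 ...
```

one row per airway-pressure index detecting low effort against one
Pes-derived criterion, at the Youden cutoff shown.

There is also a thin CLI for on-disk pipelines:

```
respeffort all --seed 1 --outdir out/            # simulate -> analyze -> evaluate
respeffort simulate --config cohort.yaml ...
```

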