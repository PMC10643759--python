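"""Airway-occlusion indices with quality control.

Runs one end-expiratory and one end-inspiratory occlusion maneuver,
measures P0.1, dPocc and PMI from the airway pressure alone, and then
corrupts the end-inspiratory plateau with each artifact class to show the
QC screen catching it.
"""

from respeffort import (EffortProfile, PatientParams, VentSettings,
                        compute_dpocc, compute_p01, compute_pmi,
                        detect_occlusions, inject_artifact,
                        qc_end_insp_occlusion, simulate_occlusion)

patient = PatientParams(ers=18.0, ecw=12.0, rrs=9.0, peepi=0.0, pes_ee=8.0)
vent = VentSettings(ps=8.0, peep=5.0)
effort = EffortProfile(pmus_max=8.0, respiratory_rate=16.0)

rec, truth = simulate_occlusion(patient, vent, effort, "end_expiratory",
                                1.2, duration=25.0, seed=3)
occ = [o for o in detect_occlusions(rec) if o.kind == "end_expiratory"][0]
t = truth.occlusions[0]
print("end-expiratory occlusion:")
print(f"  P0.1  = {compute_p01(rec, occ):.2f} cmH2O (truth {t.p01:.2f})"
      "   -- drive: Paw drop over the first 100 ms of the occluded effort")
print(f"  dPocc = {compute_dpocc(rec, occ):.2f} cmH2O (truth {t.dpocc:.2f})"
      "   -- maximal occluded swing, tracks peak Pmus")

rec2, truth2 = simulate_occlusion(patient, vent, effort, "end_inspiratory",
                                  2.5, duration=25.0, seed=3)
occ2 = [o for o in detect_occlusions(rec2) if o.kind == "end_inspiratory"][0]
status = qc_end_insp_occlusion(rec2, occ2)
pmi = compute_pmi(rec2, occ2, qc_status=status)
print("end-inspiratory occlusion:")
print(f"  QC {status}; PMI = {pmi:.2f} cmH2O "
      f"(truth {truth2.occlusions[0].pmi:.2f})"
      "  -- plateau minus peak Paw; positive when the patient was")
print("     still pushing at end-insufflation, negative under over-assistance")

print("artifact injection -> QC label:")
for kind in ("short_hold", "air_leak", "extra_insp_effort", "extra_exp_effort"):
    bad, _ = inject_artifact(rec2, kind, truth=truth2)
    det = [o for o in detect_occlusions(bad) if o.kind == "end_inspiratory"][0]
    print(f"  {kind:<18} -> {qc_end_insp_occlusion(bad, det)}")
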