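"""Measure esophageal-pressure effort metrics and compare with truth.

Segments simulated breaths by flow zero-crossings, finds the effort onset
on the Pes derivative, reconstructs the muscle-pressure trace against the
chest-wall recoil line, and averages Pmus and the pressure-time product
over the level — then shows how close each estimate is to the simulator's
ground truth.
"""

from respeffort import (EffortProfile, PatientParams, VentSettings,
                        detect_occlusions, segment_breaths, simulate_breaths,
                        summarize_level)

patient = PatientParams(ers=20.0, ecw=13.0, rrs=10.0, peepi=1.0, pes_ee=8.0)
vent = VentSettings(ps=8.0, peep=5.0)
effort = EffortProfile(pmus_max=9.0, respiratory_rate=16.0)

rec, truth = simulate_breaths(patient, vent, effort, duration=60.0, seed=2,
                              noise_pressure=0.2, noise_flow=0.01)

occl = detect_occlusions(rec)
breaths = segment_breaths(rec, occlusions=occl)
measures = summarize_level(rec, breaths, ecw=patient.ecw, occlusions=occl)
true = truth.level_summary()

print(f"breaths averaged: {measures.n_breaths_averaged}")
print(f"{'quantity':<18}{'measured':>10}{'truth':>10}")
print(f"{'Pmus_max (cmH2O)':<18}{measures.pmus_max:>10.2f}{true['pmus_max']:>10.2f}")
print(f"{'PTP/breath':<18}{measures.ptp_breath:>10.2f}{true['ptp_breath']:>10.2f}")
print(f"{'PTP/min':<18}{measures.ptp_min:>10.1f}{true['ptp_min']:>10.1f}")
print(f"{'RR (/min)':<18}{measures.respiratory_rate:>10.1f}{true['respiratory_rate']:>10.1f}")
print(f"{'PEEPi (cmH2O)':<18}{measures.peepi:>10.2f}{patient.peepi:>10.2f}")
print("Pmus is the gap between the chest-wall recoil line and Pes; its")
print("time-integral per breath times respiratory rate is the per-minute")
print("pressure-time product used as the effort reference standard.")
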