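"""Physiologic invariants of the patient-ventilator simulator."""

import numpy as np
import pytest

from respeffort import (EffortProfile, PatientParams, VentSettings,
                        inject_artifact, simulate_breaths, simulate_occlusion,
                        simulate_titration, CohortSpec)
from respeffort.errors import ParameterError


def test_passive_quasi_static_tidal_volume():
    # with no muscle activity and near-complete resistive decay,
    # VT approaches PS / Ers = 10/25 = 0.40 L
    pat = PatientParams(ers=25, ecw=15, rrs=10)
    vent = VentSettings(ps=10, peep=5, cycle_off_fraction=0.02)
    eff = EffortProfile(pmus_max=0.0, respiratory_rate=12)
    _, gt = simulate_breaths(pat, vent, eff, duration=30, seed=0)
    vt = np.mean(gt.tidal_volumes[1:])
    assert vt == pytest.approx(0.40, abs=0.02)


def test_volume_conserved_over_each_cycle(free_breathing):
    rec, gt = free_breathing
    dt = rec.dt
    starts = [rec.index_at(s) for s, _ in gt.insufflation_bounds]
    for i0, i1 in zip(starts[2:6], starts[3:7]):
        net = np.trapezoid(rec.flow[i0:i1], dx=dt)
        assert abs(net) < 1e-3  # < 1 mL


def test_same_seed_reproduces_recording(std_patient, std_vent, std_effort):
    r1, _ = simulate_breaths(std_patient, std_vent, std_effort, 20,
                             seed=5, noise_pressure=0.3, breath_cv=0.1)
    r2, _ = simulate_breaths(std_patient, std_vent, std_effort, 20,
                             seed=5, noise_pressure=0.3, breath_cv=0.1)
    np.testing.assert_array_equal(r1.paw, r2.paw)
    np.testing.assert_array_equal(r1.flow, r2.flow)


def test_passive_limit_pes_follows_chest_wall(std_vent):
    # pmus == 0  =>  pes - pes_ee == ecw * V at every sample
    pat = PatientParams(ers=20, ecw=12, rrs=8, pes_ee=7.0)
    eff = EffortProfile(pmus_max=0.0, respiratory_rate=14)
    rec, gt = simulate_breaths(pat, std_vent, eff, duration=30, seed=0)
    # the engine integrates volume with forward-Euler steps of the emitted
    # flow, so the identity holds exactly against the running flow sum
    vol = np.cumsum(rec.flow) * rec.dt
    np.testing.assert_allclose(rec.pes - 7.0, 12 * vol, atol=1e-9)


def test_zero_flow_identity_during_occlusion(std_patient, std_vent, std_effort):
    rec, gt = simulate_occlusion(std_patient, std_vent, std_effort,
                                 "end_expiratory", 1.2, duration=25, seed=0)
    occ = gt.occlusions[0]
    i0, i1 = rec.index_at(occ.start) + 1, rec.index_at(occ.end) - 1
    # paw + pmus is constant (= recoil at frozen volume + total PEEP)
    total = rec.paw[i0:i1] + gt.pmus[i0:i1]
    np.testing.assert_allclose(total, total[0], atol=1e-9)


def test_ee_occlusion_truth_values(std_patient, std_vent):
    eff = EffortProfile(pmus_max=8.0, rise_time=0.8, respiratory_rate=18)
    _, gt = simulate_occlusion(std_patient, std_vent, eff,
                               "end_expiratory", 1.2, duration=25, seed=0)
    occ = gt.occlusions[0]
    assert occ.dpocc == pytest.approx(8.0, abs=0.05)
    assert occ.p01 == pytest.approx(8 * np.sin(np.pi * 0.1 / 1.6), abs=0.02)


def test_ee_occlusion_without_effort_reads_zero(std_patient, std_vent):
    eff = EffortProfile(pmus_max=0.0, respiratory_rate=12)
    _, gt = simulate_occlusion(std_patient, std_vent, eff,
                               "end_expiratory", 1.2, duration=30, seed=0)
    occ = gt.occlusions[0]
    assert occ.p01 == pytest.approx(0.0, abs=1e-9)
    assert occ.dpocc == pytest.approx(0.0, abs=1e-9)


def test_ei_occlusion_truth_matches_closed_form(std_patient):
    # plateau - peak = Ers*VT + PEEPi - PS
    vent = VentSettings(ps=8, peep=5)
    eff = EffortProfile(pmus_max=8, respiratory_rate=18)
    rec, gt = simulate_occlusion(std_patient, vent, eff,
                                 "end_inspiratory", 2.5, duration=25, seed=0)
    occ = gt.occlusions[0]
    vt = gt.tidal_volumes[2]
    assert occ.pmi == pytest.approx(25 * vt - 8, abs=0.15)


def test_pmi_truth_equals_pmus_at_zero_flow_transition(std_patient):
    # with a small cycle-off fraction the resistive term vanishes and the
    # plateau-peak difference reads the remaining muscle pressure
    vent = VentSettings(ps=8, peep=5, cycle_off_fraction=0.05)
    eff = EffortProfile(pmus_max=8, respiratory_rate=16)
    rec, gt = simulate_occlusion(std_patient, vent, eff,
                                 "end_inspiratory", 2.5, duration=25, seed=0)
    occ = gt.occlusions[0]
    i0 = rec.index_at(occ.start)
    assert occ.pmi == pytest.approx(gt.pmus[i0 + 1], abs=0.5)


def test_over_assistance_gives_negative_pmi(std_patient):
    vent = VentSettings(ps=16, peep=5)
    eff = EffortProfile(pmus_max=1.5, respiratory_rate=14)
    _, gt = simulate_occlusion(std_patient, vent, eff,
                               "end_inspiratory", 2.5, duration=30, seed=0)
    assert gt.occlusions[0].pmi < 0


@pytest.mark.parametrize("kind", ["air_leak", "extra_insp_effort",
                                  "extra_exp_effort", "short_hold"])
def test_artifact_injection_labels_truth(ei_occlusion, kind):
    rec, gt = ei_occlusion
    rec2, gt2 = inject_artifact(rec, kind, truth=gt)
    occ = [o for o in gt2.occlusions if o.kind == "end_inspiratory"][-1]
    assert occ.artifact == kind
    if kind == "short_hold":
        assert occ.end - occ.start == pytest.approx(1.2, abs=0.02)
    else:
        assert rec2.n_samples == rec.n_samples


def test_unknown_artifact_kind_rejected(ei_occlusion):
    with pytest.raises(ParameterError):
        inject_artifact(ei_occlusion[0], "cosmic_ray")


def test_titration_counts_and_determinism():
    spec = CohortSpec(n_patients=2, ps_levels=(12, 8, 4))
    recs = simulate_titration(spec, seed=3)
    assert len(recs) == 6
    # three occlusions of each kind per level
    for lr in recs:
        kinds = [o.kind for o in lr.truth.occlusions]
        assert kinds.count("end_expiratory") == 3
        assert kinds.count("end_inspiratory") == 3
    recs2 = simulate_titration(spec, seed=3)
    np.testing.assert_array_equal(recs[0].recording.paw, recs2[0].recording.paw)


def test_titration_effort_rises_as_support_falls(small_cohort):
    by_patient = {}
    for lr in small_cohort:
        by_patient.setdefault(lr.patient_id, []).append(
            (lr.ps, lr.truth.level_summary()["ptp_min"]))
    for levels in by_patient.values():
        levels.sort()
        ptps = [p for _, p in levels]
        # PS ascending -> true PTP/min non-increasing
        assert all(a >= b - 1e-9 for a, b in zip(ptps, ptps[1:]))


def test_invalid_parameters_rejected():
    with pytest.raises(ParameterError):
        PatientParams(ers=10, ecw=12)       # ecw > ers
    with pytest.raises(ParameterError):
        PatientParams(rrs=-1)
    with pytest.raises(ParameterError):
        VentSettings(cycle_off_fraction=1.5)
    with pytest.raises(ParameterError):
        EffortProfile(pmus_max=-2)
    with pytest.raises(ParameterError):
        simulate_titration(CohortSpec(n_patients=1, ps_levels=(4, 8)), seed=0)
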