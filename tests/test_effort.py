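"""Pes-derived reference effort metrics."""

import numpy as np
import pytest

from respeffort import (EffortProfile, PatientParams, VentSettings,
                        compute_peepi, compute_pmus_trace, compute_ptp,
                        compute_ptp_min, estimate_ecw, estimate_ers,
                        segment_breaths, simulate_breaths, summarize_level,
                        detect_occlusions)
from respeffort.errors import DataError, OnsetMissing, ParameterError
from respeffort.pipeline import estimate_ecw_from_level
from respeffort.simulator import simulate_occlusion


def test_ecw_arithmetic():
    assert estimate_ecw(12.0, 8.0, 0.5) == pytest.approx(8.0)
    assert estimate_ecw(8.0, 8.0, 0.5) == 0.0
    with pytest.raises(ParameterError):
        estimate_ecw(12.0, 8.0, 0.0)


def test_ers_arithmetic():
    assert estimate_ers(17.0, 5.0, 0.5) == pytest.approx(24.0)


def test_ecw_recovered_from_high_support_occlusion():
    # minimal effort at high support: the occluded Pes plateau reads
    # chest-wall recoil
    pat = PatientParams(ers=16, ecw=11, rrs=10, pes_ee=8)
    vent = VentSettings(ps=20, peep=5)
    eff = EffortProfile(pmus_max=1.5, respiratory_rate=14)
    rec, _ = simulate_occlusion(pat, vent, eff, "end_inspiratory", 2.5,
                                duration=30, seed=0)
    ecw = estimate_ecw_from_level(rec)
    assert ecw == pytest.approx(11.0, abs=0.5)


@pytest.mark.parametrize("peepi,tol", [(0.0, 0.3), (3.0, 0.5)])
def test_peepi_recovery(peepi, tol):
    pat = PatientParams(ers=20, ecw=13, rrs=10, peepi=peepi, pes_ee=8)
    vent = VentSettings(ps=8, peep=5)
    eff = EffortProfile(pmus_max=8, respiratory_rate=15)
    rec, _ = simulate_breaths(pat, vent, eff, duration=40, seed=0)
    breaths = segment_breaths(rec)
    vals = [compute_peepi(rec, b) for b in breaths[1:-1]
            if b.effort_onset is not None]
    assert np.median(vals) == pytest.approx(peepi, abs=tol)


def test_peepi_requires_onset(free_breathing):
    rec, _ = free_breathing
    b = segment_breaths(rec)[2]
    b.effort_onset = None
    with pytest.raises(OnsetMissing):
        compute_peepi(rec, b)


def test_pmus_zero_when_pes_tracks_recoil(free_breathing):
    # constructed: pes exactly on the recoil line -> pmus identically 0
    rec, _ = free_breathing
    breaths = segment_breaths(rec, detect_onsets=False)
    b = breaths[3]
    import copy
    rec2 = copy.deepcopy(rec)
    i0 = rec.index_at(b.insufflation_start)
    i1 = rec.index_at(b.insufflation_end)
    vol = np.concatenate(([0.0], np.cumsum(
        (rec.flow[i0 + 1:i1 + 1] + rec.flow[i0:i1]) * 0.5 * rec.dt)))
    rec2.pes[:] = 8.0
    rec2.pes[i0:i1 + 1] = 8.0 + 15.0 * vol
    rec2.pes[i1 + 1:] = 8.0 + 15.0 * vol[-1]   # hold plateau: no step edge
    b.effort_onset = b.insufflation_start
    _, pmus, pmax, _ = compute_pmus_trace(rec2, b, ecw=15.0, pes_ee=8.0)
    assert pmax < 0.05
    assert np.all(pmus < 0.05)


def test_pmus_max_recovered_from_simulation():
    pat = PatientParams(ers=25, ecw=15, rrs=10, pes_ee=8)
    vent = VentSettings(ps=8, peep=5)
    eff = EffortProfile(pmus_max=10, respiratory_rate=16)
    rec, gt = simulate_breaths(pat, vent, eff, duration=40, seed=0)
    breaths = segment_breaths(rec)
    vals = [compute_pmus_trace(rec, b, ecw=15.0)[2] for b in breaths[1:-1]]
    assert np.median(vals) == pytest.approx(10.0, abs=0.5)


def test_triangular_pmus_recovered_by_inverse_construction():
    # build Pes from a known recoil line minus a triangular pmus; the
    # estimator must return the constructed peak
    fs = 200.0
    n = 3000
    t = np.arange(n) / fs
    flow = np.zeros(n)
    ins = (t >= 5.0) & (t < 6.0)
    flow[ins] = 0.4
    vol = np.cumsum(flow) / fs
    pmus = np.interp(t, [4.8, 5.5, 6.2], [0, 6, 0])
    pes = 8.0 + 12.0 * vol - pmus
    from respeffort import WaveformRecording, Breath
    rec = WaveformRecording(time=t, flow=flow, paw=np.full(n, 13.0), pes=pes,
                            sample_rate=fs)
    b = Breath(insufflation_start=5.0, insufflation_end=6.0,
               expiration_end=10.0, tidal_volume=0.4, effort_onset=4.8)
    _, tr, pmax, _ = compute_pmus_trace(rec, b, ecw=12.0, pes_ee=8.0)
    # the 50 ms smoothing rounds the triangular apex slightly
    assert pmax == pytest.approx(6.0, abs=0.2)


def test_ptp_of_simple_shapes():
    t = np.linspace(0, 1, 201)
    assert compute_ptp(t, np.full_like(t, 5.0)) == pytest.approx(5.0, rel=1e-6)
    tri = np.interp(t, [0, 0.5, 1.0], [0, 6, 0])
    assert compute_ptp(t, tri) == pytest.approx(3.0, rel=1e-3)


def test_ptp_per_breath_close_to_truth(free_breathing):
    rec, gt = free_breathing
    breaths = segment_breaths(rec)
    onsets = np.array(gt.effort_onsets)
    for b in breaths[2:8]:
        k = int(np.argmin(np.abs(onsets - (b.effort_onset or b.insufflation_start))))
        t, pm, _, _ = compute_pmus_trace(rec, b, ecw=15.0)
        assert compute_ptp(t, pm) == pytest.approx(gt.ptp_breaths[k], rel=0.05)


def test_ptp_min_linear_in_rate():
    assert compute_ptp_min([3.0, 3.0], 20.0) == pytest.approx(60.0)
    assert compute_ptp_min([3.0], 40.0) == pytest.approx(120.0)
    with pytest.raises(DataError):
        compute_ptp_min([], 15.0)


def test_passive_breaths_read_near_zero_effort():
    pat = PatientParams(ers=20, ecw=13, rrs=9, pes_ee=8)
    vent = VentSettings(ps=12, peep=5, cycle_off_fraction=0.1)
    eff = EffortProfile(pmus_max=0.0, respiratory_rate=14)
    rec, _ = simulate_breaths(pat, vent, eff, duration=40, seed=0)
    breaths = segment_breaths(rec)
    for b in breaths[1:-1]:
        t, pm, pmax, _ = compute_pmus_trace(rec, b, ecw=13.0)
        assert pmax < 0.5
        assert compute_ptp(t, pm) < 0.5


def test_summarize_level_averages_and_flags(free_breathing):
    rec, gt = free_breathing
    occs = detect_occlusions(rec)
    breaths = segment_breaths(rec, occlusions=occs)
    m = summarize_level(rec, breaths, ecw=15.0, occlusions=occs)
    assert m.n_breaths_averaged >= 15
    assert m.respiratory_rate == pytest.approx(18.0, abs=0.5)
    assert m.pmus_max == pytest.approx(8.0, abs=0.5)
    assert m.ptp_min == pytest.approx(
        np.mean(gt.ptp_breaths[1:-1]) * 18.0, rel=0.08)
    assert "short_window" in m.flags  # 60 s recording, no occlusion marker
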