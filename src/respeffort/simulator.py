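"""Pressure-support ventilation simulator with ground-truth effort.

The engine integrates the single-compartment equation of motion of the
respiratory system on a fixed 200-Hz grid::

    Paw(t) + Pmus(t) = Rrs * V'(t) + Ers * V(t) + PEEP + PEEPi

with volume V referenced to the end-expiratory lung volume (V = 0, clamped:
expiratory flow stops at V = 0, which traps the intrinsic-PEEP recoil
offset).  The ventilator pressurizes the circuit to PEEP + PS with a
first-order rise once patient flow exceeds the trigger threshold, and cycles
off when inspiratory flow decays to a set fraction of its peak.  Esophageal
pressure follows the chest wall: Pes = Pes_ee + Ecw * V - Pmus.

Airway occlusions freeze volume and force zero flow; the occluded airway
pressure then reads the alveolar pressure, PEEP + PEEPi + Ers*V - Pmus,
which is what makes P0.1, dPocc and PMI measurable at the airway opening.

Every simulation returns a :class:`~respeffort.recording.WaveformRecording`
plus a :class:`GroundTruth` carrying the true muscle-pressure trace, effort
onsets, per-breath tidal volumes and pressure-time products, and the true
value of each occlusion index — so downstream detectors and estimators can
be tested without patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, PlacementError, SimulationError
from .recording import DEFAULT_SAMPLE_RATE, WaveformRecording

__all__ = [
    "PatientParams", "EffortProfile", "VentSettings", "OcclusionTruth",
    "GroundTruth", "CohortSpec", "LevelRecord", "simulate_breaths",
    "simulate_occlusion", "inject_artifact", "simulate_titration",
]

ARTIFACT_KINDS = ("air_leak", "extra_insp_effort", "extra_exp_effort", "short_hold")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientParams:
    """Passive respiratory mechanics of the simulated patient.

    ers/ecw/rrs are respiratory-system elastance (cmH2O/L), chest-wall
    elastance (cmH2O/L) and resistance (cmH2O.s/L); peepi is intrinsic PEEP
    (cmH2O, >= 0) and pes_ee the end-expiratory esophageal baseline (cmH2O).
    """

    ers: float = 16.0
    ecw: float = 11.0
    rrs: float = 10.0
    peepi: float = 0.0
    pes_ee: float = 8.0

    def __post_init__(self):
        if not (self.ers >= self.ecw > 0):
            raise ParameterError(f"need ers >= ecw > 0, got ers={self.ers}, ecw={self.ecw}")
        if self.rrs <= 0:
            raise ParameterError(f"rrs must be > 0, got {self.rrs}")
        if self.peepi < 0:
            raise ParameterError(f"peepi must be >= 0, got {self.peepi}")

    @property
    def elung(self) -> float:
        return self.ers - self.ecw


@dataclass(frozen=True)
class EffortProfile:
    """Shape and timing of the inspiratory muscle-pressure waveform.

    Each effort rises to ``pmus_max`` over ``rise_time`` (half-sine or ramp)
    and then releases exponentially with time constant ``release_time/3``
    (truncated after two release times).  Efforts repeat at
    ``respiratory_rate`` breaths/min.
    """

    pmus_max: float = 8.0
    rise_time: float = 0.8
    release_time: float = 0.6
    respiratory_rate: float = 18.0
    shape: str = "half_sine"

    def __post_init__(self):
        if self.pmus_max < 0:
            raise ParameterError("pmus_max must be >= 0")
        if self.shape not in ("half_sine", "ramp"):
            raise ParameterError(f"unknown effort shape {self.shape!r}")
        if self.rise_time + self.release_time >= self.period:
            raise ParameterError("rise_time + release_time must fit in the breath period")

    @property
    def period(self) -> float:
        return 60.0 / self.respiratory_rate

    def value(self, tau: float, amplitude: float | None = None) -> float:
        """Muscle pressure ``tau`` seconds after effort onset."""
        amp = self.pmus_max if amplitude is None else amplitude
        if tau < 0 or amp <= 0:
            return 0.0
        if tau <= self.rise_time:
            if self.shape == "ramp":
                return amp * tau / self.rise_time
            return amp * math.sin(0.5 * math.pi * tau / self.rise_time)
        tau2 = tau - self.rise_time
        if tau2 > 2.0 * self.release_time:
            return 0.0
        return amp * math.exp(-3.0 * tau2 / self.release_time)


@dataclass(frozen=True)
class VentSettings:
    """Pressure-support ventilator settings.

    ``trigger_flow`` (L/s) is the patient flow that triggers pressurization;
    ``cycle_off_fraction`` cycles the breath off when inspiratory flow falls
    to that fraction of its peak; ``rise_constant`` (s) is the first-order
    pressurization time constant.
    """

    ps: float = 8.0
    peep: float = 5.0
    trigger_flow: float = 0.05
    cycle_off_fraction: float = 0.25
    rise_constant: float = 0.08

    def __post_init__(self):
        if self.ps < 0 or self.peep < 0:
            raise ParameterError("ps and peep must be >= 0")
        if not (0.0 < self.cycle_off_fraction < 1.0):
            raise ParameterError("cycle_off_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class OcclusionTruth:
    start: float
    end: float
    kind: str                       # "end_expiratory" | "end_inspiratory"
    p01: float | None = None        # cmH2O, EE only
    dpocc: float | None = None      # cmH2O, EE only
    pmi: float | None = None        # cmH2O, EI only
    artifact: str | None = None     # injected artifact label, if any


@dataclass
class GroundTruth:
    """Truth channel emitted alongside every simulated recording."""

    effort_onsets: list[float] = field(default_factory=list)
    effort_amplitudes: list[float] = field(default_factory=list)
    pmus: np.ndarray | None = None
    occlusions: list[OcclusionTruth] = field(default_factory=list)
    insufflation_bounds: list[tuple[float, float]] = field(default_factory=list)
    tidal_volumes: list[float] = field(default_factory=list)
    ptp_breaths: list[float] = field(default_factory=list)
    patient: PatientParams | None = None
    vent: VentSettings | None = None
    effort: EffortProfile | None = None

    def level_summary(self, window_end: float | None = None) -> dict:
        """True per-level effort summary over efforts before ``window_end``.

        Only efforts that triggered a ventilator breath enter the
        pressure-time product (an ineffective effort has no insufflation
        to integrate to), and the respiratory rate is the actual breath
        rate in the window — the quantities the offline Pes analysis can
        measure.  Returns pmus_max (mean true per-breath peak),
        ptp_breath, ptp_min and respiratory_rate.
        """
        if window_end is None:
            occ_starts = [o.start for o in self.occlusions]
            window_end = min(occ_starts) if occ_starts else math.inf
        amps, ptps = [], []
        for onset, amp, ptp in zip(self.effort_onsets, self.effort_amplitudes,
                                   self.ptp_breaths):
            if onset < window_end and ptp is not None:
                amps.append(amp)
                ptps.append(ptp)
        starts = [s for s, _ in self.insufflation_bounds if s < window_end]
        if len(starts) >= 2:
            rr = 60.0 / float(np.mean(np.diff(starts)))
        elif self.effort is not None:
            rr = self.effort.respiratory_rate
        else:
            rr = float("nan")
        pmus = float(np.mean(amps)) if amps else 0.0
        ptp = float(np.mean(ptps)) if ptps else 0.0
        return {"pmus_max": pmus, "ptp_breath": ptp,
                "ptp_min": ptp * rr, "respiratory_rate": rr}


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def _integrate(patient: PatientParams, vent: VentSettings, effort: EffortProfile,
               duration: float, *, sample_rate: float = DEFAULT_SAMPLE_RATE,
               seed: int | None = None, noise_pressure: float = 0.0,
               noise_flow: float = 0.0, breath_cv: float = 0.0,
               ee_requests: dict[int, float] | None = None,
               ei_requests: dict[int, float] | None = None,
               first_onset: float = 0.5, time_trigger: bool = True,
               meta: dict | None = None) -> tuple[WaveformRecording, GroundTruth]:
    """Fixed-step state-machine integration of the patient-ventilator system.

    ``ee_requests``/``ei_requests`` map an effort index to a hold duration:
    an end-expiratory hold closes the valve shortly before that effort's
    onset, an end-inspiratory hold closes it at that breath's cycle-off.
    """
    ee_requests = dict(ee_requests or {})
    ei_requests = dict(ei_requests or {})
    fs = sample_rate
    dt = 1.0 / fs
    n = int(round(duration * fs))
    if n < 2:
        raise ParameterError("duration too short for the sample rate")

    rng = np.random.default_rng(seed)
    jitter = (np.exp(rng.normal(0.0, breath_cv, size=max(64, int(duration / effort.period) + 8)))
              if breath_cv > 0 else None)

    flow = np.zeros(n)
    paw = np.zeros(n)
    pes = np.zeros(n)
    pmus_arr = np.zeros(n)

    ers, ecw, rrs = patient.ers, patient.ecw, patient.rrs
    peepi, pes_ee = patient.peepi, patient.pes_ee
    peep, ps = vent.peep, vent.ps
    trigger_flow = vent.trigger_flow
    cof = vent.cycle_off_fraction
    k_rise = min(1.0, dt / vent.rise_constant)
    k_fall = min(1.0, dt / 0.06)        # expiratory-valve opening constant
    ee_lead = 0.2                        # hold starts this long before onset
    post_hold_gap = 0.3                  # patient pause after an EI hold
    min_insp = 0.25                      # refractory before cycle-off (s)
    max_insp = 4.0

    truth = GroundTruth(patient=patient, vent=vent, effort=effort)

    phase = "exp"
    V = 0.0
    paw_val = float(peep)
    next_onset = first_onset
    last_onset = -math.inf
    cur_amp = 0.0
    effort_count = 0
    machine_fire = False
    peak_flow = 0.0
    insp_start = 0.0
    hold_end = math.inf
    V_hold = 0.0
    cur_occ: OcclusionTruth | None = None
    occ_running_max = 0.0

    for i in range(n):
        t = i * dt
        # --- patient effort clock -----------------------------------------
        if t + 1e-12 >= next_onset:
            if phase == "hold_ei":
                # patient pauses during an end-inspiratory hold
                next_onset = hold_end + post_hold_gap
            else:
                last_onset = next_onset
                cur_amp = effort.pmus_max * (jitter[effort_count % len(jitter)]
                                             if jitter is not None else 1.0)
                truth.effort_onsets.append(last_onset)
                truth.effort_amplitudes.append(cur_amp)
                effort_count += 1
                next_onset += effort.period
                machine_fire = True
                if phase == "hold_ee" and cur_occ is not None:
                    cur_occ.p01 = effort.value(0.100, cur_amp)

        pm = effort.value(t - last_onset, cur_amp)

        # --- end-expiratory hold entry ------------------------------------
        if (phase == "exp" and any(k <= effort_count for k in ee_requests)
                and t >= next_onset - ee_lead):
            hold_dur = ee_requests.pop(min(k for k in ee_requests
                                           if k <= effort_count))
            phase = "hold_ee"
            V_hold = V
            hold_end = t + hold_dur
            cur_occ = OcclusionTruth(start=t, end=hold_end, kind="end_expiratory")
            occ_running_max = 0.0
            truth.occlusions.append(cur_occ)

        # --- dynamics ------------------------------------------------------
        if phase in ("hold_ee", "hold_ei"):
            f = 0.0
            paw_val = peep + peepi + ers * V_hold - pm
            if phase == "hold_ee":
                occ_running_max = max(occ_running_max, pm)
            if t >= hold_end:
                if cur_occ is not None:
                    cur_occ.end = t
                    if cur_occ.kind == "end_expiratory":
                        cur_occ.dpocc = occ_running_max
                    cur_occ = None
                phase = "exp"
                V = V_hold
                hold_end = math.inf
        if phase not in ("hold_ee", "hold_ei"):
            target = peep + ps if phase == "insp" else peep
            k = k_rise if phase == "insp" else k_fall
            paw_val += (target - paw_val) * k
            vdot = (paw_val + pm - peep - peepi - ers * V) / rrs
            if V <= 0.0 and vdot < 0.0:
                vdot = 0.0
                V = 0.0
            V += vdot * dt
            f = vdot
            if phase == "exp":
                if f > trigger_flow or (machine_fire and time_trigger
                                        and effort.pmus_max == 0.0):
                    phase = "insp"
                    insp_start = t
                    peak_flow = 0.0
                machine_fire = False
            elif phase == "insp":
                peak_flow = max(peak_flow, f)
                dur_insp = t - insp_start
                if (dur_insp > min_insp and f <= cof * peak_flow) or dur_insp > max_insp:
                    # serve the earliest end-inspiratory request that has
                    # come due (robust to efforts that failed to trigger)
                    due = [k for k in ei_requests if k <= effort_count - 1]
                    if due:
                        hold_dur = ei_requests.pop(min(due))
                        phase = "hold_ei"
                        V_hold = V
                        hold_end = t + hold_dur
                        cur_occ = OcclusionTruth(
                            start=t, end=hold_end, kind="end_inspiratory",
                            pmi=(peep + peepi + ers * V) - paw_val)
                        truth.occlusions.append(cur_occ)
                    else:
                        phase = "exp"

        flow[i] = f
        paw[i] = paw_val
        pes[i] = pes_ee + ecw * (V_hold if phase in ("hold_ee", "hold_ei") else V) - pm
        pmus_arr[i] = pm

    if not (np.isfinite(flow).all() and np.isfinite(paw).all() and np.isfinite(pes).all()):
        raise SimulationError(
            f"non-finite waveform values for patient={patient}, vent={vent}")
    if ee_requests or ei_requests:
        missing = sorted(list(ee_requests) + list(ei_requests))
        raise PlacementError(
            f"occlusion request(s) for effort index {missing} never placed "
            f"(duration too short or no stable phase)")

    clean_flow = flow
    if noise_pressure > 0 or noise_flow > 0:
        paw = paw + rng.normal(0.0, noise_pressure, n)
        pes = pes + rng.normal(0.0, noise_pressure, n)
        flow = flow + rng.normal(0.0, noise_flow, n)

    time = np.arange(n) * dt
    rec = WaveformRecording(time=time, flow=flow, paw=paw, pes=pes,
                            sample_rate=fs, meta=dict(meta or {}))
    rec.meta.setdefault("ps_level", vent.ps)
    rec.meta.setdefault("peep_set", vent.peep)

    truth.pmus = pmus_arr
    _fill_breath_truth(truth, clean_flow, pmus_arr, dt)
    return rec, truth


def _fill_breath_truth(truth: GroundTruth, flow: np.ndarray,
                       pmus: np.ndarray, dt: float) -> None:
    """Derive true insufflation bounds, tidal volumes and per-breath PTP.

    ``flow`` is the noise-free integrated flow, so the truth is exact even
    when the emitted recording carries sensor noise.
    """
    holds = [(o.start, o.end) for o in truth.occlusions]

    def in_hold(t):
        return any(s - 1e-9 <= t < e + 1e-9 for s, e in holds)

    n = flow.size
    bounds = []
    i = 1
    while i < n:
        if flow[i - 1] <= 0.0 < flow[i] and not in_hold(i * dt):
            j = i + 1
            while j < n and flow[j] > 0.0:
                j += 1
            if j < n and not in_hold(i * dt):
                bounds.append((i * dt, j * dt))
            i = j
        i += 1
    truth.insufflation_bounds = bounds
    truth.tidal_volumes = [
        float(np.trapezoid(flow[int(round(s / dt)):int(round(e / dt)) + 1], dx=dt))
        for s, e in bounds]
    # per-breath PTP: integral of true pmus from onset to the end of the
    # insufflation this effort triggered; None when the effort never
    # triggered a breath (ineffective effort)
    ptps = []
    for onset in truth.effort_onsets:
        end = next((e for s, e in bounds
                    if onset - 0.1 <= s <= onset + 1.5 and e > onset), None)
        if end is None:
            ptps.append(None)
            continue
        i0, i1 = int(round(onset / dt)), int(round(end / dt))
        i1 = min(i1, pmus.size - 1)
        ptps.append(float(np.trapezoid(pmus[i0:i1 + 1], dx=dt)) if i1 > i0 else 0.0)
    truth.ptp_breaths = ptps


# ---------------------------------------------------------------------------
# public simulation operations
# ---------------------------------------------------------------------------

def simulate_breaths(patient: PatientParams, vent: VentSettings,
                     effort: EffortProfile, duration: float = 60.0,
                     seed: int | None = None, *, noise_pressure: float = 0.0,
                     noise_flow: float = 0.0, breath_cv: float = 0.0,
                     sample_rate: float = DEFAULT_SAMPLE_RATE,
                     meta: dict | None = None) -> tuple[WaveformRecording, GroundTruth]:
    """Simulate free pressure-support breathing (no occlusions)."""
    if duration < effort.period:
        raise ParameterError("duration must cover at least one breath period")
    return _integrate(patient, vent, effort, duration, sample_rate=sample_rate,
                      seed=seed, noise_pressure=noise_pressure,
                      noise_flow=noise_flow, breath_cv=breath_cv, meta=meta)


def simulate_occlusion(patient: PatientParams, vent: VentSettings,
                       effort: EffortProfile, kind: str,
                       hold_duration: float, duration: float = 25.0,
                       seed: int | None = None, *, occluded_effort: int = 3,
                       noise_pressure: float = 0.0, noise_flow: float = 0.0,
                       sample_rate: float = DEFAULT_SAMPLE_RATE,
                       meta: dict | None = None) -> tuple[WaveformRecording, GroundTruth]:
    """Simulate breathing with a single airway-occlusion maneuver.

    ``kind`` is ``end_expiratory`` (valve closes just before the
    ``occluded_effort``-th effort; P0.1 and dPocc are measurable) or
    ``end_inspiratory`` (valve closes at that breath's cycle-off; PMI is
    measurable after muscle relaxation).
    """
    if hold_duration <= 0:
        raise ParameterError("hold_duration must be > 0")
    if kind == "end_expiratory":
        reqs = {"ee_requests": {occluded_effort: hold_duration}}
    elif kind == "end_inspiratory":
        reqs = {"ei_requests": {occluded_effort: hold_duration}}
    else:
        raise ParameterError(f"unknown occlusion kind {kind!r}")
    return _integrate(patient, vent, effort, duration, sample_rate=sample_rate,
                      seed=seed, noise_pressure=noise_pressure,
                      noise_flow=noise_flow, meta=meta, **reqs)


def inject_artifact(recording: WaveformRecording, kind: str,
                    params: dict | None = None,
                    truth: GroundTruth | None = None,
                    ) -> tuple[WaveformRecording, GroundTruth]:
    """Corrupt an end-inspiratory occlusion with a known artifact class.

    Kinds: ``air_leak`` (Paw decays through the hold, Pes stays at plateau),
    ``extra_insp_effort`` (simultaneous Paw and Pes dip), ``extra_exp_effort``
    (simultaneous rise), ``short_hold`` (hold truncated below the QC
    minimum).  Returns a modified copy and a truth object labelling the
    injected class.
    """
    if kind not in ARTIFACT_KINDS:
        raise ParameterError(f"unknown artifact kind {kind!r}; "
                             f"choose from {ARTIFACT_KINDS}")
    params = dict(params or {})
    hold = _locate_ei_hold(recording, truth)
    if hold is None:
        raise ParameterError("recording contains no end-inspiratory occlusion")
    i0, i1 = hold
    fs = recording.sample_rate
    dt = 1.0 / fs
    flow = recording.flow.copy()
    paw = recording.paw.copy()
    pes = recording.pes.copy()

    if kind == "short_hold":
        keep = params.get("duration", 1.2)
        n_keep = int(round(keep * fs))
        if i0 + n_keep >= i1:
            raise ParameterError("short_hold duration is not shorter than the hold")
        sel = np.r_[0:i0 + n_keep, i1:recording.n_samples]
        flow, paw, pes = flow[sel], paw[sel], pes[sel]
        time = np.arange(flow.size) * dt
        out = WaveformRecording(time=time, flow=flow, paw=paw, pes=pes,
                                sample_rate=fs, meta=dict(recording.meta))
        occ = OcclusionTruth(start=i0 * dt, end=(i0 + n_keep) * dt,
                             kind="end_inspiratory", artifact=kind)
        return out, _artifact_truth(truth, occ)

    t_rel = (np.arange(i0, i1) - i0) * dt
    hold_len = (i1 - i0) * dt
    if kind == "air_leak":
        slope = params.get("slope", -2.0)       # cmH2O/s, must be negative
        delay = params.get("delay", 0.2)
        ramp = np.where(t_rel > delay, (t_rel - delay) * slope, 0.0)
        paw[i0:i1] += ramp
    else:
        depth = params.get("depth", 2.0)        # cmH2O
        width = params.get("width", 0.5)        # s
        center = params.get("center_fraction", 0.65) * hold_len
        lo, hi = center - width / 2.0, center + width / 2.0
        mask = (t_rel >= lo) & (t_rel <= hi)
        bump = np.zeros_like(t_rel)
        bump[mask] = np.sin(np.pi * (t_rel[mask] - lo) / width) ** 2 * depth
        sign = -1.0 if kind == "extra_insp_effort" else 1.0
        paw[i0:i1] += sign * bump
        pes[i0:i1] += sign * bump
    out = WaveformRecording(time=recording.time.copy(), flow=flow, paw=paw,
                            pes=pes, sample_rate=fs, meta=dict(recording.meta))
    occ = OcclusionTruth(start=i0 * dt, end=i1 * dt,
                         kind="end_inspiratory", artifact=kind)
    return out, _artifact_truth(truth, occ)


def _artifact_truth(base: GroundTruth | None, occ: OcclusionTruth) -> GroundTruth:
    gt = GroundTruth() if base is None else replace(
        base, occlusions=[o for o in base.occlusions
                          if o.kind != "end_inspiratory"])
    gt = GroundTruth(effort_onsets=list(gt.effort_onsets),
                     effort_amplitudes=list(gt.effort_amplitudes),
                     pmus=gt.pmus, occlusions=list(gt.occlusions) + [occ],
                     patient=gt.patient, vent=gt.vent, effort=gt.effort)
    return gt


def _locate_ei_hold(rec: WaveformRecording,
                    truth: GroundTruth | None) -> tuple[int, int] | None:
    """Index bounds of the end-inspiratory zero-flow hold."""
    if truth is not None:
        for o in truth.occlusions:
            if o.kind == "end_inspiratory":
                return rec.index_at(o.start), rec.index_at(o.end)
    zero = np.abs(rec.flow) < 0.02
    best = None
    i = 0
    n = zero.size
    while i < n:
        if zero[i]:
            j = i
            while j < n and zero[j]:
                j += 1
            length = (j - i) / rec.sample_rate
            # an EI hold shows occluded Paw well above the circuit baseline
            if length >= 0.8 and np.median(rec.paw[i:j]) > np.median(rec.paw) + 1.0:
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
            i = j
        i += 1
    return best


# ---------------------------------------------------------------------------
# titration cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study-condition defaults for a simulated downward PS titration.

    Each patient breathes through descending PS levels; per level, three
    end-expiratory and three end-inspiratory occlusions are embedded after a
    free-breathing window.  Patient mechanics are drawn around the observed
    cohort medians (Ers ~16, Ecw ~0.7*Ers, Rrs ~10, PEEPi mostly 0-1); the
    effort-versus-support rule pmus_max = c0 + c1*(20 - PS) makes effort
    rise as support is withdrawn.
    """

    n_patients: int = 28
    ps_levels: tuple = (20, 18, 16, 14, 12, 10, 8, 6, 4, 2)
    peep: float = 5.0
    breath_window: float = 30.0     # free-breathing seconds before occlusions
    n_occlusions: int = 3           # per kind per level
    ee_hold: float = 1.2
    ei_hold: float = 2.5
    noise_pressure: float = 0.2     # cmH2O std
    noise_flow: float = 0.01        # L/s std
    breath_cv: float = 0.05
    effort_intercept: tuple = (1.5, 0.5)   # c0 mean, sd (cmH2O)
    effort_slope: tuple = (0.55, 0.15)     # c1 mean, sd (cmH2O per cmH2O PS)

    def __post_init__(self):
        if self.n_patients < 1:
            raise ParameterError("need n_patients >= 1")
        if any(b >= a for a, b in zip(self.ps_levels, self.ps_levels[1:])):
            raise ParameterError("ps_levels must be strictly descending")
        if min(self.noise_pressure, self.noise_flow, self.breath_cv) < 0:
            raise ParameterError("noise levels must be >= 0")
        if self.ee_hold <= 0 or self.ei_hold <= 0:
            raise ParameterError("hold durations must be > 0")


@dataclass
class LevelRecord:
    patient_id: str
    ps: float
    recording: WaveformRecording
    truth: GroundTruth


def _draw_patient(rng: np.random.Generator, spec: CohortSpec):
    ers = max(8.0, rng.normal(16.1, 3.0))
    ecw = float(np.clip(rng.normal(0.70, 0.06), 0.5, 0.85)) * ers
    rrs = max(4.0, rng.normal(10.0, 2.0))
    peepi = float(rng.choice([0.0, 1.0, 2.0], p=[0.5, 0.35, 0.15]))
    pes_ee = rng.normal(8.0, 1.0)
    patient = PatientParams(ers=ers, ecw=ecw, rrs=rrs, peepi=peepi, pes_ee=pes_ee)
    # a spontaneously breathing patient must overcome the intrinsic-PEEP
    # threshold load plus the resistive drop at trigger flow on every
    # breath, so the effort floor rises with PEEPi and resistance
    trigger_load = peepi + rrs * 0.05
    c0 = max(0.3, trigger_load + 0.6, rng.normal(*spec.effort_intercept))
    c1 = max(0.1, rng.normal(*spec.effort_slope))
    rr = rng.uniform(16.0, 24.0)
    rise = float(np.clip(rng.normal(0.8, 0.12), 0.5, 1.1))
    return patient, (c0, c1), rr, rise


def simulate_titration(spec: CohortSpec | None = None,
                       seed: int = 0) -> list[LevelRecord]:
    """Simulate the full downward-titration cohort.

    Returns one :class:`LevelRecord` per patient x PS level (levels must be
    descending).  Per-patient mechanics and the effort rule are drawn once
    per patient; noise and breath-to-breath jitter are re-seeded per level.
    The per-level ground truth carries the true effort summary for the
    free-breathing window and the true value of every occlusion index.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    records: list[LevelRecord] = []
    for p in range(spec.n_patients):
        patient, (c0, c1), rr, rise = _draw_patient(rng, spec)
        pid = f"p{p + 1:02d}"
        for ps in spec.ps_levels:
            pmax = float(np.clip(c0 + c1 * (20.0 - ps), 0.2, 28.0))
            # respiratory drive slows the rate under generous support and
            # speeds it as support is withdrawn; the slow-down at high PS
            # also leaves time for the large assisted breaths to empty
            rr_level = rr * (0.65 + 0.35 * (20.0 - ps) / 18.0)
            effort = EffortProfile(pmus_max=pmax, rise_time=rise,
                                   release_time=0.6, respiratory_rate=rr_level)
            vent = VentSettings(ps=float(ps), peep=spec.peep)
            period = effort.period
            first_onset = 0.5
            k0 = int(math.ceil((spec.breath_window - first_onset) / period))
            ee = {k0 + 2 * j: spec.ee_hold for j in range(spec.n_occlusions)}
            ei = {k0 + 2 * spec.n_occlusions + 2 * j: spec.ei_hold
                  for j in range(spec.n_occlusions)}
            n_efforts = k0 + 4 * spec.n_occlusions
            duration = (first_onset + (n_efforts + 1.5) * period
                        + spec.n_occlusions * (spec.ei_hold + 1.0) + 3.0)
            level_seed = int(rng.integers(0, 2**31 - 1))
            rec, truth = _integrate(
                patient, vent, effort, duration, seed=level_seed,
                noise_pressure=spec.noise_pressure, noise_flow=spec.noise_flow,
                breath_cv=spec.breath_cv, ee_requests=ee, ei_requests=ei,
                first_onset=first_onset,
                meta={"patient_id": pid, "ps_level": float(ps),
                      "peep_set": spec.peep})
            records.append(LevelRecord(patient_id=pid, ps=float(ps),
                                       recording=rec, truth=truth))
    return records
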