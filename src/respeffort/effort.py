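"""Esophageal-pressure-derived reference effort metrics.

The reference standard for inspiratory effort is built from Pes: the muscle
pressure Pmus(t) is the gap between the quasi-static chest-wall recoil line
(Pes_ee + Ecw * V(t)) and the measured Pes; its peak (Pmus_max) and its
time integral from effort onset to the end of ventilator insufflation
(PTPmus per breath, scaled by respiratory rate to PTPmus/min) quantify the
effort.  Chest-wall elastance comes from the Pes plateau during an
end-inspiratory occlusion at the highest support level, where effort is
minimal; intrinsic PEEP is the Pes drop between effort onset and the start
of insufflation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, LevelSkipped, OnsetMissing, ParameterError
from .events import Breath, OcclusionEvent, smooth
from .recording import WaveformRecording

__all__ = ["EffortMeasures", "estimate_ecw", "estimate_ers", "compute_peepi",
           "compute_pmus_trace", "compute_ptp", "compute_ptp_min",
           "summarize_level"]

PES_BASELINE_WINDOW = 0.100   # s before effort onset defining Pes_ee


@dataclass
class EffortMeasures:
    """Per-level Pes-derived effort summary (averaged over eligible breaths)."""

    pmus_max: float
    ptp_breath: float
    ptp_min: float
    respiratory_rate: float
    n_breaths_averaged: int
    peepi: float | None = None
    ecw: float | None = None
    ers: float | None = None
    flags: tuple = ()

    @property
    def elung(self) -> float | None:
        if self.ers is None or self.ecw is None:
            return None
        return self.ers - self.ecw


def estimate_ecw(pes_plateau: float, pes_ee: float, tidal_volume: float) -> float:
    """Chest-wall elastance from an occluded Pes plateau.

    ecw = (pes_plateau - pes_ee) / VT, in cmH2O/L.  Computed at the highest
    support level, where residual muscle activity is minimal and the plateau
    reflects pure chest-wall recoil.  A negative result is physically
    implausible and should be flagged by the caller.
    """
    if tidal_volume <= 0:
        raise ParameterError(f"tidal_volume must be > 0, got {tidal_volume}")
    return (pes_plateau - pes_ee) / tidal_volume


def estimate_ers(paw_plateau: float, peep_total: float, tidal_volume: float) -> float:
    """Respiratory-system elastance from the occluded Paw plateau.

    ers = (paw_plateau - peep_total) / VT with peep_total = set PEEP +
    intrinsic PEEP.
    """
    if tidal_volume <= 0:
        raise ParameterError(f"tidal_volume must be > 0, got {tidal_volume}")
    return (paw_plateau - peep_total) / tidal_volume


def _pes_smooth(rec: WaveformRecording) -> np.ndarray:
    return smooth(rec.pes, rec.sample_rate)


def compute_peepi(rec: WaveformRecording, breath: Breath) -> float:
    """Intrinsic PEEP: |Pes(effort onset) - Pes(insufflation start)|.

    The esophageal pressure the patient must spend before any inspiratory
    flow appears.  Requires a detected effort onset.
    """
    if breath.effort_onset is None:
        raise OnsetMissing("breath has no detected effort onset")
    pes_s = _pes_smooth(rec)
    i_on = rec.index_at(breath.effort_onset)
    i_ins = rec.index_at(breath.insufflation_start)
    return float(abs(pes_s[i_on] - pes_s[i_ins]))


def compute_pmus_trace(rec: WaveformRecording, breath: Breath, ecw: float,
                       pes_ee: float | None = None,
                       ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Muscle-pressure trace over one breath.

    Returns ``(times, pmus, pmus_max, onset_missing)``.  The chest-wall
    recoil line is anchored at ``pes_ee`` (mean Pes over the 100 ms before
    effort onset when not supplied) and follows ecw * V(t) with V integrated
    from the insufflation start; Pmus = recoil - Pes, clipped at zero before
    the effort onset.  When the onset is missing the insufflation start is
    used instead and flagged.
    """
    if ecw <= 0:
        raise ParameterError(f"ecw must be > 0, got {ecw}")
    fs = rec.sample_rate
    dt = 1.0 / fs
    onset_missing = breath.effort_onset is None
    onset = breath.insufflation_start if onset_missing else breath.effort_onset
    i_on = rec.index_at(onset)
    i_ins = rec.index_at(breath.insufflation_start)
    i_end = rec.index_at(breath.insufflation_end)
    if pes_ee is None:
        j0 = max(0, i_on - int(round(PES_BASELINE_WINDOW * fs)))
        pes_ee = float(np.mean(rec.pes[j0:i_on + 1]))
    # volume referenced to this breath's end-expiration (zero before the
    # insufflation start); integrating per breath removes flow-sensor drift
    idx = np.arange(i_on, i_end + 1)
    vol = np.zeros(idx.size)
    if i_end > i_ins:
        seg = rec.flow[i_ins:i_end + 1]
        v_seg = np.concatenate(([0.0], np.cumsum((seg[1:] + seg[:-1]) * 0.5 * dt)))
        vol[idx >= i_ins] = v_seg[(idx[idx >= i_ins] - i_ins)]
    recoil = pes_ee + ecw * vol
    pes_s = _pes_smooth(rec)[idx]
    pmus = recoil - pes_s
    pmus[idx * dt < onset] = np.maximum(pmus[idx * dt < onset], 0.0)
    pmus_max = float(pmus.max()) if pmus.size else 0.0
    return idx * dt, pmus, max(pmus_max, 0.0), onset_missing


def compute_ptp(times: np.ndarray, pmus: np.ndarray) -> float:
    """Pressure-time product of one breath: trapezoidal integral of Pmus.

    The trace is expected to span effort onset to insufflation end (the
    output of :func:`compute_pmus_trace`); units cmH2O.s.
    """
    if times.size < 2:
        return 0.0
    return float(np.trapezoid(np.maximum(pmus, 0.0), times))


def compute_ptp_min(ptp_breaths: list[float], respiratory_rate: float) -> float:
    """Per-minute pressure-time product: mean per-breath PTP x RR."""
    if not ptp_breaths:
        raise DataError("no per-breath PTP values to average")
    return float(np.mean(ptp_breaths)) * respiratory_rate


def summarize_level(rec: WaveformRecording, breaths: list[Breath],
                    ecw: float, *, occlusions: list[OcclusionEvent] | None = None,
                    window: float = 60.0, ers: float | None = None,
                    pes_excursion_bound: float = 40.0,
                    ) -> EffortMeasures:
    """Average Pes-derived effort over eligible breaths before the occlusions.

    Eligible breaths fall inside the ``window`` seconds preceding the first
    occlusion (the whole recording when there is none; windows shorter than
    one minute are flagged), and pass the artifact screen (Pes excursion
    within physical bounds, positive tidal volume).  Respiratory rate is
    taken from the mean inter-breath interval.
    """
    first_occ = min((o.start for o in occlusions), default=rec.time[-1]) \
        if occlusions is not None else rec.time[-1]
    w_lo = max(rec.time[0], first_occ - window)
    flags = []
    if first_occ - rec.time[0] < window:
        flags.append("short_window")

    eligible: list[Breath] = []
    pes_s = _pes_smooth(rec)
    for b in breaths:
        if not (w_lo <= b.insufflation_start and b.insufflation_end <= first_occ):
            continue
        i0, i1 = rec.index_at(b.insufflation_start), rec.index_at(b.expiration_end)
        exc = float(pes_s[i0:i1 + 1].max() - pes_s[i0:i1 + 1].min()) if i1 > i0 else 0.0
        if exc > pes_excursion_bound or b.tidal_volume <= 0.01:
            continue
        eligible.append(b)
    if not eligible:
        raise LevelSkipped("no eligible breaths in the pre-occlusion window")

    pmus_vals, ptp_vals, peepi_vals = [], [], []
    onset_flagged = False
    for b in eligible:
        t, pm, pmax, missing = compute_pmus_trace(rec, b, ecw)
        onset_flagged |= missing
        pmus_vals.append(pmax)
        ptp_vals.append(compute_ptp(t, pm))
        if b.effort_onset is not None:
            peepi_vals.append(compute_peepi(rec, b))
    if onset_flagged:
        flags.append("onset_missing")

    if len(eligible) > 1:
        starts = np.array([b.insufflation_start for b in eligible])
        rr = 60.0 / float(np.mean(np.diff(starts)))
    else:
        rr = 60.0 / max(eligible[0].expiration_end - eligible[0].insufflation_start, 1e-6)
    return EffortMeasures(
        pmus_max=float(np.mean(pmus_vals)),
        ptp_breath=float(np.mean(ptp_vals)),
        ptp_min=compute_ptp_min(ptp_vals, rr),
        respiratory_rate=rr,
        n_breaths_averaged=len(eligible),
        peepi=float(np.mean(peepi_vals)) if peepi_vals else None,
        ecw=ecw, ers=ers, flags=tuple(flags))
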