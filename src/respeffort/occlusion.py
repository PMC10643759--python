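"""Airway-pressure occlusion indices: P0.1, dPocc, PMI with quality control.

Against an end-expiratory occlusion the airway pressure mirrors the
occluded inspiratory effort: P0.1 is the Paw drop over the first 100 ms of
the occluded effort and dPocc the maximal drop from the pre-hold baseline.
After an end-inspiratory occlusion Paw relaxes to a plateau; the pressure
muscle index (PMI) is plateau minus the peak Paw at the onset of zero flow
— positive when the patient was contributing inspiratory pressure at
end-insufflation, negative under over-assistance.

PMI is only trusted on a clean plateau.  The quality-control screen
discards maneuvers with a plateau shorter than 1.5 s, an air leak (Paw
drifts down while Pes holds its plateau), or additional inspiratory or
expiratory effort during the hold (simultaneous Paw and Pes excursion).
Triplicate maneuvers at a support level are averaged over accepted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (LevelMissing, ManeuverTooShort, ParameterError, QCRejected)
from .events import OcclusionEvent, smooth
from .recording import WaveformRecording

__all__ = ["PawIndices", "QCThresholds", "compute_p01", "compute_dpocc",
           "qc_end_insp_occlusion", "compute_pmi", "average_maneuvers"]

QC_STATUSES = ("accepted", "short_plateau", "air_leak",
               "extra_insp_effort", "extra_exp_effort")


@dataclass(frozen=True)
class QCThresholds:
    """Configurable end-inspiratory plateau quality-control thresholds."""

    min_plateau: float = 1.5       # s
    leak_slope: float = 1.0        # cmH2O/s downward Paw drift
    pes_plateau_band: float = 0.5  # cmH2O Pes stability for the leak call
    effort_band: float = 1.0       # cmH2O simultaneous Paw+Pes excursion
    ref_window: tuple[float, float] = (0.5, 0.8)  # s after hold start


@dataclass
class PawIndices:
    """Per-level averages of the occlusion indices with QC bookkeeping."""

    p01: float | None = None
    dpocc: float | None = None
    pmi: float | None = None
    p01_values: list = field(default_factory=list)
    dpocc_values: list = field(default_factory=list)
    pmi_values: list = field(default_factory=list)       # accepted only
    qc_statuses: list = field(default_factory=list)      # one per EI maneuver
    n_ee_averaged: int = 0
    n_ei_averaged: int = 0


def _hold_indices(rec: WaveformRecording, occ: OcclusionEvent) -> tuple[int, int]:
    return rec.index_at(occ.start), rec.index_at(occ.end)


def _prehold_baseline(paw_s: np.ndarray, i0: int, fs: float,
                      window: float = 0.100) -> float:
    lo = max(0, i0 - int(round(window * fs)))
    return float(np.mean(paw_s[lo:i0])) if i0 > lo else float(paw_s[i0])


def compute_p01(rec: WaveformRecording, occ: OcclusionEvent, *,
                drop_threshold: float = 0.5, onset_eps: float = 0.15) -> float:
    """Airway occlusion pressure P0.1 from an end-expiratory hold (cmH2O).

    The occluded effort onset is located where Paw first falls
    ``drop_threshold`` cmH2O below the pre-hold baseline, backtracked to
    the latest sample still within ``onset_eps`` of the occluded-trace
    maximum (the edge of the pre-effort plateau); P0.1 = Paw(onset) -
    Paw(onset + 100 ms), reported as a positive magnitude.  Returns 0.0
    when Paw never declines during the hold (no occluded effort); raises
    :class:`ManeuverTooShort` when the hold ends before onset + 100 ms.
    """
    if occ.kind != "end_expiratory":
        raise ParameterError(f"P0.1 needs an end-expiratory hold, got {occ.kind}")
    fs = rec.sample_rate
    i0, i1 = _hold_indices(rec, occ)
    paw_s = smooth(rec.paw, fs)
    j = _occluded_onset(paw_s, i0, i1, fs, drop_threshold, onset_eps)
    if j is None:
        return 0.0
    j100 = j + int(round(0.100 * fs))
    if j100 >= i1 - i0:
        raise ManeuverTooShort(
            f"hold ends {occ.end:.2f}s, before onset + 100 ms")
    # read the drop on the raw trace: the moving average pulls the onset
    # kink down and would bias P0.1 low
    read = _point_read(rec.paw, i0 + j) - _point_read(rec.paw, i0 + j100)
    return max(float(read), 0.0)


def _occluded_onset(paw_s: np.ndarray, i0: int, i1: int, fs: float,
                    drop_threshold: float, onset_eps: float) -> int | None:
    """Occluded effort onset within a hold, as an offset from ``i0``.

    First sample where smoothed Paw falls ``drop_threshold`` below its
    within-window running maximum (so a plateau elevated by trapped
    end-expiratory recoil is handled the same as one at circuit PEEP),
    backtracked to the latest sample still within ``onset_eps`` of that
    plateau; ``None`` when Paw never declines (no occluded effort).
    """
    seg = paw_s[i0:i1]
    cm = np.maximum.accumulate(seg)
    below = np.flatnonzero(cm - seg > drop_threshold)
    if below.size == 0:
        return None
    k = int(below[0])
    at_top = np.flatnonzero(seg[:k + 1] >= cm[k] - onset_eps)
    return int(at_top[-1])


def _point_read(x: np.ndarray, i: int) -> float:
    """Three-sample mean around ``i``: robust to single-sample noise."""
    return float(np.mean(x[max(0, i - 1):i + 2]))


def compute_dpocc(rec: WaveformRecording, occ: OcclusionEvent, *,
                  drop_threshold: float = 0.5, onset_eps: float = 0.15) -> float:
    """Maximal Paw decline during an end-expiratory hold (cmH2O, >= 0).

    The decline is referenced to the occluded pre-effort plateau (median
    Paw from the hold start to the detected effort onset).  That plateau
    equals the measured circuit pressure when exhalation was complete, but
    also absorbs trapped end-expiratory recoil (incomplete exhalation,
    intrinsic PEEP), so the index reads the occluded muscle-pressure swing
    itself.  Falls back to the pre-hold baseline when no onset is found.
    """
    if occ.kind != "end_expiratory":
        raise ParameterError(f"dPocc needs an end-expiratory hold, got {occ.kind}")
    fs = rec.sample_rate
    i0, i1 = _hold_indices(rec, occ)
    paw_s = smooth(rec.paw, fs)
    seg = paw_s[i0:i1]
    j = _occluded_onset(paw_s, i0, i1, fs, drop_threshold, onset_eps)
    if j is None:
        base = _prehold_baseline(paw_s, i0, fs)
    else:
        # occluded plateau just before the effort: the detected window can
        # reach back into quiet pre-hold expiration at circuit PEEP, which
        # must not dilute the trapped-recoil baseline
        lo = max(0, j - int(round(0.150 * fs)))
        base = float(np.median(seg[lo:j + 1]))
    return max(float(base - seg.min()), 0.0)


def qc_end_insp_occlusion(rec: WaveformRecording, occ: OcclusionEvent,
                          thresholds: QCThresholds | None = None) -> str:
    """Quality-control status of an end-inspiratory plateau.

    Order of checks: plateau shorter than the minimum -> ``short_plateau``;
    simultaneous Paw and Pes dip beyond the effort band ->
    ``extra_insp_effort``; simultaneous rise -> ``extra_exp_effort``;
    monotone Paw decline with a stable Pes plateau -> ``air_leak``;
    otherwise ``accepted``.  Reference levels are medians over a short
    window after the post-occlusion relaxation has settled.
    """
    if occ.kind != "end_inspiratory":
        raise ParameterError(f"QC needs an end-inspiratory hold, got {occ.kind}")
    th = thresholds or QCThresholds()
    if occ.duration < th.min_plateau:
        return "short_plateau"
    fs = rec.sample_rate
    i0, i1 = _hold_indices(rec, occ)
    paw_s = smooth(rec.paw, fs)[i0:i1]
    pes_s = smooth(rec.pes, fs)[i0:i1]
    r0 = int(round(th.ref_window[0] * fs))
    r1 = min(int(round(th.ref_window[1] * fs)), paw_s.size)
    paw_ref = float(np.median(paw_s[r0:r1]))
    pes_ref = float(np.median(pes_s[r0:r1]))

    paw_dev = paw_s[r1:] - paw_ref
    pes_dev = pes_s[r1:] - pes_ref
    if np.any((paw_dev < -th.effort_band) & (pes_dev < -th.effort_band)):
        return "extra_insp_effort"
    if np.any((paw_dev > th.effort_band) & (pes_dev > th.effort_band)):
        return "extra_exp_effort"

    half = (i1 - i0) // 2
    t_half = np.arange(half, i1 - i0) / fs
    slope = float(np.polyfit(t_half, paw_s[half:], 1)[0])
    pes_stable = float(np.max(np.abs(pes_s[half:] - pes_ref))) <= th.pes_plateau_band
    if slope < -th.leak_slope and pes_stable:
        return "air_leak"
    return "accepted"


def compute_pmi(rec: WaveformRecording, occ: OcclusionEvent, *,
                qc_status: str | None = None,
                plateau_at: float = 1.0, plateau_window: float = 0.050,
                peak_window: float = 0.050) -> float:
    """Pressure muscle index from an accepted end-inspiratory hold (cmH2O).

    pmi = plateau - peak, sign preserved.  Peak is the mean Paw over the
    ``peak_window`` just before zero flow; plateau the mean over a
    ``plateau_window`` centered ``plateau_at`` seconds after the hold
    start.  A QC-rejected maneuver raises :class:`QCRejected` carrying the
    failing status.
    """
    if occ.kind != "end_inspiratory":
        raise ParameterError(f"PMI needs an end-inspiratory hold, got {occ.kind}")
    if qc_status is None:
        qc_status = qc_end_insp_occlusion(rec, occ)
    if qc_status != "accepted":
        raise QCRejected(qc_status)
    fs = rec.sample_rate
    i0, i1 = _hold_indices(rec, occ)
    # refine the zero-flow onset: smoothing delays the detected window start
    # past the true valve closure, where occluded Paw has already dipped
    back = int(round(0.150 * fs))
    seg = rec.flow[max(0, i0 - back):i0 + 1]
    moving = np.flatnonzero(seg > 0.05)
    r = max(0, i0 - back) + int(moving[-1]) + 1 if moving.size else i0
    k = max(1, int(round(peak_window * fs)))
    peak = float(np.mean(rec.paw[max(0, r - k):r]))
    c = i0 + int(round(plateau_at * fs))
    h = max(1, int(round(plateau_window * fs / 2)))
    lo, hi = max(i0, c - h), min(i1, c + h)
    if lo >= hi:
        raise ManeuverTooShort("hold too short for the plateau read")
    plateau = float(np.mean(rec.paw[lo:hi]))
    return plateau - peak


def average_maneuvers(values: list[float | None]) -> tuple[float, int]:
    """Mean of the accepted (non-missing) maneuver values at one level.

    Returns ``(mean, n_averaged)``; raises :class:`LevelMissing` when no
    maneuver was accepted, mirroring the 'immeasurable level' outcome.
    """
    accepted = [v for v in values if v is not None and np.isfinite(v)]
    if not accepted:
        raise LevelMissing("no accepted maneuver at this level")
    return float(np.mean(accepted)), len(accepted)
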