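"""Breath segmentation, effort-onset detection and occlusion detection.

Breaths are bounded by zero-crossings of the (lightly smoothed) flow signal:
ventilator insufflation runs from a positive-going to the next
negative-going crossing.  Esophageal effort onset is the point where the
smoothed Pes derivative drops below a slope threshold and stays there,
backtracked to the local Pes maximum.  Occlusion maneuvers are sustained
zero-flow windows, classified end-inspiratory when the volume reached at the
window start is a large fraction of the preceding tidal volume.

All detections operate on flow alone or on Pes derivatives; adding a
constant to Paw/Pes does not move any boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import WindowError
from .recording import WaveformRecording

__all__ = ["Breath", "OcclusionEvent", "segment_breaths",
           "detect_effort_onset", "detect_occlusions", "smooth"]

# detection defaults; the clinical definitions are qualitative, so every
# threshold is exposed as a keyword argument
SMOOTH_WINDOW = 0.050        # s, centered moving average
ZERO_FLOW_THRESHOLD = 0.02   # L/s
MIN_OCCLUSION = 0.200        # s
EI_VOLUME_FRACTION = 0.5     # of preceding tidal volume
ONSET_SLOPE = -2.0           # cmH2O/s on the smoothed Pes derivative
ONSET_PERSIST = 0.040        # s the slope must stay below threshold
MIN_INSUFFLATION = 0.150     # s, rejects noise crossings
MIN_PEAK_FLOW = 0.10         # L/s, rejects noise crossings


@dataclass
class Breath:
    """One respiratory cycle; times in seconds from recording start."""

    insufflation_start: float
    insufflation_end: float
    expiration_end: float
    tidal_volume: float
    effort_onset: float | None = None

    def __post_init__(self):
        if not (self.insufflation_start < self.insufflation_end
                <= self.expiration_end):
            raise ValueError("breath bounds out of order")


@dataclass
class OcclusionEvent:
    """A sustained zero-flow maneuver window, half-open [start, end)."""

    start: float
    end: float
    kind: str                        # "end_expiratory" | "end_inspiratory"
    preceding_breath: int | None = None   # index into the breath list

    @property
    def duration(self) -> float:
        return self.end - self.start


def smooth(x: np.ndarray, sample_rate: float,
           window: float = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; window rounded to an odd sample count."""
    n = max(1, int(round(window * sample_rate)))
    if n % 2 == 0:
        n += 1
    if n == 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(n) / n
    pad = n // 2
    xp = np.pad(np.asarray(x, dtype=float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def _zero_flow_windows(flow_s: np.ndarray, fs: float,
                       threshold: float, min_window: float) -> list[tuple[int, int]]:
    below = np.abs(flow_s) < threshold
    windows = []
    i = 0
    n = below.size
    min_n = int(round(min_window * fs))
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_n:
                windows.append((i, j))
            i = j
        i += 1
    return windows


def detect_occlusions(rec: WaveformRecording, *,
                      zero_flow_threshold: float = ZERO_FLOW_THRESHOLD,
                      min_window: float = MIN_OCCLUSION,
                      volume_fraction: float = EI_VOLUME_FRACTION,
                      paw_signature: float = 0.5,
                      ) -> list[OcclusionEvent]:
    """Locate zero-flow maneuver windows and classify their kind.

    A sustained near-zero-flow window is end-inspiratory when it interrupts
    an insufflation at its end: the flow just before the window is still
    inspiratory and the volume accumulated since the last positive-going
    crossing reaches ``volume_fraction`` of the preceding complete tidal
    volume.  Otherwise it is accepted as an end-expiratory occlusion only
    when Paw falls more than ``paw_signature`` cmH2O below its
    within-window running maximum (the mark of an occluded inspiratory
    effort, whether the occluded plateau sits at circuit PEEP or is
    elevated by trapped recoil) — quiet late-expiratory flow also sits
    below the zero-flow threshold and must not be reported as a maneuver.
    Windows shorter than ``min_window`` are ignored.
    """
    fs = rec.sample_rate
    dt = 1.0 / fs
    flow_s = smooth(rec.flow, fs)
    paw_s = smooth(rec.paw, fs)
    windows = _zero_flow_windows(flow_s, fs, zero_flow_threshold, min_window)
    if not windows:
        return []

    sign_pos = flow_s > 0
    pos_cross = np.flatnonzero(~sign_pos[:-1] & sign_pos[1:]) + 1
    neg_cross = np.flatnonzero(sign_pos[:-1] & ~sign_pos[1:]) + 1

    events = []
    for (i0, i1) in windows:
        starts_before = pos_cross[pos_cross < i0]
        vol_at_start = 0.0
        ref = None
        if starts_before.size:
            p = int(starts_before[-1])
            # volume accumulated since the most recent insufflation start
            vol_at_start = float(np.trapezoid(flow_s[p:i0 + 1], dx=dt))
            ref = _last_complete_vt(flow_s, pos_cross, neg_cross, i0, dt)
        if ref is None:
            ref = vol_at_start
        # inspiratory flow right before the window marks an interrupted
        # insufflation (end-inspiratory hold); expiration precedes an
        # end-expiratory hold or quiet-flow stretch
        pre_lo = max(0, i0 - int(round(0.150 * fs)))
        pre_hi = max(pre_lo + 1, i0 - int(round(0.040 * fs)))
        pre_flow = float(np.mean(flow_s[pre_lo:pre_hi]))
        if (pre_flow > zero_flow_threshold and vol_at_start > 0.05
                and vol_at_start >= volume_fraction * max(ref, 1e-6)):
            events.append(OcclusionEvent(start=i0 * dt, end=i1 * dt,
                                         kind="end_inspiratory"))
            continue
        seg = paw_s[i0:i1]
        fall = float(np.max(np.maximum.accumulate(seg) - seg)) if seg.size else 0.0
        if fall > paw_signature:
            events.append(OcclusionEvent(start=i0 * dt, end=i1 * dt,
                                         kind="end_expiratory"))
    return events


def _last_complete_vt(flow_s, pos_cross, neg_cross, before_idx, dt):
    """Tidal volume of the last complete insufflation ending before an index."""
    ends = neg_cross[neg_cross < before_idx]
    for e in ends[::-1]:
        starts = pos_cross[pos_cross < e]
        if starts.size:
            p = int(starts[-1])
            vt = float(np.trapezoid(flow_s[p:int(e) + 1], dx=dt))
            if vt > 0.05:
                return vt
    return None


def segment_breaths(rec: WaveformRecording, *,
                    occlusions: list[OcclusionEvent] | None = None,
                    min_insufflation: float = MIN_INSUFFLATION,
                    min_peak_flow: float = MIN_PEAK_FLOW,
                    detect_onsets: bool = True,
                    ) -> list[Breath]:
    """Segment ventilator breaths by flow zero-crossings.

    Breaths overlapping an occlusion window are excluded from the list (the
    occluded maneuver is analyzed separately).  Tidal volume is the flow
    integral over the insufflation.  When ``detect_onsets`` is set, the
    esophageal effort onset is attached to every breath with a sufficient
    pre-insufflation window.
    """
    fs = rec.sample_rate
    dt = 1.0 / fs
    flow_s = smooth(rec.flow, fs)
    if occlusions is None:
        occlusions = detect_occlusions(rec)
    occ_bounds = [(o.start, o.end) for o in occlusions]

    sign_pos = flow_s > 0
    pos_cross = np.flatnonzero(~sign_pos[:-1] & sign_pos[1:]) + 1
    neg_cross = np.flatnonzero(sign_pos[:-1] & ~sign_pos[1:]) + 1

    def overlaps_occlusion(t0, t1):
        return any(t0 < e and s < t1 for s, e in occ_bounds)

    def refine(idx, positive_going):
        # snap a smoothed-flow crossing to the nearest raw-flow crossing;
        # the moving average leads the true crossing when the preceding
        # flow hovers near zero
        lo = max(1, idx - 6)
        hi = min(rec.n_samples - 1, idx + 6)
        raw = rec.flow
        best, dist = idx, len(raw)
        for j in range(lo, hi + 1):
            hit = (raw[j - 1] <= 0.0 < raw[j]) if positive_going \
                else (raw[j - 1] > 0.0 >= raw[j])
            if hit and abs(j - idx) < dist:
                best, dist = j, abs(j - idx)
        return best

    breaths: list[Breath] = []
    for k, p in enumerate(pos_cross):
        ends = neg_cross[neg_cross > p]
        if ends.size == 0:
            break
        p = refine(int(p), True)
        e = refine(int(ends[0]), False)
        t0, t1 = p * dt, e * dt
        if (t1 - t0) < min_insufflation:
            continue
        if flow_s[p:e].max() < min_peak_flow:
            continue
        if overlaps_occlusion(t0, t1):
            continue
        nxt = pos_cross[pos_cross > e]
        exp_end = float(nxt[0] * dt) if nxt.size else rec.time[-1]
        for s, oe in occ_bounds:
            if t1 <= s < exp_end:
                exp_end = s
                break
        vt = float(np.trapezoid(rec.flow[p:e + 1], dx=dt))
        breaths.append(Breath(insufflation_start=t0, insufflation_end=t1,
                              expiration_end=exp_end, tidal_volume=max(vt, 0.0)))
    if detect_onsets:
        for b in breaths:
            try:
                b.effort_onset = detect_effort_onset(rec, b)
            except WindowError:
                b.effort_onset = None
    return breaths


def detect_effort_onset(rec: WaveformRecording, breath: Breath, *,
                        slope_threshold: float = ONSET_SLOPE,
                        persistence: float = ONSET_PERSIST,
                        pre_window: float = 1.5,
                        max_lead: float = 1.0,
                        smooth_window: float = SMOOTH_WINDOW,
                        ) -> float | None:
    """Esophageal effort onset preceding a breath, or ``None`` if passive.

    Scans the smoothed Pes derivative over the pre-insufflation window; the
    onset is where the derivative falls below ``slope_threshold``
    (cmH2O/s) and stays below it for ``persistence`` seconds, backtracked
    to the local Pes maximum.  The onset is clamped to at most ``max_lead``
    seconds before the insufflation start: when the effort deflection
    merges with the passive expiratory Pes decay the unbounded backtrack
    would wander into the previous breath.  Raises :class:`WindowError`
    when less than 300 ms of pre-insufflation signal is available.
    """
    fs = rec.sample_rate
    dt = 1.0 / fs
    i_ins = rec.index_at(breath.insufflation_start)
    i_lo = max(0, rec.index_at(breath.insufflation_start - pre_window))
    if (i_ins - i_lo) * dt < 0.300:
        raise WindowError(
            f"pre-insufflation window {(i_ins - i_lo) * dt * 1e3:.0f} ms < 300 ms")
    # include a short stretch into the insufflation so onsets right at the
    # trigger are not missed
    i_hi = min(rec.n_samples - 1, i_ins + int(round(0.100 * fs)))
    pes_s = smooth(rec.pes[i_lo:i_hi + 1], fs, smooth_window)
    deriv = np.gradient(pes_s, dt)
    below = deriv < slope_threshold
    need = max(1, int(round(persistence * fs)))
    # sustained below-threshold runs; the effort is the run closest to the
    # insufflation (an earlier run is the passive expiratory Pes decay,
    # which also falls faster than the slope threshold)
    starts = []
    run = 0
    for j, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run == need:
            starts.append(j - need + 1)
    if not starts:
        return None
    start = starts[-1]
    # Locate the slope break.  Approaching the onset, the passive
    # expiratory Pes decay flattens (derivative rising toward zero) and
    # the effort then plunges it, so the derivative peaks at the onset.
    # When the effort deflection merges with a still-active expiratory
    # decay into one sustained run, that peak lies inside the run, so the
    # search spans from shortly before the run start up to the
    # insufflation: take the last sample within 1 cmH2O/s of the peak.
    lo = max(0, start - int(round(0.500 * fs)))
    hi = min(deriv.size - 1, max(start, i_ins - i_lo))
    window = deriv[lo:hi + 1]
    peak = float(window.max())
    near_peak = np.flatnonzero(window >= peak - 1.0)
    j = lo + int(near_peak[-1])
    onset = (i_lo + j) * dt
    return float(max(onset, breath.insufflation_start - max_lead))
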