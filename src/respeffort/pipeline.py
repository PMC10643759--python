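"""End-to-end orchestration: simulate -> analyze -> evaluate.

`analyze_level` turns one recording into the per-level effort summary and
occlusion indices; `analyze_dataset` walks a titration cohort (estimating
chest-wall elastance at each patient's highest support level and reusing it
below, the way the offline analysis is done); `evaluate_dataset` classifies
effort and produces the diagnostic-accuracy report tables.  Everything here
is thin glue over the measurement modules — no physiology lives in this
file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .effort import EffortMeasures, estimate_ecw, estimate_ers, summarize_level
from .errors import (DataError, LevelMissing, LevelSkipped, QCRejected,
                     RespEffortError)
from .events import (OcclusionEvent, detect_occlusions, segment_breaths, smooth)
from .occlusion import (PawIndices, QCThresholds, average_maneuvers,
                        compute_dpocc, compute_p01, compute_pmi,
                        qc_end_insp_occlusion)
from .recording import WaveformRecording
from .simulator import LevelRecord

log = logging.getLogger("respeffort")

INDEX_COLUMNS = ("p01", "dpocc", "pmi")
CRITERIA = ("pmus", "ptp_min")


@dataclass
class LevelAnalysis:
    """All measurements extracted from one per-level recording."""

    patient_id: str
    ps: float
    effort: EffortMeasures | None
    indices: PawIndices
    ecw_used: float | None
    ers: float | None = None
    skip_reason: str | None = None
    breaths: list = field(default_factory=list)
    occlusions: list = field(default_factory=list)


def _occluded_volume(rec: WaveformRecording, occ: OcclusionEvent) -> float | None:
    """Volume trapped at the start of an end-inspiratory hold."""
    fs = rec.sample_rate
    flow_s = smooth(rec.flow, fs)
    i0 = rec.index_at(occ.start)
    pos = np.flatnonzero((flow_s[:-1] <= 0) & (flow_s[1:] > 0)) + 1
    starts = pos[pos < i0]
    if starts.size == 0:
        return None
    p = int(starts[-1])
    return float(np.trapezoid(flow_s[p:i0 + 1], dx=1.0 / fs))


def _pes_plateau(rec: WaveformRecording, occ: OcclusionEvent,
                 at: float = 1.0, window: float = 0.050) -> float:
    i0 = rec.index_at(occ.start)
    c = i0 + int(round(at * rec.sample_rate))
    h = max(1, int(round(window * rec.sample_rate / 2)))
    return float(np.mean(rec.pes[c - h:c + h]))


def _paw_plateau(rec: WaveformRecording, occ: OcclusionEvent,
                 at: float = 1.0, window: float = 0.050) -> float:
    i0 = rec.index_at(occ.start)
    c = i0 + int(round(at * rec.sample_rate))
    h = max(1, int(round(window * rec.sample_rate / 2)))
    return float(np.mean(rec.paw[c - h:c + h]))


def _pes_end_expiratory(rec: WaveformRecording, breaths) -> float | None:
    """Median pre-onset Pes baseline over breaths with a detected onset."""
    fs = rec.sample_rate
    vals = []
    for b in breaths:
        anchor = b.effort_onset if b.effort_onset is not None else b.insufflation_start
        i = rec.index_at(anchor)
        j = max(0, i - int(round(0.100 * fs)))
        if i > j:
            vals.append(float(np.mean(rec.pes[j:i])))
    return float(np.median(vals)) if vals else None


def estimate_ecw_from_level(rec: WaveformRecording,
                            qc_thresholds: QCThresholds | None = None,
                            ) -> float | None:
    """Chest-wall elastance from the first accepted end-inspiratory hold.

    Meant for the highest support level, where residual effort is minimal:
    ecw = (occluded Pes plateau - end-expiratory Pes) / trapped volume.
    """
    occs = detect_occlusions(rec)
    breaths = segment_breaths(rec, occlusions=occs)
    for occ in occs:
        if occ.kind != "end_inspiratory":
            continue
        if qc_end_insp_occlusion(rec, occ, qc_thresholds) != "accepted":
            continue
        vt = _occluded_volume(rec, occ)
        pes_ee = _pes_end_expiratory(rec, breaths)
        if vt and vt > 0.05 and pes_ee is not None:
            try:
                ecw = estimate_ecw(_pes_plateau(rec, occ), pes_ee, vt)
            except RespEffortError:
                continue
            if ecw > 0:
                return ecw
    return None


def analyze_level(rec: WaveformRecording, ecw: float, *,
                  qc_thresholds: QCThresholds | None = None,
                  window: float = 60.0) -> LevelAnalysis:
    """Measure one per-level recording with a known chest-wall elastance."""
    meta = rec.meta
    pid = str(meta.get("patient_id", ""))
    ps = float(meta.get("ps_level", np.nan))
    peep = float(meta.get("peep_set", np.nan))

    occs = detect_occlusions(rec)
    breaths = segment_breaths(rec, occlusions=occs)
    indices = PawIndices()

    for occ in occs:
        if occ.kind == "end_expiratory":
            try:
                indices.p01_values.append(compute_p01(rec, occ))
            except RespEffortError:
                indices.p01_values.append(None)
            indices.dpocc_values.append(compute_dpocc(rec, occ))
        else:
            status = qc_end_insp_occlusion(rec, occ, qc_thresholds)
            indices.qc_statuses.append(status)
            if status == "accepted":
                try:
                    indices.pmi_values.append(compute_pmi(rec, occ, qc_status=status))
                except (QCRejected, RespEffortError):
                    indices.pmi_values.append(None)
    try:
        indices.p01, indices.n_ee_averaged = average_maneuvers(indices.p01_values)
        indices.dpocc, _ = average_maneuvers(indices.dpocc_values)
    except LevelMissing:
        pass
    try:
        indices.pmi, indices.n_ei_averaged = average_maneuvers(indices.pmi_values)
    except LevelMissing:
        indices.pmi = None

    effort = None
    skip = None
    try:
        effort = summarize_level(rec, breaths, ecw, occlusions=occs, window=window)
    except (LevelSkipped, DataError) as exc:
        skip = str(exc)

    # Ers from an accepted end-inspiratory plateau at this level
    ers = None
    peepi = effort.peepi if effort and effort.peepi is not None else 0.0
    if np.isfinite(peep):
        for occ, status in zip(
                [o for o in occs if o.kind == "end_inspiratory"],
                indices.qc_statuses):
            if status != "accepted":
                continue
            vt = _occluded_volume(rec, occ)
            if vt and vt > 0.05:
                ers = estimate_ers(_paw_plateau(rec, occ), peep + peepi, vt)
                break
    if effort is not None and ers is not None:
        effort.ers = ers

    return LevelAnalysis(patient_id=pid, ps=ps, effort=effort, indices=indices,
                         ecw_used=ecw, ers=ers, skip_reason=skip,
                         breaths=breaths, occlusions=occs)


def analyze_dataset(records: list[LevelRecord], *,
                    qc_thresholds: QCThresholds | None = None,
                    window: float = 60.0) -> pd.DataFrame:
    """Analyze a titration cohort into one row per patient x PS level.

    Chest-wall elastance is estimated once per patient at the highest
    support level (falling back to the next level when no hold is
    accepted there) and reused across that patient's levels.  Rows carry
    the measured quantities side by side with the simulator ground truth.
    """
    by_patient: dict[str, list[LevelRecord]] = {}
    for lr in records:
        by_patient.setdefault(lr.patient_id, []).append(lr)

    rows = []
    for pid, levels in by_patient.items():
        levels = sorted(levels, key=lambda lr: -lr.ps)
        ecw = None
        for lr in levels:
            ecw = estimate_ecw_from_level(lr.recording, qc_thresholds)
            if ecw is not None:
                break
        if ecw is None:
            log.warning("patient %s: no usable occlusion for Ecw; skipped", pid)
            continue
        for lr in levels:
            la = analyze_level(lr.recording, ecw, qc_thresholds=qc_thresholds,
                               window=window)
            truth = lr.truth
            summary = truth.level_summary()
            occ_truth = {
                "truth_p01": _mean_or_nan([o.p01 for o in truth.occlusions
                                           if o.kind == "end_expiratory"]),
                "truth_dpocc": _mean_or_nan([o.dpocc for o in truth.occlusions
                                             if o.kind == "end_expiratory"]),
                "truth_pmi": _mean_or_nan([o.pmi for o in truth.occlusions
                                           if o.kind == "end_inspiratory"]),
            }
            qc = la.indices.qc_statuses
            rows.append({
                "patient_id": pid, "ps": lr.ps,
                "pmus_max": la.effort.pmus_max if la.effort else np.nan,
                "ptp_breath": la.effort.ptp_breath if la.effort else np.nan,
                "ptp_min": la.effort.ptp_min if la.effort else np.nan,
                "respiratory_rate": la.effort.respiratory_rate if la.effort else np.nan,
                "peepi": la.effort.peepi if la.effort and la.effort.peepi is not None else np.nan,
                "ecw": ecw, "ers": la.ers if la.ers is not None else np.nan,
                "n_breaths": la.effort.n_breaths_averaged if la.effort else 0,
                "p01": _nan(la.indices.p01), "dpocc": _nan(la.indices.dpocc),
                "pmi": _nan(la.indices.pmi),
                "n_ee": la.indices.n_ee_averaged,
                "n_ei": la.indices.n_ei_averaged,
                "qc_short_plateau": qc.count("short_plateau"),
                "qc_air_leak": qc.count("air_leak"),
                "qc_extra_insp": qc.count("extra_insp_effort"),
                "qc_extra_exp": qc.count("extra_exp_effort"),
                "truth_pmus_max": summary["pmus_max"],
                "truth_ptp_min": summary["ptp_min"],
                "truth_peepi": truth.patient.peepi if truth.patient else np.nan,
                "truth_ecw": truth.patient.ecw if truth.patient else np.nan,
                "truth_ers": truth.patient.ers if truth.patient else np.nan,
                **occ_truth,
            })
    return pd.DataFrame(rows)


def _mean_or_nan(vals):
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else np.nan


def _nan(v):
    return np.nan if v is None else v


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_dataset(df: pd.DataFrame, seed: int = 0, *,
                     reference: str = "measured") -> dict:
    """Diagnostic-accuracy report for the three indices.

    ``reference`` selects the effort columns used as the class reference:
    the Pes-derived measurements (``measured``, the study design) or the
    simulator truth (``truth``).  Returns a dict with:

    - ``diagnostics``: DataFrame, one row per task (low/high) x criterion
      (pmus / ptp_min) x index, with AUC (DeLong CI), Youden cutoff,
      sensitivity/specificity/PPV/NPV (exact CIs) and tenfold
      cross-validated pooled performance;
    - ``reference_intervals``: DataFrame of 10th/90th-percentile limits
      per index and criterion with bootstrap CIs and grey-zone fractions;
    - ``association``: DataFrame of between-/within-patient R^2 of each
      index against each reference quantity.
    """
    pref = "" if reference == "measured" else "truth_"
    ref_cols = {"pmus": f"{pref}pmus_max", "ptp_min": f"{pref}ptp_min"}
    diag_rows, ri_rows, assoc_rows = [], [], []

    for criterion in CRITERIA:
        ref = df[ref_cols[criterion]]
        classes = ref.apply(
            lambda v: dx.classify_effort(v, criterion).label
            if np.isfinite(v) else None)
        for task, direction in (("low", "lesser"), ("high", "greater")):
            labels_all = (classes == task).astype(int)
            for index in INDEX_COLUMNS:
                ok = df[index].notna() & classes.notna()
                scores = df.loc[ok, index].to_numpy()
                labels = labels_all[ok].to_numpy()
                row = {"task": task, "criterion": criterion, "index": index,
                       "n": int(ok.sum()), "n_positive": int(labels.sum())}
                try:
                    res = dx.roc_auc(scores, labels, direction)
                    cut, j = dx.youden_cutoff(scores, labels, direction)
                    res.youden_j = j
                    res = dx.confusion_stats(scores, labels, cut, direction,
                                             result=res)
                    cv = dx.cross_validate_tenfold(scores, labels, direction,
                                                   seed=seed)
                    res.per_fold_cutoffs = cv["fold_cutoffs"]
                    row.update({
                        "auc": res.auc, "auc_lo": res.auc_ci[0],
                        "auc_hi": res.auc_ci[1], "cutoff": res.cutoff,
                        "youden_j": res.youden_j,
                        "sensitivity": res.sensitivity,
                        "specificity": res.specificity,
                        "ppv": res.ppv, "npv": res.npv,
                        "cv_sensitivity": cv["pooled"]["sensitivity"],
                        "cv_specificity": cv["pooled"]["specificity"],
                        "cv_cutoff_sd": float(np.std(cv["fold_cutoffs"]))
                        if cv["fold_cutoffs"] else np.nan,
                    })
                except RespEffortError as exc:
                    row["error"] = str(exc)
                diag_rows.append(row)

        # reference intervals: limits fitted on the acceptable-effort band,
        # grey zone read over all classified levels (literal definition:
        # outside [lower, upper])
        for index in INDEX_COLUMNS:
            ok_all = df[index].notna() & classes.notna()
            band = ok_all & (classes == "intermediate")
            try:
                ri = dx.reference_interval(df.loc[band, index].to_numpy(),
                                           seed=seed)
                vals = df.loc[ok_all, index].to_numpy()
                grey_all = float(np.mean((vals < ri.lower) | (vals > ri.upper)))
                ri_rows.append({
                    "criterion": criterion, "index": index,
                    "lower": ri.lower, "upper": ri.upper,
                    "lower_ci_lo": ri.lower_ci[0], "lower_ci_hi": ri.lower_ci[1],
                    "upper_ci_lo": ri.upper_ci[0], "upper_ci_hi": ri.upper_ci[1],
                    "grey_zone_fraction": grey_all,
                    "n_reference": int(band.sum())})
            except RespEffortError as exc:
                ri_rows.append({"criterion": criterion, "index": index,
                                "error": str(exc)})

        for index in INDEX_COLUMNS:
            ok = df[index].notna() & ref.notna()
            try:
                between, within = dx.variance_explained(
                    df.loc[ok, index], ref[ok], df.loc[ok, "patient_id"])
                assoc_rows.append({"criterion": criterion, "index": index,
                                   "r2_between": between, "r2_within": within})
            except RespEffortError as exc:
                assoc_rows.append({"criterion": criterion, "index": index,
                                   "error": str(exc)})

    return {"diagnostics": pd.DataFrame(diag_rows),
            "reference_intervals": pd.DataFrame(ri_rows),
            "association": pd.DataFrame(assoc_rows)}
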