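"""Multi-channel respiratory waveform recordings and their text dialect.

A :class:`WaveformRecording` holds synchronized flow, airway-pressure (Paw)
and esophageal-pressure (Pes) channels on a uniform time grid, with the
acquisition metadata needed downstream (set PEEP, pressure-support level,
patient id).  Units are fixed internally: flow in L/s with inspiration
positive, pressures in cmH2O (absolute, not relative to PEEP).

Files are plain delimited text: ``# key=value`` metadata lines, a header row
``time_s,flow_lps,paw_cmh2o,pes_cmh2o`` (comma or tab, auto-detected), one
row per sample.  The dialect is deliberately diff-friendly; vendor export
formats (EDF, WFDB, proprietary ICU software) are out of scope.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, GridError, MissingChannel, ValidationError

DEFAULT_SAMPLE_RATE = 200.0  # Hz
GRID_RTOL = 1e-9

_CHANNEL_HEADER = ("time_s", "flow_lps", "paw_cmh2o", "pes_cmh2o")
# scale factors into internal units, keyed by recognised header aliases
_UNIT_ALIASES = {
    "flow_lps": 1.0,
    "flow_lpm": 1.0 / 60.0,   # L/min -> L/s
    "flow_mls": 1e-3,         # mL/s -> L/s
    "paw_cmh2o": 1.0,
    "paw_hpa": 1.01972,       # hPa -> cmH2O
    "pes_cmh2o": 1.0,
    "pes_hpa": 1.01972,
}


@dataclass
class WaveformRecording:
    """Synchronized flow/Paw/Pes channels on a uniform grid.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing, constant step.
    flow : array of float
        Flow in L/s, inspiration positive.
    paw : array of float
        Airway pressure in cmH2O.
    pes : array of float
        Esophageal pressure in cmH2O.
    sample_rate : float
        Samples per second; the time step must equal ``1/sample_rate``.
    meta : dict
        Free-form metadata; recognised keys are ``patient_id``, ``ps_level``
        (cmH2O), ``peep_set`` (cmH2O) and ``label``.
    """

    time: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    pes: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)
        self.pes = np.asarray(self.pes, dtype=float)

    # -- basic geometry -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Recording span in seconds (n_samples / sample_rate)."""
        return self.n_samples / self.sample_rate

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to range)."""
        i = int(round((t - self.time[0]) * self.sample_rate))
        return min(max(i, 0), self.n_samples - 1)

    def validate(self) -> None:
        """Raise :class:`ValidationError` on the first violated invariant."""
        issues = validate_recording(self)
        if issues:
            raise ValidationError("; ".join(i.message for i in issues))


@dataclass
class ValidationIssue:
    kind: str        # "grid" | "nan" | "range" | "structure"
    channel: str
    index: int | None
    message: str


def validate_recording(
    rec: WaveformRecording,
    pressure_bounds: tuple[float, float] = (-50.0, 80.0),
) -> list[ValidationIssue]:
    """Report-only structural check of a recording.

    Returns a list of :class:`ValidationIssue`; an empty list means the
    recording satisfies every invariant (uniform grid at ``1/sample_rate``,
    equal channel lengths >= 2, finite values, pressures within
    ``pressure_bounds``).
    """
    issues: list[ValidationIssue] = []
    n = rec.time.size
    if rec.sample_rate <= 0:
        issues.append(ValidationIssue("structure", "", None, "sample_rate must be > 0"))
        return issues
    if n < 2:
        issues.append(ValidationIssue("structure", "time", None, "need at least 2 samples"))
        return issues
    for name in ("flow", "paw", "pes"):
        ch = getattr(rec, name)
        if ch.size != n:
            issues.append(ValidationIssue(
                "structure", name, None,
                f"channel '{name}' length {ch.size} != time length {n}"))
    if issues:
        return issues

    dt = 1.0 / rec.sample_rate
    steps = np.diff(rec.time)
    # relative tolerance on each step; absorbs float accumulation on long grids
    rel_bad = np.flatnonzero(np.abs(steps / dt - 1.0) > 1e-6)
    for i in rel_bad[:10]:
        issues.append(ValidationIssue(
            "grid", "time", int(i),
            f"time step at index {i} is {steps[i]:.9g}s, expected {dt:.9g}s"))
    if np.any(steps <= 0):
        issues.append(ValidationIssue("grid", "time", None, "time not strictly increasing"))

    for name in ("flow", "paw", "pes"):
        ch = getattr(rec, name)
        nan_idx = np.flatnonzero(~np.isfinite(ch))
        for i in nan_idx[:10]:
            issues.append(ValidationIssue(
                "nan", name, int(i), f"non-finite value in '{name}' at index {i}"))
        if nan_idx.size > 10:
            issues.append(ValidationIssue(
                "nan", name, None, f"... {nan_idx.size} non-finite values in '{name}' total"))
    lo, hi = pressure_bounds
    for name in ("paw", "pes"):
        ch = getattr(rec, name)
        finite = ch[np.isfinite(ch)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            issues.append(ValidationIssue(
                "range", name, None,
                f"'{name}' outside physical bounds [{lo}, {hi}] cmH2O "
                f"(range {finite.min():.2f}..{finite.max():.2f})"))
    return issues


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

def _coerce_meta(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def read_recording(path: str | Path) -> WaveformRecording:
    """Read a channel file written by :func:`write_recording`.

    Delimiter (comma or tab) is auto-detected from the header row; unit
    suffixes in the header select the conversion into internal units.
    Raises :class:`MissingChannel`, :class:`GridError` or
    :class:`FormatError` (with the offending line number) as appropriate.
    """
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = _coerce_meta(val.strip())
                continue
            if header is None:
                delim = "\t" if "\t" in line else ","
                header = [c.strip().lower() for c in line.split(delim)]
                continue
            parts = line.split(delim)
            if len(parts) != len(header):
                raise FormatError(
                    f"expected {len(header)} fields, got {len(parts)}", line=lineno)
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(str(exc), line=lineno) from None
    if header is None or not rows:
        raise FormatError(f"no data rows in {path}")

    cols = {name: i for i, name in enumerate(header)}
    if "time_s" not in cols:
        raise MissingChannel("channel file lacks 'time_s' column")
    data = np.asarray(rows, dtype=float)

    def channel(prefix: str) -> np.ndarray:
        for name, scale in _UNIT_ALIASES.items():
            if name.startswith(prefix) and name in cols:
                return data[:, cols[name]] * scale
        raise MissingChannel(f"channel file lacks a '{prefix}' column")

    time = data[:, cols["time_s"]]
    sample_rate = float(meta.pop("sample_rate_hz", 0.0)) or None
    if sample_rate is None:
        if time.size < 2:
            raise GridError("cannot infer sample rate from a single sample")
        sample_rate = 1.0 / float(np.median(np.diff(time)))
        sample_rate = round(sample_rate, 6)
    steps = np.diff(time)
    if steps.size and np.any(np.abs(steps * sample_rate - 1.0) > 1e-6):
        raise GridError("non-uniform time grid beyond tolerance")

    rec = WaveformRecording(
        time=time, flow=channel("flow"), paw=channel("paw"), pes=channel("pes"),
        sample_rate=sample_rate, meta=meta)
    issues = validate_recording(rec)
    structural = [i for i in issues if i.kind in ("structure", "nan")]
    if structural:
        raise ValidationError("; ".join(i.message for i in structural))
    return rec


def write_recording(rec: WaveformRecording, path: str | Path,
                    precision: int = 6, delimiter: str = ",") -> None:
    """Write ``rec`` as delimited text invertible by :func:`read_recording`.

    Values are printed at ``precision`` significant decimals; metadata go in
    ``# key=value`` comment lines including the sample rate.
    """
    issues = validate_recording(rec)
    structural = [i for i in issues if i.kind in ("structure", "nan", "grid")]
    if structural:
        raise ValidationError("cannot write invalid recording: "
                              + "; ".join(i.message for i in structural))
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# sample_rate_hz={rec.sample_rate:g}\n")
    for key, val in rec.meta.items():
        buf.write(f"# {key}={val}\n")
    buf.write(delimiter.join(_CHANNEL_HEADER) + "\n")
    fmt = f"%.{precision}f"
    stacked = np.column_stack([rec.time, rec.flow, rec.paw, rec.pes])
    for row in stacked:
        buf.write(delimiter.join(fmt % v for v in row) + "\n")
    path.write_text(buf.getvalue())
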