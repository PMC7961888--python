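"""Readers and writers for all on-disk artifacts.

Everything is plain, diff-able text:

* recordings / envelopes / force traces — comma-separated time series with
  ``#``-prefixed header lines (format tag, sampling rate, channel labels,
  units, JSON metadata) and one row per sample;
* calibration profiles and score tables — JSON documents;
* session logs — a ``#`` header plus one CSV record per trial with a
  running cumulative score.

Counts round-trip bit-exactly; floating-point series are serialized at
full precision.  All schema violations raise :class:`FormatError` with a
line number where known; nothing is silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ScoreTableError
from .games import ScoreBin, ScoreTable, SessionLog, TrialResult
from .pipeline import CalibrationProfile, Envelope, PipelineConfig
from .recording import COUNTS, VOLTS, EmgRecording

_REC_TAG = "emgseries v1"
_LOG_TAG = "emglog v1"
_PROFILE_TAG = "calprofile v1"
_TABLE_TAG = "scoretable v1"

#: counts↔volts convention used throughout: volts = counts * supply_v / (2**bits - 1)
SERIES_UNITS = (COUNTS, VOLTS, "normalized", "fraction_mvc")


def _parse_header(path: Path) -> tuple[dict, int]:
    """Read ``# key=value`` lines; returns (header dict, body start line index)."""
    header: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                return header, lineno
            body = line[1:].strip()
            if not body:
                continue
            if "=" in body:
                key, _, val = body.partition("=")
                header[key.strip()] = val.strip()
            else:
                header.setdefault("format", body)
    return header, lineno + 1


def _write_series(
    fs_hz: float,
    channels: tuple[str, ...],
    samples: np.ndarray,
    units: str,
    meta: dict,
    path: str | Path,
) -> None:
    is_int = np.issubdtype(samples.dtype, np.integer)
    n = samples.shape[1]
    t = np.arange(n) / fs_hz
    with open(path, "w") as fh:
        fh.write(f"# {_REC_TAG}\n")
        fh.write(f"# fs_hz={fs_hz!r}\n")
        fh.write(f"# channels={','.join(channels)}\n")
        fh.write(f"# units={units}\n")
        fh.write(f"# meta={json.dumps(meta, sort_keys=True)}\n")
        fh.write("time_s," + ",".join(channels) + "\n")
        fmt = "%d" if is_int else "%.17g"
        for i in range(n):
            row = ",".join(fmt % v for v in samples[:, i])
            fh.write(f"{t[i]:.7f},{row}\n")


def write_recording(rec: EmgRecording, path: str | Path) -> None:
    """Serialize a recording as delimited text."""
    _write_series(rec.fs_hz, rec.channels, rec.samples, rec.units, rec.meta, path)


def read_series(path: str | Path) -> tuple[float, tuple[str, ...], np.ndarray, str, dict]:
    """Parse any delimited series file: ``(fs_hz, channels, samples, units, meta)``."""
    path = Path(path)
    header, body_line = _parse_header(path)
    if header.get("format") != _REC_TAG:
        raise FormatError(f"not a {_REC_TAG} file: format={header.get('format')!r}", line=1)
    try:
        fs_hz = float(header["fs_hz"])
        channels = tuple(header["channels"].split(","))
        units = header["units"]
        meta = json.loads(header.get("meta", "{}"))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"bad header: {exc}", line=1) from exc
    if units not in SERIES_UNITS:
        raise FormatError(f"unknown units {units!r}", line=1)
    try:
        body = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"unparseable body: {exc}", line=body_line) from exc
    cols = list(body.columns)
    if cols[0] != "time_s" or tuple(cols[1:]) != channels:
        raise FormatError(
            f"column header {cols} does not match declared channels {list(channels)}",
            line=body_line,
        )
    if body.isna().any().any():
        raise FormatError("ragged or missing values in body", line=body_line)
    samples = body[list(channels)].to_numpy().T
    if units == COUNTS:
        if not np.allclose(samples, np.round(samples)):
            raise FormatError("units=counts but samples are not integers", line=body_line)
        samples = samples.astype(np.int32)
    return fs_hz, channels, samples, units, meta


def read_recording(path: str | Path) -> EmgRecording:
    """Parse a raw recording file (counts or volts); lossless for counts."""
    fs_hz, channels, samples, units, meta = read_series(path)
    if units not in (COUNTS, VOLTS):
        raise FormatError(
            f"units {units!r} is not a raw recording; use read_series", line=1
        )
    return EmgRecording(fs_hz=fs_hz, channels=channels, samples=samples, units=units, meta=meta)


def write_envelope(env: Envelope, path: str | Path) -> None:
    """Serialize a processed envelope; reuses the series format with units=normalized."""
    _write_series(
        env.fs_hz, env.channels, env.values, "normalized",
        {"calibration": env.calibration}, path,
    )


def write_force(force_values: np.ndarray, fs_hz: float, path: str | Path) -> None:
    """Serialize a force trace (fraction of MVC) as a one-channel series."""
    _write_series(
        fs_hz, ("force",), np.atleast_2d(np.asarray(force_values, dtype=float)),
        "fraction_mvc", {}, path,
    )


def write_profile(profile: CalibrationProfile, path: str | Path) -> None:
    doc = {
        "format": _PROFILE_TAG,
        "amplitudes": profile.amplitudes,
        "window_s": profile.window_s,
        "stat": profile.stat,
        "units": profile.units,
        "source": profile.source,
        "created": profile.created,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_profile(path: str | Path) -> CalibrationProfile:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON: {exc}", line=exc.lineno) from exc
    if doc.get("format") != _PROFILE_TAG:
        raise FormatError(f"not a {_PROFILE_TAG} document")
    try:
        return CalibrationProfile(
            amplitudes={k: float(v) for k, v in doc["amplitudes"].items()},
            window_s=float(doc["window_s"]),
            stat=doc.get("stat", "windowed_max"),
            units=doc.get("units", COUNTS),
            source=doc.get("source", ""),
            created=doc.get("created"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"bad calibration profile: {exc}") from exc


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    doc = {
        "format": _TABLE_TAG,
        "bins": [
            {"er_low": b.er_low, "er_high": b.er_high,
             "outcomes": [[pts, p] for pts, p in b.outcomes]}
            for b in table.bins
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_score_table(path: str | Path) -> ScoreTable:
    """Parse and validate a score table (probability sums checked on construction)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON: {exc}", line=exc.lineno) from exc
    if doc.get("format") != _TABLE_TAG:
        raise FormatError(f"not a {_TABLE_TAG} document")
    try:
        bins = tuple(
            ScoreBin(
                er_low=float(b["er_low"]), er_high=float(b["er_high"]),
                outcomes=tuple((int(pts), float(p)) for pts, p in b["outcomes"]),
            )
            for b in doc["bins"]
        )
        return ScoreTable(bins=bins)
    except (KeyError, TypeError, ValueError, ScoreTableError) as exc:
        raise FormatError(f"bad score table: {exc}") from exc


_LOG_COLUMNS = "trial,onset_s,er,ext_mean,flex_mean,points,bin,degenerate,cumulative"


def write_session_log(log: SessionLog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_LOG_TAG}\n")
        fh.write(f"# meta={json.dumps(log.meta, sort_keys=True)}\n")
        fh.write(_LOG_COLUMNS + "\n")
        acc = 0
        for t in log.trials:
            acc += t.points
            fh.write(
                f"{t.index},{t.onset_s:.6f},{t.er:.9f},{t.ext_mean:.9g},"
                f"{t.flex_mean:.9g},{t.points},{t.bin},{int(t.degenerate)},{acc}\n"
            )


def read_session_log(path: str | Path) -> SessionLog:
    """Parse a session log; re-checks the cumulative-score invariant."""
    path = Path(path)
    header, body_line = _parse_header(path)
    if header.get("format") != _LOG_TAG:
        raise FormatError(f"not a {_LOG_TAG} file", line=1)
    meta = json.loads(header.get("meta", "{}"))
    body = pd.read_csv(path, comment="#")
    if list(body.columns) != _LOG_COLUMNS.split(","):
        raise FormatError(f"unexpected log columns {list(body.columns)}", line=body_line)
    trials = []
    acc = 0
    for k, row in enumerate(body.itertuples(index=False)):
        acc += int(row.points)
        if int(row.cumulative) != acc:
            raise FormatError(
                f"cumulative score {row.cumulative} != running sum {acc}",
                line=body_line + k + 1,
            )
        trials.append(TrialResult(
            index=int(row.trial), onset_s=float(row.onset_s), er=float(row.er),
            ext_mean=float(row.ext_mean), flex_mean=float(row.flex_mean),
            points=int(row.points), bin=int(row.bin), degenerate=bool(row.degenerate),
        ))
    return SessionLog(trials=trials, meta=meta)


def write_summaries(summaries, path: str | Path) -> None:
    """Session summaries as a delimited table (one row per session)."""
    rows = [
        {
            "session_index": s.session_index, "ext_mean": s.ext_mean,
            "flex_mean": s.flex_mean, "er_mean": s.er_mean, "n_trials": s.n_trials,
            "score": s.score if s.score is not None else np.nan,
            "excluded": int(s.excluded), "reason": s.reason or "",
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_summaries(path: str | Path):
    from .stats import SessionSummary

    df = pd.read_csv(path)
    required = {"session_index", "ext_mean", "flex_mean", "er_mean", "excluded"}
    if not required.issubset(df.columns):
        raise FormatError(f"summary table missing columns {sorted(required - set(df.columns))}")
    out = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score", np.nan)
        out.append(SessionSummary(
            session_index=int(row.session_index),
            ext_mean=float(row.ext_mean), flex_mean=float(row.flex_mean),
            er_mean=float(row.er_mean),
            n_trials=int(getattr(row, "n_trials", 0)),
            score=None if pd.isna(score) else float(score),
            excluded=bool(row.excluded),
            reason=(str(getattr(row, "reason", "")) or None),
        ))
    return out
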