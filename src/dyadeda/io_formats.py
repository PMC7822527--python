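"""Reading and writing the pipeline's external representations.

Skin-conductance traces travel as two-column CSV (time_s, conductance_uS);
proposal annotations as Praat TextGrid interval tiers or a simpler columnar
CSV; participant metadata, rate tables and stats reports as CSV/JSON.

TextGrid convention: proposals live on a single interval tier named
``proposals``; each non-empty interval's label is ``proposer_id;response``
where response is one of ``accepting``, ``non_accepting``, ``rejecting``.
Empty-label intervals are the gaps between proposals.

All times are seconds on a common clock; intervals are half-open
``[t_start, t_end)``.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

RESPONSE_CATEGORIES = ("accepting", "non_accepting", "rejecting")

#: Relative tolerance on sample spacing when inferring the sampling rate
#: from a time column (device clocks print rounded timestamps).
_FS_RTOL = 1e-3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SCTrace:
    """One participant's raw skin-conductance series.

    Parameters
    ----------
    participant_id, dyad_id
        Opaque labels.
    fs
        Sampling rate in Hz (the study hardware records at 128 Hz).
    t0
        Time of the first sample in seconds; sample ``k`` is at
        ``t0 + k / fs``.
    samples
        Conductance in microsiemens.
    """

    participant_id: str
    dyad_id: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise FormatError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise FormatError(f"non-finite conductance at sample {bad}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class ProposalEvent:
    """One annotated proposal with its response category."""

    dyad_id: str
    event_id: str
    proposer_id: str
    t_start: float
    t_end: float
    response: str

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise FormatError(
                f"event {self.event_id}: t_start {self.t_start} must precede "
                f"t_end {self.t_end}"
            )
        if self.response not in RESPONSE_CATEGORIES:
            raise FormatError(
                f"event {self.event_id}: unknown response {self.response!r}; "
                f"expected one of {RESPONSE_CATEGORIES}"
            )


@dataclass(frozen=True)
class ParticipantMeta:
    """Participant metadata: dyad membership and diagnosis flag (1 = depression)."""

    participant_id: str
    dyad_id: str
    diagnosis: int

    def __post_init__(self) -> None:
        if self.diagnosis not in (0, 1):
            raise FormatError(
                f"diagnosis must be 0 or 1, got {self.diagnosis!r}"
            )


def validate_dyads(meta: Sequence[ParticipantMeta]) -> dict[str, tuple[ParticipantMeta, ParticipantMeta]]:
    """Group metadata by dyad, enforcing exactly two participants per dyad."""
    by_dyad: dict[str, list[ParticipantMeta]] = {}
    for m in meta:
        by_dyad.setdefault(m.dyad_id, []).append(m)
    out = {}
    for dyad_id, members in by_dyad.items():
        if len(members) != 2:
            raise DataError(
                f"dyad {dyad_id} has {len(members)} participants, expected 2"
            )
        out[dyad_id] = (members[0], members[1])
    return out


# ---------------------------------------------------------------------------
# SC traces
# ---------------------------------------------------------------------------

def read_sc_trace(
    path: str | Path,
    participant_id: str,
    dyad_id: str,
    fs: float | None = None,
) -> SCTrace:
    """Read a trace from two-column (time_s, conductance_uS) or single-column CSV.

    Two-column files must be uniformly sampled: the sampling rate is inferred
    from the time spacing and non-uniform timestamps are rejected rather than
    resampled. Single-column files require an explicit ``fs``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trace file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] == 1:
        if fs is None:
            raise FormatError(
                f"{path}: single-column trace needs an explicit sampling rate"
            )
        samples = df.iloc[:, 0].to_numpy(dtype=float)
        t0 = 0.0
    elif df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        samples = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            # dt[i] spans data rows i+1, i+2 -> file lines i+2, i+3 (header)
            line = int(np.flatnonzero(dt <= 0)[0]) + 3
            raise FormatError(f"{path}: time column not increasing at line {line}")
        if dt.max() - dt.min() > _FS_RTOL * dt.mean():
            raise FormatError(f"{path}: non-uniform sampling; resampling is not done here")
        inferred = 1.0 / dt.mean()
        if fs is not None and abs(inferred - fs) > _FS_RTOL * fs:
            raise FormatError(
                f"{path}: declared fs {fs} Hz disagrees with spacing ({inferred:.3f} Hz)"
            )
        fs = inferred
        t0 = float(t[0])
    else:
        raise FormatError(f"{path}: expected 1 or 2 columns, got {df.shape[1]}")
    if np.any(~np.isfinite(samples)):
        line = int(np.flatnonzero(~np.isfinite(samples))[0]) + 2
        raise FormatError(f"{path}: non-finite conductance at line {line}")
    # snap near-integer rates (1/0.0078125 prints cleanly, but arbitrary
    # rounded timestamps may infer e.g. 127.9987 Hz)
    if abs(fs - round(fs)) < _FS_RTOL * fs:
        fs = float(round(fs))
    return SCTrace(participant_id=participant_id, dyad_id=dyad_id,
                   fs=float(fs), samples=samples, t0=t0)


def write_sc_trace(trace: SCTrace, path: str | Path, precision: int = 6) -> None:
    """Write a trace as two-column CSV with a header row."""
    path = Path(path)
    t = trace.times
    with open(path, "w", newline="") as fh:
        fh.write("time_s,conductance_uS\n")
        for ti, xi in zip(t, trace.samples):
            fh.write(f"{ti:.{precision + 2}f},{xi:.{precision}f}\n")


# ---------------------------------------------------------------------------
# Proposal events: columnar dialect
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["dyad_id", "event_id", "proposer_id", "t_start", "t_end", "response"]


def _sort_events(events: list[ProposalEvent]) -> list[ProposalEvent]:
    return sorted(events, key=lambda e: (e.t_start, e.t_end, e.event_id))


def read_proposal_events(
    path: str | Path,
    dialect: str = "columnar",
    dyad_id: str | None = None,
    tier_name: str = "proposals",
) -> list[ProposalEvent]:
    """Read proposal annotations, returned sorted by onset time.

    ``dialect="columnar"``: CSV with columns
    dyad_id,event_id,proposer_id,t_start,t_end,response (header optional).
    ``dialect="textgrid"``: Praat TextGrid (long text format); ``dyad_id``
    must be supplied since TextGrids carry no dyad label.

    Rejecting events are retained — excluding them is a downstream decision.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"event file not found: {path}")
    if dialect == "columnar":
        events = _read_events_columnar(path)
    elif dialect == "textgrid":
        if dyad_id is None:
            raise FormatError("TextGrid dialect needs an explicit dyad_id")
        events = _read_events_textgrid(path, dyad_id, tier_name)
    else:
        raise FormatError(f"unknown event dialect {dialect!r}")
    events = _sort_events(events)
    _warn_overlaps(events, path)
    return events


def _read_events_columnar(path: Path) -> list[ProposalEvent]:
    events = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip() == "dyad_id":
                continue  # header
            if len(row) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(row)}")
            d, e, p, ts, te, resp = (c.strip() for c in row)
            try:
                t_start, t_end = float(ts), float(te)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad time field") from exc
            try:
                events.append(ProposalEvent(d, e, p, t_start, t_end, resp))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return events


def write_proposal_events(events: Iterable[ProposalEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENT_COLUMNS)
        for e in events:
            writer.writerow([e.dyad_id, e.event_id, e.proposer_id,
                             f"{e.t_start:.6f}", f"{e.t_end:.6f}", e.response])


def _warn_overlaps(events: list[ProposalEvent], path: Path) -> None:
    by_dyad: dict[str, list[ProposalEvent]] = {}
    for e in events:
        by_dyad.setdefault(e.dyad_id, []).append(e)
    for dyad_events in by_dyad.values():
        for a, b in zip(dyad_events, dyad_events[1:]):
            if b.t_start < a.t_end:
                warnings.warn(
                    f"{path}: events {a.event_id} and {b.event_id} overlap "
                    f"([{a.t_start},{a.t_end}) vs [{b.t_start},{b.t_end})); both kept"
                )


# ---------------------------------------------------------------------------
# Proposal events: Praat TextGrid dialect (long text format)
# ---------------------------------------------------------------------------

_TG_NUM = re.compile(r"(xmin|xmax|intervals: size|size)\s*=\s*([0-9.eE+-]+)")
_TG_STR = re.compile(r'(class|name|text)\s*=\s*"((?:[^"]|"")*)"')


def _read_events_textgrid(path: Path, dyad_id: str, tier_name: str) -> list[ProposalEvent]:
    """Parse intervals off the named tier of a long-format TextGrid."""
    text = Path(path).read_text(encoding="utf-8")
    if "TextGrid" not in text.split("\n", 3)[1 if text.startswith("File type") else 0]:
        if '"TextGrid"' not in text:
            raise FormatError(f"{path}: not a TextGrid file")
    # split into item blocks: "item [k]:" headers
    blocks = re.split(r"\n\s*item \[\d+\]:", text)
    events: list[ProposalEvent] = []
    found_tier = False
    for block in blocks[1:]:
        name_m = re.search(r'name\s*=\s*"((?:[^"]|"")*)"', block)
        class_m = re.search(r'class\s*=\s*"((?:[^"]|"")*)"', block)
        if not name_m or not class_m:
            continue
        if name_m.group(1) != tier_name:
            continue
        if class_m.group(1) != "IntervalTier":
            raise FormatError(f"{path}: tier {tier_name!r} is not an IntervalTier")
        found_tier = True
        k = 0
        for im in re.finditer(
            r"intervals \[(\d+)\]:\s*\n\s*xmin = ([0-9.eE+-]+)\s*\n"
            r'\s*xmax = ([0-9.eE+-]+)\s*\n\s*text = "((?:[^"]|"")*)"',
            block,
        ):
            idx, xmin, xmax, label = im.groups()
            label = label.replace('""', '"').strip()
            if not label:
                continue
            k += 1
            if ";" not in label:
                raise FormatError(
                    f"{path}: tier {tier_name!r} interval {idx}: label {label!r} "
                    "does not match 'proposer_id;response'"
                )
            proposer_id, response = (s.strip() for s in label.split(";", 1))
            try:
                events.append(ProposalEvent(
                    dyad_id=dyad_id, event_id=f"{dyad_id}_e{k}",
                    proposer_id=proposer_id,
                    t_start=float(xmin), t_end=float(xmax), response=response,
                ))
            except FormatError as exc:
                raise FormatError(
                    f"{path}: tier {tier_name!r} interval {idx}: {exc}"
                ) from exc
    if not found_tier:
        raise FormatError(f"{path}: no interval tier named {tier_name!r}")
    return events


def write_textgrid(
    events: Sequence[ProposalEvent],
    path: str | Path,
    xmin: float,
    xmax: float,
    tier_name: str = "proposals",
) -> None:
    """Write events as a long-format Praat TextGrid with one interval tier.

    Gaps between proposals become empty-label intervals so the tier tiles
    ``[xmin, xmax]`` as Praat requires.
    """
    events = _sort_events(list(events))
    for a, b in zip(events, events[1:]):
        if b.t_start < a.t_end:
            raise DataError(
                f"cannot write overlapping events {a.event_id}/{b.event_id} to one tier"
            )
    intervals: list[tuple[float, float, str]] = []
    cursor = xmin
    for e in events:
        if e.t_start < xmin or e.t_end > xmax:
            raise DataError(f"event {e.event_id} outside TextGrid span [{xmin},{xmax}]")
        if e.t_start > cursor:
            intervals.append((cursor, e.t_start, ""))
        intervals.append((e.t_start, e.t_end, f"{e.proposer_id};{e.response}"))
        cursor = e.t_end
    if cursor < xmax:
        intervals.append((cursor, xmax, ""))
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.6f}",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        f"        xmin = {xmin:.6f}",
        f"        xmax = {xmax:.6f}",
        f"        intervals: size = {len(intervals)}",
    ]
    for i, (a, b, label) in enumerate(intervals, start=1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {a:.6f}",
            f"            xmax = {b:.6f}",
            f'            text = "{label.replace(chr(34), chr(34) * 2)}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Participant metadata, rate tables, reports
# ---------------------------------------------------------------------------

def read_participant_meta(path: str | Path) -> list[ParticipantMeta]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"metadata file not found: {path}")
    df = pd.read_csv(path)
    needed = {"participant_id", "dyad_id", "diagnosis"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: metadata needs columns {sorted(needed)}")
    return [
        ParticipantMeta(str(r.participant_id), str(r.dyad_id), int(r.diagnosis))
        for r in df.itertuples()
    ]


def write_participant_meta(meta: Iterable[ParticipantMeta], path: str | Path) -> None:
    pd.DataFrame(
        [{"participant_id": m.participant_id, "dyad_id": m.dyad_id,
          "diagnosis": m.diagnosis} for m in meta]
    ).to_csv(path, index=False)


def write_json_report(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
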