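"""Foraging event-log data model, CSV round-trip, and visit extraction.

A :class:`ForagingEventLog` is the single currency between the simulator
and the analysis: an ordered stream of position samples (time, view,
x, y) plus discrete events (patch entry, patch exit, reward pickup).
Patch visits — the unit on which leave times are scored — are recovered
by pairing entry/exit events.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Sample",
    "Event",
    "ForagingEventLog",
    "PatchVisit",
    "EventLogError",
    "read_event_log",
    "write_event_log",
    "extract_visits",
]

AERIAL = "aerial"
PATCH = "patch"

EVENT_TYPES = ("patch_enter", "patch_exit", "reward")


class EventLogError(ValueError):
    """Malformed or invariant-violating event log."""


@dataclass(frozen=True)
class Sample:
    t: float
    view: str  # "aerial" | "patch"
    patch_id: int | None
    x: float
    y: float


@dataclass(frozen=True)
class Event:
    t: float
    type: str  # "patch_enter" | "patch_exit" | "reward"
    patch_id: int
    resource_index: int | None = None


@dataclass
class ForagingEventLog:
    participant_id: str
    run_index: str  # "pre" | "post"
    duration: float
    samples: list[Sample] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)

    def reward_times(self) -> list[float]:
        return [e.t for e in self.events if e.type == "reward"]

    def validate(self) -> None:
        """Raise :class:`EventLogError` on any invariant violation."""
        if self.run_index not in ("pre", "post"):
            raise EventLogError(f"run_index must be 'pre' or 'post', got {self.run_index!r}")
        if self.duration <= 0:
            raise EventLogError("duration must be positive")
        prev = -float("inf")
        for s in self.samples:
            if not (0.0 <= s.t <= self.duration):
                raise EventLogError(f"sample time {s.t} outside [0, {self.duration}]")
            if s.t <= prev:
                raise EventLogError(f"sample times not strictly increasing at t={s.t}")
            prev = s.t
        prev = -float("inf")
        for e in self.events:
            if not (0.0 <= e.t <= self.duration):
                raise EventLogError(f"event time {e.t} outside [0, {self.duration}]")
            if e.t < prev:
                raise EventLogError(f"events not time-sorted at t={e.t}")
            prev = e.t
            if e.type not in EVENT_TYPES:
                raise EventLogError(f"unknown event type {e.type!r}")
        # every reward must fall inside an enter/exit bracket of its patch
        open_patch: int | None = None
        for e in self.events:
            if e.type == "patch_enter":
                if open_patch is not None:
                    raise EventLogError(
                        f"patch_enter at t={e.t} while patch {open_patch} still open"
                    )
                open_patch = e.patch_id
            elif e.type == "patch_exit":
                if open_patch != e.patch_id:
                    raise EventLogError(
                        f"patch_exit for patch {e.patch_id} at t={e.t} without matching entry"
                    )
                open_patch = None
            elif e.type == "reward":
                if open_patch != e.patch_id:
                    raise EventLogError(
                        f"reward at t={e.t} outside any visit of patch {e.patch_id}"
                    )


@dataclass(frozen=True)
class PatchVisit:
    """One stay inside a patch; ``t_exit`` is the actual leave time (ALT)."""

    patch_id: int
    t_enter: float
    t_exit: float
    rewards: int
    censored: bool = False  # run ended while still inside the patch


_HEADER = "t,record_type,view,patch_id,x,y,resource_index"


def _fmt(v) -> str:
    return "" if v is None else (repr(v) if isinstance(v, float) else str(v))


def write_event_log(log: ForagingEventLog, path: str | Path) -> None:
    """Write one run to CSV (metadata in leading ``#`` lines, then rows).

    Floats use shortest round-trip representation, so ``read_event_log``
    recovers every field exactly.
    """
    buf = io.StringIO()
    buf.write(f"# participant_id={log.participant_id}\n")
    buf.write(f"# run_index={log.run_index}\n")
    buf.write(f"# duration={_fmt(log.duration)}\n")
    buf.write(_HEADER + "\n")
    rows: list[tuple[float, int, str]] = []
    for i, s in enumerate(log.samples):
        rows.append((s.t, i, f"{_fmt(s.t)},sample,{s.view},{_fmt(s.patch_id)},{_fmt(s.x)},{_fmt(s.y)},"))
    for i, e in enumerate(log.events):
        rows.append((e.t, i, f"{_fmt(e.t)},{e.type},,{e.patch_id},,,{_fmt(e.resource_index)}"))
    # stable by time; samples and events each preserve their own order
    rows.sort(key=lambda r: r[0])
    for _, _, line in rows:
        buf.write(line + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_event_log(path: str | Path) -> ForagingEventLog:
    """Parse an event-log CSV; inverse of :func:`write_event_log`.

    Raises :class:`EventLogError` naming the first offending row for any
    schema or invariant violation.
    """
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise EventLogError(f"{path}: empty file")
    meta: dict[str, str] = {}
    samples: list[Sample] = []
    events: list[Event] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if not header_seen:
            if line != _HEADER:
                raise EventLogError(f"row {lineno}: expected header {_HEADER!r}, got {line!r}")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 7:
            raise EventLogError(f"row {lineno}: expected 7 fields, got {len(parts)}")
        t_s, rtype, view, pid_s, x_s, y_s, ridx_s = parts
        try:
            t = float(t_s)
        except ValueError:
            raise EventLogError(f"row {lineno}: bad time {t_s!r}") from None
        if rtype == "sample":
            if view not in (AERIAL, PATCH):
                raise EventLogError(f"row {lineno}: bad view {view!r}")
            try:
                samples.append(
                    Sample(
                        t=t,
                        view=view,
                        patch_id=int(pid_s) if pid_s else None,
                        x=float(x_s),
                        y=float(y_s),
                    )
                )
            except ValueError:
                raise EventLogError(f"row {lineno}: bad sample fields") from None
        elif rtype in EVENT_TYPES:
            if not pid_s:
                raise EventLogError(f"row {lineno}: event missing patch_id")
            try:
                events.append(
                    Event(
                        t=t,
                        type=rtype,
                        patch_id=int(pid_s),
                        resource_index=int(ridx_s) if ridx_s else None,
                    )
                )
            except ValueError:
                raise EventLogError(f"row {lineno}: bad event fields") from None
        else:
            raise EventLogError(f"row {lineno}: unknown record_type {rtype!r}")
    for key in ("participant_id", "run_index", "duration"):
        if key not in meta:
            raise EventLogError(f"{path}: missing metadata line '# {key}=...'")
    log = ForagingEventLog(
        participant_id=meta["participant_id"],
        run_index=meta["run_index"],
        duration=float(meta["duration"]),
        samples=samples,
        events=events,
    )
    log.validate()
    return log


def extract_visits(log: ForagingEventLog) -> list[PatchVisit]:
    """Pair entry/exit events into time-ordered :class:`PatchVisit` records.

    An unmatched final ``patch_enter`` (the run clock expired inside the
    patch) yields a visit ending at ``log.duration`` flagged ``censored``.
    An unmatched ``patch_exit`` raises.
    """
    visits: list[PatchVisit] = []
    open_enter: Event | None = None
    rewards = 0
    for e in log.events:
        if e.type == "patch_enter":
            if open_enter is not None:
                raise EventLogError(f"nested patch_enter at t={e.t}")
            open_enter = e
            rewards = 0
        elif e.type == "reward":
            if open_enter is None or e.patch_id != open_enter.patch_id:
                raise EventLogError(f"reward outside a visit at t={e.t}")
            rewards += 1
        elif e.type == "patch_exit":
            if open_enter is None or e.patch_id != open_enter.patch_id:
                raise EventLogError(f"unmatched patch_exit at t={e.t}")
            visits.append(
                PatchVisit(
                    patch_id=e.patch_id,
                    t_enter=open_enter.t,
                    t_exit=e.t,
                    rewards=rewards,
                )
            )
            open_enter = None
    if open_enter is not None:
        visits.append(
            PatchVisit(
                patch_id=open_enter.patch_id,
                t_enter=open_enter.t,
                t_exit=log.duration,
                rewards=rewards,
                censored=True,
            )
        )
    return visits
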