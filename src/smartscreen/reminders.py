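"""Pre/post due-date reminder scheduling and iCalendar export.

Each due screening test gets a fixed six-shot notification schedule per
channel: two weeks, one week and three days *before* the due date, and —
for overdue tests — three days, one week and two weeks *after* it. Offsets
are wall-calendar days with no business-day adjustment, and there is never
an event on the due date itself. Message transport (SMTP, SMS gateways) is
out of scope: the module emits events as data, as JSON, or as an ICS file
with one date-valued VEVENT per reminder.
"""

from __future__ import annotations

import json
from datetime import date, datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel

from .engine import ScreeningPlan
from .records import TestCode

#: The fixed reminder offsets in days relative to the due date.
OFFSETS: tuple[int, ...] = (-14, -7, -3, 3, 7, 14)


class Phase(str, Enum):
    pre = "pre"
    post = "post"


class Channel(str, Enum):
    email = "email"
    sms = "sms"


class ReminderEvent(BaseModel):
    person_id: str
    test_code: TestCode
    due_date: date
    fire_date: date
    phase: Phase
    offset_days: int
    channel: Channel


def reminder_schedule(due_date: date, *, person_id: str = "",
                      test_code: TestCode = TestCode.FPG,
                      channel: Channel = Channel.email) -> list[ReminderEvent]:
    """The six reminder events for one due test on one channel, sorted by
    fire date: offsets -14, -7, -3 (phase ``pre``) and +3, +7, +14 (``post``)."""
    events = [
        ReminderEvent(
            person_id=person_id, test_code=test_code, due_date=due_date,
            fire_date=due_date + timedelta(days=off),
            phase=Phase.pre if off < 0 else Phase.post,
            offset_days=off, channel=channel)
        for off in OFFSETS
    ]
    return sorted(events, key=lambda e: e.fire_date)


def pending_notifications(
    plans: Iterable[ScreeningPlan],
    window_start: date,
    window_end: date,
    completed: Optional[dict[tuple[str, TestCode], date]] = None,
) -> list[ReminderEvent]:
    """All reminder events firing within ``[window_start, window_end]``.

    Only indicated recommendations generate events, and only on channels for
    which the plan has contact information. ``completed`` maps
    ``(person_id, test_code)`` to a completion date: post-due reminders for a
    test cease once it is completed.
    """
    if window_start > window_end:
        raise ValueError("window_start must be <= window_end")
    completed = completed or {}
    out: list[ReminderEvent] = []
    for plan in plans:
        channels = []
        if plan.contact.email:
            channels.append(Channel.email)
        if plan.contact.phone:
            channels.append(Channel.sms)
        for rec in plan.indicated():
            if rec.due_date is None:
                continue
            done = completed.get((plan.person_id, rec.test_code))
            for channel in channels:
                for ev in reminder_schedule(rec.due_date, person_id=plan.person_id,
                                            test_code=rec.test_code, channel=channel):
                    if not window_start <= ev.fire_date <= window_end:
                        continue
                    if done is not None and ev.phase == Phase.post and ev.fire_date >= done:
                        continue
                    out.append(ev)
    return sorted(out, key=lambda e: (e.fire_date, e.person_id,
                                      e.test_code.value, e.channel.value))


def events_to_json(events: list[ReminderEvent]) -> str:
    return json.dumps([json.loads(e.model_dump_json()) for e in events], indent=1)


# ---------------------------------------------------------------------------
# Minimal iCalendar writer/reader (date-valued all-day VEVENTs only)

def _fold(line: str) -> str:
    # RFC 5545 75-octet line folding; our lines are ASCII
    out = []
    while len(line) > 73:
        out.append(line[:73])
        line = " " + line[73:]
    out.append(line)
    return "\r\n".join(out)


def export_calendar(events: list[ReminderEvent], path: str | Path) -> None:
    """Write one all-day VEVENT per reminder event to an ICS file."""
    lines = ["BEGIN:VCALENDAR", "VERSION:2.0", "PRODID:-//smartscreen//screening reminders//EN"]
    stamp = datetime(2000, 1, 1).strftime("%Y%m%dT%H%M%SZ")
    for i, ev in enumerate(events):
        summary = (f"{'Upcoming' if ev.phase == Phase.pre else 'Overdue'} screening: "
                   f"{ev.test_code.value} for {ev.person_id} due {ev.due_date.isoformat()} "
                   f"[{ev.channel.value}]")
        lines += [
            "BEGIN:VEVENT",
            f"UID:{i}-{ev.person_id}-{ev.test_code.value}-{ev.offset_days:+d}-{ev.channel.value}@smartscreen",
            f"DTSTAMP:{stamp}",
            f"DTSTART;VALUE=DATE:{ev.fire_date.strftime('%Y%m%d')}",
            _fold(f"SUMMARY:{summary}"),
            f"CATEGORIES:{ev.phase.value.upper()}",
            "END:VEVENT",
        ]
    lines.append("END:VCALENDAR")
    Path(path).write_text("\r\n".join(lines) + "\r\n")


def read_calendar(path: str | Path) -> list[dict]:
    """Re-parse an ICS file written by :func:`export_calendar`.

    Returns one dict per VEVENT with the unfolded property values; used for
    round-trip checks, not as a general iCalendar parser.
    """
    raw = Path(path).read_text()
    unfolded: list[str] = []
    for line in raw.splitlines():
        if line[:1] in (" ", "\t") and unfolded:
            unfolded[-1] += line[1:]
        else:
            unfolded.append(line)
    events: list[dict] = []
    current: Optional[dict] = None
    for line in unfolded:
        if line == "BEGIN:VEVENT":
            current = {}
        elif line == "END:VEVENT":
            if current is None:
                raise ValueError("END:VEVENT without BEGIN:VEVENT")
            events.append(current)
            current = None
        elif current is not None and ":" in line:
            key, value = line.split(":", 1)
            if key == "DTSTART;VALUE=DATE":
                current["fire_date"] = datetime.strptime(value, "%Y%m%d").date()
            else:
                current[key.lower()] = value
    return events
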