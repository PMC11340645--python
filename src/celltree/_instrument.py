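"""Lightweight event counters for verifying the import-once contract.

The batch renderer promises that after a single matrix import, any number
of figures can be produced without touching the source matrix again, with
one tree parse and one store open per run. These counters make that
promise testable.
"""

from __future__ import annotations

from collections import Counter

_events: Counter[str] = Counter()


def count_event(name: str) -> None:
    _events[name] += 1


def event_count(name: str) -> int:
    return _events[name]


def reset_events() -> None:
    _events.clear()
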