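"""Mapping the decoded class stream to debounced wheelchair commands.

Each 200 ms window yields one class label; acting on every window would
jitter a safety-critical actuator, so a motion command is only emitted after
the same non-rest class wins ``debounce_k`` consecutive windows (default 3,
i.e. 600 ms of agreement).  REST means "hold current state" — it never moves
the chair and never re-arms the currently active command.  An explicit STOP
token models the emergency brake and bypasses debouncing entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import CLASSES, LABEL_FREQS
from .stimulus import StimulusConfig

#: Emergency-stop token accepted in a label stream.
STOP = "STOP"


@dataclass(frozen=True)
class CommandEvent:
    """One emitted wheelchair command."""

    command: str
    t_s: float
    source_windows: int


def map_stream(
    labels: list[str],
    config: StimulusConfig | None = None,
    debounce_k: int = 3,
    step_s: float = 0.2,
) -> list[CommandEvent]:
    """Convert a time-ordered label stream into debounced command events.

    Window ``i`` is stamped ``t_s = i * step_s``.  A command is emitted when a
    non-rest class completes a run of ``debounce_k`` identical windows and
    differs from the currently active command; the same command is never
    emitted twice without an intervening change.  STOP tokens emit
    immediately.
    """
    if not labels:
        raise ValueError("label stream is empty")
    if debounce_k < 1:
        raise ValueError("debounce_k must be >= 1")
    if config is None:
        config = StimulusConfig()

    events: list[CommandEvent] = []
    active: str | None = None
    streak_label: str | None = None
    streak = 0
    for i, label in enumerate(labels):
        if label == STOP:
            events.append(CommandEvent("stop", i * step_s, 1))
            active = "stop"
            streak_label, streak = None, 0
            continue
        if label not in CLASSES:
            raise ValueError(f"unknown label {label!r} at window {i}")
        if label == "REST":
            streak_label, streak = None, 0  # rest holds state, breaks runs
            continue
        if label == streak_label:
            streak += 1
        else:
            streak_label, streak = label, 1
        if streak == debounce_k:
            command = config.command_for(LABEL_FREQS[label])
            if command != active:
                events.append(CommandEvent(command, i * step_s, streak))
                active = command
    return events
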