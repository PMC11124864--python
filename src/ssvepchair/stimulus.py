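"""Flicker-stimulus planning for an LCD-based SSVEP interface.

On a monitor refreshing at ``r`` Hz, a black/white pattern-reversal stimulus
can only flicker at frequencies ``r / k`` for integer ``k >= 2``, because each
half-cycle must occupy a whole number of frames (or, for odd periods, an
alternating long/short pair of frame runs).  This module enumerates those
admissible frequencies, warns about harmonic collisions between concurrently
displayed stimuli (two SSVEP responses overlap when one stimulation frequency
is an integer multiple of the other), and expands a chosen frequency into the
per-frame ON/OFF schedule a renderer would execute.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Screen positions of the four stimuli.
POSITIONS = ("up", "down", "left", "right")

#: Wheelchair motion command associated with each screen position.
DEFAULT_COMMAND_MAP = {
    "up": "forward",
    "down": "backward",
    "left": "turn_left",
    "right": "turn_right",
}

#: Default stimulation frequencies (Hz) for a 60 Hz monitor.
DEFAULT_FREQUENCIES = (7.5, 10.0, 12.0, 15.0)

#: Default frequency -> position assignment (ascending frequency over
#: up, down, left, right).  The assignment is a free design choice; any
#: bijection onto the four positions is valid.
DEFAULT_POSITIONS = {7.5: "up", 10.0: "down", 12.0: "left", 15.0: "right"}

_INT_TOL = 1e-9


class UnsupportedFrequencyError(ValueError):
    """Raised when a frequency does not divide the monitor refresh rate."""

    def __init__(self, frequency_hz: float, refresh_rate_hz: float):
        k = max(2, round(refresh_rate_hz / frequency_hz))
        self.nearest_hz = refresh_rate_hz / k
        super().__init__(
            f"{frequency_hz:g} Hz is not refresh/k for integer k>=2 at a "
            f"{refresh_rate_hz:g} Hz refresh rate; nearest admissible "
            f"frequency is {self.nearest_hz:g} Hz"
        )


def _frames_per_period(frequency_hz: float, refresh_rate_hz: float) -> int:
    p = refresh_rate_hz / frequency_hz
    if abs(p - round(p)) > _INT_TOL or round(p) < 2:
        raise UnsupportedFrequencyError(frequency_hz, refresh_rate_hz)
    return round(p)


@dataclass(frozen=True)
class StimulusConfig:
    """Layout of the four flickering command stimuli on the monitor.

    Defaults reproduce the deployed interface: a 60 Hz, 1920x1080 monitor with
    200x200 px rectangles at 7.5, 10, 12 and 15 Hz mapped to the four motion
    commands.
    """

    refresh_rate_hz: float = 60.0
    frequencies_hz: tuple[float, ...] = DEFAULT_FREQUENCIES
    positions: dict[float, str] = field(
        default_factory=lambda: dict(DEFAULT_POSITIONS)
    )
    command_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMMAND_MAP)
    )
    stimulus_size_px: tuple[int, int] = (200, 200)
    monitor_resolution_px: tuple[int, int] = (1920, 1080)

    def __post_init__(self):
        if self.refresh_rate_hz <= 0:
            raise ValueError("refresh_rate_hz must be positive")
        if len(self.frequencies_hz) != 4:
            raise ValueError("exactly four stimulation frequencies required")
        for f in self.frequencies_hz:
            _frames_per_period(f, self.refresh_rate_hz)  # raises if inadmissible
        if sorted(self.positions) != sorted(self.frequencies_hz):
            raise ValueError("positions must be keyed by the stimulation frequencies")
        if sorted(self.positions.values()) != sorted(POSITIONS):
            raise ValueError(f"positions must be a bijection onto {POSITIONS}")
        conflicts = harmonic_conflicts(list(self.frequencies_hz))
        for lo, hi in conflicts:
            logger.warning(
                "stimulation frequencies %g Hz and %g Hz are harmonically "
                "related (%g = %d x %g); their SSVEP responses may overlap",
                lo, hi, hi, round(hi / lo), lo,
            )

    def command_for(self, frequency_hz: float) -> str:
        """Motion command attached to a stimulation frequency."""
        return self.command_map[self.positions[frequency_hz]]


def available_frequencies(
    refresh_rate_hz: float, max_divisor: int = 12
) -> list[tuple[int, float]]:
    """Enumerate admissible flicker frequencies ``refresh / k``, k = 2..max.

    Returns ``(divisor, frequency_hz)`` pairs in descending frequency order.
    Values are exact quotients; round only for display.
    """
    if refresh_rate_hz <= 0:
        raise ValueError("refresh_rate_hz must be positive")
    if max_divisor < 2:
        raise ValueError("max_divisor must be at least 2")
    return [(k, refresh_rate_hz / k) for k in range(2, max_divisor + 1)]


def harmonic_conflicts(
    frequencies: list[float], tolerance: float = 1e-6
) -> list[tuple[float, float]]:
    """Find frequency pairs whose ratio is an integer >= 2.

    Such pairs evoke overlapping SSVEP responses (the lower frequency's
    harmonic lands on the higher fundamental) and should not be displayed
    concurrently.  Pairs are reported as ``(f_lo, f_hi)`` with f_lo < f_hi.
    """
    if len(frequencies) < 2:
        raise ValueError("need at least two frequencies to check for conflicts")
    out = []
    fs = sorted(frequencies)
    for i, lo in enumerate(fs):
        for hi in fs[i + 1:]:
            ratio = hi / lo
            if round(ratio) >= 2 and abs(ratio - round(ratio)) <= tolerance:
                out.append((lo, hi))
    return out


def flicker_frame_sequence(
    frequency_hz: float, refresh_rate_hz: float, duration_s: float
) -> np.ndarray:
    """Binary per-frame schedule (1 = white, 0 = black) for one stimulus.

    The square-wave pattern reversal has period ``refresh/frequency`` frames.
    For even periods each half-cycle is exactly ``refresh/(2f)`` frames; for
    odd periods ON and OFF runs alternate between ``(p+1)//2`` and ``p//2``
    frames so the duty cycle is exactly 50% over every two periods.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    p = _frames_per_period(frequency_hz, refresh_rate_hz)
    n_frames = round(duration_s * refresh_rate_hz)
    long_run, short_run = (p + 1) // 2, p // 2
    # Run lengths per two periods: ON long, OFF short, ON short, OFF long.
    runs = [long_run, short_run, short_run, long_run]
    seq = np.empty(n_frames, dtype=np.int8)
    i = 0
    state = 1
    run_idx = 0
    while i < n_frames:
        n = min(runs[run_idx % 4], n_frames - i)
        seq[i:i + n] = state
        i += n
        state ^= 1
        run_idx += 1
    return seq


def format_frequency_table(entries: list[tuple[int, float]]) -> str:
    """Render divisor/frequency pairs as a two-row listing (2-decimal display)."""
    head = "\t".join(["f"] + [f"f/{k}" for k, _ in entries])
    vals = "\t".join(["Hz"] + [f"{round(f, 2):g}" for _, f in entries])
    return head + "\n" + vals
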