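"""Signal conditioning: mains notch, Butterworth band-pass, sliding windows.

The acquisition chain notch-filters the power-line frequency and then applies
a 2nd-order Butterworth band-pass of 0.5–45 Hz before decoding.  Windowing
follows the real-time strategy: overlapping 1 s segments advanced by 200 ms.
Filtering defaults to causal (a wheelchair controller cannot look ahead);
zero-phase filtering is available for offline analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import RawRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    notch_hz: float = 50.0
    notch_q: float = 30.0
    bp_low_hz: float = 0.5
    bp_high_hz: float = 45.0
    order: int = 2
    mode: str = "causal"  # or "zero-phase"

    def __post_init__(self):
        if not 0 < self.bp_low_hz < self.bp_high_hz:
            raise ValueError("need 0 < bp_low_hz < bp_high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.mode not in ("causal", "zero-phase"):
            raise ValueError("mode must be 'causal' or 'zero-phase'")
        if self.notch_hz <= 0 or self.notch_q <= 0:
            raise ValueError("notch_hz and notch_q must be positive")


@dataclass
class EpochWindow:
    """One fixed-length analysis segment cut from a recording."""

    samples: np.ndarray
    fs_hz: float
    t_start_s: float
    label: str | None = None

    def __len__(self) -> int:
        return self.samples.size


def design_sos(spec: FilterSpec, fs_hz: float) -> np.ndarray:
    """Cascaded second-order sections: notch followed by band-pass."""
    if spec.bp_high_hz >= fs_hz / 2 or spec.notch_hz >= fs_hz / 2:
        raise ValueError(
            f"filter edges must lie below Nyquist ({fs_hz / 2:g} Hz)"
        )
    b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=fs_hz)
    notch_sos = signal.tf2sos(b, a)
    bp_sos = signal.butter(
        spec.order, [spec.bp_low_hz, spec.bp_high_hz], btype="bandpass",
        fs=fs_hz, output="sos",
    )
    return np.vstack([notch_sos, bp_sos])


def apply_filters(rec: RawRecording, spec: FilterSpec) -> RawRecording:
    """Notch + band-pass a recording; output has the same length and metadata."""
    sos = design_sos(spec, rec.fs_hz)
    if spec.mode == "zero-phase":
        filtered = signal.sosfiltfilt(sos, rec.samples)
    else:
        filtered = signal.sosfilt(sos, rec.samples)
    return RawRecording(filtered, rec.fs_hz, label=rec.label, seed=rec.seed)


def sliding_windows(
    rec: RawRecording, window_s: float = 1.0, step_s: float = 0.2
) -> list[EpochWindow]:
    """Cut overlapping windows starting at 0, step, 2*step, ...

    Yields ``floor((T - window)/step) + 1`` windows; a recording shorter than
    one window produces an empty list (with a warning) so streaming callers
    degrade gracefully.
    """
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be positive")
    win_n = round(window_s * rec.fs_hz)
    step_n = round(step_s * rec.fs_hz)
    if len(rec) < win_n:
        logger.warning(
            "recording of %d samples is shorter than the %d-sample window; "
            "no windows extracted", len(rec), win_n,
        )
        return []
    out = []
    for start in range(0, len(rec) - win_n + 1, step_n):
        out.append(
            EpochWindow(
                rec.samples[start:start + win_n],
                rec.fs_hz,
                t_start_s=start / rec.fs_hz,
                label=rec.label,
            )
        )
    return out
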