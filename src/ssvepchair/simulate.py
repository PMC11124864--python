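"""Synthetic single-channel occipital EEG with SSVEP structure.

A trial is a mixture of four components:

* the SSVEP response — a sum of sinusoids at the stimulation frequency and
  its harmonics, each harmonic attenuated geometrically and given a random
  phase, absent for REST trials;
* pink (1/f) background noise, the standard model of spontaneous EEG;
* broadband white sensor noise at 30% of the pink-noise RMS;
* an optional mains (power-line) sinusoid.

The SSVEP component is rescaled so that its power relative to the total
background-noise power (pink + white, mains excluded) realises the requested
SNR in dB exactly.  ``snr_db="noise-free"`` yields the pure SSVEP component
alone, which makes a noise-free REST trial identically zero.  Everything is
deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

#: The five decoder classes: four stimulation frequencies plus rest.
CLASSES = ("F7.5", "F10", "F12", "F15", "REST")

#: Stimulation frequency per class label (None for rest).
LABEL_FREQS: dict[str, float | None] = {
    "F7.5": 7.5,
    "F10": 10.0,
    "F12": 12.0,
    "F15": 15.0,
    "REST": None,
}

_WHITE_RMS = 0.3  # sensor-noise RMS relative to unit-RMS pink background


@dataclass(frozen=True)
class TrialSpec:
    """Parameters for one simulated gaze trial.

    ``snr_db`` is the stimulus-band vs background-noise power ratio in dB, or
    the string ``"noise-free"`` for a pure SSVEP signal.  Defaults emulate the
    deployed acquisition: 250 Hz sampling, four harmonics, each harmonic at
    half the previous amplitude, 50 Hz mains, and a low -10 dB SNR matching
    the non-prominent spectral peaks seen in real single-channel recordings.
    """

    label: str
    duration_s: float = 4.0
    fs_hz: float = 250.0
    snr_db: Union[float, str] = -10.0
    n_harmonics: int = 4
    harmonic_decay: float = 0.5
    powerline_hz: float = 50.0
    powerline_amp: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration_s and fs_hz must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.harmonic_decay <= 0:
            raise ValueError("harmonic_decay must be positive")
        if self.powerline_amp < 0:
            raise ValueError("powerline_amp must be nonnegative")
        if isinstance(self.snr_db, str) and self.snr_db != "noise-free":
            raise ValueError('snr_db must be a number or "noise-free"')
        f = LABEL_FREQS[self.label]
        if f is not None and self.n_harmonics * f >= self.fs_hz / 2:
            raise ValueError(
                f"highest harmonic {self.n_harmonics * f:g} Hz aliases at "
                f"fs={self.fs_hz:g} Hz"
            )


@dataclass
class RawRecording:
    """A single-channel EEG time series (µV-scaled arbitrary units)."""

    samples: np.ndarray
    fs_hz: float
    label: str | None = None
    seed: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = np.inf  # kill DC
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n)
    return pink / np.sqrt(np.mean(pink**2))


def generate_components(spec: TrialSpec) -> dict[str, np.ndarray]:
    """Generate the (already SNR-scaled) constituent signals of one trial.

    Returns ``{"ssvep", "noise", "powerline"}`` arrays; their sum is the
    trial.  Exposed so the realised SNR can be measured on the components.
    """
    n = round(spec.duration_s * spec.fs_hz)
    t = np.arange(n) / spec.fs_hz
    rng = np.random.default_rng(spec.seed)
    f0 = LABEL_FREQS[spec.label]

    ssvep = np.zeros(n)
    if f0 is not None:
        for h in range(1, spec.n_harmonics + 1):
            amp = spec.harmonic_decay ** (h - 1)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            ssvep += amp * np.sin(2.0 * np.pi * h * f0 * t + phase)

    if spec.snr_db == "noise-free":
        return {"ssvep": ssvep, "noise": np.zeros(n), "powerline": np.zeros(n)}

    noise = _pink_noise(rng, n) + _WHITE_RMS * rng.standard_normal(n)
    if f0 is not None:
        p_noise = np.mean(noise**2)
        p_sig = np.mean(ssvep**2)
        gain = np.sqrt(10.0 ** (float(spec.snr_db) / 10.0) * p_noise / p_sig)
        ssvep *= gain

    powerline = np.zeros(n)
    if spec.powerline_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        powerline = spec.powerline_amp * np.sin(
            2.0 * np.pi * spec.powerline_hz * t + phase
        )
    return {"ssvep": ssvep, "noise": noise, "powerline": powerline}


def realized_snr_db(spec: TrialSpec) -> float:
    """SNR actually realised by the generated components, in dB."""
    c = generate_components(spec)
    return 10.0 * np.log10(np.mean(c["ssvep"] ** 2) / np.mean(c["noise"] ** 2))


def generate_trial(spec: TrialSpec) -> RawRecording:
    """Simulate one labeled gaze (or rest) trial."""
    c = generate_components(spec)
    samples = c["ssvep"] + c["noise"] + c["powerline"]
    return RawRecording(samples, spec.fs_hz, label=spec.label, seed=spec.seed)


def generate_dataset(
    n_per_class: int, spec_template: TrialSpec, base_seed: int
) -> list[RawRecording]:
    """Simulate a class-balanced dataset of ``5 * n_per_class`` trials.

    Per-trial seeds are derived from ``base_seed`` through a seed sequence, so
    identical arguments reproduce the dataset bit-for-bit.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(5 * n_per_class)
    trials = []
    i = 0
    for label in CLASSES:
        for _ in range(n_per_class):
            spec = replace(spec_template, label=label, seed=int(seeds[i] & 0x7FFFFFFF))
            trials.append(generate_trial(spec))
            i += 1
    return trials
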