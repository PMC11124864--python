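"""Pipeline configuration: one object tying every stage's parameters together.

The defaults reproduce the deployed system's settings end to end: 250 Hz
sampling, 50 Hz notch + 0.5–45 Hz order-2 Butterworth band-pass, 1 s windows
advanced by 200 ms, four-harmonic references, FFT amplitude features,
degree-3 polynomial SVM, stratified 80/20 split, and 3-window debouncing.
Configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .preprocess import FilterSpec
from .stimulus import StimulusConfig

FEATURE_SETS = ("fft", "fft+cca", "cca-only")


@dataclass(frozen=True)
class PipelineConfig:
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    window_s: float = 1.0
    step_s: float = 0.2
    n_harmonics: int = 4
    feature_set: str = "fft"
    rest_threshold: float = 0.5
    svm_degree: int = 3
    svm_c: float = 1.0
    train_fraction: float = 0.8
    seed: int = 0
    debounce_k: int = 3

    def __post_init__(self):
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValueError("window_s and step_s must be positive")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if not 0.0 <= self.rest_threshold <= 1.0:
            raise ValueError("rest_threshold must lie in [0, 1]")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.debounce_k < 1:
            raise ValueError("debounce_k must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        # YAML mapping keys must be plain scalars; keep frequency keys as str
        d["stimulus"]["positions"] = {
            str(k): v for k, v in d["stimulus"]["positions"].items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        stim = d.pop("stimulus", {})
        filt = d.pop("filter", {})
        if "positions" in stim:
            stim["positions"] = {float(k): v for k, v in stim["positions"].items()}
        for key in ("frequencies_hz", "stimulus_size_px", "monitor_resolution_px"):
            if key in stim:
                stim[key] = tuple(stim[key])
        return cls(
            stimulus=StimulusConfig(**stim),
            filter=FilterSpec(**filt),
            **d,
        )
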