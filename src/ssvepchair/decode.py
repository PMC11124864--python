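"""SSVEP decoding: harmonic references, CCA scoring, spectral features.

For each candidate stimulation frequency ``f`` a reference matrix stacks
``sin(2*pi*h*f*t)`` and ``cos(2*pi*h*f*t)`` rows for harmonics ``h = 1..N``
(N = 4 by default).  A window is scored against a reference by the maximum
canonical correlation; since the recording is single-channel this is the
square root of the fraction of (mean-centered) window variance captured by
orthogonal projection onto the reference row space.

Spectral features are single-frequency amplitude estimates at the four
stimulation frequencies, evaluated at the exact target frequency by a
Goertzel-style correlation sum rather than the nearest FFT bin — with 1 s
windows at 250 Hz the bins fall on a 1 Hz grid and 7.5 Hz would otherwise
land between bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochWindow
from .simulate import LABEL_FREQS

logger = logging.getLogger(__name__)

#: Stimulation frequencies whose amplitudes form the default feature vector.
TARGET_FREQS = (7.5, 10.0, 12.0, 15.0)


@dataclass(frozen=True)
class Reference:
    """Harmonic sin/cos reference matrix for one stimulation frequency."""

    frequency_hz: float
    fs_hz: float
    n_harmonics: int
    matrix: np.ndarray  # shape (2 * n_harmonics, n_samples)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


def build_reference(
    f: float, fs_hz: float, n_samples: int, n_harmonics: int = 4
) -> Reference:
    """Construct the 2N x n_samples reference for frequency ``f``.

    Rows are ordered sin_1, cos_1, sin_2, cos_2, ..., evaluated at
    ``t = k / fs``.  The highest harmonic must stay below Nyquist.
    """
    if f <= 0 or fs_hz <= 0 or n_samples < 1 or n_harmonics < 1:
        raise ValueError("f, fs_hz, n_samples and n_harmonics must be positive")
    if n_harmonics * f >= fs_hz / 2:
        raise ValueError(
            f"harmonic {n_harmonics}f = {n_harmonics * f:g} Hz aliases at "
            f"fs = {fs_hz:g} Hz"
        )
    t = np.arange(n_samples) / fs_hz
    rows = []
    for h in range(1, n_harmonics + 1):
        w = 2.0 * np.pi * h * f * t
        rows.append(np.sin(w))
        rows.append(np.cos(w))
    return Reference(f, fs_hz, n_harmonics, np.vstack(rows))


class ReferenceSet(dict):
    """Mapping frequency -> :class:`Reference`, keyed in ascending order."""

    @classmethod
    def for_frequencies(
        cls,
        frequencies: tuple[float, ...] = TARGET_FREQS,
        fs_hz: float = 250.0,
        n_samples: int = 250,
        n_harmonics: int = 4,
    ) -> "ReferenceSet":
        return cls(
            (f, build_reference(f, fs_hz, n_samples, n_harmonics))
            for f in sorted(frequencies)
        )


def cca_correlation(window: EpochWindow, ref: Reference) -> float:
    """Maximum canonical correlation between a window and a reference.

    Both sides are mean-centered; the window is projected onto an orthonormal
    basis of the reference rows (QR decomposition) and the correlation is the
    projected fraction of its norm.  A zero-variance window scores 0 (with a
    warning) rather than raising.  Invariant to affine rescaling a*x + b.
    """
    x = np.asarray(window.samples, dtype=float)
    if x.size != ref.n_samples:
        raise ValueError(
            f"window length {x.size} != reference length {ref.n_samples}"
        )
    xc = x - x.mean()
    norm = np.linalg.norm(xc)
    if norm == 0.0:
        logger.warning("zero-variance window at t=%gs; correlation set to 0",
                       window.t_start_s)
        return 0.0
    yc = ref.matrix - ref.matrix.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(yc.T)
    r = np.linalg.norm(q.T @ xc) / norm
    return float(min(r, 1.0))


def single_freq_amplitude(x: np.ndarray, f: float, fs_hz: float) -> float:
    """Goertzel-style amplitude estimate at exactly ``f`` Hz.

    Normalised so a unit-amplitude sinusoid completing a whole number of
    cycles in the window returns 1.0 (matching ``2/n`` FFT-magnitude scaling
    at on-grid frequencies).
    """
    n = x.size
    k = np.arange(n)
    return float(2.0 / n * np.abs(np.sum(x * np.exp(-2j * np.pi * f * k / fs_hz))))


@dataclass
class FeatureVector:
    """Per-window decoder features: spectral amplitudes, optional CCA scores."""

    fft_amps: np.ndarray
    cca_corrs: np.ndarray | None = None
    label: str | None = None

    def as_array(self, feature_set: str = "fft") -> np.ndarray:
        """Flatten to the feature layout a classifier consumes.

        ``feature_set`` is one of ``fft`` (default), ``fft+cca``, ``cca-only``.
        """
        if feature_set == "fft":
            return np.asarray(self.fft_amps, dtype=float)
        if self.cca_corrs is None:
            raise ValueError(f"feature set {feature_set!r} needs CCA scores")
        if feature_set == "fft+cca":
            return np.concatenate([self.fft_amps, self.cca_corrs]).astype(float)
        if feature_set == "cca-only":
            return np.asarray(self.cca_corrs, dtype=float)
        raise ValueError(f"unknown feature set {feature_set!r}")


def fft_features(
    window: EpochWindow, target_freqs: tuple[float, ...] = TARGET_FREQS
) -> FeatureVector:
    """Amplitude-spectrum features at the stimulation frequencies."""
    x = np.asarray(window.samples, dtype=float)
    if x.size == 0:
        raise ValueError("window is empty")
    for f in target_freqs:
        if f >= window.fs_hz / 2:
            raise ValueError(f"target {f:g} Hz is at or above Nyquist")
    amps = np.array(
        [single_freq_amplitude(x, f, window.fs_hz) for f in target_freqs]
    )
    return FeatureVector(fft_amps=amps, label=window.label)


def extract_features(
    windows: list[EpochWindow],
    refs: ReferenceSet | None = None,
    target_freqs: tuple[float, ...] = TARGET_FREQS,
    with_cca: bool = False,
) -> list[FeatureVector]:
    """Feature vectors for a window stream, optionally appending CCA scores."""
    if with_cca and refs is None:
        raise ValueError("with_cca=True requires a ReferenceSet")
    out = []
    for w in windows:
        fv = fft_features(w, target_freqs)
        if with_cca:
            fv.cca_corrs = np.array(
                [cca_correlation(w, refs[f]) for f in sorted(refs)]
            )
        out.append(fv)
    return out


def classify_by_cca(
    window: EpochWindow, refs: ReferenceSet, rest_threshold: float = 0.5
) -> str:
    """Training-free decoder: argmax CCA score, or REST below threshold.

    Ties break toward the lowest frequency.
    """
    freqs = sorted(refs)
    corrs = np.array([cca_correlation(window, refs[f]) for f in freqs])
    # ties (within numerical tolerance) break toward the lowest frequency
    best = int(np.flatnonzero(corrs >= corrs.max() - 1e-12)[0])
    if corrs[best] < rest_threshold:
        return "REST"
    f = freqs[best]
    for label, lf in LABEL_FREQS.items():
        if lf is not None and abs(lf - f) < 1e-9:
            return label
    raise ValueError(f"reference frequency {f:g} Hz has no class label")
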