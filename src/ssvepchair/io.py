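"""Recording I/O: plain-text CSV (native) and EDF (clinical interchange).

The native format is a one-line header ``fs_hz=<value>[,label=<class>]``
followed by one sample per line, lossless for round-tripping synthetic
trials.  EDF files are read through MNE; a minimal single-record 16-bit EDF
writer is provided for producing interchange fixtures (EDF quantizes to
16-bit integers over the signal's physical range, so round-trips agree to
one quantization step).  The class label rides in the EDF channel name
(``EEG <label>``).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .simulate import RawRecording


class RecordingFormatError(ValueError):
    """Raised when a recording file violates its format contract."""


def write_recording_csv(rec: RawRecording, path: str | Path) -> None:
    header = f"fs_hz={rec.fs_hz:.10g}"
    if rec.label is not None:
        header += f",label={rec.label}"
    lines = [header] + [f"{v:.17g}" for v in rec.samples]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_csv(path: Path) -> RawRecording:
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(
            item.split("=", 1) for item in header.split(",") if "=" in item
        )
        if "fs_hz" not in fields:
            raise RecordingFormatError(
                f"{path}: header must declare fs_hz (got {header!r})"
            )
        fs = float(fields["fs_hz"])
        label = fields.get("label")
        samples = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                samples.append(float(line))
            except ValueError:
                raise RecordingFormatError(
                    f"{path}:{lineno}: non-numeric sample {line!r}"
                ) from None
    return RawRecording(np.array(samples), fs, label=label)


def write_recording_edf(rec: RawRecording, path: str | Path) -> None:
    """Write a single-channel, single-data-record EDF file.

    Samples are scaled to the full 16-bit digital range over the signal's
    physical min/max (µV).  MNE's EDF reader recovers them to within one
    quantization step.
    """
    x = rec.samples
    n = x.size
    # symmetric physical range rounded up to 3 significant digits so the
    # 8-byte ASCII header fields always fit
    amp = max(float(np.max(np.abs(x))), 1e-3)
    bound = float(f"{amp:.3g}")
    while bound < amp:
        bound = float(f"{bound * 1.01:.3g}")
    pmin, pmax = -bound, bound
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((x - pmin) * gain + dmin).astype("<i2")

    label = f"EEG {rec.label}" if rec.label is not None else "EEG"
    record_s = n / rec.fs_hz

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
        return b.ljust(width)

    header = b"".join([
        pad("0", 8),                      # version
        pad("X X X X", 80),               # local patient id (anonymous)
        pad("Startdate X", 80),           # local recording id
        pad("01.01.00", 8),               # start date
        pad("00.00.00", 8),               # start time
        pad(str(256 + 256), 8),           # header bytes: fixed + 1 signal
        pad("", 44),                      # reserved
        pad("1", 8),                      # number of data records
        pad(f"{record_s:.6g}", 8),        # record duration (s)
        pad("1", 4),                      # number of signals
        pad(label, 16),                   # channel label
        pad("AgAgCl electrode", 80),      # transducer
        pad("uV", 8),                     # physical dimension
        pad(f"{pmin:.3g}", 8),
        pad(f"{pmax:.3g}", 8),
        pad(str(dmin), 8),
        pad(str(dmax), 8),
        pad("", 80),                      # prefiltering
        pad(str(n), 8),                   # samples per record
        pad("", 32),                      # reserved
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack(f"<{n}h", *digital.tolist()))


def _read_edf(path: Path) -> RawRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data(picks=[0], units="uV")[0]
    name = raw.ch_names[0]
    label = None
    if name.startswith("EEG ") and len(name) > 4:
        label = name[4:].strip()
    return RawRecording(np.asarray(data, dtype=float), fs, label=label)


def read_recording(path: str | Path, format: str | None = None) -> RawRecording:
    """Load a recording from CSV or EDF; the format defaults to the suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown recording format {format!r}")
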