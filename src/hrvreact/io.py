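"""Signal and table I/O.

Signals travel either as two-column delimited text (time_s, mV; uniform
sampling enforced) or as single-channel EDF.  EDF writing is a minimal
format implementation (ASCII header, 16-bit integer data records);
reading EDF delegates to mne when available.  Tables are plain delimited
text with documented headers and fixed float formatting so repeated runs
are byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FLAG_REJECTED, RRSeries, Waveform

FLOAT_FORMAT = "%.9g"


# --------------------------------------------------------------------------
# Delimited signals


def write_signal_text(wave: Waveform, path) -> None:
    """Two-column delimited text: time_s <TAB> mV."""
    t = wave.times_s
    with open(path, "w") as fh:
        fh.write(f"# channel: {wave.channel_label}\n")
        fh.write("time_s\tmv\n")
        for ti, xi in zip(t, wave.samples):
            fh.write(f"{ti:.6f}\t{xi:.6f}\n")


def read_signal_text(path) -> Waveform:
    label = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# channel:"):
            label = first.split(":", 1)[1].strip()
    data = np.loadtxt(path, skiprows=2 if label or first.startswith("#") else 1,
                      delimiter="\t")
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("expected two columns (time_s, mV) with >=2 rows")
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6 * max(abs(dt[0]), 1e-12)):
        raise ValueError("non-uniform sampling in delimited signal")
    fs = 1.0 / dt[0]
    return Waveform(x, fs, channel_label=label, start_time_s=float(t[0]))


# --------------------------------------------------------------------------
# EDF (one channel)


def write_signal_edf(
    wave: Waveform,
    path,
    physical_range: tuple[float, float] | None = None,
    patient_id: str = "X",
) -> None:
    """Minimal single-channel EDF writer.

    One 1-s data record per second of signal; requires an integer
    sampling rate.  Samples are scaled to 16-bit integers over the
    physical range (default: symmetric around the signal extremes).
    """
    fs = wave.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writing requires an integer sampling rate")
    fs = int(round(fs))
    x = wave.samples
    n_records = int(math.ceil(x.size / fs))
    padded = np.zeros(n_records * fs)
    padded[: x.size] = x
    if physical_range is None:
        amp = max(float(np.max(np.abs(padded))), 1e-6)
        physical_range = (-amp, amp)
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((padded - pmin) * scale + dmin), dmin, dmax
    ).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s.encode("ascii")[:n].ljust(n)

    header = b"".join(
        [
            pad("0", 8),
            pad(patient_id, 80),
            pad("synthetic recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad("1", 4),
        ]
    )
    sig_header = b"".join(
        [
            pad(wave.channel_label or "EMG-ECG-MIX", 16),
            pad("synthetic", 80),
            pad("mV", 8),
            pad(f"{pmin:.6g}", 8),
            pad(f"{pmax:.6g}", 8),
            pad(str(dmin), 8),
            pad(str(dmax), 8),
            pad("", 80),
            pad(str(fs), 8),
            pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.tobytes())


def read_signal_edf(path) -> Waveform:
    """Read a single-channel EDF via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires mne (install the 'edf' extra)"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()[0]
    # mne converts voltage-like channels to SI units (V); recover mV
    if raw.info["chs"][0]["unit_mul"] == 0:
        data = data * 1e3
    return Waveform(
        data, float(raw.info["sfreq"]), channel_label=raw.ch_names[0]
    )


def read_signal(path, fmt: str | None = None) -> Waveform:
    """Dispatch on format (``edf`` or ``delimited``; inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        return read_signal_edf(path)
    if fmt == "delimited":
        return read_signal_text(path)
    raise ValueError(f"unknown signal format {fmt!r}")


def write_signal(wave: Waveform, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        write_signal_edf(wave, path)
    elif fmt == "delimited":
        write_signal_text(wave, path)
    else:
        raise ValueError(f"unknown signal format {fmt!r}")


# --------------------------------------------------------------------------
# RR series and tables


def write_rr(rr: RRSeries, path) -> None:
    df = pd.DataFrame(
        {
            "rr_s": rr.intervals_s,
            "end_time_s": rr.interval_end_times_s,
            "flag": np.where(rr.flags == FLAG_REJECTED, "rejected", "ok"),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_rr(path) -> RRSeries:
    df = pd.read_csv(path, sep="\t")
    flags = (df["flag"] == "rejected").astype(int).to_numpy()
    return RRSeries(
        df["rr_s"].to_numpy(float), df["end_time_s"].to_numpy(float), flags
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
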