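"""Signal file formats: CSV signals and PhysioNet-style (WFDB) records.

The CSV dialect is comma-separated with a header row; an optional leading
comment line ``# fs=<Hz>`` carries the sampling rate, otherwise the rate
is inferred from a uniform ``time_s`` column.

The WFDB reader is a minimal, self-contained parser for single-segment
records stored in format 16 (little-endian 16-bit integers, channels
interleaved), which covers the waveform records this pipeline consumes.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import SignalRecord

__all__ = ["read_signal_csv", "write_signal_csv", "read_wfdb_record",
           "write_wfdb_record", "FormatError"]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


def write_signal_csv(record: SignalRecord, path):
    path = Path(path)
    t = np.arange(record.samples.size) / record.fs
    with open(path, "w") as fh:
        fh.write(f"# fs={float(record.fs)!r}\n")
        fh.write("time_s,amplitude\n")
        for ti, xi in zip(t, record.samples):
            fh.write(f"{float(ti)!r},{float(xi)!r}\n")


def read_signal_csv(path, subject_id=None, source_tag: str = "") -> SignalRecord:
    """Read a single-channel signal CSV; fs from the ``# fs=`` metadata line
    or inferred from a uniform time column (relative jitter <= 1e-6)."""
    path = Path(path)
    fs = None
    try:
        with open(path) as fh:
            first = fh.readline()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    m = re.match(r"#\s*fs\s*=\s*([0-9.eE+-]+)", first)
    if m:
        fs = float(m.group(1))
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    cols = {c.lower(): c for c in df.columns}
    amp_col = next((cols[c] for c in ("amplitude", "ppg", "signal", "value")
                    if c in cols), None)
    if amp_col is None:
        raise FormatError(f"{path}: no amplitude column among {list(df.columns)}")
    amp = df[amp_col].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(amp))
    if bad.size:
        raise FormatError(
            f"{path}: non-finite amplitude at data row(s) {bad[:10].tolist()}"
        )
    time_col = next((cols[c] for c in ("time_s", "time", "t")
                     if c in cols), None)
    if time_col is not None:
        t = df[time_col].to_numpy(dtype=float)
        if t.size >= 2:
            dt = np.diff(t)
            if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * max(dt.mean(), 1e-12):
                raise FormatError(f"{path}: time grid is not uniform")
            inferred = 1.0 / dt.mean()
            if fs is None:
                fs = inferred
    if fs is None:
        raise FormatError(f"{path}: no '# fs=' header and no usable time column")
    return SignalRecord(samples=amp, fs=fs, subject_id=subject_id,
                        source_tag=source_tag, record_id=path.stem)


# -- minimal WFDB (PhysioNet waveform) support -----------------------------

def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea_path}: malformed record line {lines[0]!r}")
    name, nsig, fs, nsamp = head[0], int(head[1]), float(head[2]), int(head[3])
    channels = []
    for ln in lines[1 : 1 + nsig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0]
        gain, baseline = 200.0, 0
        if len(tok) > 2:
            m = re.match(r"([0-9.eE+-]+)(?:\(([-0-9]+)\))?(?:/.*)?", tok[2])
            if m:
                gain = float(m.group(1)) or 200.0
                baseline = int(m.group(2)) if m.group(2) else 0
        desc = tok[-1] if len(tok) > 3 else f"ch{len(channels)}"
        channels.append({"file": fname, "fmt": fmt, "gain": gain,
                         "baseline": baseline, "name": desc})
    return name, nsig, fs, nsamp, channels


def read_wfdb_record(path, channel_name: str) -> SignalRecord:
    """Read one named channel of a format-16 single-segment WFDB record.

    ``path`` is the record path without extension; a ``.hea``/``.dat`` pair
    must exist next to it.
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing header file {hea}")
    name, nsig, fs, nsamp, channels = _parse_header(hea)
    names = [c["name"] for c in channels]
    if channel_name not in names:
        raise FormatError(
            f"channel '{channel_name}' not in record; available: {names}"
        )
    idx = names.index(channel_name)
    ch = channels[idx]
    if ch["fmt"] != "16":
        raise FormatError(f"unsupported WFDB signal format '{ch['fmt']}' (only 16)")
    dat = base.parent / ch["file"]
    if not dat.exists():
        raise FormatError(f"missing signal file {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    raw = raw[: (raw.size // nsig) * nsig].reshape(-1, nsig)
    if nsamp:
        raw = raw[:nsamp]
    phys = (raw[:, idx].astype(float) - ch["baseline"]) / ch["gain"]
    return SignalRecord(samples=phys, fs=fs, subject_id=None,
                        source_tag=name, record_id=base.stem)


def write_wfdb_record(path, signals: dict[str, np.ndarray], fs: float,
                      gain: float = 200.0):
    """Write a format-16 WFDB record (used to build test fixtures)."""
    base = Path(path)
    names = list(signals)
    arrs = [np.asarray(signals[n], dtype=float) for n in names]
    n = min(a.size for a in arrs)
    digital = np.stack([np.round(a[:n] * gain).astype("<i2") for a in arrs], axis=1)
    with open(base.with_suffix(".hea"), "w") as fh:
        fh.write(f"{base.stem} {len(names)} {fs:g} {n}\n")
        for name in names:
            fh.write(f"{base.stem}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 {name}\n")
    digital.tofile(base.with_suffix(".dat"))
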