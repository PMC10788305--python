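"""PSG file I/O: EDF signals and stage annotation TSVs.

Reading uses MNE's native EDF reader; all signals are converted to µV
from the SI volts MNE returns, so downstream code never sees EDF
physical-dimension quirks (a file stored in mV simply arrives scaled).
Writing produces plain 16-bit EDF with per-channel physical ranges
taken from the data, so a write -> read round trip is exact to within
one quantization step.
"""

from __future__ import annotations

import numpy as np

from .hypnogram import Hypnogram, EPOCH_SECONDS, normalize_stage
from .recording import Recording, EEG_CHANNELS

_EDF_HEADER_DATE = "01.01.01"


def _pad(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return (s + " " * (width - len(s))).encode("ascii")


def write_edf(path, rec: Recording, record_seconds: float = 1.0) -> None:
    """Write a Recording as 16-bit EDF in physical units µV."""
    fs = rec.fs
    spr = int(round(fs * record_seconds))
    if abs(spr - fs * record_seconds) > 1e-9:
        raise ValueError("record_seconds must hold an integer sample count")
    n_rec = int(np.ceil(rec.n_samples / spr))
    n_ch = len(rec.channels)

    data = np.zeros((n_ch, n_rec * spr))
    data[:, :rec.n_samples] = rec.data

    phys_min = np.floor(data.min(axis=1)) - 1.0
    phys_max = np.ceil(data.max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))                      # patient id
        f.write(_pad("Startdate X X X X", 80))            # recording id
        f.write(_pad(_EDF_HEADER_DATE, 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(256 * (1 + n_ch)), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad(f"{record_seconds:g}", 8))
        f.write(_pad(str(n_ch), 4))
        for ch in rec.channels:
            f.write(_pad(f"EEG {ch}", 16))
        for _ in rec.channels:
            f.write(_pad("", 80))                          # transducer
        for _ in rec.channels:
            f.write(_pad("uV", 8))
        for v in phys_min:
            f.write(_pad(f"{v:g}", 8))
        for v in phys_max:
            f.write(_pad(f"{v:g}", 8))
        for _ in rec.channels:
            f.write(_pad(str(dig_min), 8))
        for _ in rec.channels:
            f.write(_pad(str(dig_max), 8))
        for _ in rec.channels:
            f.write(_pad("", 80))                          # prefiltering
        for _ in rec.channels:
            f.write(_pad(str(spr), 8))
        for _ in rec.channels:
            f.write(_pad("", 32))                          # reserved

        scale = (dig_max - dig_min) / (phys_max - phys_min)
        for r in range(n_rec):
            for ci in range(n_ch):
                seg = data[ci, r * spr:(r + 1) * spr]
                dig = np.round((seg - phys_min[ci]) * scale[ci] + dig_min)
                f.write(dig.astype("<i2").tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file into a µV Recording with normalized channel names."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = []
    for name in raw.ch_names:
        n = name.upper().replace("EEG", "").replace("-M1", "").replace("-M2", "")
        names.append(n.strip())
    data = raw.get_data() * 1e6  # volts -> µV
    return Recording(names, data, float(raw.info["sfreq"]),
                     reference={n: "raw" for n in names})


def read_psg(edf_path, stage_path,
             required: tuple = EEG_CHANNELS) -> tuple[Recording, Hypnogram]:
    """Read an EDF plus its stage TSV, checking channels and durations.

    The stage file must cover the record duration to within one 30-s
    epoch (a trailing partial epoch is truncated); larger mismatches
    raise.
    """
    rec = read_edf(edf_path)
    missing = [c for c in required if c not in rec.channels]
    if missing:
        raise ValueError(
            f"missing channel(s) {missing}; found {rec.channels}")
    hyp = Hypnogram.from_tsv(stage_path)
    n_full = int(rec.duration_s // EPOCH_SECONDS)
    if abs(hyp.n_epochs - n_full) * EPOCH_SECONDS > EPOCH_SECONDS:
        raise ValueError(
            f"stage file covers {hyp.duration_s:.0f} s but record holds "
            f"{rec.duration_s:.0f} s")
    if hyp.n_epochs > n_full:
        hyp = Hypnogram(hyp.stages[:n_full])
    return rec, hyp
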