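"""SO-spindle coupling: gross overlap, phase at spindle peak, ITPC,
and permutation z-scores.

Phase convention (documented prominently because coupling angles are
interpreted relative to it): the instantaneous 0.5-4 Hz phase from the
filter-Hilbert method is mapped so that 0 deg is the SO *positive*
peak, 180 deg the negative peak, and phase increases with time.

Three observed metrics per channel and spindle class:

* overlap proportion — share of spindles whose peak falls inside a
  detected SO interval [down_zc, end_zc);
* coupling angle — circular mean of SO phase at overlapping spindle
  peaks;
* ITPC — magnitude of the mean unit phasor of those phases.

Permutation nulls (n_perm draws, seeded independently of detection):

* overlap null: spindle peaks are circularly shifted by a uniform
  random offset along the concatenated retained-stage timeline,
  preserving event counts;
* ITPC null: each overlapping spindle is reassigned a uniformly random
  time within a randomly chosen SO interval, preserving counts *and*
  gross overlap.

z = (observed - null mean) / null SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import bandpass_filter, SO_BAND
from .so import SOEvent


def so_phase(signal: np.ndarray, fs: float, prefiltered: bool = False) -> np.ndarray:
    """Instantaneous SO phase in degrees [0, 360).

    0 deg = positive peak, 180 deg = negative peak, increasing with
    time (for cos(wt) the Hilbert argument is exactly wt).
    """
    x = signal if prefiltered else bandpass_filter(
        np.asarray(signal, dtype=float), fs, *SO_BAND)
    return np.degrees(np.angle(sps.hilbert(x))) % 360.0


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    z = np.exp(1j * np.radians(np.asarray(angles_deg, dtype=float)))
    return float(np.degrees(np.angle(z.mean())) % 360.0)


def itpc(angles_deg: np.ndarray) -> float:
    z = np.exp(1j * np.radians(np.asarray(angles_deg, dtype=float)))
    return float(np.abs(z.mean()))


@dataclass
class CouplingResult:
    spindle_class: str
    channel: str
    n_spindles: int
    n_overlap: int
    overlap_prop: float
    mean_angle_deg: float   # NaN when no overlap
    itpc: float             # NaN when no overlap
    overlap_z: float = np.nan
    itpc_z: float = np.nan
    n_perm: int = 0
    reason: str = ""


def _so_interval_arrays(sos: list[SOEvent]) -> tuple[np.ndarray, np.ndarray]:
    starts = np.array([s.down_zc_s for s in sos], dtype=float)
    ends = np.array([s.end_zc_s for s in sos], dtype=float)
    order = np.argsort(starts)
    return starts[order], ends[order]


def _peaks_in_intervals(peaks: np.ndarray, starts: np.ndarray,
                        ends: np.ndarray) -> np.ndarray:
    """Boolean mask: peak inside some [start, end). Intervals disjoint."""
    if len(starts) == 0 or len(peaks) == 0:
        return np.zeros(np.shape(peaks), dtype=bool)
    edges = np.ravel(np.column_stack([starts, ends]))
    idx = np.searchsorted(edges, peaks, side="right")
    return (idx % 2) == 1


def couple(spindle_peaks: np.ndarray, sos: list[SOEvent],
           phase_deg: np.ndarray, fs: float, spindle_class: str = "",
           channel: str = "") -> CouplingResult:
    """Observed coupling metrics.

    ``spindle_peaks`` are peak times (s) and ``phase_deg`` the SO phase
    series, both on the same (concatenated retained-stage) timeline.
    """
    peaks = np.asarray(spindle_peaks, dtype=float)
    n_spindles = len(peaks)
    if n_spindles == 0:
        return CouplingResult(spindle_class, channel, 0, 0, np.nan,
                              np.nan, np.nan, reason="no_spindles")
    starts, ends = _so_interval_arrays(sos)
    inside = _peaks_in_intervals(peaks, starts, ends)
    n_overlap = int(inside.sum())
    if n_overlap == 0:
        return CouplingResult(spindle_class, channel, n_spindles, 0, 0.0,
                              np.nan, np.nan, reason="no_overlap")
    idx = np.minimum((peaks[inside] * fs).astype(int), len(phase_deg) - 1)
    angles = phase_deg[idx]
    return CouplingResult(
        spindle_class, channel, n_spindles, n_overlap,
        n_overlap / n_spindles, circular_mean_deg(angles), itpc(angles))


def permutation_null(result: CouplingResult, spindle_peaks: np.ndarray,
                     sos: list[SOEvent], phase_deg: np.ndarray, fs: float,
                     timeline_s: float | None = None, n_perm: int = 10000,
                     seed: int = 0) -> CouplingResult:
    """Attach permutation z-scores to an observed CouplingResult.

    Vectorized over permutations; the permutation RNG is independent of
    any detection seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    peaks = np.asarray(spindle_peaks, dtype=float)
    out = CouplingResult(**{**result.__dict__})
    out.n_perm = n_perm
    if result.n_spindles == 0 or not sos:
        out.reason = out.reason or "degenerate_null"
        return out
    T = timeline_s if timeline_s is not None else len(phase_deg) / fs
    starts, ends = _so_interval_arrays(sos)

    # overlap null: circular shift of the whole spindle-peak series
    shifts = rng.uniform(0.0, T, size=n_perm)
    shifted = (peaks[None, :] + shifts[:, None]) % T
    null_overlap = _peaks_in_intervals(shifted.ravel(), starts, ends) \
        .reshape(n_perm, -1).mean(axis=1)
    sd = null_overlap.std()
    if sd > 0:
        out.overlap_z = float((result.overlap_prop - null_overlap.mean()) / sd)
    else:
        out.reason = (out.reason + ";" if out.reason else "") + "overlap_null_sd0"

    # ITPC null: uniform resampling of times within random SO intervals
    if result.n_overlap >= 1 and np.isfinite(result.itpc):
        k = rng.integers(0, len(starts), size=(n_perm, result.n_overlap))
        u = rng.uniform(0.0, 1.0, size=(n_perm, result.n_overlap))
        t = starts[k] + u * (ends[k] - starts[k])
        idx = np.minimum((t * fs).astype(int), len(phase_deg) - 1)
        ang = np.radians(phase_deg[idx])
        null_itpc = np.abs(np.exp(1j * ang).mean(axis=1))
        sd = null_itpc.std()
        if sd > 0:
            out.itpc_z = float((result.itpc - null_itpc.mean()) / sd)
        else:
            out.reason = (out.reason + ";" if out.reason else "") + "itpc_null_sd0"
    return out
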