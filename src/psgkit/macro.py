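"""Hypnogram-derived sleep macro-architecture metrics.

Computes the standard whole-night summary statistics: total sleep time
(TST), sleep maintenance efficiency (SME), wake after sleep onset
(WASO), sleep fragmentation index (SFI), stage durations/proportions,
REM latency, NREM cycle count and mean duration, and the NREM<->R
transition index (TI NR-R).

Definitions (AASM-style conventions, configurable where the field has
no single standard):

* sleep onset  = first epoch scored N1/N2/N3/R
* TST          = minutes scored in any sleep stage
* SME          = TST / minutes from sleep onset to the end of the last
                 sleep epoch
* WASO         = wake minutes within that sleep-onset-to-last-sleep span
* SFI          = transitions from N2/N3/R to W or N1, per hour of TST
* REM latency  = minutes from sleep onset to the first R epoch
* TI NR-R      = count of boundaries between maximal NREM segments and
                 R segments (either direction)
* NREM cycles  = Feinberg & Floyd-style rules, see ``detect_nrem_cycles``
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, SLEEP_STAGES, NREM_STAGES


@dataclass
class CycleRules:
    """Adapted Feinberg & Floyd criteria for NREM cycle segmentation."""

    min_nrem_minutes: float = 15.0
    min_rem_minutes: float = 5.0
    first_rem_exempt: bool = True       # first R period may be < min_rem_minutes
    terminal_nrem_counts: bool = True   # trailing NREM >= min counts as final cycle


@dataclass
class MacroMetrics:
    tst: float
    sme: float
    waso: float
    sfi: float
    stage_minutes: dict
    stage_proportion: dict
    rem_latency: float | None
    n_cycles: int
    mean_cycle_minutes: float | None
    ti_nr_r: int

    def to_series(self) -> pd.Series:
        d = asdict(self)
        flat = {}
        for k, v in d.items():
            if isinstance(v, dict):
                for stage, val in v.items():
                    flat[f"{k}_{stage}"] = val
            else:
                flat[k] = v
        return pd.Series(flat)


def _segments(stages: np.ndarray):
    """Maximal runs of identical labels as (label, start, stop) half-open."""
    out = []
    start = 0
    for i in range(1, len(stages) + 1):
        if i == len(stages) or stages[i] != stages[start]:
            out.append((stages[start], start, i))
            start = i
    return out


def detect_nrem_cycles(hyp: Hypnogram, rules: CycleRules | None = None):
    """Segment the night into NREM-R cycles.

    A cycle is an NREM period of at least ``min_nrem_minutes`` followed
    by an R period of at least ``min_rem_minutes`` (the first R period
    is exempt from the minimum).  A terminal NREM period without
    subsequent R still counts as a final cycle if it meets the NREM
    minimum.  Short interposed NREM (below the minimum) does not start
    a new cycle.

    Returns a list of dicts with keys start_epoch, end_epoch (half-open),
    nrem_minutes, rem_minutes.
    """
    rules = rules or CycleRules()
    epm = hyp.epoch_seconds / 60.0
    # collapse to NREM / R / W chunks (W is transparent inside a period)
    segs = _segments(np.asarray(
        ["N" if s in NREM_STAGES else s for s in hyp.stages], dtype=object))

    cycles = []
    cur = None  # current cycle accumulator
    seen_rem = False
    for label, a, b in segs:
        minutes = (b - a) * epm
        if label == "N":
            if cur is None:
                cur = {"start_epoch": a, "end_epoch": b,
                       "nrem_minutes": minutes, "rem_minutes": 0.0}
            elif cur["rem_minutes"] > 0:
                # NREM after an R period: new cycle only if the R period
                # was long enough (or was the exempt first R) and the new
                # NREM block itself reaches the minimum
                rem_ok = (cur["rem_minutes"] >= rules.min_rem_minutes
                          or (rules.first_rem_exempt and not seen_rem))
                if rem_ok and minutes >= rules.min_nrem_minutes:
                    seen_rem = True
                    cycles.append(cur)
                    cur = {"start_epoch": a, "end_epoch": b,
                           "nrem_minutes": minutes, "rem_minutes": 0.0}
                else:
                    cur["nrem_minutes"] += minutes
                    cur["end_epoch"] = b
            else:
                cur["nrem_minutes"] += minutes
                cur["end_epoch"] = b
        elif label == "R":
            if cur is None:
                continue  # R before any NREM: not part of a cycle
            cur["rem_minutes"] += minutes
            cur["end_epoch"] = b
        # W inside the night does not break a cycle
    if cur is not None:
        if cur["rem_minutes"] > 0 or (
            rules.terminal_nrem_counts
            and cur["nrem_minutes"] >= rules.min_nrem_minutes
        ):
            cycles.append(cur)
    return cycles


def compute_macro(hyp: Hypnogram, rules: CycleRules | None = None) -> MacroMetrics:
    """Compute all macro-architecture metrics from a hypnogram."""
    stages = np.asarray(hyp.stages, dtype=object)
    epm = hyp.epoch_seconds / 60.0
    sleep = hyp.is_sleep()
    if not sleep.any():
        raise ValueError("no sleep epochs in hypnogram")

    onset = int(np.flatnonzero(sleep)[0])
    last = int(np.flatnonzero(sleep)[-1])
    span = stages[onset: last + 1]
    span_sleep = np.isin(span, SLEEP_STAGES)

    tst = float(sleep.sum() * epm)
    waso = float((~span_sleep).sum() * epm)
    sme = tst / (len(span) * epm)

    stage_minutes = {s: float((stages == s).sum() * epm) for s in SLEEP_STAGES}
    stage_proportion = {s: stage_minutes[s] / tst for s in SLEEP_STAGES}

    # SFI numerator: transitions from established sleep (N2/N3/R) to W or N1
    frag = 0
    for i in range(1, len(span)):
        if span[i - 1] in ("N2", "N3", "R") and span[i] in ("W", "N1"):
            frag += 1
    sfi = frag / (tst / 60.0)

    rem_idx = np.flatnonzero(stages == "R")
    rem_latency = None
    if rem_idx.size:
        rem_latency = float((rem_idx[0] - onset) * epm)

    # TI NR-R: boundaries between maximal NREM segments and R segments,
    # ignoring intervening wake
    collapsed = [s for s in ("N" if x in NREM_STAGES else x for x in span)
                 if s in ("N", "R")]
    ti = 0
    for i in range(1, len(collapsed)):
        if collapsed[i] != collapsed[i - 1]:
            ti += 1

    cycles = detect_nrem_cycles(hyp, rules)
    n_cycles = len(cycles)
    mean_cycle = None
    if n_cycles:
        mean_cycle = float(np.mean(
            [(c["end_epoch"] - c["start_epoch"]) * epm for c in cycles]))

    return MacroMetrics(
        tst=tst, sme=sme, waso=waso, sfi=sfi,
        stage_minutes=stage_minutes, stage_proportion=stage_proportion,
        rem_latency=rem_latency, n_cycles=n_cycles,
        mean_cycle_minutes=mean_cycle, ti_nr_r=ti,
    )
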