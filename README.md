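# psgkit

Pediatric sleep-EEG analysis in Python: from overnight polysomnography
(PSG) signals and a 30-s hypnogram to sleep macro-architecture, stage-wise
spectral band power, slow/fast sleep-spindle and slow-oscillation (SO)
events, permutation-calibrated SO–spindle coupling, and a sleep-based
**brain-age** model whose gap (predicted − chronological age) flags
atypical neurodevelopment.

Sleep micro-architecture changes dramatically across childhood: spindle
density roughly doubles between ages 4 and 16, intra-spindle deceleration
("chirp") deepens, SO amplitude falls while SO rate rises, and SO–spindle
phase coupling tightens. `psgkit` implements the full measurement chain for
these quantities, plus a ground-truthed **synthetic-PSG generator** so that
every stage — detector, estimator, statistical model — is testable end to
end without access-controlled clinical data. It is aimed at sleep and
neurodevelopment researchers who need a transparent, reproducible pipeline
they can validate on known ground truth before pointing it at real EDFs.

## What's inside

| module | what it does |
| --- | --- |
| `psgkit.synth` | stage-structured synthetic EEG: 1/f^α background, Hann-windowed spindles with linear frequency ramps, biphasic raised-cosine SOs, von-Mises SO-phase coupling, injectable artifacts, age-structured cohorts — all logged as ground truth |
| `psgkit.io` | EDF read (via MNE) / 16-bit EDF write, stage-TSV parsing with an alias table |
| `psgkit.preprocess` | contralateral-mastoid referencing, 200 Hz resampling, spectrum-interpolation mains removal, 0.5–35 Hz zero-phase band-pass, Hjorth-parameter epoch rejection, polarity resolution, record exclusions |
| `psgkit.macro` | TST, SME, WASO, SFI, stage composition, REM latency, NREM cycles, NREM↔R transition index |
| `psgkit.spectral` | Welch PSD (4-s Tukey segments, 0.25 Hz bins) and band summaries (absolute, log, relative) |
| `psgkit.spindles` | dual-threshold Morlet-envelope detection of 11 Hz and 15 Hz spindles, band-ratio QC, density/amplitude/duration/frequency/chirp |
| `psgkit.so` | zero-crossing SO detection with relative or absolute amplitude thresholds, morphology metrics |
| `psgkit.coupling` | gross overlap, SO phase at spindle peak (0° = positive peak), ITPC, permutation z-scores |
| `psgkit.brainage` | covariate-adjusted age associations with FDR, correlation pruning, OLS brain-age model with 10-fold CV, resampled gap group analysis, age-bin similarity profiles |
| `psgkit.validation` | the end-to-end benchmarks backing the acceptance results |

## Worked example

Synthesize a night with known spindle/SO content, detect events, and
quantify coupling:

```python
import numpy as np
from psgkit import (EventSpec, SubjectProfile, Hypnogram, synthesize_record,
                    epoch_record, detect_channel_spindles, spindle_metrics,
                    detect_so, SOThresholds, so_phase, couple,
                    permutation_null)

hyp = Hypnogram(np.array(["N2"] * 40, dtype=object))      # 20 min of N2
specs = [EventSpec("so", density=6.0, amplitude=80, p2p=130, duration=1.2,
                   channels=("C3",)),
         EventSpec("fast_spindle", density=2.0, amplitude=30, duration=1.0,
                   frequency=15.0, coupling_phase=0.0, coupling_kappa=20.0,
                   channels=("C3",))]
rec, truth = synthesize_record(SubjectProfile("demo", age=8.0), hyp, specs,
                               fs=200.0, seed=5, channels=["C3"])

ep = epoch_record(rec, hyp)
spindles = [e for e in detect_channel_spindles(ep, "C3", "fast") if e.qc_pass]
m = spindle_metrics(spindles, ep.kept_minutes("N2", "C3"))
print(f"density {m['density']:.2f}/min  frequency {m['frequency']:.2f} Hz")

x = rec.get("C3")
sos = detect_so(x, 200.0, SOThresholds(mode="absolute"))
phase = so_phase(x, 200.0)
peaks = np.array([e.peak_time_s for e in spindles])
res = permutation_null(couple(peaks, sos, phase, 200.0), peaks, sos,
                       phase, 200.0, n_perm=2000, seed=99)
print(f"overlap {res.overlap_prop:.2f}  angle {res.mean_angle_deg:.1f} deg  "
      f"itpc {res.itpc:.3f}  itpc_z {res.itpc_z:.2f}")
```

Output:

```
density 2.00/min  frequency 15.01 Hz
overlap 0.95  angle 358.1 deg  itpc 0.876  itpc_z 8.08
```

The detector recovers the implanted 2/min density and 15 Hz frequency
exactly; 95 % of spindle peaks fall inside detected SOs, clustered within
2° of the implanted preference at the SO positive peak (0°/360°), with an
ITPC permutation z-score of 8.1 — far beyond the 1.96 significance line,
as its κ=20 coupling should produce.

The same stages are scriptable from the shell:

```bash
psgkit synth record --seed 4 --out night/
psgkit preprocess --edf night/record.edf --stages night/stages.tsv --out night/prep
psgkit spindles --edf night/record.edf --stages night/stages.tsv --out night/spn
psgkit macro --stages night/stages.tsv --out night/macro.csv
```

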