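# pkjpause

Trial-by-trial analysis of the conditional firing pause in cerebellar
Purkinje cells.

In eyeblink conditioning, a conditional stimulus (CS) that predicts a
periocular unconditional stimulus (US) at a fixed CS–US interval *T* comes
to evoke, in a trained Purkinje cell, a pause in the cell's high-rate
spontaneous simple-spike firing. The pause's onset latency (↑) and offset
latency (↓) scale with *T*: the cell carries a read-out of the learned
duration. Because the pause is usually a single unusually long interspike
interval superimposed on irregular 40–80 Hz background firing, averaging
across trials smears its structure; locating it **on single trials** is
the measurement problem this package solves, for electrophysiologists and
computational neuroscientists analysing trial-aligned spike-time data.

## The method

Trial time is divided into 1-ms moments and each trial is binarized
(at most one spike per moment), converting firing rate into a momentary
spike probability *p*. A peri-CS histogram (15-ms bins over [−0.3 s, *T*])
supplies three statistics: the anchor (the bin in (0, *T*] where *p* is
minimal), the probability at that low point *p*<sub>low</sub>, and the mean
pre-CS probability *p*<sub>pre</sub>.

Reading the binarized trial **backward** from the anchor, pause-onset
estimation becomes Bayesian change-point detection on a Bernoulli
sequence: a no-change model (constant *p*, Beta prior centred on
*p*<sub>pre</sub>) is compared with a one-change model (a step from a
Beta(*κp*<sub>low</sub>+ε, *κ*(1−*p*<sub>low</sub>)+ε) segment up to a
Beta(*κp*<sub>pre</sub>+ε, ·) segment, with a uniform prior over step
locations). Both marginal likelihoods are exact conjugate integrals. The
**weight of evidence** is the log₁₀ Bayes factor: 1 ⇔ 10:1 odds for a
step, 2 ⇔ 100:1. The offset is found by the mirrored construction on the
forward sequence. A pause is detected only when the evidence exceeds 1
**and** the estimated pre-CS-side probability exceeds the in-pause
probability (no detection when firing accelerates during the CS). Each
detected trial yields ↑, ↓, width W = ↓−↑, the longest within-pause ISI M,
and the abruptness (latency from ↑ to the start of M).

Around the detector sit the supporting analyses: Fano factors
(variance/mean of spike counts) with stationary-Poisson plausibility
limits (χ² and Monte-Carlo), exponential fits to the ISI distribution with
a tail-excess statistic, acquisition-trial estimation from cumulative
records of pre-CS minus within-CS rate differences (10-Hz criterion), and
the descriptive battery: per-cell quartiles and CoV = σ/μ (constant CoV
across *T* is scalar variability, Weber's law for timing), the six
pairwise correlations among ↑, ↓, W, M, and the backward ISI regression
that tests for graded rather than step-like onsets. A calibrated synthetic
generator (renewal background with refractory floor and heavy ISI tail,
trial-to-trial rate drift, scalar-variability pause injection) makes every
stage testable end to end.

## Worked example

```python
import numpy as np
from pkjpause import (Protocol, generate_cell_recording, detect_all,
                      summarize_cell, between_trial_fano)

proto = Protocol(cs_us_interval=0.3, cs_duration=0.3, iti=15.0)
rec, truth = generate_cell_recording(proto, n_trials=20, seed=7, cell_id="demo")

pauses = detect_all(rec)
print(pauses[["trial_index", "onset_s", "offset_s", "width_s",
              "longest_isi_s", "onset_woe", "detected"]].head(5).round(4))

summary = summarize_cell(pauses, proto)
print(summary.stats.round(3))

fano = between_trial_fano(rec, window=(-1.0, 0.0), alpha=0.01, sided="upper")
print(f"between-trial Fano = {fano.fano:.2f} "
      f"(upper stationary-Poisson limit {fano.upper_limit:.2f})")
```

Output:

```
   trial_index  onset_s  offset_s  width_s  longest_isi_s  onset_woe  detected
0            0   0.0945    0.3455    0.251         0.2522     1.9398      True
1            1   0.0925    0.3605    0.268         0.2693     2.8044      True
2            2   0.1105    0.3105    0.200         0.2002     1.9916      True
3            3   0.1135    0.3195    0.206         0.2068     1.7608      True
4            4   0.1195    0.3225    0.203         0.2027     1.3676      True
              mean  median     q1     q2     q3    cov
onset        0.092   0.094  0.080  0.094  0.104  0.173
offset       0.322   0.316  0.301  0.316  0.332  0.106
width        0.229   0.222  0.205  0.222  0.244  0.157
longest_isi  0.230   0.223  0.205  0.223  0.245  0.157
between-trial Fano = 2.43 (upper stationary-Poisson limit 1.90)
```

Onsets cluster near *T*/3 ≈ 0.1 s and offsets near *T* = 0.3 s — the
injected scalar-timing structure read back from single trials. Width and
longest-ISI rows nearly coincide: the pause *is* one long interspike
interval. The Fano factor of pre-CS counts (2.43) far exceeds the 0.01
upper limit for a stationary Poisson process (1.90), reflecting the
generator's trial-to-trial basal-rate drift.

The same stages are available from a shell:

```bash
pkjpause simulate --cells 6 --trials 20 --seed 0 --out data/
pkjpause detect --in data/ --out pauses.csv
pkjpause fano --in data/ --out fano.csv
pkjpause acquisition --in data/ --out acquisition.csv
pkjpause stats --pauses pauses.csv --spikes data/ --out-dir stats/
pkjpause run --seed 0 --out run_out/          # full pipeline + manifest
```

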