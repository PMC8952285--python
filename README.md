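# capcri

Cardiopulmonary resonance indices (CRI) for sleep microstructure: detect
the cyclic alternating pattern (CAP) of NREM sleep and screen for
insomnia and narcolepsy from cardiorespiratory signals alone — ECG-derived
RR intervals, respiration, and chest acceleration — no EEG required.

The package is aimed at sleep-research and physiological-signal-processing
groups who want an EEG-free CAP/staging pipeline they can test end to end:
it ships a complete synthetic polysomnography generator, so every stage of
the method is exercised without any data download.

## The method in brief

Respiratory sinus arrhythmia — the drive of respiration on heart rate —
is quantified by Granger causality.  Per 120-s window (10-s steps), the
cleaned RR tachogram and respiration are resampled to 4 Hz and fitted
with a bivariate AR model

```
RRI(t) = Σⱼ A11ⱼ·RRI(t−j) + Σⱼ A12ⱼ·RSP(t−j) + ε₁(t)
RSP(t) = Σⱼ A21ⱼ·RRI(t−j) + Σⱼ A22ⱼ·RSP(t−j) + ε₂(t)
```

The time-domain causality is `ln var(ε₁ᴿ)/var(ε₁ᵁ)` (restricted model
omits the A12 lags) and Geweke's spectral decomposition attributes it
across frequency, giving a curve G(f).  The cardiopulmonary resonance
indices summarise G(f) in the respiratory band (0.03–0.5 Hz): resonance
frequency F_A (argmax), amplitude CRA (peak height), bandwidth CRB
(width at half maximum), quality factor CRQ = F_A/CRB, and resistance
CRR = CRB/(2π·F_A²), so that CRQ·CRR·2π·F_A = 1 (unit-capacitance RLC
convention).  Per 30-s epoch, 21 features (3 body-movement, 12 HRV, 6
CRI) plus two HMM-derived CRA-stability features feed a two-layer random
forest: layer 1 scores the six macro stages (W, REM, S1–S4), layer 2
scores the CAP phase (A1/A2/A3/NA) within each NREM stage.  A
subject-level RBF SVM over staged-feature summaries separates healthy,
insomnia, and narcolepsy profiles.

## Worked example

Simulate a short healthy recording, extract the CRI track, and print the
median indices:

```python
import numpy as np
from capcri.synthetic import HEALTHY, SimConfig, simulate_cardioresp
from capcri.causality import cri_track

cfg = SimConfig(duration_s=1500.0, seed=5)
sim = simulate_cardioresp(["S4-NA"] * 50, HEALTHY, cfg,
                          np.random.default_rng(11))
track = cri_track(sim["rri"], sim["rsp"])
valid = [r for r in track if r.valid]
print(f"{len(valid)} valid windows of {len(track)}")
print(f"median F_A  = {np.median([r.f_a for r in valid]):.3f} Hz")
print(f"median CRA  = {np.median([r.cra for r in valid]):.2f}")
print(f"median CRQ  = {np.median([r.crq for r in valid]):.1f}")
```

Output:

```
130 valid windows of 138
median F_A  = 0.223 Hz
median CRA  = 3.73
median CRQ  = 9.3
```

The resonance frequency tracks the simulated breathing rate (deep-sleep
breathing runs slow, ~0.22 Hz); CRA ≈ 3.7 reflects the strong stage-S4
coupling of the healthy profile, and the quality factor the narrow,
regular deep-sleep resonance.  Running the same snippet with
`NARCOLEPSY` in place of `HEALTHY` drops the median CRA to 1.93 — the
globally weak coupling (high damping) that the diagnosis stage keys on.

The same pipeline is available from the shell:

```bash
capcri simulate --profile healthy --hours 8 --seed 7 --out rec/
capcri cri --rr rec/rr.csv --resp rec/resp.csv --out cri.csv
capcri features --in rec/ --out features.csv
capcri train --features features.csv --out model.bin --seed 17
capcri classify --model model.bin --features features.csv --out hypnogram.tsv
capcri evaluate --pred hypnogram.tsv --truth rec/annotations.tsv --out report.json
```

## Layout

| module | contents |
|--------|----------|
| `capcri.preprocess` | quality gate Q, RR artifact gate + repair, wavelet/Butterworth denoising, R-peak detection, windowing |
| `capcri.causality` | bivariate AR fit, time/spectral Granger causality, CRI extraction, the 120-s/10-s CRI track |
| `capcri.features`  | per-epoch BM / HRV / CRI features |
| `capcri.hmm`       | supervised 18-state HMM over CRA, Viterbi, stability features |
| `capcri.staging`   | training-epoch selection, outlier compensation, two-layer random-forest stager (`CapStager`) |
| `capcri.diagnosis` | subject summaries, SVM diagnoser (`SubjectDiagnoser`), versioned training library |
| `capcri.synthetic` | the surrogate-recording generator (profiles, sleep architecture, cardiorespiratory signals) |
| `capcri.evaluate`  | confusion matrices, F1 reports, collapsed views, ANOVA + Dunnett, subject-level cross-validation |
| `capcri.io`, `capcri.cli` | CSV/TSV/EDF readers and writers, `capcri` command-line entry points |
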