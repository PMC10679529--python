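# tremorloop

A computational model of Parkinsonian rest tremor and its modulation by
cerebellar transcranial alternating current stimulation (tACS), together
with the accelerometer feature pipeline used to quantify tremor and a
synthetic cohort generator that makes the whole statistics pipeline
testable without clinical recordings.

**Who it is for.** Researchers in computational neuroscience and
neuromodulation who want a small, fully reproducible sandbox for
coupled-oscillator tremor dynamics: how basal-ganglia-controlled coupling
strength moves a cortico–cerebello–spinal loop between a quiet "healthy"
regime and a hyperactive Parkinsonian regime, and what a sinusoidal drive
into the cerebellum does to the measured tremor output.

## The model

Three Van der Pol oscillators stand in for the cortex, the cerebellum and
the spinal-circuit/muscular system (SC-MS, whose output Y_s plays the
role of the measured hand acceleration):

```
Y''_co - (λ - Y_co²) Y'_co + p_co² Y_co = BR (Y_ce - Y_co)
Y''_ce - (λ - Y_ce²) Y'_ce + p_ce² Y_ce = BR (Y_co - Y_ce) + B1 Y_s + I(t)
Y''_s  - (λ - Y_s²)  Y'_s  + p_s²  Y_s  = B2 Y_co
```

with bifurcation parameter λ = 0.3 and intrinsic frequencies
p = (15, 20, 10) Hz. The basal ganglia enter only through the static
coupling weights BR, B1, B2 — an abstraction of the dopamine level:
weights in [30, 40] define the healthy state, weights in [1, 10] the
Parkinsonian (PD) state. I(t) is the tACS drive into the cerebellum:
`A sin(2π w t)` while stimulation is on, `A e^{-bt} sin(2π w t)` after it
ends. (See `docs/methods.md` for the time convention that makes the
printed p values intrinsic frequencies in Hz.)

The feature pipeline implements the three tremor features used on
accelerometer data: resultant acceleration RA = √(x²+y²+z²), approximate
entropy ApEn(m, r) = φ_m(r) − φ_{m+1}(r) with Chebyshev matching and
self-matches included (defaults m = 2, r = 0.2·SD), and the FFT peak
frequency/amplitude. The synthetic cohort generator emulates the clinical
sessions: 15 subjects, tremor in 4–7 Hz, three recording states
(pre/during/post stimulation) of 65 s, each holding three 15-s intervals
separated by 10-s gaps.

## Worked example

```python
>>> import tremorloop as tl
>>> comp = tl.compare_states()          # healthy B=35 vs PD B=5, 120 s each
>>> round(comp.amplitude_healthy["scms"], 3), round(comp.amplitude_pd["scms"], 3)
(0.67, 0.697)
>>> round(comp.apen_healthy, 3), round(comp.apen_pd, 3)
(0.464, 0.192)
```

Lowering the coupling weights from the healthy to the PD preset makes
every unit *more* active (mean |Y_s| rises from 0.670 to 0.697 — the
hyperactivity signature of the low-dopamine state) and makes the SC-MS
output markedly *more regular* (ApEn drops from 0.46 to 0.19): the three
units synchronize into a cleaner, larger oscillation — a rest tremor.

Driving the PD model's cerebellum with tACS at its own tremor peak:

```python
>>> feats = tl.simulate_protocol()      # 30 s pre, 60 s tACS, 60 s post
>>> {k: round(v, 4) for k, v in feats.mean_accel.items()}
{'pre': 0.6966, 'during': 0.6867, 'post': 0.6964}
>>> {k: round(v, 3) for k, v in feats.apen.items()}
{'pre': 0.193, 'during': 0.182, 'post': 0.188}
```

The tremor output is suppressed while the drive is on and recovers only
partway during the decaying offline phase (pre > post > during for both
the mean acceleration and the entropy), while the tremor peak frequency
stays at 10 Hz throughout. The suppression the model can produce is small
(~1.5%); the loop architecture caps it — see `docs/methods.md`.

The same pipeline runs on synthetic accelerometer cohorts:

```python
>>> import pandas as pd
>>> cohort = tl.generate_cohort(15, master_seed=1)   # default effect profile
>>> feats = pd.concat([tl.session_features(s) for s in cohort])
>>> report = tl.paired_stats(feats)
>>> report.loc[0, ["comparison", "percent_change", "p_value"]].tolist()
['during_vs_pre', 76.81, 6.1e-05]
```

The generator injects a 76% during-stimulation attenuation of the mean
resultant acceleration (and 68% post); the feature-and-Wilcoxon pipeline
recovers it from the raw tri-axial signals.

## Command line

```bash
tremorloop simulate --state pd --out runs/pd          # trajectory + features
tremorloop simulate --stimulate --out runs/protocol   # pre/during/post tACS run
tremorloop sweep --b-grid 1,5,10,15,20,25,30,35,40 --out runs/sweep
tremorloop synth --n-subjects 15 --seed 1 --out runs/cohort
tremorloop analyze runs/cohort/manifest.json --out runs/analysis
```

Each command accepts a YAML `--config` and writes a resolved-config copy
next to its outputs, so every run is reproducible from that file alone.

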