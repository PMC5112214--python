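# mocgain

Psychophysical estimation of medial-olivocochlear (MOC) cochlear gain
reduction from temporal masking curves (TMCs), with click-evoked
otoacoustic emission (CEOAE) suppression analysis and a full synthetic
experiment simulator.

## The problem

The cochlear amplifier boosts low-level sounds by tens of dB and
compresses the intensity range of the basilar-membrane response.  The MOC
efferent reflex can turn this gain down — e.g. when a contralateral noise
"elicitor" is played to the other ear.  The TMC method measures the effect
behaviourally: forward-masking thresholds for a brief 2-kHz tone are
tracked as a function of the masker–signal gap, with the masker either at
the signal frequency (*on-frequency*, gain-compressed tip response) or
well below it (*off-frequency*, linear tail response).  Comparing the two
curves, with and without the elicitor, yields the listener's cochlear
input–output (IO) function and the elicitor-induced gain reduction.

This package is for auditory psychophysicists who want to fit this model
to TMC data, to simulate the whole experiment (adaptive tracking included)
to validate an analysis, or to reuse its group statistics (exhaustive
bootstrap with Gaussian/Nakagami density fits) and its CEOAE suppression
chain.

## The model

The tip-response IO function is piecewise linear in dB,
`f_a(L) = L + G(L)` with

```
G(L) = G_max                        for L <= BP1
G(L) = (c - 1)(L - BP1) + G_max     for BP1 <= L <= BP2
G(L) = 0                            for L >= BP2
```

so `G_max = (1 - c)(BP2 - BP1)`; the tail response is `f_p(L) = L - P`.
The masker effect decays at `mu` dB/ms of gap `t`, and threshold
corresponds to a fixed intensity ratio `k` between signal and masker
responses:

```
MThr_on(t)  = f_a^-1( f_a(L_s) / (k e^{-mu t}) )
MThr_off(t) = f_p^-1( f_a(L_s) / (k e^{-mu t}) )
```

A contralateral elicitor is modelled as reducing `G_max` by `dG` with the
break points fixed, which raises the compression exponent to
`c~ = 1 - (G_max - dG)/(BP2 - BP1)`.  The six baseline parameters
(`G_max, c, BP_ctr, k, mu, P`) are estimated per listener by bounded
multistart least squares on the without-elicitor thresholds; `dG` is then
the single free parameter for the with-elicitor thresholds.

Also included: dual-roex excitation patterns (active tip + passive tail
filters), CEOAE analysis (zero-phase 250–6000-Hz band-pass, 6–16-ms
window, co-spectrum amplitude, reproducibility gating, normalized
suppression index ΔCEOAEn), and exact group statistics — the exhaustive
multinomial-weighted bootstrap of the mean over all C(2N−1, N) resamples
with Gaussian (moments) and Nakagami (weighted ML) density fits.

## Worked example

Simulate one listener (true `G_max` 30 dB, `c` 0.2, `dG` 10 dB) through
the 3-AFC two-up/one-down adaptive tracking procedure at 2-dB observer
noise, fit the model, and summarize the reference cohort:

```python
import numpy as np
from mocgain import CochlearIOParams, MaskingContext, load_reference_cohort
from mocgain import enumerate_bootstrap, fit_nakagami, nakagami_mean
from mocgain import synthetic_data as sd, tmc_fit

params = CochlearIOParams(g_max=30.0, c=0.2, bp1=28.125, p=20.0)
ctx = MaskingContext(l_s=20.0, k=1.5, mu=0.5)
subject = sd.SubjectRecord("demo", params, ctx, delta_g=10.0, noise_sd=2.0)
table = sd.generate_tmc_dataset(
    subject, sd.identifiable_design(subject), rng=np.random.default_rng(1)
)
fit = tmc_fit.fit_subject(table)
print(f"G_max = {fit.params.g_max:5.2f} dB, c = {fit.params.c:4.2f}, "
      f"dG = {fit.effect.delta_g:5.2f} dB, RMSD = {fit.rmsd_db:.2f} dB")

cohort = load_reference_cohort()
m, omega = fit_nakagami(enumerate_bootstrap(cohort["dG"].to_numpy()))
print(f"mean dG across listeners: {nakagami_mean(m, omega):.1f} dB "
      f"(Nakagami m = {m:.2f}, Omega = {omega:.2f} dB^2)")
```

prints

```
G_max = 30.83 dB, c = 0.20, dG = 10.22 dB, RMSD = 0.62 dB
mean dG across listeners: 4.4 dB (Nakagami m = 1.48, Omega = 23.25 dB^2)
```

i.e. the track-simulated thresholds return the generating parameters to
within a dB, and the bootstrap of the reference cohort's gain-reduction
column is positively skewed with an expected mean reduction of 4.4 dB
(about 18 % of the mean 23.9-dB gain).

The same pipeline runs from the shell:

```sh
mocgain all --seed 1 --out-dir out/      # simulate -> fit -> summarize -> ceoae
mocgain fit my_tmc_table.csv --out-dir out/
```

TMC tables are delimited text with columns `subject_id, gap_ms, masker
(on|off), elicitor (with|without), threshold_db_spl, signal_level_db_spl`.

## Layout

| module | contents |
| --- | --- |
| `mocgain.io_model` | IO functions, TMC/GOM predictions, elicitor and excitatory-masking effects |
| `mocgain.tmc_fit` | per-listener least-squares estimation, fit reports |
| `mocgain.excitation` | roex excitation patterns (tip + tail filters) |
| `mocgain.group_stats` | exhaustive bootstrap, density fits, correlations |
| `mocgain.ceoae` | CEOAE filtering/windowing/co-spectrum chain |
| `mocgain.synthetic_data` | cohort sampler, adaptive-track simulator, CEOAE generator |
| `mocgain.cli` | `mocgain` command-line pipeline |

See `docs/methods.md` for modelling assumptions, parameter conventions and
known limitations.
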