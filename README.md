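# balancenet

Time-variant directed EEG connectivity analysis for postural-balance
experiments: multi-trial Kalman tvMVAR modelling, time-variant
generalized partial directed coherence (gPDC), phase-locking-based
artifact screening, directed-network statistics, and 4-mode PARAFAC
decomposition of the group connectivity tensor — with a synthetic-data
generator that emulates the balance experiment so the whole chain is
testable end-to-end against planted ground truth.

## The problem

In a balance perturbation experiment, a subject stands on a platform
that is held stable and is released at a known onset into free
oscillation, while EEG is recorded over repeated trials (e.g. 32
channels, 1000 Hz, 8 s epochs with the stable→unstable transition at
3 s).  The scientific question is *directed*: which cortical areas
drive which others, in which frequency band, and how does that change
when balance becomes unstable?

The chain implemented here answers it as follows:

1. **Preprocessing** — onset detection on the platform trace (5-SD
   rule over a 5 s baseline), 8 s epoching (3 s pre / 5 s post),
   common-average reference, regression-based ocular correction,
   decimation 1000→100 Hz (order-8 Chebyshev-I, zero-phase).
2. **tvMVAR** — a time-variant VAR(p) whose coefficients follow a
   random walk, estimated by a multi-trial Kalman filter: all trials
   update the same coefficient state at each time step, so trial
   information is fused without averaging the data.  Control
   parameters: innovation-variance adaptation rate c1 = 0.02,
   random-walk step width c2 = 0.005, order p = 20 at 100 Hz (AIC-guided,
   fixed by configuration).
3. **Time–frequency analysis** — parametric amplitude maps from the
   model; matched (multi-window) Gabor amplitude/phase maps; the
   phase-locking index across trials PLI(t,f) = |mean e^{iφ}|,
   thresholded by the Rayleigh critical value √(−ln α / n); screening
   of phase-locked sway-interference harmonics (2.6, 5.2, 7.8,
   10.4 Hz) that would masquerade as neural rhythms.
4. **Connectivity** — time-variant gPDC

       π(i←j, t, f) = (|Ā_ij(f,t)| / σ_i) / sqrt(Σ_m |Ā_mj(f,t)|² / σ_m²),

   with Ā(f,t) = I − Σ_k A_k(t)·e^{−i2πfk/fs}; scale-invariant through
   the residual-variance normalization, columns normalized to 1.
   ROI means (theta 5–7 Hz, alpha 9–11 Hz × four 1 s intervals after
   the onset) are discretized at 0.08/0.10/0.12 into weighted directed
   networks; node strength (in+out weight) and its network average
   (ANS) quantify global connectedness; subject-level bootstrap
   confidence tubes (1000 replicates, 2.5/97.5% quantiles) and
   Bonferroni-corrected paired t-tests test condition differences.
5. **Tensor decomposition** — the per-subject gPDC maps of all directed
   pairs form a 4-mode tensor (space × time × frequency × subject),
   decomposed by nonnegative PARAFAC (HALS, multi-start, monotone in
   reconstruction error) into M rank-1 factors: spatial interaction
   patterns, time courses, frequency profiles, subject loadings.

Everything is exercised on synthetic cohorts with planted, time-varying
directed couplings (AR cross-terms switching gain at the onset), so the
package's claims — oracle equivalence, calibration of the statistics,
recovery of planted structure — are tested, not assumed.  See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
import balancenet as bn
from balancenet.preprocess import downsample
from balancenet.tvmvar import grand_mean_model

# a small cohort with a planted theta coupling CPz -> Cz that switches
# on at the onset (3 s)
cfg = bn.SimulationConfig(
    n_subjects=3, n_trials=10,
    channel_names=["Cz", "CPz", "O1", "Oz", "O2"],
    couplings=[bn.Coupling("CPz", "Cz", (5, 7), pre_gain=0.0, post_gain=0.4, lag=2)],
    oscillators=[bn.Oscillator(("CPz", "Cz"), 6.0, 7.5),
                 bn.Oscillator(("O1", "Oz", "O2"), 10.0, 10.0)],
    include_eog=False, onset_impulse_amplitude=0.0,
    sway=bn.SwayInterference(amplitude=0.0), seed=42,
)
rec = downsample(bn.simulate_dataset(cfg), 10)           # 1000 -> 100 Hz

fits = [bn.TimeVaryingVAR(rec.subject(s), order=8).fit() for s in range(3)]
print(fits[0].summary())

freqs = np.arange(2.0, 20.5, 0.5)
pdc = grand_mean_model(fits).gpdc(freqs=freqs, t_step=5)  # grand-mean model
net = bn.discretize(
    bn.roi_mean(pdc, bn.ROISpec((5, 7), (6.5, 7.5), "theta-TI4")),
    pdc.channel_names,
)
print(net.to_dataframe().head(3))
```

prints

```
Time-variant VAR (multi-trial Kalman filter)
==============================================
channels:        5 (Cz, CPz, O1, Oz, O2)
model order p:   8
samples:         800 @ 100 Hz
trials fused:    10
c1 (innov. adapt): 0.02
c2 (random walk):  0.005
stable (rho<1):  False
mean resid. var: 6.651 µV²

  source target    weight  level
0    CPz     Cz  0.958272      3
1     O1     Cz  0.135344      3
2     Oz     Cz  0.112000      2
```

The planted CPz→Cz edge dominates the late theta network (ROI mean
0.96, discretization level 3 = strongest) and points in the planted
direction; the remaining edges are the estimator's noise floor.  The
`stable: False` flag is the stability monitor reporting that the
*estimated* coefficient trajectory transiently crosses the unit circle
(ρ ≈ 1.01) while tracking the strong post-onset coupling — a flag, not
an error.  Condition-wise node strength confirms the global effect:

```python
band = (freqs >= 5) & (freqs <= 7)
ans = [bn.condition_ans(f.gpdc(freqs=freqs, t_step=5), onset_time=3.0) for f in fits]
print(np.mean([a["bss"][band].mean() for a in ans]),
      np.mean([a["bus"][band].mean() for a in ans]))
```

gives a theta-band ANS of 1.35 during stable vs 1.39 during unstable
balancing for this cohort (averaged over subjects) — higher once the
coupling is active.  The 4-mode PARAFAC of the same cohort
(`bn.Parafac(bn.build_tensor([...]), rank=3).fit()`) reaches fit 0.63
and its best-matching factor's space loading peaks exactly on the
`CPz->Cz` pair, with a time loading that rises after the onset.

The full chain — simulation, preprocessing, per-subject fits, artifact
screening, networks per band and interval, ANS tests, PARAFAC — runs as
one call (`balancenet.run_pipeline(PipelineConfig(...), out_dir)`) or
from the shell:

```bash
balancenet run-all --out results/demo --seed 7 --subjects 8
balancenet simulate --config sim.yaml --out raw.h5 --seed 1
balancenet preprocess --in raw.h5 --out epochs.h5 --downsample 10
balancenet fit --in epochs.h5 --out model.h5 --order 20
balancenet pdc --model model.h5 --out net.json --band 5:7 --ti 6.5:7.5
```

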