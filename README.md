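# somatodec

Offline analyses for intracortical brain–computer interface (iBCI) recordings
from two microelectrode arrays implanted at different mediolateral positions
on the precentral gyrus, together with a seeded synthetic cortical-population
generator that makes every stage of the pipeline verifiable against ground
truth.

Motor cortex is somatotopically organised: proximal arm movements (shoulder,
elbow) are represented more dominantly medially, distal movements (grasp,
wrist) more laterally.  For iBCI users this matters directly — which array a
decoder draws on determines how well it can reconstruct reach versus grasp
intent.  This package implements the full offline analysis chain used to
quantify that dependence:

1. **Preprocessing** — multi-unit threshold-crossing counts binned at 50 Hz
   are converted to firing rates with a causal 440 ms exponential smoothing
   window and z-scored per channel.
2. **Somatotopy mapping** — for each movement type the population response
   window (500 ms) is centred on the peak magnitude of PC1 of the
   trial-averaged z-scored rates (*t*&#8202;<sub>M</sub>); per-channel tuning
   is tested with a two-tailed one-sample *t*-test on Movement-minus-Baseline
   spike counts (Bonferroni-corrected, per-test α = 0.0125), and depth of
   modulation is the trial-averaged largest signed rate excursion.
3. **Movement classification** — Naive Bayes on Movement-window spike
   counts, full leave-one-out cross-validation, confusion matrices pooled
   across sessions (chance = 25% for four movements).
4. **Velocity decoding** — a per-channel linear encoding model
   *f* = *b*₀ + *b*ₓ*v*ₓ + *b*ᵧ*v*ᵧ + *b*<sub>z</sub>*v*<sub>z</sub> +
   *b*<sub>g</sub>*v*<sub>g</sub> fit by ridge regression and inverted
   (indirect optimal linear estimation) to decode 3-D translation and 1-D
   grasp velocity, evaluated leave-one-trial-out as squared correlation
   (r²) over movement periods, separately for the both-arrays, medial-only
   and lateral-only conditions.  Cursor-task variants decode (X, Y), with
   either abstract (arm-like) or wrist imagery driving the tuning.
5. **Click decoding** — a two-state hidden Markov model on a Fisher
   discriminant projection of the z-rates classifies clicked vs unclicked
   time points, leave-one-epoch-out (chance = 50%).
6. **Group statistics** — array conditions compared across sessions with a
   Friedman test (α = 0.05) and gated post-hoc Wilcoxon signed-rank tests
   (Bonferroni-corrected threshold 0.05/3 ≈ 0.0167).

The classifier, OLE decoder, click HMM and the preprocessing steps are
scikit-learn estimators (`SpikeCountNB`, `IndirectOLEDecoder`,
`ClickHMMClassifier`, `ExponentialSmoother`, `ChannelZScorer`) and compose
with sklearn pipelines; the analysis functions are thin wrappers over them.

## Worked example

```python
import somatodec as sd

cfg = sd.GeneratorConfig(seed=1)          # 96 channels per array, 20 blocks
pop = sd.make_population(cfg)             # ground-truth tuning + coefficients

session = sd.simulate_somatotopy_session(pop, cfg)   # 80 trials, 4 movements
sm = sd.preprocess_session(session.counts)
tuning, windows = sd.map_session(session, sm)
print(sd.proportions_by_array(tuning))

res = sd.classify_session(session, windows, sm.active)
print(res.confusion_frame(), res.accuracy)

reach = sd.simulate_reach_grasp_session(pop, cfg)
smr = sd.preprocess_session(reach.counts)
for cond in ("both", "medial", "lateral"):
    p = sd.loocv_decode(reach, cond, smr, lam=10.0)
    print(cond, round(p.translation_r2, 3), round(p.grasp_r2, 3))
```

At seed 1 this prints tuning proportions that recover the generated
gradient — the lateral array favours distal movements (grasp 1.000,
wrist 0.938 vs elbow 0.688, shoulder 0.708) while the medial array favours
proximal ones (shoulder 0.927, elbow 0.891 vs grasp 0.727, wrist 0.636) —
a diagonal confusion matrix (accuracy 1.000 at the default modulation
depths), and the array-dependent decoding pattern:

```
both     translation r2 = 0.733   grasp r2 = 0.699
medial   translation r2 = 0.692   grasp r2 = 0.389
lateral  translation r2 = 0.387   grasp r2 = 0.680
```

Translation decodes better from the medial (arm-area) array, grasp from the
lateral (hand-area) array, and both arrays together are best — the
qualitative signature of the somatotopic gradient.

The same analyses are exposed on the command line:

```sh
somatodec simulate --task somatotopy --seed 1 --out sess/
somatodec map sess/ --out tuning.csv
somatodec classify sess/
somatodec report --seed 1 --n-sessions 5 --out report/
```

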