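# tempocontext

Analysis pipeline for studying how the temporal context of serially
presented visual stimuli shapes perception at three scales: the
immediately preceding event (**micro** — repeat vs. alternate on a
reference plane), short sequences of the last five events (**meso** —
eight symmetric repeat/alternate sequence classes ranked by expectancy),
and the long-run event statistics of a session (**macro** — expected vs.
unexpected under a biased repeat probability). It is written for
researchers in visual psychophysics and cognitive neuroscience who work
with trial-based behavioral data, pupillometry, and epoched EEG/MEG-like
recordings.

The package covers the full analysis chain:

* **Context labeling** (`tempocontext.context`) — repeat/alternate codes
  on the task-related, task-unrelated, and stimulus-related planes,
  signed Δ location in (−180°, 180°], five-event sequence classes, macro
  expectedness, and sequence-validity masks around block boundaries and
  reproduction trials.
* **Behavior** (`tempocontext.behavior`) — condition summaries (median
  RT after a 2 s cutoff, accuracy), maximum-likelihood fitting of the
  von Mises + uniform mixture of recall errors
  p(e) = (1−g)·f_vM(e; μ, κ) + g/360, Δ-binned serial-dependence curves
  (per-bin bias μ and precision log₁₀κ), and the nonparametric effect
  sizes (matched rank-biserial r, tie-corrected Kendall's W).
* **Pupillometry** (`tempocontext.pupil`) — blink/outlier masking,
  interpolation, zero-phase Butterworth filtering, epoching, baselining,
  downsampling to 125 Hz, and time-resolved condition analyses.
* **Decoding** (`tempocontext.lda`, `tempocontext.iem`) — time-resolved
  diagonal-covariance LDA of stimulus side with shuffle-label baseline
  correction of slow-drift bias, and an inverted encoding model
  (B = WC + E; five rectified-sinusoid channels; Ledoit–Wolf-shrunk noise
  covariance; spatial filters v = Σ̃⁻¹w/(wᵀΣ̃⁻¹w); phasor-sum angle
  decoding with circular accuracy/precision/bias summaries over 12 Δ
  bins).
* **Inference** (`tempocontext.cluster`) — cluster-based permutation
  correction for participant × time curves and participant × time ×
  circular-feature maps (uniform smoothing with wraparound, max-cluster-
  mass null, 95th-percentile threshold).
* **Synthetic data** (`tempocontext.synth`) — a first-class generator
  that emulates the three experimental designs and the EEG-like paradigm
  with planted, recoverable effects (mixture parameters, serial-bias
  amplitude, RT effects, pupil surprise dilation, expectation-dependent
  sensor gain/latency, and the AR(1) across-trial drift that produces the
  repeat-classification confound).

The estimator-shaped pieces (`VonMisesUniformMixture`,
`DiagLinearDiscriminant`, `InvertedEncodingModel`) follow scikit-learn
conventions (`fit`/`predict`, fitted attributes with trailing
underscores) and compose with sklearn model selection.

See `docs/methods.md` for the models, defaults, numerical choices, and
known limitations (including the deterministic aliasing of the printed
five-channel basis and the interpretation of the pupil filter band).

## Worked example

Simulate a biased (75% repeat) session, label it, and run the behavioral
analyses:

```python
import tempocontext as tc
from tempocontext import behavior

sim = tc.simulate_experiment("2", tc.SimConfig(n_blocks=15), seed=7)
trials = sim["trials"]          # labeled trial table (pandas DataFrame)

print(behavior.condition_summary(trials, "macro_task_related"))
err = trials.loc[trials["is_repro"], "repro_error_deg"].dropna()
fit = behavior.fit_mixture(err)
print(f"kappa={fit.kappa:.2f}  g={fit.g:.3f}  mu={fit.mu:.2f} deg  (n={fit.n})")
```

Output:

```
 condition  n_trials  median_rt  accuracy  absent
  expected       984   0.578254  0.970528   False
unexpected       341   0.608688  0.909091   False
kappa=5.76  g=0.093  mu=-2.08 deg  (n=162)
```

Reading the numbers: about 75% of labelable trials are expected (the
session's planted repeat bias), expected trials are answered ~30 ms
faster and more accurately (the planted context effects on the shifted
log-normal RTs and choice accuracy), and the mixture fit on the 162
reproduction trials recovers a concentrated von Mises (κ̂ = 5.8 against a
planted κ = 8 — within sampling error at this n) with a ~9% guess rate
(planted 10%) and near-zero overall bias.

A command-line interface wraps the same stages:

```bash
tempocontext simulate --experiment 2 --seed 7 --out session/
tempocontext lda --epochs session/epochs.h5 --split micro --out lda.csv
tempocontext run --seed 7 --out results/
```

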