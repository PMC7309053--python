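# Methods

## Problem and model

`ecgid` identifies *who* a short single-channel ECG trace belongs to, given a
closed set of enrolled subjects. The premise is biometric: the shape of a
person's P wave, QRS complex and T wave is stable within a recording and
differs between people. The classifier is a stacked recurrent network that
reads the preprocessed signal one sample per time step.

### Recurrent unit

Each unit is a standard LSTM memory cell. With input x_t and previous hidden
state h_{t-1}:

    i_t = σ(U_i x_t + W_i h_{t-1} + b_i)       input gate
    f_t = σ(U_f x_t + W_f h_{t-1} + b_f)       forget gate
    g_t = tanh(U_g x_t + W_g h_{t-1} + b_g)    input modulation
    o_t = σ(U_o x_t + W_o h_{t-1} + b_o)       output gate
    c_t = f_t ⊙ c_{t-1} + g_t ⊙ i_t            internal state
    h_t = tanh(c_t) ⊙ o_t                      hidden state

The modulation nonlinearity is tanh by default; a sigmoid variant is
selectable (`activation_g="sigmoid"`). The hidden state is bounded,
|h_t| ≤ 1, because it is a tanh–sigmoid product; the internal state is not,
which is what lets the cell carry information over long windows when the
forget gate saturates near 1.

### Stack, directionality and fusion

Layers are stacked bottom-up. In a bidirectional layer a forward track reads
the window left-to-right and an independent backward track reads it
right-to-left; the next layer receives the per-step concatenation
[h_t^f ; h_t^b]. A linear projection maps each top-layer step to a vector of
class scores y_t ∈ R^c. The window-level score is either

* **late fusion (sum rule)** — Y = (1/T) Σ_t y_t, used by the bidirectional
  architectures (for a bidirectional top layer, projecting the concatenated
  state is exactly the sum of the forward and backward per-step score
  contributions, up to a shared bias), or
* **last step** — Y = y_T, used by the unidirectional architectures, whose
  final hidden state has seen the entire window.

Probabilities are softmax(Y), computed max-subtracted; prediction is the
argmax with ties broken toward the lowest class index.

The registry exposes six architectures: 1–3 stacked unidirectional layers
with last-step readout (ids 1–3) and 1–3 bidirectional layers with late
fusion (ids 4–6). Id 6 — three bidirectional layers, late fusion, softmax —
is the configuration the package's own benchmark uses.

### Training

Mean cross-entropy between softmax(Y) and the one-hot subject label,
minimized by Adam (lr 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e-8) over seeded,
reshuffled mini-batches. Backpropagation through time is exact (no
truncation) and implemented in NumPy float64; a finite-difference test
checks every parameter group. Gradients are clipped to a global norm of 5 —
without clipping the loss on 500+ step windows occasionally diverges after
reaching small values (observed directly; clipping is the standard remedy).
Weights, including the output head, use uniform fan-based (Glorot-style)
initialization with the forget-gate bias at 1. Head scale matters: in
controlled runs on the benchmark task, a zeroed or 10×-down-scaled head
stalled training (held-out accuracy 0.31–0.65), while the full-scale head
reached 1.0 — the early gradient signal into the recurrent layers passes
through the head, so it must start at unit scale. When the epoch loss
plateaus for 5 epochs the learning rate is halved (floor 1e-4): with a
fixed rate, runs on 500+ step windows intermittently spike (epoch loss
jumping from ~0.5 to >1.3) and can stall; after a decay the descent is
smooth. Training can optionally run in single precision
(``compute_dtype="float32"``, ~1.6× faster, master weights and Adam state
in float64); the default is full double precision. Epochs default to 50
with early stopping
once the epoch loss falls below 5e-3 or fails to improve by 1e-4 for 16
epochs (with 16-window batches the epoch loss is noisy and mid-training
plateaus of ~10 epochs occur before further descent, so a short patience
stops runs prematurely). Dropout is available as a keep-probability knob
and defaults to off.

## Preprocessing

Fixed order: derivative filter → moving-average filter → normalization.

* **Derivative** — first difference y[n] = x[n] − x[n−1] (zero-padded first
  sample), central difference selectable. Removes baseline wander and
  emphasises the QRS upstroke.
* **Moving average** — centered, odd window, shrinking at the edges so
  length is preserved. Default span **0.05 s**. This span is deliberately
  shorter than a QRS complex: with spans much longer than the QRS (e.g.
  0.15 s) the moving average flattens a narrow R deflection more than a
  broad tall T wave, and the peak detector's envelope contrast between QRS
  and T collapses (measured on the synthetic cohort: worst-subject recall
  fell to 0.81 at 10 dB SNR at 0.15 s, versus 1.00 at 0.05 s).
* **Normalization** — y[n] = 2(x[n] − median(x)) / (max(x) − min(x)),
  computed over the whole record *before* segmentation; the output span is
  exactly 2 and the formula is invariant to positive affine transforms of
  the input. A flat record is a degenerate-input error, never a division by
  zero.

## Segmentation

Two modes produce equal-length labelled windows:

* **Fixed window** — consecutive non-overlapping slices of `window_samples`
  (288 samples at 128 Hz = 2.25 s; 444 at 360 Hz = 1.23 s); the trailing
  remainder is dropped rather than padded.
* **R-peak grouped** — each detected beat is trimmed to
  `beat_window_samples` with 1/3 of the window before the R peak (so both
  the P and the T wave fit); runs of `group_n` consecutive beats are
  concatenated into one window. Groups are non-overlapping and temporal;
  beats whose window would run off the record, and leftover beats short of
  a full group, are discarded.

The R-peak detector squares the preprocessed signal, integrates it over a
150 ms moving window, thresholds the envelope adaptively
(max(0.3 × 99th percentile, 1.5 × median)), merges above-threshold regions
closer than the refractory span, and takes each region's energy centroid as
the beat position. The centroid, not the envelope argmax, is used because
the envelope of a differentiated QRS is multi-lobed and its argmax can jump
between lobes; the centroid stays at the QRS energy center. A final greedy
pass enforces the clinical refractory bound — no two peaks closer than
200 ms (300 bpm) — keeping the larger-amplitude peak of any violating pair.
The detector is a means to segmentation, not a contribution; its contract
is recovering ground-truth beat positions of the synthetic generator
(recall and precision ≥ 0.99 within ±50 ms at 10 dB SNR).

## Synthetic data

The generator emulates exactly the features the pipeline depends on:

* per-subject stable morphology: five Gaussian bumps (P, Q, R, S, T) whose
  amplitudes, widths and positions are drawn once per subject from
  documented uniform ranges (R amplitude 0.8–1.6 units dominates all other
  waves; wave order is enforced by disjoint offset ranges);
* R-R variability: Gaussian intervals around 60/HR with the subject's rate
  drawn from 55–85 bpm and s.d. 1–4 bpm, truncated at the 0.2 s clinical
  floor so synthetic data never violates the refractory assumption;
* sinusoidal baseline wander (default 0.1 units at 0.3 Hz, random phase)
  and additive white Gaussian noise.

Everything is deterministic in (seed, subject index), and exact R-peak
positions are returned as ground truth. What the model does *not* emulate:
pathological rhythms, respiratory modulation, electrode-motion artifacts,
multi-lead structure, or any guarantee that two real humans differ as much
as two sampled morphologies. Passing tests therefore demonstrate that the
pipeline is mechanically correct and can exploit subject-stable morphology
under noise — not that it reaches any particular accuracy on real clinical
recordings.

A nearest-centroid check (classify each beat by the closest per-subject
average beat) must separate a noise-free cohort perfectly; it confirms the
data carries identity signal independent of any recurrent model.

## Benchmark problem sizes

The package's end-to-end benchmark (`synthetic_identification_run`, also
exercised by `scripts/acceptance.py`) uses six subjects, 60 s per subject at
360 Hz, noise set for ≈10 dB SNR against the clean signal RMS, R-peak
grouped segmentation with three beats per window and a 180-sample (0.5 s)
beat window, architecture 6 with hidden width 32, batch size 16, an
80-epoch cap with the plateau schedule above, and a stratified 80/20
split. These sizes were chosen as a desk-scale experiment a single CPU
trains in a few minutes; held-out overall accuracy is ≥ 0.95 per seed.
With one minute of ECG per subject the split yields roughly 18 training
and 4–5 test windows per subject, so a single misclassified window moves
overall accuracy by about 4 points — per-seed results below 1.0 are
within that quantization.

## Numerical and design notes

* The forget-gate recurrent term multiplies h_{t-1} (not the previous
  input), and the modulation gate has its own bias b_g — the standard cell;
  a sigmoid modulation activation is available as an option.
* Metrics: per-class precision/recall from one-vs-rest counts; overall
  precision/recall are unweighted (macro) means; overall accuracy is the
  fraction of correct predictions Σ_c tp_c / N; F1 is support-weighted,
  Σ_c 2(n_c/N)·P_c·R_c/(P_c+R_c). A class with zero predicted (or actual)
  positives contributes 0 to the affected metric, with a warning, rather
  than dividing by zero.
* Splits are stratified per class and seeded; the test half always receives
  at least one window per class. A chronological (temporal) split is
  offered because windows cut from one recording are autocorrelated; the
  stratified split is the default.
* Checkpoints (.npz with a JSON descriptor) and HDF5 segment containers
  round-trip bit-exactly; every experiment directory receives a resolved
  config echo sufficient to rerun it.
* WFDB reading covers the 212 and 16 signal formats used by the two MIT-BIH
  databases, converting to physical units at read time; the writer emits
  format 16. Exotic WFDB dialects are out of scope.

## Known limitations

* Scalar input per time step (input_dim 1): multi-lead fusion is not
  supported.
* The detector's adaptive threshold is global per record; it has no
  search-back stage, so very non-stationary amplitude profiles (not
  produced by the generator) could drop beats.
* Training is CPU NumPy; it is exact but not fast. Hundreds of subjects or
  hour-long records would need a GPU framework behind the same interfaces.
* No authentication operating point (EER) analysis; the classifier answers
  "which enrolled subject", not "accept or reject".
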