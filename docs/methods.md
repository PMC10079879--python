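# Methods

This note records the modelling choices behind the package: what is
computed, which decisions were genuinely open, and what the synthetic test
bench does and does not establish.

## Preprocessing and windowing

Each trial is cut left-to-right into non-overlapping windows of
`round(ratio × sr)` samples (`ratio` is the window length as a fraction of
one second); a trailing remainder is dropped, and a trial shorter than one
window contributes nothing (logged). Every window inherits its parent
trial's class label and subject id. Windows are then linearly detrended
and z-scored per channel: "detrend" is the least-squares line (the common
EEG convention for removing slow drift), and a channel with zero residual
variance maps to all zeros rather than NaN. Detrend + z-score is
idempotent, which the suite asserts.

The design-arithmetic helper `expected_sample_count` computes
`N = Σ_pop n_subjects × EPP × TPE × TLPT / ratio`, truncating the grand
total toward zero. Two subtleties are deliberate:

- truncation (not rounding) of fractional totals — required to match the
  published total for the 305 s-trial emotion design (514,687.5 → 514,687);
- the formula charges each trial `TLPT/ratio` windows even when that is
  fractional, so it agrees with physical floor-per-trial windowing only
  when the window divides the trial length exactly. Tests and the
  acceptance script cross-check formula vs. actual windowing only on such
  exact-multiple designs.

For cued SSVEP recordings, `crop_trials` optionally trims a 0.5 s cue and
0.5 s offset before windowing; it is off by default for synthetic data,
whose trials contain stimulation only.

Channel subsets (`occ3`, `occ6`, `occ9`, `cp32`, `all64`) follow the usual
10-20 montage names. The 32-channel posterior+central set is reconstructed
from region membership (occipital + parieto-occipital + parietal +
centro-parietal rows, plus C3/C1/Cz/C2/C4/FCz); the source material names
the regions, not the individual electrodes, so the exact roster is this
package's reading.

## Network

**Front end.** Three depth-wise conv layers, kernel 1×10, valid padding,
stride 1, 120 filters (configurable). Layer 1 shares one filter bank
across EEG channels — features are extracted channel-wise with identical
filters, which makes the front end equivariant to channel permutation (a
tested property). Layers 2–3 preserve the map count (120 → 120); the
stated output shape S×C×Lₑ forces this reading. No activation or
normalization between conv layers is prescribed anywhere, so the default
is GELU after layers 1–2 and none after layer 3, configurable down to
fully linear; biases are off by default because the inputs are z-scored.

**Attention stages.** All three stages share one block design: pre-norm
LayerNorm before the Q/K/V projections (the literal reading of
q = W_Q·LN(z)), softmax(q·k/√D_h) over the content tokens *plus* the
classification token, head concatenation projected by W_O, residual add,
then LN + MLP (affine–GELU–affine, hidden width 4·D) with a second
residual. One learnable classification token per stage is prepended to
every token sequence and dropped from the stage output; it participates
in attention like any token. Latent dim D = 120, A = 8 heads, K = 3 blocks
are defaults exposed in config — D and A are not prescribed by the
architecture's description, K = 3 is.

Axis conventions between stages are normalized to one canonical S×C×D grid
after the regional stage and C×S×D after the synchronous stage; the
temporal stage mean-compresses the D axis into M groups (M = 10 by
default; must divide D), flattens each S×C slab into a length-L1 = S·C
patch, and after its K blocks projects each D-dimensional token back to L1
with a learned map. That final projection is this package's resolution of
a shape inconsistency: per-block token shapes of M×L1 cannot support
residual connections when the embedding is D-dimensional, so tokens stay
D-dimensional inside the blocks and become L1-dimensional once at the end.

**Ablation wiring.** For encoder variants missing a stage: without the
regional stage the Lₑ axis is embedded into D by a learned linear map;
without the synchronous stage the grid is transposed through unchanged;
without the temporal stage the averaging compression + flatten produces
the M×L1 output with no attention. These adapters are inventions — the
ablation grid defines which stages run, not how partial wirings connect —
chosen as the minimal glue that leaves every variant's output shape
identical.

**Decoder.** The three conv collapses (filter axis by w₁ ∈ R^{C×1},
spatial axis by w₂ ∈ R^{S×N} with N = 32, temporal halving) and a softmax
FC layer. The halving layer's printed weight shape is ambiguous; it is
implemented as one (M/2)×M linear map shared across the N decoder filters.
GELU after the three conv layers by default (none is prescribed),
configurable. M must be even.

**Loss.** Mean categorical cross-entropy over the batch plus λ·Σ|w| with
λ = 1e-4 over *all* trainable parameters (the penalty's scope is
unspecified; the widest reading is taken). A true-class probability of
exactly zero is clamped at 1e-12 with a warning. The L1 subgradient at 0
is sign(0) = 0.

## Autodiff and optimization

The network runs on a small reverse-mode engine (`eegformer.autograd`):
float64 throughout, dynamic graphs, iterative topological backward, ~20
primitives including the two convolution forms, softmax, LayerNorm and a
per-row gather for the cross-entropy. Every primitive and a composite
attention-style chain are checked against central finite differences.
Adam uses the standard (0.9, 0.999, 1e-8) moments. Training is minibatch
Adam with batch 64 and lr 0.001 by default; early stopping monitors
validation loss on a held-out 10% of the training split (patience 20,
min-delta 1e-4), restoring the best state. Early stopping on *test* data
is deliberately not implemented. Everything is seeded: weight init by the
model config's `init_seed`, shuffling/validation split by the train
config's `seed`; identical seeds reproduce losses bit-for-bit.

## Metrics and protocols

Sensitivity/specificity follow the binary one-vs-rest formulas
SEN = TP/(TP+FN), SPE = TN/(TN+FP). With two classes the higher label is
the positive class. With more classes, SEN/SPE are macro-averaged
one-vs-rest over the classes present in the truth, and ACC pools the
one-vs-rest confusion counts — note pooled one-vs-rest ACC is not the
plain fraction-correct for >2 classes, so the plain accuracy is reported
alongside in every report. K-fold splits are shuffled and seeded
(scikit-learn); leave-one-subject-out holds out every window of one
subject per fold. Splits are asserted leak-free. The ablation and
segment-length runners reuse identical folds and seeds across
configurations so rows are comparable.

## Synthetic data

The generators exist to make the pipeline testable with known ground
truth, emulating the *structure* of three benchmark families: a 40-class
SSVEP design (64 channels, 250 Hz, stimulus frequencies 8.0–15.8 Hz in
0.2 Hz steps, cohort split between 2 s and 3 s trials), a 3-class
long-trial emotion design (62 channels, 200 Hz), and a binary long-trial
depression design (6 channels, 500 Hz — the 6-channel reading of the
design table is used).

SSVEP trials are harmonic stacks `Σ_h a_h sin(2π h f t + φ_s)` (3
harmonics, amplitudes 1/0.5/0.25, harmonics above Nyquist dropped) scaled
by an occipital-dominant channel topography derived from 10-20 name
prefixes, plus pink noise (spectrally shaped white noise, amplitude
∝ 1/f^α, α = 1) and white noise, both scaled by `noise_sd` (default 0.5).
Per-subject amplitude jitter (SD 0.2) and a per-subject phase are drawn
once per subject, so cross-subject splits are genuinely harder than
pooled splits. Band-power sets are broadband 1/f noise whose amplitude
spectrum inside a band (default 8–13 Hz) is scaled by √factor per class —
a pure power effect with untouched phases. Labels cycle through trials so
designs are balanced.

Generator validity is established by classical oracles, not by the
network: matched-frequency spectral classification (a DTFT projection at
the exact candidate frequencies and harmonics — FFT-bin matching cannot
resolve the 0.2 Hz class spacing of 2 s trials) reaches ≥95% on the
default SSVEP conditions, and a relative-band-power threshold (band/total
power, which cancels subject gain) reaches ≥90% on a 2× alpha-gain
effect. A null effect sits at chance.

What passing tests do **not** show: the generators contain no volume
conduction, no artifacts (blinks, EMG), no non-stationarity, no realistic
inter-channel correlation structure beyond the shared signal, and no
class-overlapping confounds. Results on them bound nothing about
benchmark-scale recordings; the published benchmark accuracies are
explicitly out of scope here and are not acceptance values for this
package.

## Problem sizes

Defaults target desk scale on one CPU core: the shipped examples and the
test suite use 3–9 channels, 30–200-sample windows, 8–16 conv filters,
D = 8–16 and tens-to-hundreds of segments; the learning sanity check (a
D=16/A=4/K=1/M=4 model reaching ≥95% training accuracy on 64 high-SNR
4-class SSVEP trials) converges in ~30 epochs / well under a minute.
Full-size configurations (64 channels, 120 filters, D=120, K=3) construct
and run correctly — the shape law is property-tested across geometries —
but training them at benchmark scale is outside what a pure-NumPy engine
is for.

## Known limitations

- No GPU path and no float32 mode; the engine favours checkability over
  speed.
- No dropout, attention masking, or learned temporal compression
  (averaging only, by design).
- The EDF reader imports `mne` lazily and is untested against real
  recordings in this repository (no binary fixtures are shipped).
- Early-stopping patience/criterion and several architectural details
  (activations between conv/decoder layers, D, A, MLP width, the partial
  ablation wiring) are not prescribed by the architecture's description;
  the defaults here are this package's documented choices, all exposed in
  config.
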