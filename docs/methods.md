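# Methods

## Problem and pipeline

The package detects ictal (seizure) intervals in annotated EEG by
classifying short overlapping fragments. The pipeline is: segmentation →
wavelet scalograms → three unsupervised feature extractors (global PCA,
per-channel stacked denoising autoencoders, CBOW "EEG word" embeddings) →
concatenative fusion → SVM. Everything upstream of the SVM is trained
without labels; only the detector sees them.

## Segmentation and labeling

Windows are 3 s with a 1 s step; window and step lengths convert to sample
counts with `floor`, so a 23.6 s record sampled at 173.61 Hz gives a
520-sample window, a 173-sample step, and exactly 21 fragments
(`floor((n − w)/s) + 1`). A fragment is labeled ictal iff it overlaps a
(merged) seizure interval by strictly more than
`min_overlap_fraction × window` seconds; the default 0 is the
any-positive-overlap rule, the most sensitive convention for a screening
detector. Fragments straddling a seizure boundary are kept, not discarded.
Classes are balanced by seeded down-sampling of the majority class, then
split 4:1 into train/test, stratified per class so both folds stay 1:1
(±1 on odd counts).

## Scalogram representation

The continuous wavelet transform uses the complex Morlet wavelet
Ψ(u) = π^{-1/4} e^{iω₀u} e^{-u²/2} with ω₀ = 6; the small
non-admissibility correction term is below 10⁻⁸ at this ω₀ and is omitted.
Pseudo-frequency maps to scale as f = ω₀/(2πa). Defaults: 32 log-spaced
scales covering 1 Hz to Nyquist. The transform is evaluated as a Riemann
sum on the signal's sample grid via FFT convolution, with the wavelet
truncated at 8 envelope standard deviations (tail < 10⁻¹⁴ of peak) and the
signal implicitly zero-padded; the cone of influence is not masked (a
config option exists for the mother wavelet but masking is out of scope).
Unit tests verify agreement with direct quadrature of the integral to
better than 10⁻⁶ relative error.

Power images are mean-pooled onto a 16×16 grid (256 inputs — chosen to
keep the autoencoder modest), flattened row-major, and min–max normalized
to [0, 1] *per fragment*. The normalization matters: the autoencoders use
sigmoid outputs with cross-entropy loss, which requires inputs
interpretable as probabilities. A constant image maps to the zero vector
(with a warning) rather than dividing by zero.

Only the Morlet mother is implemented; `morse` and `bump` are accepted
configuration values that raise a clear unsupported error.

## Channel-wise SDAEs and the EEG-word dictionary

One 2-layer stack per channel, hidden sizes 80 then 60. Corruption is
masking noise (each input zeroed independently with probability 0.3);
encoder and decoder weights are untied; the optimizer is plain mini-batch
SGD (defaults: 40 epochs, batch 16, learning rate 0.5, L2 penalty 10⁻⁴),
Glorot-uniform initialization, all seeded. Training is greedy and
layer-wise: corruption applies only to the layer currently training, and
the codes fed upward are computed from clean inputs — the common SDAE
convention. Layer freezing is structural (layers train sequentially), and
tests assert bitwise equality of lower layers between shallow and deep
runs.

"Max probability pooling" is read as the argmax over last-layer
activations, ties breaking to the lowest unit index. The dictionary is
per-channel (60 words per channel); word identity across channels is kept
by offsetting ids into a global space (channel c, unit u → c·60 + u).

## EEG embeddings

Sentences are per (record, channel) word sequences; sentence boundaries
are record boundaries. The CBOW objective maximizes the mean log
probability of each interior word given the average of its 2k context
vectors (k = 2). Hierarchical softmax factorizes p(w | ctx) along a
Huffman-tree path of sigmoid decisions, so an update touches only the 2k
context vectors and the O(log |V|) path parameters — asserted bitwise in
tests. Huffman construction breaks ties deterministically by (frequency,
creation order); θ starts at zero (so every initial branch probability is
½ and p(w) = 2^(−code length)), embeddings start uniform in
[−0.5/q, 0.5/q] with q = 20. No subsampling or negative sampling is used.
The gradient step for each branch is lr·(1 − d − f(θᵀctx)); context
vectors receive the accumulated path gradient divided by 2k (the exact
gradient of the averaged context).

A fragment's temporal feature is the embedding of its own word, averaged
over channels for multi-channel data. The embedding matrix spans the full
C×60 dictionary so a word first seen at test time still has a (randomly
initialized) vector; this keeps the lookup total.

## Global PCA

Standard centered PCA over the concatenated all-channel scalogram vectors;
k defaults to 10. k can instead be selected by maximizing the validation
accuracy of a PCA → standardize → linear-SVM probe; the default protocol
is stratified 5-fold (exact leave-one-out is available behind a flag but
is quadratic in cost and selected identically on every synthetic scale we
ran). Ties prefer the smallest k.

## Fusion and detection

Blocks concatenate in fixed order (global, channel-wise, temporal) with
recorded spans; a detector refuses prediction if the span layout differs
from training. Features are z-scored with training-fold statistics, then
classified by an RBF SVM with C and γ chosen by a small grid
(C ∈ {1, 10, 100}, γ ∈ {scale, 10⁻², 10⁻³}) under stratified 3-fold CV
inside the training fold; a linear kernel is a config option. Hard labels
use the default decision boundary; curves use continuous decision scores.
AUCs are trapezoidal; the PR curve is integrated in threshold-traversal
order so duplicate recall values contribute zero width. Zero-denominator
metrics report 0 with a warning.

All extractors fit on the training fold only — the stricter reading of a
hold-out protocol — so deleting the test fold changes no fitted parameter
(asserted in tests). A consequence: embedding sentences are built from the
training-fold fragments of each record in temporal order, not from whole
records. The orchestration order is therefore segment → label →
balance/split → scalograms → fit extractors on train → fuse → detect.
Any subset of the three contexts can be enabled for ablations.

## Synthetic data

Background is pink (1/f-amplitude) noise per channel (RMS 20 µV) plus
white sensor noise (2 µV), matching the EEG spectral slope closely enough
that the wavelet stage is non-trivial. Inside a seizure interval the
background is multiplied by `ictal_gain` (default 3) and a 7 Hz sinusoid
of amplitude gain×background RMS with per-channel random phase is added —
increased amplitude and changed frequency content, the two ictal phenomena
the detector targets. Not modeled: spike-wave morphology, inter-patient
variability, electrode artifacts (EMG, eye blinks), channel correlation
structure. Passing tests therefore demonstrate that the pipeline's stages
are correct and that it detects amplitude/rhythm signatures; they do not
certify clinical performance on real corpora, where ictal patterns are
subtler and artifacts abound.

The default study dataset is ten 30 s 4-channel records, one 8 s seizure
each at a seeded random position: ~100 ictal and ~180 non-ictal fragments,
about 200 after balancing — small enough that the full pipeline runs in
seconds, large enough that every stage (including embedding training on
multi-sentence corpora) is exercised. `ictal_gain → 1` grades difficulty
downward for robustness studies.

## Numerical choices and degenerate inputs

- Sigmoids are computed in the numerically stable two-branch form;
  cross-entropy clamps reconstructions at 10⁻¹².
- Non-finite training loss aborts with diagnostics rather than continuing.
- NaN signal samples are rejected at the CWT boundary.
- Records shorter than one window yield an empty fragment sequence and a
  logged warning, not an exception.
- Overlapping or touching seizure annotations are merged before labeling;
  labeling is invariant to annotation order and to splitting intervals.
- Every stochastic step (corruption, SGD shuffling, embedding init, data
  generation, splitting) derives from explicit integer seeds; identical
  seeds give bitwise-identical models.

## I/O formats

EDF is read through `mne` after a fixed-width header pre-check that
rejects truncated files and mixed per-channel sampling rates; a minimal
EDF writer (16-bit quantization over each channel's physical range) exists
for synthetic export and round-trip testing. Bonn-style records are
one-sample-per-line ASCII. Seizure annotations travel in a sidecar TSV
(`record_id, start_s, end_s`); parsing corpus-specific summary dialects is
out of scope. Fragments and scalogram tensors persist as NPZ; SDAE and PCA
models as NPZ; embeddings as word2vec-style text.

## Known limitations

- The scalogram resolution, scale set, SVM kernel and hyperparameters, and
  PCA k are not dictated by the method itself; the defaults above are
  reasonable choices and are all configurable.
- Per-channel dictionaries (rather than one dictionary over the
  concatenated hidden layer) are one of two defensible readings of the
  design; the global-id offset preserves channel identity either way.
- The detector is offline and fragment-level: no onset localization, no
  streaming, no patient-specific tuning.
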