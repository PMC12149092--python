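# Methods

## Overview

`vgeeg` classifies fixed-length windows of multi-channel EEG by combining
frequency-domain summaries with a topological re-description of the
spectrum.  The processing chain for each recording is:

1. **Referencing.** Subtract a reference from every channel.  The default
   is the common average (the instantaneous cross-channel mean); a named
   single-channel reference is available (`channel:<label>`).  No other
   preprocessing — no filtering, artifact rejection or resampling — is
   applied.
2. **Windowing.** Cut the recording into contiguous, non-overlapping
   windows of fixed length (seconds).  Trailing samples that do not fill a
   whole window are discarded rather than zero-padded, so all windows are
   exactly comparable.
3. **Welch PSD.** Estimate each window's one-sided power spectral density
   per channel by Welch's method: mean-detrended, Hann-tapered segments of
   `2 × sampling_rate` samples with 50% overlap by default, giving 0.5 Hz
   frequency resolution.  Density scaling is used, so the integral of the
   PSD over frequency approximates the signal variance.
4. **Band decomposition.** Slice the spectrum into the five canonical EEG
   bands: delta 0.5–4 Hz, theta 4–8 Hz, alpha 8–12 Hz, beta 12–30 Hz and
   gamma 30–100 Hz.  Band edges are inclusive at both ends (a bin exactly
   on a shared edge belongs to both neighbouring bands) and the upper edge
   is clipped to the Nyquist frequency.  At 0.5 Hz resolution the narrow
   delta band keeps 8 bins — enough for a non-degenerate visibility graph.
5. **Visibility graph.** Treat each band's ordered (frequency, power)
   sequence as a bar chart and connect two points when the straight chord
   between them passes strictly above every intermediate point:
   `y_k < y_j + (y_i − y_j)(s_j − s_k)/(s_j − s_i)` for all `i < k < j`.
   Adjacent points are connected vacuously, so every graph contains the
   path backbone and is connected.
6. **Graph embedding.** Describe each graph by eight scalars: average
   degree `2|E|/n`, maximum degree, density `2|E|/(n(n−1))`, radius,
   diameter, entropy, global efficiency and exact maximum clique size.
7. **Classification.** Feed the per-window feature vector to one of four
   neural architectures (MLP, LSTM, InceptionTime-style CNN, ChronoNet-
   style CNN+GRU) and evaluate with repeated stratified k-fold
   cross-validation.

## Feature modes

* `vg_only` — 8 graph features × channels × bands (e.g. 14 × 5 × 8 = 560).
* `psd_only` — one integrated band power per channel-band (trapezoidal
  integral of the PSD over the band), log(1+x)-transformed because EEG
  band powers are heavy-tailed.  Band power was chosen over raw PSD bins
  as the standard scalar summary of a band; raw sequences remain available
  through the spectral API.
* `combined` — the vg block followed by the psd block (e.g. 630 values).

Standardization (column-wise z-scoring) is always estimated on the
training split of a fold and applied to the held-out split, so no
statistics leak across the cross-validation boundary.  Zero-variance
columns are centered but not scaled.

## Graph feature definitions and choices

Distances are unweighted hop counts (the graphs carry no edge weights).
Radius and diameter are the minimum and maximum vertex eccentricity; for
any connected graph they satisfy `r ≤ D ≤ 2r`, which the test suite
asserts over thousands of generated visibility graphs.  Global efficiency
is the mean of `1/d(u, v)` over ordered pairs, with unreachable pairs
contributing zero; radius/diameter instead raise on a disconnected input
because visibility graphs are connected by construction and a silent
infinity would hide an upstream bug.

The entropy combines two normalized node distributions,
`H = −Σ p_i ln p_i − Σ q_i ln q_i`, with `p` the degree distribution
(`d_i / Σ d_j`) and `q` the normalized local clustering coefficients.
`0 · ln 0` is taken as 0 and a triangle-free graph contributes a zero
q-term.  Degrees and clustering are the two most widely used node-level
summaries and are always well defined; the entropy is reported in nats.

Maximum clique is computed exactly with a Bron–Kerbosch branch-and-bound
search with pivoting over bitset node sets.  Band-level PSD sequences have
at most ~140 points at the default resolution, so exact search costs
microseconds to milliseconds; no heuristic approximation is used.

Visibility is evaluated with the strict inequality as written: a point
lying exactly on the chord blocks visibility.  Ties are measure-zero for
real PSD values but matter for synthetic integer-valued tests.  The
builder runs in O(n²) via a running maximum of slopes per left endpoint,
which is algebraically identical to the chord criterion; the test suite
checks edge-set equality against a literal triple-loop evaluation and
against `networkx.visibility_graph`.

Band slicing operates on the Welch PSD of the broadband signal.  An
alternative path (4th-order zero-phase Butterworth band-pass in the time
domain before Welch) is available via `time_domain_bandpass=True`; for the
features used here the two are equivalent up to filter transition bands,
and slicing avoids filter-design ambiguity.

## Classifier architectures

All four end in a single sigmoid unit trained on binary cross-entropy with
Adam (learning rate 1e-3, batch size 16, 100 epochs by default — modest
settings suited to cohorts of hundreds of windows; no early stopping).
The networks run on a small in-package reverse-mode autodiff core whose
gradients are finite-difference-tested for every architecture.

* **MLP** — six fully connected ReLU layers of 64 units on the flat
  feature vector.
* **LSTM** — layers of 100 and 50 units returning sequences, batch
  normalization after the first, 20% dropout after the second, then a
  25-unit layer returning only its final state.
* **InceptionTime** — three stacked inception modules; each runs
  convolutions with kernel sizes 1, 3 and 5 in parallel plus an
  average-pool → 1×1-convolution branch, concatenated on the channel axis;
  filters per branch grow 16 → 32 → 64; flatten + sigmoid dense.
* **ChronoNet** — two blocks of three parallel convolutions (kernel sizes
  2, 4, 8; stride 1; ReLU) concatenated on the channel axis, followed by
  two stacked GRU layers of 32 units, then the sigmoid dense layer.

Sequence models receive the flat vector reshaped to one step per
(channel, band) pair with that pair's features as per-step channels —
e.g. 70 steps × 9 features for combined mode on 14 channels.  This gives
recurrent/convolutional models a physically meaningful axis (the spatial ×
spectral lattice in a fixed, deterministic order).

Depth, filter counts and training lengths beyond the layer plans above are
this package's own defaults, chosen small enough for CPU training on
desk-scale cohorts; all are exposed through `ModelSpec`/`TrainingParams`
and the run configuration.

## Evaluation protocol

Stratified k-fold cross-validation (default 5 folds) repeated with fresh
shuffles (default 10 repeats); metrics (accuracy, precision, recall, F1 at
the fixed 0.5 threshold) are averaged over all folds of all repeats, with
standard deviations reported alongside.  Zero-division cases (no positive
predictions / labels) report 0 with a logged warning.  The ROC curve is
averaged vertically over a fixed 101-point false-positive-rate grid and
the AUC is the trapezoidal area of each fold's curve, averaged.

Fold grouping is an explicit analysis choice.  `by_window` (the default)
splits at the window level: windows from one subject can land on both
sides of a split, which leaks subject identity and inflates scores on
clinical data — a warning is logged whenever it is used with more than one
subject.  `by_subject` keeps each subject's windows together
(stratified-group folds) and is the defensible choice for diagnosis-style
claims.  Stratification is used in both cases because unbalanced cohorts
with small folds can otherwise lose a class entirely.

## Synthetic cohorts

The generator emulates small resting-state clinical cohorts: each channel
is a sum of one sinusoid per active band — at the band's geometric-mean
frequency, e.g. √(8·12) ≈ 9.8 Hz for alpha, keeping the tone away from
band edges — with class-dependent amplitude and an independent uniform
phase per channel, plus 1/f^β Gaussian background noise (white noise
shaped by f^(−β/2) in the frequency domain, DC zeroed, renormalized to a
target standard deviation; β = 1 by default, matching the broadband
character of resting EEG).  Channels are generated independently; there is
no inter-channel covariance model, because the feature pipeline treats
channels independently.  Generation is bit-deterministic: every
(class, subject) pair draws from its own seed-derived stream.

Two named study conditions are provided:

* `alpha_contrast_spec` — 14 channels at 128 Hz, 120 s per subject,
   20 subjects per class, identical delta/theta/beta amplitudes and a 3:1
  alpha amplitude ratio (9:1 in power) between classes.
* `shape_contrast_spec` — 10 subjects per class, 60 s, classes exchange
  power between theta/beta and alpha so that both individual band powers
  and the overall spectral profile differ.

What passing on these cohorts shows — and what it does not: the synthetic
classes are separated by stationary, phase-random band-power differences,
which is the mechanism the feature set directly measures.  Real clinical
EEG adds artifacts, nonstationarity, volume conduction and inter-subject
variability that the generator deliberately omits, so synthetic accuracy
is an internal-consistency check of the pipeline, not a clinical
performance estimate.

## Problem sizes and numerical notes

The bundled experiments use 5-second windows (960 windows for the
alpha-contrast cohort, 240 for the shape-contrast cohort), 5-fold CV with
3 repeats, and the MLP; these sizes give stable estimates on a single CPU
in minutes and are the sizes `scripts/acceptance.py` reports.

Numerical conventions: visibility uses strict `<` exactly as defined (so
exactly collinear points never connect — synthetic tests must use
binary-exact slopes); Welch segments are mean-detrended to keep DC leakage
out of the delta band; probabilities are clipped by an ε = 1e-7 inside the
cross-entropy; EDF round-trips quantize to 16 bits of the per-channel
physical range.

## Known limitations

* Only binary classification; the output head is a single sigmoid unit.
* The autodiff core is CPU-only and unbatched across folds; LSTM/GRU
  training on long sequences is slow compared to framework backends.
* No artifact simulation or removal, no feature selection, no
  significance testing between architectures.
* `by_window` cross-validation is optimistic on multi-window subjects;
  use `by_subject` for subject-level claims.
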