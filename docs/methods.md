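# Methods

## Problem setting

A steady-state visual evoked potential (SSVEP) speller presents the
user with N_f flickering targets, each at a distinct frequency f_i.
Gazing at a target entrains occipital EEG at f_i and its harmonics.
Decoding a trial means deciding, from a short multichannel epoch
X ∈ R^{N_c × N_t}, which vocabulary frequency the user attended.

## Static core: CCA and FBCCA

For each candidate frequency a harmonic reference matrix

    Y_f = [cos 2πft; sin 2πft; …; cos 2πkft; sin 2πkft],
    t = 1/f_s, …, N_s/f_s

is built (k harmonics; the time axis starts at 1/f_s, not 0, so the
construction is bit-reproducible). The canonical correlation
ρ = max_{w_X,w_Y} corr(w_Xᵀ X, w_Yᵀ Y_f) measures how much of the
epoch lies in the reference subspace. The solver centers both variable
sets, orthonormalizes each by SVD with effective-rank truncation at
1e−10·σ_max (so a flat channel is dropped instead of crashing), and
takes the largest singular value of the cross-product of the bases.
This QR/SVD route is algebraically equal to the generalized-eigenvalue
formulation Σ_xx⁻¹Σ_xy Σ_yy⁻¹Σ_yx but numerically stabler; the test
suite checks the two against each other on random instances to 1e−8.
Centering before CCA follows the definition of correlation; no other
detrending is applied.

FBCCA filters the epoch into D sub-bands, computes ρ_d per band
against Y_f, and scores

    score(f) = Σ_{d=1}^{D} w(d) · ρ_d²,   w(d) = d^(−a) + b,

with a = 1.25, b = 0.25. The decision is argmax over f, lowest index
on ties (ties have measure zero in floats but must be defined).

### Filter bank

Sub-band d passes [8·d, 88] Hz: each successive band removes the
lowest harmonic while keeping the rest, the standard SSVEP bank
design. Filters are Chebyshev type-I band-passes (order 4, 0.5 dB
ripple) run forward-backward with mirrored-edge padding of
3·(order+1) samples. Zero-phase filtering keeps the operation linear
and delay-free — required because the adaptive classifier superimposes
signals, and filtering must commute with superposition (verified to
1e−8). Band edges, family, order and ripple are all open parameters
of `FilterBankSpec`; only D is pinned by the two standard operating
points (D = 5 for the 40-class setting, D = 3 for the 12-class one).

## The adaptive classifier

SSVEP is time- and phase-locked: two epochs of the same target sum
coherently at the stimulus frequency while their background EEG sums
incoherently, so superposition of same-frequency epochs raises
narrowband SNR and superposition of different-frequency epochs lowers
it. The unsupervised adaptive classifier (UAC) exploits this with a
template bank Z ∈ R^{N_f × N_c × N_t}, initialized to zero, built
online from the classifier's own estimated labels. Per trial:

1. p'_i = FBCCA(X, Y_i) — static scores;
2. p_i = FBCCA(X + Z_i, Y_i) — template-augmented scores (for an
   empty template Z_i = 0 this collapses to p'_i);
3. p̃_i = p'_i + w·p_i — integrated scores; decide f_max = argmax p̃;
4. update only the decided slot: Z_{f_max} ← (X + Z_{f_max}) / 2.

Design choices that were genuinely open, and how they were resolved:

- **The halving update, not a running mean.** Z' = (X + Z)/2 is an
  exponentially-weighted average favoring recent trials: after n
  identical epochs the template is X·(1 − 2^(−n)), not X·n/n. This
  recency bias is what lets the bank track slow non-stationarity. A
  count-weighted running mean is available as
  `update_policy="running_mean"` but is not the default and is not
  used in acceptance checks.
- **No confidence gating.** Templates are updated on every decision,
  wrong ones included. Wrong labels corrupt templates and this error
  propagation is the method's known failure mode at low SNR — the gain
  over static FBCCA shrinks toward zero there. Gating would change the
  method.
- **No amplitude normalization** of epoch or template before the sum;
  superposition is a raw elementwise addition.
- **Scoring precedes updating** within a trial (online causal order);
  a batch is processed strictly sequentially.
- **Integration weight** defaults: w = 0.45 for 40-class vocabularies
  and w = 0.65 for 12-class ones. The weight trades off the static
  score (reliable from trial one) against the template score (better
  once templates are filled, but misleading early and after label
  errors). `weight_sweep` reproduces the tuning procedure on any
  cohort and reports the whole accuracy-vs-w curve plus the argmax
  (lowest w on ties) rather than hard-coding a value.
- **w = 0 reduction.** With w = 0 the integrated scores equal the
  static scores bitwise, so the adaptive and static label streams are
  identical — used as an exact invariant in tests.

Implementation note: because zero-phase filtering is linear,
filter(X + Z_i) = filter(X) + filter(Z_i); the classifier caches the
filtered templates per sub-band and invalidates only the one slot each
update touches. This is a pure optimization — results are identical to
refiltering, up to float associativity — and makes the sequential
protocol roughly N_f times cheaper.

## Synthetic data generator

The generator emulates the statistical structure the method relies on,
at controlled operating points:

- per-target response: harmonics h = 1..H at amplitudes
  decay^(h−1) (default H = 3, decay = 0.5), each with the fixed
  per-target phase h·φ_i — phase-locked across trials, so cross-trial
  averaging is coherent (the √n law is verified: averaging 64 epochs
  gains 18 ± 1 dB of narrowband SNR);
- a fixed per-subject channels × harmonics mixing matrix (random
  orthonormal, drawn once from the session seed) standing in for the
  cortical projection to the 8-channel occipital montage;
- additive noise, 1/f-shaped above 1 Hz (or white), independent per
  channel and then mixed by a fixed random orthonormal matrix to
  induce channel correlation;
- SNR defined as total harmonic signal power over noise power in the
  6–90 Hz analysis band, both measured spectrally, with the signal at
  nominal amplitude. The default is −10 dB with 1 s epochs, which
  places static FBCCA accuracy for the 40-class vocabulary near 0.7 —
  a mid-range operating point where adaptation has room to help and
  enough correct labels exist to build useful templates;
- optional per-block amplitude drift (1 + δ)^block modelling slow
  response non-stationarity; since noise is scaled to the nominal
  amplitude, drift changes the effective SNR, which is its purpose.

Every epoch is a pure function of (seed, target, block, trial) through
`numpy` seed sequences, so all experiments are exactly reproducible.

What the generator does *not* emulate: artifact topographies (blinks,
EMG), latency jitter of the visual response, spontaneous alpha rhythms
inside the stimulus band, inter-subject montage variability. Passing
tests therefore demonstrate the decoding mechanics — coherent
superposition, template learning, score integration — under idealized
phase-locking, not performance on recorded EEG. The dataset readers
exist precisely so the identical harness can replay real sessions when
the user supplies the public recordings.

## Evaluation protocol

`run_sequential_protocol` replays a session in recording order from a
fresh zero bank, logging the static and adaptive decision for every
trial (paired by construction). Cohort accuracy averages per-subject
first, then across subjects. The block-accumulation experiment
truncates a session to its first m blocks and reruns from scratch,
showing the gain grow with usage. ITR uses the standard N-choice
formula

    ITR = (60/T)·[log₂N + p·log₂p + (1−p)·log₂((1−p)/(N−1))]

with the p → 0, 1 limits taken continuously; the selection time T is
stimulus duration plus a configurable gaze-shift time (0.5 s default —
the common convention for these paradigms; reported ITRs depend on
this convention, so it is explicit). Paired per-subject accuracy
vectors are exposed for a Wilcoxon signed-rank test via any standard
statistics library; the test itself is not re-implemented.

## Problem sizes and numerical choices

The bundled experiments use 10 simulated subjects × 6 blocks of the
40-class vocabulary (2 400 trials) and the same for the 12-class one
(720 trials); these sizes give stable cohort means while a full run of
suite plus acceptance script stays in the few-minute range on one
core. Tolerances: CCA vs oracle 1e−8; filtering linearity 1e−8;
exact-arithmetic checks (w = 0 reduction, halving recursion on
dyadic-valued epochs) are bitwise. Rank truncation at 1e−10·σ_max;
canonical correlations are clipped to [0, 1] against floating-point
overshoot.

## Dataset readers

Readers for the two public layouts (40-target benchmark: 64 × N_t ×
40 × 6 per-subject arrays at 250 Hz; 12-target: 12 × 8 × N_t × 15 at
256 Hz) accept both MATLAB dialects (v5 and v7.3/HDF5). Epochs are cut
from flicker onset plus a 0.14 s visual-latency offset — the typical
visual-pathway delay; the choice moves accuracy and is therefore an
explicit manifest field, as are the analysis window and channel
subset (default: the eight occipital/parieto-occipital electrodes).
Nothing is downloaded; paths are supplied by the user, and no test
depends on external data.

## Known limitations

- Error propagation: below roughly −14 dB (40-class, 1 s) most labels
  are wrong, templates are built from mislabeled epochs, and the
  adaptive gain vanishes or goes negative. This is inherent to
  ungated unsupervised adaptation.
- Templates are amplitude-sensitive: a gross amplitude artifact
  absorbed into a template pollutes that frequency until enough clean
  trials halve it away.
- The template bank assumes fixed epoch geometry (channels, samples);
  changing the analysis window invalidates a saved bank.
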