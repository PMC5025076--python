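# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `icabci`. It is written for users who want to know *why* the
toolkit behaves the way it does, not just what its functions return.

## Problem setting

Three-class motor-imagery BCIs classify single EEG trials (left hand, right
hand, foot) from the event-related desynchronization (ERD) of the mu rhythm:
imagery depresses 8–14 Hz band power over the contralateral primary motor
cortex (under electrode C4 for left hand, C3 for right hand, and near Cz for
foot). ICA can extract the three motor-related components (MRICs) whose
scalp projections peak at C3, Cz and C4, but single-trial ICA models are
easily destroyed by high-amplitude broadband bursts (body movement, cable or
electrode artifacts). The toolkit automates (a) detecting the MRICs from the
mixing-matrix topographies, (b) rejecting corrupted trials in two rounds,
(c) building optimized detection filters from the surviving best trials, and
(d) localizing artifact segments with an accuracy matrix.

## Preprocessing

All temporal filters are Hamming windowed-sinc FIR designs applied
forward–backward (`scipy.signal.filtfilt`), so outputs are exactly
zero-phase and the effective magnitude response is the squared single-pass
design. Design choices, none of which are sharp:

* Band-pass: transition width 2 Hz; the −6 dB cutoffs sit half a transition
  band *outside* the requested band so the band edges themselves stay near
  unity gain. For 8–30 Hz at 250 Hz this is a 413-tap filter with ≥ 60 dB
  single-pass attenuation at 4 Hz and 41 Hz.
* Notch: band-stop at ±1 Hz around the line frequency with a 0.5 Hz
  transition (1651 taps at 250 Hz); ≥ 60 dB single-pass at 50 Hz, < 0.1 dB
  at 45/55 Hz.
* Edge handling: odd-reflect padding of one filter length (clipped to the
  signal length for short trials).
* Epochs are half-open `[start, end)` in samples; sample indices are
  0-based internally while trial indices are 1-based in every report and
  export, matching the "43rd trial" convention of BCI practice.
* The subject-specific classification band (typically 10–14 or 12–16 Hz) is
  a configuration parameter. Automatic reactive-band discovery from
  time-frequency maps is out of scope.

## Infomax ICA

The separating matrix W is learned by stochastic natural-gradient ascent,

    dW ∝ [ I − E( K tanh(u) uᵀ + u uᵀ ) ] W,   u = W x,

with the diagonal switch matrix K set each iteration from the sign of the
excess kurtosis of each current source (+1 super-Gaussian, −1 sub-Gaussian).
Channels are centered but *not* pre-whitened — the natural gradient makes
the update equivariant, so whitening is unnecessary and the implementation
stays closest to the update rule as written. W is initialized to 0.1·I.

Optimizer constants (none of which have canonical values):

* `learning_rate` — default 0.05/ln(N). We benchmarked 0.01/ln(N) first: on
  ~10% of random well-conditioned Laplacian mixtures it left the iteration
  short of the separation basin at 512 passes (Amari index ≈ 0.2 where twice
  the iterations reach ≈ 0.02). 0.05/ln(N) converges on all benchmark seeds;
  a divergence guard restarts with a halved rate (at most 3 restarts).
* Annealing ×0.9 whenever the angle between successive epoch updates
  exceeds 60°.
* `block_size` 256 samples; one iteration is a full pass over the data in
  seed-shuffled blocks; the kurtosis switch is re-estimated once per pass on
  the full current sources.
* `max_iter` 512, `tol` 1e-7 on the largest absolute element of the
  per-pass change of W. Pipeline-scale runs (75 single-trial fits per run,
  975 segment fits per accuracy matrix) use reduced operating points —
  max_iter 128 for trial-length fits and 48–64 for 5 s segments — chosen
  because separation quality and MRIC matching on the simulator are
  indistinguishable from the full-budget fits at a fraction of the cost.

After fitting, sources are rescaled to unit standard deviation, the scale is
absorbed into the mixing matrix A = W⁻¹ (removing ICA's amplitude
indeterminacy), and each pattern/filter pair is flipped so the pattern's
dominant electrode weight is positive (removing the sign indeterminacy
before topography matching). Permutation indeterminacy is what the MRIC
matching step resolves.

## MRIC detection and the zero-training classifier

A column of A is an MRIC pattern if its largest-magnitude entry lies at C3,
Cz or C4; when several columns peak at the same electrode the largest
magnitude wins. A trial is a round-one "good trial" only if all three motor
electrodes receive (necessarily distinct) columns. Matching uses magnitudes
because sign has already been canonicalized away.

Subscripts are hemisphere-based: w_l is the W-row of the C3-dominant
(left-hemisphere) component, w_r of the C4-dominant, w_f of the Cz-dominant.
The classifier computes the three source variances on the subject band over
the 0.5–5 s analysis window and assigns the class whose *contralateral*
source is quietest:

    V = min(var(u_l), var(u_r), var(u_f))
    class 1 (left hand)  if V = var(u_r)
    class 2 (right hand) if V = var(u_l)
    class 3 (foot)       if V = var(u_f)

Exact ties resolve in the order (u_r, u_l, u_f), i.e. class 1 first. The
rule has no trainable parameters, is deterministic, and is invariant under
common positive scaling of the trial.

Implementation note: since var(w x) = w C wᵀ for the channel covariance C of
the band-filtered, windowed trial, the evaluator precomputes one covariance
per trial and scores any number of filter sets with 3×3 quadratic forms.
This is an exact algebraic identity, not an approximation.

ICA itself is fitted on the 8–30 Hz data; classification variances are taken
on the subject band. The broad band gives ICA the full mu/beta structure to
separate, while the narrow band concentrates the ERD contrast.

## Two-round trial selection, ICA-T and ICA-S

Round one labels each trial good/bad by single-trial ICA + topography
matching (ICA failures label the trial bad rather than aborting). Each good
trial's filters form a single-trial BCI (st-BCI) whose training-set accuracy
R_j is that trial's quality score; round-one bad trials are recorded with
R_j = 0 but excluded from all statistics. Round two keeps good trials with
R_j at or above a threshold — by default the mean of the nonzero
accuracies; absolute and quantile rules are available.

ICA-T concatenates the kept trials with the m = 10 highest accuracies (ties
broken by ascending trial index, for reproducibility) and refits ICA once on
the concatenation; the matched MRIC rows are the final optimized filters. If
fewer than m trials survive, all kept trials are used with a warning. ICA-S,
the unoptimized baseline, fits ICA on a sliding window of 10 trials at step
1. For 75 trials this yields 66 windows (the count formula
L − win + 1); windows whose matching fails contribute null entries.

`affected_windows` returns every 1-based window index whose trial range
intersects a given artifact-trial set; with 75 trials, window 10, step 1,
artifact trials {43, 46} flag windows 34–46.

## CSP baseline

For trial-averaged, per-trial trace-normalized class covariances S⁺ and S⁻
("centered and scaled" is read as trace normalization, standard CSP
practice), the generalized eigenproblem S⁺v = λ(S⁺+S⁻)v yields W with
Wᵀ(S⁺+S⁻)W = I and WᵀS⁺W = diag(λ). The eigenvectors of the largest and
smallest λ form one filter pair per binary problem. The three-class problem
is decomposed one-versus-rest: 3 splits × 2 filters = 6 retained spatial
filters, each split carrying a linear discriminant (scikit-learn LDA) on
log-variance features. Voting assigns the class of the unique positive
split; zero or multiple positive votes fall back to the largest
discriminant score. The self-testing protocol trains on a random stratified
80% of trials and scores *all* trials, repeated 30 times.

## Accuracy matrix

A trial of length T_t is cut into M = round((T_t − T_o)/(T_s − T_o))
consecutively overlapping segments (rounding half away from zero — the
convention is documented and tested because the worked value (11, 5, 4.5) →
13 does not exercise it). Segment i starts at (i−1)(T_s − T_o) s; a final
segment running past the trial end is truncated and zero-padded (logged).
Each (segment, trial) cell gets its own ICA fit and MRIC matching; matched
cells store the filter set's accuracy over the test set, failed cells store
the sentinel −1 ("no BCI", deliberately distinct from an accuracy of 0,
which is a working BCI that always errs). Row summaries are five-number
statistics with sentinels excluded; all-sentinel rows are omitted with a
warning. Low columns localize artifact trials, low cells localize artifact
segments within a trial.

## Synthetic data generator

The simulator emulates the acquisition protocol the pipeline targets: 8- or
9-channel 10–20 montages, 250 Hz, 10 s (or 11 s) trials, 25 trials per class
in randomized order, with ground-truth mixing available for every dataset.

* **Mixing matrix.** MRIC topographies are unimodal Gaussian profiles over a
  2-D montage layout centered at C3/Cz/C4, with FWHM of one inter-electrode
  spacing. Background sources get jittered Gaussian patches under *distinct
  non-motor* electrodes. Diverse patch centers keep cond(A_true) ≈ 2–3;
  with fully random smooth topographies the mixing matrix was nearly
  collinear (condition number ~85) and inverse filters amplified sensor
  noise enough to destroy every downstream contract.
* **MRIC sources.** Band-limited noise in the subject band,
  amplitude-stabilized by its smoothed Hilbert envelope and re-modulated by
  a slow positive envelope (depth 0.4, < 5 Hz). The stabilization is
  deliberate: raw band-limited Gaussian noise at 4 Hz bandwidth has
  ~1/√(BT) ≈ 24% power fluctuation across a 4.5 s window, which rivals a 2×
  ERD contrast — no classifier could reach the intended accuracy on such a
  substrate, and real ongoing mu is far steadier (and mildly sub-Gaussian,
  as these carriers are). The kurtosis stays bounded away from zero so the
  Infomax switch matrix has a stable sign.
* **ERD.** During each trial's imagery window (default 0.5–5 s) exactly one
  MRIC's amplitude is multiplied by √erd_depth (power ratio = erd_depth,
  default 0.5) with 0.2 s raised-cosine ramps: class 1 attenuates the C4
  source, class 2 the C3 source, class 3 the Cz source — the unique mapping
  consistent with contralateral ERD and the classification rule.
* **Noise and artifacts.** White sensor noise at snr_db (default 10 dB
  relative to mean mixed-signal power). Eye blinks are biphasic ~0.4 s
  pulses on the frontal-most row; alpha bursts are 10 Hz Hanning-windowed
  oscillations on the posterior-most row; both are *physiological* and not
  flagged as artifact trials. Bursts are Tukey-tapered white noise with RMS
  equal to `amplitude` channel standard deviations (peaks ≈ 3× that),
  0.5–1 s long, on a random strict subset (roughly half to two-thirds) of
  the montage with independent waveforms per channel. The subset matters:
  a burst confined to one channel is a rank-one addition that ICA isolates
  harmlessly, while independent transients on 5–7 of 9 channels cannot be
  absorbed by any single component and usually corrupt the fit — which is
  the phenomenon the two-round selection exists to catch. The default burst
  amplitude is 15× (the "seriously contaminated" regime; note the 8–30 Hz
  filter passes only ~42% of a white transient's amplitude). Calibration on
  independent draws measured per-trial corruption of the single-trial fit
  at ~85% for 10× bursts and ~96% at 15×: Infomax is genuinely somewhat
  robust to isolated transients (tanh bounds their influence, and weak
  background components are sacrificed to model them), so a small tail of
  short, late, many-channel bursts always survives with clean filters.
  Rejection of *both* of two contaminated trials in a run is therefore a
  ~0.9-probability event per run, not a certainty — the corresponding
  end-to-end test measures 17/20 seeded runs, while the practical
  consequences (contaminated trials never enter the top-10 concatenation;
  ICA-T beats the mean single-trial accuracy held-out) hold in 20/20.
* **Determinism.** All randomness flows from one `numpy` Generator seeded
  by `SimConfig.seed`; identical seeds give bit-identical datasets.

What the simulator does **not** model: volume-conduction head geometry
(topographies are parametric, not BEM/FEM), inter-session nonstationarity,
ECG, electrode drift, or 50 Hz line interference. Passing tests on this
substrate show the pipeline's selection logic and filter algebra behave as
designed under controlled ERD and artifact conditions; they do not certify
accuracy levels on human EEG.

## Chance-control protocol

Label permutation leaves ICA fits untouched (they are unsupervised), so the
control evaluates trained models against *independently shuffled* labels of
a held-out run: both ICA-T and CSP must score 1/3 within noise. CSP
self-testing on shuffled labels is deliberately not used as the control —
training and scoring on the same 75 trials overfits shuffled labels to
well above chance (≈ 0.58 observed), which is a property of any flexible
supervised pipeline, not a defect of CSP.

## Degenerate inputs and error policy

* ICA: non-finite input and T < 20 N raise immediately; numerical blow-up
  restarts with a halved learning rate, erroring after 3 restarts;
  zero-variance sources are reported by index.
* Pipeline: a failed single-trial fit labels that trial bad (logged), a
  failed accuracy-matrix cell stores the sentinel (logged); neither aborts
  a run. A failed match on the ICA-T concatenation *is* an error (the
  caller should change m or the seed).
* Selection with P = 0 good trials raises rather than returning an empty
  report.
* CSP: empty classes, rank-deficient composite covariances (named
  channels), and missing classes raise; constant channels warn.

## Known limitations

* The Infomax stopping tolerance (1e-7 on max |ΔW|) is rarely reached
  before max_iter on real-scale data; `converged=False` with a good model
  is therefore common and not an error signal.
* MRIC matching assumes the montage contains C3, Cz and C4 and that exactly
  one component projects dominantly to each; montages without the motor row
  are rejected.
* The EDF reader (optional, via `mne`) maps annotations to classes through
  a user-supplied table and has no writer counterpart, so round-trip tests
  use the native run format.
* `build_accuracy_matrix` is embarrassingly parallel across cells but runs
  serially; a 13 × 75 self-test at segment-level operating points takes
  on the order of a minute.
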