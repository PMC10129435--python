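# Methods

## The model

Surface EMG recorded from five lower-limb muscles during walking —
gastrocnemius medialis (GA), tibialis anterior (TA), vastus lateralis
(VL), gluteus maximus (GM), biceps femoris (BF) — is summarized per
subject as a nonnegative matrix `M` (101 cycle points × 5 muscles) of
linear-envelope amplitudes, each muscle expressed as a fraction of its
own per-cycle maximum. The muscle-synergy hypothesis models `M` as a low-
rank nonnegative product

    M ≈ H W,     H ≥ 0 (101 × k),  W ≥ 0 (k × 5),

where each of the `k` synergies couples one time-varying activation
coefficient (a column of `H`) to a fixed vector of relative muscle
weights (a row of `W`). The factors are estimated by minimizing the
Frobenius reconstruction error with Lee–Seung multiplicative updates;
goodness of fit is measured by the uncentered variance accounted for,
per muscle `m`:

    VAF_m = 1 − Σ_t (rec_tm − exp_tm)² / Σ_t exp_tm² .

The number of synergies is the smallest `k` for which every muscle's
VAF exceeds 0.9. Note some reports print the VAF formula without the
squares; that linear form is sign-sensitive and can exceed 1, so the
squared form is the default here and the linear form is available as
`form="linear"` for comparison only.

## Preprocessing chain

Raw EMG (1000 Hz) → Butterworth band-pass 10–500 Hz → full-wave
rectification → Butterworth low-pass 6 Hz → per-cycle segmentation at
provided gait events → per-cycle submaximal normalization (each channel
divided by its in-cycle maximum) → natural-cubic-spline resampling to
101 points spanning 0–100 % of the cycle inclusive → element-wise
average over cycles, with a final per-column rescale so the averaged
matrix again satisfies max = 1 per muscle.

Choices worth noting:

- **Filter family/order.** Butterworth order 4, applied zero-phase
  (forward–backward, `sosfiltfilt`). Zero-phase filtering matters
  because burst *timing* on the cycle axis is an analysis output; a
  causal filter would shift every peak by its group delay.
- **Nyquist-degenerate band.** A 10–500 Hz band at 1000 Hz sampling has
  its upper edge at Nyquist; the edge is clipped to 0.99 × Nyquist with
  a warning rather than failing.
- **Averaging then renormalizing.** Per-cycle-normalized envelopes peak
  at slightly different cycle points, so their average has column maxima
  below 1; the final rescale restores the documented [0, 1] contract and
  is recorded in the matrix provenance.
- **Gait events are inputs.** Event detection is out of scope; the
  synthetic generator emits exact cycle boundaries, and real data must
  provide an events CSV.

## Factorization and selection

- **Updates.** Lee–Seung multiplicative rules for the Frobenius
  objective with `1e-12` added to denominators. Loss is checked every 10
  iterations; iteration stops when the decrease falls below
  `tol × ‖M‖_F` (default `1e-6`) or at `max_iter = 2000`.
- **Initialization and restarts.** Entries uniform in (0, 1], `H` scaled
  to the data magnitude; 20 restarts by default, seeded via
  `SeedSequence(seed, k)` so results are bit-reproducible; the lowest-
  loss restart wins, ties to the earliest candidate.
- **Canonical scale.** NMF factors are scale-ambiguous per component, so
  each `W` row is scaled to maximum 1 (its entries are then "relative
  muscle weights") with the inverse scale absorbed into the `H` column.
  A side effect: the dominant muscle of each synergy has weight exactly
  1 in every subject, so that cell carries no between-subject variance
  and is excluded ("missing") from group tests.
- **Warm start across k.** When scanning k = 1, 2, …, the best
  k-solution padded with a tiny random extra component (relative scale
  1e-3, contributing O(1e-6) to the reconstruction) is added to the
  restart pool at k+1, and a zero-padded copy of the previous solution
  is kept as a floor. This makes the best loss non-increasing and the
  global-VAF-vs-k curve monotone, which the stopping rule implicitly
  assumes; with independent restarts alone the curve can dip.
- **Selection.** Stop at the first k with min-per-muscle VAF > 0.9
  (strict). If no k ≤ k_max (default: the muscle count) qualifies, the
  curve is returned flagged with a warning rather than raising.

## Group comparison

Analysis is per subject; group structure is built afterwards:

1. Synergies of the first group-A subject are put in canonical order by
   the cycle position of each activation peak (ties: larger energy
   first); every other subject in both groups is aligned to that
   reference by the permutation maximizing the summed Pearson
   correlation of activation coefficients (exhaustive over k! for
   k ≤ 8, which is exact at this scale).
2. Aligned `H` and `W` are averaged per group (mean and SD).
3. The k × k Pearson matrix between the groups' mean activation
   coefficients is classified by |r| into similarity bands
   [0, 0.3) small, [0.3, 0.7) moderate, [0.7, 1] high. The printed
   band edges (0.29/0.3, 0.69/0.7) leave gaps; left-closed intervals
   close them. Moderate values below 0.35 carry a
   `BorderlineSimilarityWarning`, because published readings of that
   zone are inconsistent (the same bands that make 0.30–0.33 "moderate"
   coexist with prose calling such values "weak"); the report surfaces
   the ambiguity instead of resolving it silently.
4. Each (synergy, muscle) relative weight and each per-subject global
   VAF (for every k up to the common k) is compared between groups with
   an independent-samples t-test at α = 0.05, Shapiro–Wilk p attached.
   No multiple-testing correction is applied by default (matching common
   practice in this literature); a NaN-aware Holm step-down and a
   Mann–Whitney option are available behind flags. Cells with zero
   variance in both groups are reported as missing.
5. The common k for comparison is the modal selected k pooled over all
   subjects; subjects whose own selection differs are refitted at that
   k and flagged.

## Synthetic data generator

The generator runs the model forward so that every downstream stage is
testable by parameter recovery:

- **Activation coefficients.** One unit-peak Gaussian burst per synergy
  on a circular 0–100 % cycle axis (bursts near the cycle boundary
  wrap). Defaults place the four bursts at 10, 35, 62 and 92 % with SD
  9, 9, 9 and 8 % — weight acceptance, push-off, early swing, late
  swing.
- **Weights.** The default `W_true` is near-diagonal: each synergy has
  one dominant muscle (GM, GA, TA, BF respectively) with small
  (0.05–0.30) cross-weights, and VL is deliberately bimodal — 0.30 in
  the first synergy and 0.90 (its column maximum) in the fourth. Two
  reasons: (a) strongly cross-correlated muscle columns make the
  envelope matrix effectively compressible below its nominal rank, and
  a k=3 fit can then already clear the 0.9 VAF rule, so a k_true=4
  condition is only realized when each burst has a muscle that needs
  it; (b) per-cycle max normalization divides each muscle by its
  envelope peak, which cancels any weight perturbation applied to the
  synergy that *produces* that peak — placing VL's maximum in synergy 4
  keeps the default ×1.5 perturbation of VL-in-synergy-1 observable.
- **Raw EMG.** Band-limited (20–450 Hz) Gaussian carrier noise, unit
  RMS, amplitude-modulated by the target envelope rendered at 1000 Hz —
  the standard interference-pattern surrogate. Stride durations are
  drawn per cycle from N(1.1 s, 0.05 s); a 2 % tonic floor keeps every
  channel nonzero in every cycle. Exact cycle boundaries are emitted as
  the event annotations.
- **Noise and variability.** Envelope noise is element-wise log-normal
  with mean 1 and scale `noise_sigma` (default 0.1, "moderate"):
  amplitude-proportional, as EMG envelope noise is. Between-subject
  variability is i.i.d. relative Gaussian jitter on the weights
  (SD 0.10, truncated at 0). Between-group effects are multiplicative
  factors on named (group, muscle, synergy) entries.
- **Two paths.** `generate_cohort` produces raw recordings and exercises
  the full filtering chain; `generate_envelope_cohort` emits the
  normalized 101-point matrices directly and exists for Monte-Carlo
  experiments (hundreds of cohorts) where the filter chain is not under
  test.

**What the generator does not emulate** — electrode placement and
cross-talk, motion artifact, within-subject cycle-shape changes,
non-Gaussian burst shapes, heteroscedastic carrier spectra, event-
detection error. Passing recovery tests therefore show the pipeline is
correct and well-calibrated *under the stated generative assumptions*,
not that real cohorts of this size will show any particular effect.

## Problem sizes and numerical choices

The standard cohort used in the test suite and reproduction script is 10
subjects per group, 3 cycles each, noise 0.1, full extraction defaults
(20 restarts, 2000 iterations, tol 1e-6, threshold 0.9, k_max 5).
Monte-Carlo calibration uses 32 null cohorts (512 testable cells) and
100 perturbed cohorts at the envelope level with 4 restarts and 400
iterations at the known k=4 — enough for stable rejection-rate
estimates while keeping the suite quick. Degenerate inputs are errors,
not silent fixes: all-zero channels (normalization and VAF undefined),
events out of bounds, cycles shorter than 4 samples, negative input to
the factorization.

## Known limitations

- The selection rule inherits the threshold's arbitrariness; 0.9 is the
  conventional value and the only one tested.
- Canonical max-1 scaling pins one cell per synergy (see above); a
  unit-norm convention would spread variance differently and is not
  implemented.
- Exhaustive permutation matching is exact but factorial; k > 8 raises
  rather than silently degrading.
- The linear VAF form is exposed but untested beyond arithmetic, since
  it is not a sound model-selection quantity.
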