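# Methods

## Data model and conventions

A trial is a pair of synchronized 2-D tracks (leader, follower) sampled at a
fixed frame rate, coordinates in mm after applying the pixel scale. Frames
must be dense: gaps are a structural error, never interpolated, because
interpolation would inject spurious autocorrelation into exactly the
quantities this package estimates. Recordings are clipped to a common
duration (default 15 min; 26 973 frames at 29.97 Hz) before analysis.

Temporal subsampling keeps every *n*-th frame with
n = round(period × frame_rate), i.e. frames n, 2n, …, giving
floor(N/n) samples. Sample counts quoted against a *printed* (rounded)
period use floor(duration / period) instead (`expected_sample_count`);
integer decimation can differ from that formula by one sample (e.g. 5394 vs
5395 at a printed 0.1668 s), which is why both conventions are exposed.

Coordinates default to a y-up axis; for image coordinates (y down) the
`y_axis_down` flag flips the turn-direction sign convention globally.
Direction labels swap; every transfer-entropy value is invariant.

## Symbolic encoding

Three alphabets per runner:

- **pausing** (`M`/`P`): a step is a pause when the distance between
  consecutive sampled positions falls at or below the q-th percentile
  (default q = 10) of step sizes pooled over *all* runners of the species at
  that sampling period. Leaders and followers are pooled jointly when
  fitting the threshold (a config flag separates them). Percentiles use
  linear interpolation between order statistics; ties at the threshold are
  pauses, so the pause fraction equals q/100 up to tie mass. One symbol per
  step: length P−1 for P positions.
- **rotation** (`CW`/`CCW`): the sign of the 2-D cross product of
  consecutive displacement vectors. Exactly-zero (collinear) cross products
  copy the previous symbol; a leading collinear run takes the first signed
  symbol retroactively, and an entirely collinear track is an error. Length
  P−2.
- **compound** (`P`/`CW`/`CCW`): pauses and rotations are mutually
  exclusive, so the pause symbol overrides the turn symbol wherever the
  pausing encoder fires; elsewhere the rotation symbol is used. Length P−2.

Whenever series of different lengths must be aligned (compound internally,
or leader/follower jointly), leading entries are dropped: the prediction
direction runs forward in time, so the latest entries are the ones that
matter.

## Information dynamics

All quantities are plug-in estimates in bits (log base 2) from empirical
block frequencies. Blocks never span trial boundaries; the headline
estimates pool counts over all trials of a species ("behavior is a property
of the species, not the pair"), while per-trial mode fits each trial alone
and feeds the paired tests. Counting is sparse — block tuples are packed
into integers and tallied with `np.unique` — so memory scales with observed
blocks (≤ series length), never with alphabet^k; the sweep conditions on
histories up to k = 20 where a dense table would be impossible for the
ternary alphabet.

The source enters through its present symbol only (source history length 1);
the destination's own history length k is the swept parameter. Local
transfer entropy is the per-transition log-ratio under the pooled
probabilities; its mean equals the pooled estimate identically, which the
tests assert to 1e-12 alongside equality with an independent brute-force
enumeration oracle and the identity T = H(X'|X^k) − H(X'|X^k, S).
Conditioning contexts with zero counts simply contribute nothing (only
observed blocks are enumerated).

Normalized transfer entropy divides by the destination's conditional
entropy, clamped to [0, 1]; the correction argument (default 0, i.e. raw)
optionally discounts the surrogate mean first, since published summaries are
ambiguous about which numerator they normalize.

## Surrogate null and statistics

A surrogate dataset re-pairs each leader with a follower from a *different*
trial — a uniform random derangement, drawn by rejection sampling — leaving
every series' marginal dynamics intact while destroying within-pair
coupling. Fifty replicates estimate the null mean (subtracted from the raw
estimate as a finite-sample bias correction) and its spread.

Two spreads must not be confused. The standard error of the ensemble mean
(std/√50) quantifies how well the correction factor is known. The null band
for the *corrected* estimate itself is the ensemble **standard deviation**:
the raw value is a single pairing draw, so its null deviation from the
ensemble mean is on the order of one std (√50 standard errors). All
null-coverage checks in this package therefore use 2× the ensemble std.
Note also that the ensemble conditions on the observed series — it captures
pairing (mixing) variability but not series-level sampling variability — so
the band is mildly anti-conservative: per-pattern coverage measures ~95% at
the study scale, and the joint two-pattern per-seed criterion ~85–95%
depending on seed.

Hypothesis tests mirror the published conventions exactly (verified against
their attainable extremes): the one-sided two-sample Wilcoxon rank-sum test
with continuity correction reports the Mann–Whitney U of the first sample
(maximum n₁n₂ = 400 at 20 vs 20), and the one-sided paired signed-rank test
reports V = the positive-rank sum (maximum n(n+1)/2 = 210 at n = 20). The
rank-sum comparison pits n per-trial experimental values against the n
per-trial values of a single surrogate replicate — the only pairing of
sample sizes consistent with the published W ranges — and is calibrated:
on 200 null simulations it rejects at 5.0 ± binomial noise.

## Parameter landscape

Net TE is computed for every cell of k ∈ {1..20} × 45 periods (multiples of
1/29.97 s up to 1.5015 s; 900 configurations), with the pause threshold
refit at each period for pause-bearing patterns. The sweep reports raw
pooled net TE — surrogate-correcting 900 cells × 50 replicates would buy
nothing for selection — and correction is applied at the selected cell only.
Selection maximizes |net TE| (the follower-led ant pausing flow makes signed
maximization ambiguous), breaking ties toward smaller k then shorter period;
cells where any trial is shorter than k+1 symbols are excluded, not
zero-filled. Every cell is a pure function of (k, period): recomputing one
in isolation reproduces the sweep value exactly.

The threshold-perturbation analysis recomputes net TE for q ∈ {5, …, 15} at
a fixed (k, period) and flags whether the flow direction (the sign) is
constant — the primary observable must not hinge on the 10% convention.

## Distance-resolved profiles

Inter-centroid distance (strictly positive by construction — centroids of
two bodies never coincide) is expressed in species mean body lengths
(*T. rugatulus* 2.34 mm, *C. formosanus* 8.89 mm, *R. speratus* 5.5 mm).
Local TE and speed are averaged within 0.1-body-length bins and smoothed
with LOESS (span 0.3, via statsmodels lowess). The bin width only shapes
intermediate reporting: the count-weighted mean over bins equals the
unconditioned mean to 1e-9, which the tests assert. Speed profiles split
steps by the sign of the distance change; zero-change steps inherit the
previous step's class (mirroring the collinear rule).

## Synthetic protocols

The generator produces coupled persistent walkers whose causal structure is
known, emulating the statistical features the analysis relies on: bimodal
step sizes (pause vs motion modes), persistent turning, pursuit, and
protocol-dependent stop-go coupling.

- **Leader**: heading drifts by ±turn_rate (a two-state Markov chain with a
  switch rate) plus Gaussian noise; advances at its speed unless paused.
  Reflective arena walls (ant default 370 × 655 mm, termite 145 × 145 mm)
  keep separations bounded.
- **Follower**: steers toward the leader's position with heading noise and
  advances up to its (higher) speed, stopping `contact_bl` (0.5 body
  lengths) short of the leader so distance stays positive.
- **ant mode**: the follower initiates search pauses (rate 0.08/s,
  geometric bouts of mean 2.5 s); the growing gap stops the leader above
  d_stop = 3.0 body lengths, and it resumes below d_go = 1.2. The
  follower's stop-go state thus temporally precedes the leader's —
  pausing flows follower→leader while turning flows leader→follower.
- **termite mode**: the leader pauses spontaneously (0.10/s, mean 1.5 s);
  the follower pauses only by catching up to a stopped leader, so both
  channels flow leader→follower.
- **independent mode**: two uncoupled walkers, each with its own turn chain
  and spontaneous pauses; no flow by construction.

Speeds are mm/s and rates events/s, converted by the frame interval, so a
protocol behaves identically at the recordings' native 29.97 Hz and at the
reduced 10 Hz used for fast experiments. A small positional jitter (0.03 mm
std per coordinate) emulates centroid-tracking noise and keeps the step-size
distribution realistically bimodal rather than spiking at zero. Defaults
are sized to the ant system (body length 2.34 mm, leader 2 mm/s) and the
*C. formosanus* system (8.89 mm, 10 mm/s); they were chosen from the
biology once and are not fitted to data. Pair i of a dataset uses seed
(master × 1000003 + i) mod 2³¹, so any pair can be re-simulated alone.

What the generator does **not** emulate: pheromone fields, antennation
micro-dynamics, corridor arena geometry, track-loss artifacts, or the
heavy-tailed speed fluctuations of real insects. Passing the recovery tests
therefore shows that the pipeline detects the designed causal structure
under realistic sampling and noise — not that real ants match these
particular parameter values.

## Problem sizes and numerics

Validation runs use: protocol recovery on 20 pairs × 900 s rendered at
10 Hz, analyzed at period 0.5 s with k = 2, q = 10 and 50 surrogate
replicates, repeated over 20 master seeds; sweep-scale checks on 3 pairs ×
90 s at 29.97 Hz (the full 900-cell grid); rank-sum calibration on 200
repetitions of 10 pairs × 60 s. These sizes give unambiguous direction
recovery (coupled-mode nets exceed their null SE by orders of magnitude)
at desk-scale runtime.

Numerical choices: base-2 logarithms throughout; exact count-ratio
arithmetic inside the local-TE log (no probability normalization round
trip), which is why the identities hold to 1e-12; percentile interpolation
is numpy's linear default; tie-breaks (threshold ties → pause, collinear →
carry previous, zero distance change → previous class, grid ties → smaller
k then shorter period) are all deterministic; every stochastic step takes
an explicit seed and derived seeds stay below 2³¹.

## Known limitations

- Plug-in TE is biased upward on finite samples; the surrogate correction
  removes the bulk but the residual depends on the block-count occupancy,
  so corrected values at large k and short series should be read with the
  surrogate std as the error bar.
- The surrogate null conditions on the observed series (see above); its
  2-std band is mildly anti-conservative for the corrected estimate.
- Only the source's present symbol conditions the prediction; multivariate
  or source-history-k estimators are out of scope.
- Reproducing published per-species tables requires the original deposited
  recordings; this repository validates the machinery on synthetic
  protocols and on the tables' internal arithmetic instead.
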