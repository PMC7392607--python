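# tandemflow

Information-flow analysis of leader–follower tandem running.

During tandem runs, one insect (the leader) guides another (the follower)
along a route, the follower keeping contact just behind the leader. Ants such
as *Temnothorax rugatulus* and termites such as *Coptotermes formosanus* and
*Reticulitermes speratus* all perform this behavior with apparently similar
short-range signals, yet use it for different ends (route teaching versus
pair cohesion). `tandemflow` implements the time-series machinery that
discriminates such communication protocols from trajectory data alone:

1. **Symbolic coarse-graining** of each runner's trajectory into behavioral
   patterns — stop-go (`M`/`P`), turn direction (`CW`/`CCW`), or the compound
   ternary alphabet (`P`/`CW`/`CCW`) — after temporal subsampling and
   percentile-based pause thresholding.
2. **Plug-in transfer entropy** between the two symbol series. For a source
   *S* and destination *X* with history length *k*,

   T(S→X) = Σ p(x_{i+1}, x_i^{(k)}, s_i) log₂ [ p(x_{i+1} | x_i^{(k)}, s_i) / p(x_{i+1} | x_i^{(k)}) ]

   in bits, estimated from pooled block frequencies with sparse counting
   (histories up to k = 20 are cheap). The per-step log-ratio (local transfer
   entropy) can be negative — misinformative moments — and its mean equals
   the pooled estimate exactly. Derived quantities: net transfer entropy
   T(L→F) − T(F→L), whose sign gives the predominant flow direction, and
   normalized transfer entropy T / H(X_{i+1}|X^{(k)}) ∈ [0, 1].
3. **Surrogate correction and tests**: re-pairing leaders with followers from
   different trials (derangements) builds a null ensemble whose mean is
   subtracted as a finite-sample bias correction; one-sided Wilcoxon
   rank-sum and signed-rank tests assess significance and direction.
4. **Parameter landscape**: net TE swept over history length k ∈ {1..20} ×
   45 sampling periods (900 configurations), maximum-|net TE| selection, and
   a pause-threshold perturbation (q ∈ {5..15}) robustness check.
5. **Distance-resolved profiles**: local TE and runner speed conditioned on
   the leader–follower separation in body lengths (binned means with LOESS
   smoothing), revealing where each information channel operates.
6. **A synthetic coupled-walker generator** with three protocols of known
   ground truth — `ant` (turns flow leader→follower, pauses follower→leader),
   `termite` (both flow leader→follower), `independent` (no flow) — so every
   stage is testable without recordings.

## Worked example

```python
import tandemflow as tf

# 20 synthetic ant-protocol pairs, 15 min at 10 Hz
cfg = tf.ant_config(seed=42, duration_s=900.0, frame_rate=10.0)
dataset = tf.simulate_dataset(cfg, n_pairs=20)
sub = tf.prepare_dataset(dataset, period_s=0.5)  # subsample to 2 Hz

for pattern in ("rotation", "pausing"):
    enc = tf.encode_dataset(sub, pattern)
    t_lf = tf.transfer_entropy(enc.leaders, enc.followers, k=2,
                               direction=("leader", "follower"))
    t_fl = tf.transfer_entropy(enc.followers, enc.leaders, k=2,
                               direction=("follower", "leader"))
    ens_lf = tf.surrogate_te(enc, 2, ("leader", "follower"), 50, seed=0)
    ens_fl = tf.surrogate_te(enc, 2, ("follower", "leader"), 50, seed=1)
    net = (tf.corrected_te(t_lf.te_bits, ens_lf)
           - tf.corrected_te(t_fl.te_bits, ens_fl))
    print(pattern, f"T(L->F)={t_lf.te_bits:.4f}", f"T(F->L)={t_fl.te_bits:.4f}",
          f"corrected net={net:+.4f}")
```

prints

```
rotation T(L->F)=0.1070 T(F->L)=0.0026 corrected net=+0.1044
pausing  T(L->F)=0.0000 T(F->L)=0.0187 corrected net=-0.0187
```

Turn information flows from the leader to the follower (+0.104 bits net: the
leader's turning history predicts the follower's next turn far beyond the
follower's own past), while stop-go information flows the other way (−0.019
bits net: the follower's search pauses predict the leader's stops and
resumptions). That opposite-signed pair of flows is the signature of the
ant-style acknowledgement protocol; under the termite protocol both nets
come out positive, and for uncoupled walkers both vanish after surrogate
correction.

The same pipeline is scriptable from the shell:

```sh
tandemflow simulate --mode ant --n-pairs 20 --duration 900 --frame-rate 10 \
    --seed 42 --out runs/ant
tandemflow report --input runs/ant/trajectories.csv --period 0.5 --k 2 \
    --n-surrogates 50 --seed 0 --config config.yaml --out runs/ant/report
```

where `config.yaml` holds `frame_rate`, `scale_mm_per_px`, `species` and
`body_length_mm`. Every command writes a manifest (parameters, seeds, input
digests) alongside its outputs.

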