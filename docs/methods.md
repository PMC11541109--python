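# Methods

This note documents the models behind `neurocodec`, the defaults chosen
where the design was open, and what the synthetic benchmarks do and do not
demonstrate.

## Signal model and synthetic data

The generator emulates a 20 kHz, 9-bit multi-channel extracellular
front-end.  A recording is the rounded, range-clipped sum of three
components, all driven by one `numpy` PCG64 generator seeded from the
config:

* **Spikes.** Each template is a 64-sample biphasic waveform (Gaussian
  depolarization plus a slower opposite-sign after-wave) whose steep edge
  sits near sample 32 of the window, mirroring the detector's 32-sample
  pre-buffer.  Onsets are Poisson per template; overlapping spikes
  superpose and both appear in the ground truth.  Default template peaks
  are 70–130 ADC counts; with the modeled LSB of ~3.9 µV that corresponds
  to large, well-isolated units of a few hundred µV.
* **Noise.** White Gaussian, default 3 counts (~12 µV RMS) — a clean but
  plausible background for a modern low-noise front-end.  Noise is a
  stand-in for thermal/electrode noise plus distant multi-unit activity;
  it is spectrally white, which real background is not.
* **LFP.** Per-channel Gaussian noise low-passed below 300 Hz (4th-order
  Butterworth), mixed across channels with weights `m^|c-d|` (rows
  L2-normalized), where the mixing parameter `m ∈ [0,1]` sets the
  inter-channel correlation.  AP-oriented recordings default to zero LFP
  amplitude, matching a front-end whose 300 Hz high-pass has already
  removed it; LFP-group fixtures enable it explicitly.

Because spikes are exact template copies plus white noise, detection and
sorting results on this data are upper bounds: real recordings add waveform
drift, bursting amplitude attenuation, correlated noise and electrode
artifacts.  Compression results are less flattering than real data in one
respect (white noise is incompressible) and more in another (templates
repeat exactly).

## Spike detection

The nonlinear energy operator `psi[n] = x[n]² - x[n-1]·x[n+1]` is computed
in exact integer arithmetic.  Every 64 samples the adaptive threshold
estimator updates:

* **Zero crossings** of `psi` (sign-bit changes, zero counted positive),
  compressed to `log_rate = floor(log2(zc+1))` — a cheap firing-rate proxy.
* **Noise level**: single-pole exponential smoothing of `|psi|` with
  `alpha = 1/64` per sample.  The smoother input is clipped at
  `max(4·level, 16)` so a spike transient perturbs the estimate only
  marginally while a sustained level change is still tracked; without the
  clip the estimate converges to the mean including spike energy, which at
  60 spikes/s inflates thresholds several-fold.
* **Threshold**: `max(floor, k · noise · (1 + beta·log_rate))` with
  defaults `k = 8`, `beta = 0.125`, `floor = 1`.  The form is monotone in
  both statistics and reduces to classic `k·noise` scaling at low rates;
  no canonical formula exists for combining the two statistics, so the
  simplest monotone affine-in-log-rate rule was chosen.

Stage 1 applies the same machinery to `|x|` with its own multiplier
(`k_amp = 5`, clip floor 4); stage 2 confirms candidates where `|psi|`
exceeds its threshold.  Both thresholds apply causally to the window after
the one they were estimated from; the first two windows only train the
estimator.  A confirmed detection takes 32 pre- and 32 post-samples and
locks the channel for 64 samples, so emitted windows never overlap.

## Intra-channel codec

**DPCM2** residuals `r(i) = s(i) - 2s(i-1) + s(i-2)` are zigzag-mapped
(0, -1, 1, -2, … → 0, 1, 2, 3, …) and entropy-coded.

**Golomb/Rice backend.** Rice code with `M = 2^k`: quotient in unary,
remainder in `k` bits.  `k` adapts causally every 256 values from the
running zero fraction `zf`: the map targets a geometric source with zero
probability `zf` and mean `(1-zf)/zf`, taking `k = round(log2(mean))`
clipped to [0, 7].  Encoder and decoder update the statistic identically,
so no side information is sent.  Initial `k` is 4.

**Arithmetic backend.** A 32-bit integer coder (underflow handled with
pending bits, two termination bits) against a *semi-adaptive* table: counts
are trained offline on a data segment, quantized to a fixed total mass of
2^16 with a floor of 1, and then frozen during coding.  The 1024 explicit
symbol counts serialize as uint16 to exactly 2048 bytes; the escape symbol
(count fixed at 1, not stored) routes larger mapped values through a 12-bit
literal.  The table is shared trained state of encoder and decoder — like
the channel tree of the cross-channel codec — and is not embedded in each
stream.

**Near-lossless framing.** Detected spike windows partition the stream
into alternating zero-runs and 64-sample spikes.  Each frame codes the run
length split bitwise into two 8-bit components (three if the run exceeds
65535 samples; a per-frame flag distinguishes the cases — a raw bit in the
Rice stream, a uniform binary symbol inside the arithmetic stream),
followed by the spike's 64 DPCM2 residuals computed with zero history, so
every frame decodes independently of discarded data.  Trailing zeros after
the last spike are implied by the sample count in the header.  The decoder
reproduces every spike window and every inter-spike interval exactly;
inter-spike samples decode to zero — that is the entire, documented
information loss.

SSR is reported as `100·(1 - payload_bits / (n_samples · bit_depth))`;
the 6-byte stream header is excluded by default since header accounting is
a container choice, not a property of the coder.

## Cross-channel codec

Channels are first DPCM-decorrelated (first order — the cross-channel
engine buffers no spike windows, so the cheaper temporal stage suffices).
Each child channel is then predicted from its parent's residuals with the
least-squares factor `γ = Σ e_c·e_r / Σ e_r²` over a training segment of
1000–2000 samples, the range in which γ estimates stabilize.  Training
builds the complete graph over the 2–8 selected channels with edge weight
equal to the per-sample residual energy after the optimal γ (the smaller of
the two directions, since the energy is what predicts coding length), takes
its minimum spanning tree so the prediction chain cannot close a loop, and
roots it at the smallest channel id — the same channel that anchors group
alignment.

γ is quantized to Q1.14 fixed point (error ≤ 2⁻¹⁵) and applied as
`e~_c = e_c - round_half_away(γ_q·e_r / 2^14)` in pure integer arithmetic,
mirrored exactly by the decoder: the quantization is what makes the spatial
stage lossless.  Residuals go through the same adaptive Rice coder as the
intra-channel engine.  One-tap prediction only: multi-tap variants add
complexity for negligible SSR gain.

## FIR filterbank

`y[n] = Σ_{i=0..15} c_i · x[n-i]` with signed 16-bit coefficients, exact
integer products, zero pre-history, and saturation of the final sum to the
signed 26-bit range `[-2^25, 2^25-1]`.  Saturation applies to the final
accumulated sum only, so below saturation the filter is exactly a linear
convolution; no output rounding or shift stage is modeled.  Up to 16
channels are filtered independently.

## Spike sorting

Spikes are aligned with their maximum-slope sample at index 20 of the
window.  The first difference is smoothed with a `[1,2,1]` kernel before
the argmax: near-flat slope maxima otherwise let sample noise flip the
alignment by ±1–2 samples, which splinters each unit into discrete
sub-clusters in feature space (measurably breaking cluster-count
selection).  Ties break to the earliest sample; shifted-in samples are
zero.

Features are either the top PCA axes of the mean-centered spike matrix
(≤ 10, orthonormal, deterministic sign) or, in the adaptive-filter style,
the ≤ 7 sample positions with the highest between-class/within-class
variance ratio under provisional labels, emitted as a sparse indicator
projection.  Projection is a plain matrix product evaluated in blocked
multiply-accumulate order; the blocking changes nothing but the float
summation order.

Clustering is k-means++ seeded Lloyd iteration (tol 1e-6, ≤ 100
iterations, 10 restarts, seeded).  The cluster count `k ≤ 8` is chosen by
silhouette over k = 2..8 among clusterings whose smallest cluster holds at
least 10% of the spikes; without that admissibility rule the silhouette
criterion prefers splitting off one or two overlap-corrupted waveforms
into singleton clusters.  Per-cluster covariances get a ridge of
`1e-3·trace/d` on the diagonal so Mahalanobis inference is always defined.
Inference assigns the nearest cluster mean under the Euclidean or
Mahalanobis metric (ties to the lowest id); the covariance-weighted metric
wins when cluster noise is anisotropic and correlated.  Accuracy against
ground truth uses the optimal one-to-one cluster↔template assignment on
the confusion matrix.

## Benchmark conditions

The headline near-lossless figure is measured on 60 s of a single 20 kHz,
9-bit channel firing at 60 spikes/s over 3-count background noise, with the
arithmetic backend and a table trained on the same segment's near-lossless
symbol stream.  The acceptance-style tests use shorter recordings (0.1–20 s,
100 seeds for the round-trip property) purely to keep the suite quick; the
codecs are size-agnostic and bit-exactness does not depend on length.

## Known limitations

* The generator's white noise and exact template repeats bracket, rather
  than match, real extracellular statistics (see above).
* The arithmetic and Rice streams are self-consistent but not
  bit-compatible with any particular hardware implementation; raster and
  container byte layouts are likewise package-defined.
* Near-lossless mode inherits the detector's decisions: a missed spike is
  not transmitted, and the refractory lockout merges spikes closer than
  64 samples.
* No streaming/online operation: encoders and the trainer work on
  in-memory arrays.
* The sorter assumes spikes from one channel at a time; no multi-electrode
  (tetrode-style) feature pooling.
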