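# Methods

## The estimator

`phibar` quantifies how much a multichannel signal behaves as one integrated
system rather than as independent parts. For a set of channels X observed at
lag τ, the effective information of a bipartition {M¹, M²} is the log-det
difference of linear prediction-error covariances,

    φ(M¹, M²) = Σ_k ½ log det Σ(E^{M^k}) − ½ log det Σ(E^X),

where E is the residual of the regression X_t = α + A·X_{t−τ} + E_t restricted
to each channel subset ("AR" estimator), or, equivalently for Gaussian data,
the conditional covariance Σ(X_{t−τ}|X_t) ("E" estimator). All logs are
natural; φ is in nats. The Gaussian differential-entropy constant that appears
in the underlying entropy expressions cancels in every difference and is never
materialized. The integrated information Φ of a channel unit is φ at the
minimum-information partition (MIP) — the bipartition minimizing φ — found by
exhaustive search over all 2^(n−1) − 1 distinct bipartitions. The customary
printed enumeration Σ_{k=1..n/2} C(n,k) (162 for n = 8) counts balanced splits
of even n twice; both counts are exposed, and the argmin is unaffected.

A full 96–128-channel MIP search is hopeless (≈1.8×10³⁸ bipartitions for 128
channels), so the practical estimator averages Φ over k random n-channel
sample units and subtracts, per unit, the median Φ of shuffle surrogates:

    Φ̄ = (1/k) Σ_i Φ_i(n) − (1/k) Σ_i median(Φ_surr(i)(n)).

Surrogates are per-channel circular shifts at a random split point within each
epoch: the per-channel amplitude distribution is preserved exactly, the
periodogram exactly (circular shift), and cross-channel phase relations are
destroyed. Defaults n = 8, k = 600, 20 surrogates, units drawn once on the
baseline condition and reused across states.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `tau` | 1 sample (2 ms at 500 Hz) | regression lag; the smallest lag maximizes AR validity inside 6-s epochs; every result is stamped with τ |
| `n`, `k` | 8, 600 | channels per unit / number of units; at k = 600 the coefficient of variance of Φ̄ over repeated unit draws is below 0.01 on a homogeneous reference system |
| `k_regional` | 30 | units per channel for the regional map Φ̄R(i) (CoV < 0.05); units are drawn constrained to contain channel i |
| `n_surrogates` | 20 | per-unit median over surrogate Φ is subtracted (median, then mean over units — in that order) |
| `normalize_mip` | off | optional argmin over φ/min(\|part\|); the reported φ at the chosen partition is always unnormalized |
| `ridge` | 1e-8 (relative) | λ·trace(Σ)/dim added to near-singular covariances, escalated ×10 up to 1e-4, then an error; every escalation is logged. Ill-conditioning (cond > 1e10) takes the ridge path even when a Cholesky would numerically succeed |
| `conn.threshold` | 0.35 | corrected wPLI above this (strictly) becomes an edge; chosen in the source protocol to avoid isolated baseline nodes |
| `conn.long_range_cm` | 9 | edges longer than this (3-D electrode distance) count as long-range |
| `bs.amp_threshold_uv` | 5 µV | suppression = channel-mean 100-ms moving-RMS envelope below threshold for ≥ 0.5 s (standard clinical convention; the source protocol states no amplitude criterion) |
| `bs.bsr_cut` | 0.3 | epochs with a burst-suppression ratio at or above this are flagged |

## Moments and numerics

Lagged second moments are estimated per epoch (per-epoch mean removal) and
pooled; lagged pairs never straddle epoch seams. The present (X_t) and past
(X_{t−τ}) marginal covariances are kept separately: on pooled moments with a
single shared marginal the AR and Gaussian-conditional estimators are
algebraically identical, and their finite-sample difference (which heavy-tailed
innovations inflate) is the only thing that distinguishes them on stationary
data.

The MIP search computes, per unit, the residual-covariance log-det of every
nonempty channel subset via batched Schur complements grouped by subset size
(254 subsets for n = 8), then forms all 127 bipartition φ values by pairing.
Units are processed in chunks of 4096 through numpy's batched solve/slogdet;
600 units × 21 datasets (real + 20 surrogates) take a few seconds on one core.
Ties in the argmin break on the canonical partition order (part 1 contains the
lowest channel index; partitions ordered by part-1 bitmask).

φ is scale-invariant by construction (log-det differences cancel any common
gain), so amplitudes are treated as µV but never rescaled.

## Companion analyses

**wPLI.** The weighted phase lag index per pair is |E{ℑS}| / E{|ℑS|} with the
expectation pooled over all (frame, frequency-bin) pairs of 3-s Hamming STFT
frames (50 % overlap, no frame straddles an epoch boundary) — pooling frames
and bins maximizes samples. A pair whose imaginary cross-spectrum is zero —
or numerically negligible relative to the pooled cross-spectral magnitude
(< 1e-12 of it, the float-rounding regime of exact zero-lag copies) — has
wPLI 0 by convention. Band-specific surrogate medians are subtracted
(different bands carry different spurious connectivity), negative corrected
values floor at 0, and the graph is binarized at strictly > 0.35.

**Modularity.** Two-group modularity Q = 1/(4m) Σ_ij (A_ij − k_i k_j / 2m)
s_i s_j is evaluated exactly. Module detection is Newman's leading-eigenvector
recursive bisection with the generalized modularity matrix for subgraphs,
accepting a split only when it increases Q; Kernighan–Lin fine-tuning is
deliberately omitted for determinism. Disconnected components are split first;
isolated nodes count as singleton modules (this matters for module counts in
sparse anesthesia-like graphs). An empty graph reports one module per node and
Q = 0 with a warning.

**Band power.** Relative power uses the same STFT frames; the denominator is
total 0.1–45 Hz power, so the five conventional bands (delta 0.1–4, theta 4–8,
alpha 8–13, beta 13–25, gamma 25–45 Hz; half-open bins) partition to exactly 1
per channel. Zero-phase band filtering is a Hamming windowed-sinc FIR applied
forward–backward; kernel length 3·fs/lo with a 2-s floor, clipped to the
record. Delta filtering therefore operates on the continuous multi-minute
record before epoching (reference → filter → epoch, fixed order).

**State descriptors.** Per state and band: Φ̄ and average degree min-max
normalized to the baseline's per-block range (values outside clip to [0, 1]
with a logged flag — burst-like states can exceed baseline), plus Pearson
topographic similarity of the Φ̄R and degree maps to baseline. Pearson r is
affine-invariant, so raw vs normalized maps give identical similarities. A
constant map (e.g. the empty suppression-state graph) has no defined
topography; its similarity axis reports 0 with a warning. The radar area over
axes (sim_Φ, rel_Φ, sim_degree, rel_degree) — similarities rescaled to [0, 1]
for geometry only — is (r₁r₂ + r₂r₃ + r₃r₄ + r₄r₁)/2, maximal (2.0) exactly at
baseline.

## The synthetic generator

The canonical family is a lag-1 VAR (matching the estimator's regression
order) with optional Student-t(3) innovations for the non-Gaussian regime.
`modular_var` plants block structure: off-diagonal entries are seeded
uniform[0.5, 1) draws scaled by the intra/inter coupling of their block (the
same law for both, so equal couplings yield a statistically uniform system),
plus a self-coupling diagonal; stationarity is enforced by rescaling to
spectral radius 0.95 with a warning. `burst_suppression_trace` alternates
full-amplitude VAR segments with low-amplitude white noise on a fixed schedule
and returns ground-truth labels. `volume_conduct` applies instantaneous
Gaussian distance-decay mixing over a deterministic Fibonacci-hemisphere
montage (9.2 cm radius; 96/128-channel inter-electrode distances span
≈1.8–18 cm). The packaged 32-channel exclusion list is the montage's 32 lowest
electrodes — a synthetic stand-in for the undisclosed face/neck set of the
real net.

Noise-driven VARs with unit innovations cannot reach the coherence needed for
corrected wPLI to clear 0.35 (their per-frame phase consistency is too low
regardless of coupling), so phase-lag network ground truth comes from
`oscillatory_scene`: each module shares a narrowband (default 10 Hz AR(2)
resonance) latent oscillator received with channel-specific conduction delays
of 2–12 samples, plus unit background noise; a `global_coupling` γ mixes the
module oscillators toward one global source, eroding segregation and raising
integration as γ → 1. This family exhibits the expected joint behavior:
module count non-decreasing as coupling vanishes, and Φ̄ vs module count
strongly negatively rank-correlated.

**What the generator does not emulate:** scalp lead fields, 1/f spectra,
artifacts, non-stationary drifts, or reference-electrode physics. Passing
tests therefore demonstrate estimator correctness on systems with known
ground truth, not clinical validity on real recordings. One consequence worth
knowing: average-referencing a *small* montage induces −1/(n−1) cross-channel
correlation, a genuine (not spurious) dependence that surrogate correction
rightly does not remove; it is negligible at 96 channels but visible below ~16.

## Problem sizes used in the checks

Reliability is verified on the homogeneous 96-channel, 2-min reference system
with repeat counts of 36–100 (tests) and 100–300 (acceptance script) per k —
the protocol's full 300 repeats at every k changes the CoV estimates'
precision, not their level, and the package's choice favors fast verification.
Null, oracle, and structure-recovery checks use 2–24-channel systems at 40–120
s. All simulations are bit-reproducible from seeds.

## Known limitations

- Only bipartitions are searched (as in the source protocol); finer partitions
  and normalized MIP variants beyond φ/min(|part|) are out of scope.
- The exhaustive search is limited to units of ≤ 16 channels.
- Weighted-graph modularity and alternative community methods are not offered.
- The burst/suppression amplitude criterion is a convention; data with slow
  high-amplitude artifacts will need a tuned threshold.
- EDF is read-only (via MNE); there is no EDF writer.
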