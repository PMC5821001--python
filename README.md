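# phibar

Practical estimation of **integrated information (Φ̄)** from multichannel
EEG-like recordings, together with the network analyses that contextualize it:
weighted-phase-lag-index (wPLI) connectivity, Newman modularity,
burst-suppression segmentation, and a four-axis descriptor that places brain
states in a common parameter space. A seeded synthetic generator provides
ground truth for every stage.

## Who this is for

Researchers quantifying *relative* changes of integrated information across
conditions (anesthesia, sleep, pathology) from high-density scalp recordings,
and methodologists who want a tested, reproducible reference implementation of
the sample-unit Φ̄ protocol on synthetic systems with known structure.

## The estimator

For channels X at lag τ, the effective information of a bipartition {M¹, M²}
is the log-det difference of linear prediction-error covariances

    φ(M¹, M²) = Σₖ ½ log det Σ(E^{Mᵏ}) − ½ log det Σ(E^X),
    X_t = α + A·X_{t−τ} + E_t ,

and the integrated information Φ of a channel unit is φ at the
minimum-information partition (MIP), found by exhaustive search over all
2^(n−1) − 1 distinct bipartitions. Because the full-montage search space is
astronomical (≈1.8×10³⁸ bipartitions for 128 channels), the practical
estimator averages over k random n-channel sample units and subtracts a
per-unit surrogate median:

    Φ̄ = (1/k) Σᵢ Φᵢ(n) − (1/k) Σᵢ median(Φ_surr(i)(n)),

with n = 8, k = 600, and 20 per-channel circular-shift surrogates by default.
φ is in nats and scale-invariant. See `docs/methods.md` for the full account.

## Worked example

Two synthetic 24-channel, 2-minute scenes share the same modular layout
(4 modules of shared 10-Hz oscillators with conduction delays); one is
globally coupled (integrated), one is not (fragmented):

```python
from phibar import synth
from phibar.preprocess import segment_epochs
from phibar.phi import PhiBarModel
from phibar.connectivity import WpliNetwork

spec = synth.SceneSpec(n_channels=24, n_modules=4, seed=3)
wake, _ = synth.oscillatory_scene(spec, 120, global_coupling=0.7)
eps = segment_epochs(wake, epoch_seconds=6, n_epochs=20)

res = PhiBarModel(eps, n=8, k=100, n_surrogates=20, seed=7).fit(seed=11)
print(res.summary())
net = WpliNetwork(eps, band="alpha", n_surrogates=20, seed=5).fit()
print(net.summary())
```

```
Integrated information (sample-unit estimator)
====================================================
estimator:            phi~AR  (tau = 1 sample(s))
channels:             24
sample units:         k = 100, n = 8 channels/unit
surrogates:           20 (split-and-swap, per-unit median)
----------------------------------------------------
mean unit Phi:         0.065650 nats
surrogate correction:  0.000767 nats
phi_bar:               0.064882 nats
MC s.e. (unit draws):  0.001276 nats
====================================================
wPLI network (surrogate-corrected)
====================================================
band:              alpha
channels:          24
surrogates:        20, threshold > 0.35
----------------------------------------------------
links (m):         216
average degree:    18.000
modules:           2 (Q = 0.0417)
====================================================
```

The globally coupled scene integrates (Φ̄ ≈ 0.065 nats, a dense 2-module
network); rerunning the same code on the fragmented scene
(`global_coupling=0.0`) yields Φ̄ ≈ 0.0002 nats — indistinguishable from the
surrogate null — and a sparse network whose 4 detected modules recover the
planted layout exactly. Integration and network segregation move in opposite
directions, which is the core empirical relationship the tooling is built to
expose.

The same analysis runs from the shell on recordings (EDF or delimited
matrices) described by a YAML config:

```bash
phibar all --config run.yaml            # full pipeline, all states and bands
phibar synthgen --out scene/ --channels 24 --modules 4 --seed 3
```

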