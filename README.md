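# commdyn

Dynamic community analysis of perturbed brain networks.

`commdyn` implements the full network-dynamics workflow used to map how a
transient perturbation (e.g. inhibitory 1 Hz rTMS over parietal cortex)
reshapes large-scale functional brain networks during a task: regional
BOLD time-series are turned into a temporal multilayer network by windowed
wavelet coherence, time-resolved communities are found by multilayer
modularity maximisation, node dynamics are quantified with
flexibility/cohesion/promiscuity/allegiance-type metrics, and
active-vs-sham differences are tested with resampling-based statistics.
Because raw stimulation fMRI datasets are rarely shareable, the package
ships a first-class synthetic generator that plants known community
structure, known membership switches, and a known transient perturbation,
so every stage of the analysis is testable end to end.

Intended users: network-neuroscience and systems-biology researchers who
want a reproducible, plain-text-interchange pipeline for temporal
community detection and condition comparison — or a tested reference for
the individual primitives.

## The model

A recording of N regions is converted into L layers: for each pair of
regions, magnitude-squared wavelet coherence (analytic Morlet, ω₀ = 6) is
averaged over the scales whose equivalent Fourier frequency lies in the
task band (default 0.06–0.12 Hz) and over non-overlapping 20-volume
(40 s) windows. Community labels g_il are found by maximising multilayer
modularity with a Louvain-style greedy algorithm:

    Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ P_ijl) δ_lr + δ_ij ω 𝟙(|l−r|=1) ] δ(g_il, g_jr)

with the weighted configuration null P_ijl = k_il k_jl / 2m_l, structural
resolution γ, and ordinal inter-layer coupling ω. The (γ, ω) operating
point can be chosen by sweeping a log-spaced grid and maximising the mean
optimised Q relative to a shuffled-edge null.

On the labels, the package computes node flexibility ξ_i = g_i/(L−1),
cohesion strength Ω_i = Σ_{j≠i} M_ij (joint moves), promiscuity,
allegiance P_ij, recruitment and integration relative to a consensus
(z-Rand-representative) reference partition, plus within-module degree and
participation coefficient for hub/integrator classification. Conditions
are compared with paired per-node t-tests (BH-FDR across nodes), sliding
sum-of-squared-difference (SSD) contrasts across epochs (BH-FDR across
epochs), a Monte-Carlo unlabeled-pool null for extreme node metrics, and a
bootstrap test of the behavioral accuracy change.

## Worked example

```python
import numpy as np
from commdyn import (GroundTruthSpec, generate_regional_bold,
                     windowed_band_coherence, DynamicCommunityModel, zrand)

spec = GroundTruthSpec(n_regions=30, n_communities=3, snr=3.0, seed=42)
ts, planted = generate_regional_bold(spec, participant=0, condition="sham")
stack = windowed_band_coherence(ts, window_length=20, band=(0.06, 0.12))
print(f"stack: {stack.n_layers} layers x {stack.n_nodes} nodes")

model = DynamicCommunityModel(stack, gamma=1.0, omega=1.0)
ens = model.fit_ensemble(n_runs=10, seed=0)
print(ens.summary())
print(f"z-Rand vs planted (layer 1): {zrand(ens.best().labels[0], planted[0]):.2f}")
```

prints

```
stack: 54 layers x 30 nodes
Louvain ensemble
================
runs: 10   gamma: 1   omega: 1
Q: mean 0.135154, sd 0.000000, max 0.135154
mean flexibility: 0.0000
z-Rand vs planted (layer 1): 20.12
```

Three 366-volume runs at TR = 2 s concatenate to 1,098 volumes, i.e. 54
coherence windows. All ten Louvain restarts land on the same optimum
(Q ≈ 0.135) recovering exactly the three planted communities in every
layer; a z-Rand of 20.1 against the planted labels is the maximum
attainable for 30 nodes in three equal groups (identical partitions), far
above chance (z ≈ 0). Flexibility is 0 because this example plants a
static partition; scheduled membership switches
(`commdyn.synthetic.rotating_schedule`) and transient perturbations
(`Perturbation`) make it non-zero.

The same stages are available from the shell:

```bash
commdyn simulate -c config.yaml -o data/
commdyn coherence -i data/ts_p0_sham.tsv -o stack/
commdyn communities detect -i stack/ -o parts/ --gamma 1.0 --omega 1.0 --runs 100 --seed 1
commdyn run-all -c config.yaml -o run/
```

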