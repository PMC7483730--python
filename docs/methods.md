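# Methods

This note documents the models, estimators, conventions and validation
design of `commdyn`, including every place where a choice had to be made
that the underlying literature leaves open.

## Synthetic data generator

The generator (`commdyn.synthetic`) emulates the statistical structure the
downstream analysis assumes, not the biophysics of BOLD.

**Signal model.** Each planted community c owns one band-limited Gaussian
signal s_c(t): white noise whose Fourier coefficients outside the task
band are zeroed, normalised to unit variance. Region i's series is
`snr · s_{c_i(t)}(t) + e_i(t)` with independent white noise e_i, then
z-scored per region over the full concatenated session. Band-passed noise
is used instead of sinusoids so within-community coherence is broadband
across the band rather than a degenerate phase-locked line. `snr` is the
amplitude ratio of community signal to noise; because the signal is
confined to the band while the noise is broadband, the in-band power
ratio is larger by the bandwidth ratio (≈ 4.2 for 0.06–0.12 Hz at
TR = 2 s), so snr = 1 already yields within-community band coherence of
roughly 0.8 and snr ≥ 2 is a comfortably recoverable regime. The
default (snr = 2) is a moderate setting; "high-snr" validation runs use
snr = 3. Planted structure is reliably recovered by the detector for
snr ≳ 1; below that, recovery degrades toward the estimator noise floor.

**Defaults** mirror the targeted acquisition: 148 regions, 3 runs × 366
volumes at TR = 2 s (1,098 volumes = 54 twenty-volume windows), band
0.06–0.12 Hz, 7 participants, 18 trials per behavioral cell, 4 behavioral
runs (the behavioral session has one more run than imaging; the count is
a parameter rather than a resolved discrepancy).

**Time-varying structure.** The planted partition is a window-indexed
schedule. `static_schedule` plants one partition for the whole session;
`rotating_schedule` displaces a fresh small set of nodes into the next
community every few windows, emulating modest membership turnover while
the bulk structure stays put. The planted labels are returned per
coherence window, aligned with the downstream layer index.

**Perturbation model.** A transient perturbation is signal *mixing*, not
amplitude change: during the perturbation windows, a perturbed node's
community component becomes `(1−β)·s_own + β·mean(s_others)` re-normalised
to unit variance, with β = (f−1)/f for coupling-increase factor f (f = 2
mixes equally). This raises the node's cross-community coherence and
lowers its within-community coherence at constant power, which is the
effect of interest (allegiance change), and leaves the z-scored spectra
otherwise unchanged. The perturbation is applied only to the 'rtms'
condition.

**Behavior.** Accuracy per (participant, run, hemifield, condition) cell
is binomial at a baseline of 0.85 (the task staircases participants to
85% accuracy), reduced by the planted effect (default 0.08) only in the
run-1 contralateral rTMS cells.

**RNG discipline.** One `numpy` Generator stream per (participant,
condition), seeded as `[master_seed, participant, condition_code]`; the
behavioral table uses its own derived stream. Identical seeds reproduce
byte-identical outputs.

**What the generator does not model** (hence what passing tests do not
show about real data): hemodynamic convolution and autocorrelation,
scanner drift and motion artifacts, spatial geometry of regions,
inter-subject variability in community architecture, and non-Gaussian
noise. Calibration results (e.g. the SSD false-positive rate) therefore
certify the statistical machinery under the generator's assumptions, not
under fMRI noise.

## Wavelet coherence

The continuous wavelet transform uses the standard analytic Morlet with
centre frequency ω₀ = 6 (pywavelets `cmor2.0-0.9549`), on a grid of 32
log-spaced scales spanning 0.01–0.25 Hz equivalent frequency — bracketing
the task band with margin. The CWT is computed once on the full
concatenated session; windows may straddle run seams, which reproduces
the 54-layer count for 3 × 366 concatenated volumes and accepts small
edge effects at the two seams.

The magnitude-squared coherence estimator is
`|S(W_x W_y*)|² / (S|W_x|² · S|W_y|²)` where S is smoothing: a boxcar
over time of one wavelet period per scale and a 3-point boxcar across
scales (the underlying literature does not state a smoother; this is
standard practice and is exposed in the API). Without smoothing the
estimator is identically 1 — a guard test asserts this, ensuring the
smoother is genuinely applied. The light smoother implies a substantial
noise floor (independent series show band coherence around 0.6), which
compresses but does not reorder the within/between-community contrast; a
planted-pair-vs-independent-pair test asserts the ordering and its
monotonicity in snr. Coherence is clipped to [0, 1], averaged over the
in-band scales and over each non-overlapping 20-volume window; a trailing
partial window is discarded (floor rule). The cone of influence is not
masked: windows are interior-dominated at these series lengths. Layer
diagonals are defined as 0 so self-coherence never enters the modularity
null model.

The production path runs a fused per-pair kernel (numba-compiled, with a
pure-Python fallback of identical semantics); it is verified against the
straightforward vectorised composition of the same operations to ~1e-13.

## Multilayer community detection

Quality function: standard multilayer modularity with the weighted
configuration (Newman–Girvan) intra-layer null, uniform ordinal coupling
ω between adjacent layers only, and 2μ = total edge weight + total
coupling weight. All-zero layers are rejected (the null model is
undefined).

Optimisation: greedy node-moves over the sparse supra-modularity matrix
(node-layer index l·N + i) in seed-randomised sweep order, followed by
community aggregation, iterated to a fixed point; move acceptance uses a
1e-12 gain tolerance, and a 1,000-sweep cap raises a convergence error
with diagnostics. The algorithm is deliberately stochastic across seeds;
the ensemble convention is 100 restarts for final labels. Returned labels
are globally persistent integers (same integer = same community through
time), relabelled 1..k by first appearance.

For stacks with N ≤ 6 and L ≤ 2 an exhaustive maximiser is provided: it
enumerates per-layer set partitions (restricted growth strings) and, since
ω ≥ 0 makes the coupling reward maximal under the best identification of
communities across layers, solves a linear assignment on the community
overlap matrix for each pair. Best-of-100 Louvain matches this optimum to
1e-12 on every toy stack in the validation suite.

The (γ, ω) sweep compares mean optimised Q on observed stacks against
shuffled-edge nulls (upper-triangle weights permuted per layer, symmetry
and zero diagonal preserved, weight multiset conserved exactly). The
optimum maximises the mean difference observed − null; a difference was
chosen over a ratio for scale stability, ties break toward smaller γ then
smaller ω, and the criterion is configurable. Sweeps are run on the
control (sham) condition only, so the operating point is not biased by
the perturbation under study. The default grid is 20 log-spaced values
from 0.25 to 31.62 per axis; sweep cells default to a reduced restart
count (10) with the full ensemble reserved for the chosen optimum.

## Node and community metrics

All metrics are invariant to relabelling of community integers (property
tested). Conventions where the literature wording is loose:

- **Flexibility** ξ_i = (label changes of i)/(L−1); undefined for L = 1.
- **Cohesion** M_ij counts steps where *both* nodes change label *and*
  land in the same community, divided by L−1; Ω_i is the off-diagonal row
  sum. A node that always moves alone has Ω = 0 despite ξ = 1.
- **Allegiance** P_ij divides the co-assignment count by L (fraction of
  layers), so a permanently co-assigned pair scores exactly 1; the
  literal "per possible change" L−1 denominator (which would exceed 1 for
  static pairs) is available as a compatibility flag.
- **Promiscuity** divides by the number of distinct communities realised
  anywhere in that partition.
- **Recruitment / integration**: mean allegiance to own- /
  other-community nodes of a reference structure; singleton reference
  communities yield a missing recruitment value.
- **z-Rand**: the pair count w is standardised by its closed-form mean
  and variance under the hypergeometric permutation model; validated
  against a 10,000-relabeling estimate (both moments within Monte-Carlo
  error). Plain Rand and adjusted Rand are also reported for descriptive
  similarity summaries since "percent similarity" claims in the
  literature rarely name their index.
- **Consensus**: the member partition maximising summed pairwise z-Rand
  against all others; undefined pairs contribute nothing; ties break to
  the lowest input index and are logged. Applied hierarchically: per
  participant over layers × restarts, then across participants.
- **Within-module degree** z-scores with the population (not sample)
  standard deviation; zero-variance communities map to 0 and singleton
  communities to missing — determinism on degenerate fixtures.
- **Participation coefficient** uses the standard orientation
  (0 = connectivity confined to one's own community).
- **Hub/integrator classification** flags nodes strictly above the 95th
  percentile (linear interpolation) of within-module degree /
  participation respectively; percentile 0 is the unconstrained boundary
  (all nodes flagged).

## Condition statistics

- **Sliding epochs**: metrics are recomputed on each 10-window epoch
  (shifted by 1 window; 54 windows → 45 epochs) per ensemble run, then
  ensemble-averaged; z-scoring of the SSD happens after ensemble
  averaging (the alternative order is not implemented behind the public
  API because the averaged series is the quantity of interest). Epoch
  timestamps are the epoch's first window start in minutes (window k at
  40·k s).
- **SSD contrast**: per participant and epoch, Σ_i (m_i^TMS − m_i^sham)²,
  z-scored across epochs within participant, then a per-epoch one-sample
  t-test across participants with BH-FDR across epochs. The test is
  one-sided (elevated) by default: within-participant z-scoring forces
  epochs away from a genuine elevation to be negative by construction, so
  a two-sided test would flag post-effect epochs as artifacts; the
  scientific question is where the discrepancy rises above its session
  mean. Two-sided remains available via `alternative`.
- **Per-node tests**: paired t per node, BH-FDR across nodes (FDR is
  always applied within the family the contrast defines). Nodes with
  identically zero differences report t = 0, p = 1.
- **Monte-Carlo metric null**: draws of size-7 means with replacement
  from the pooled unlabeled (subjects × nodes × conditions) vector;
  "extreme" is two-sided by default (outside the central 95%), because
  both extremely high and extremely low dynamics are of interest; a
  one-sided option exists. A machine-precision tolerance keeps a
  degenerate constant pool from flagging anything.
- **Behavioral bootstrap**: observed statistic = group mean run-1
  contralateral (rTMS − sham) accuracy difference; null = means of 7
  differences drawn with replacement from the pooled ipsilateral (all
  runs) and remaining contralateral (runs 2+) difference vectors, 10,000
  draws per pool; one-tailed p = proportion of null means *strictly
  below* the observed mean (ties count as non-events). Pools are sorted
  before drawing so the result is exactly invariant to participant
  relabeling.

## Validation design and problem sizes

The validation workloads (`commdyn.benchmarks`, exercised by the test
suite and by `scripts/acceptance.py`) are sized for a single CPU:

- Planted recovery: 30 regions, 3 planted communities, snr 3, full
  54-layer session; per-layer significance against a 1,000-permutation
  z-Rand null.
- Replicate studies of the sliding-SSD test: 20 regions, 3 communities,
  7 participants, full 54-layer sessions, 3-restart ensembles, with a
  rotating membership schedule (period 6 windows, 2 nodes) so the null
  condition has genuine label dynamics; snr 3 and, for the perturbed
  arm, a factor-2.5 perturbation of one community's nodes during windows
  0–14. One hundred unperturbed replicates calibrate the false-positive
  rate; twenty-five perturbed replicates measure sensitivity. Measured
  detection power at these conditions is ≈ 0.8–0.9 with no
  post-stabilisation false flags; the false-positive rate is ≈ 0.01–0.03,
  conservative relative to the nominal q = 0.05 because overlapping
  epochs are strongly positively dependent.
- Optimizer-vs-enumeration: six toy stacks (N ≤ 6, L ≤ 2), best of 100
  restarts against exhaustive search.

Full-scale defaults (148 regions, 100 restarts, 20 × 20 sweep grids)
remain the package defaults for real analyses; the scaled sizes above are
the validation choices, stated here so they are not mistaken for analysis
recommendations.

## Known limitations

- The coherence smoother is light; absolute coherence values carry a
  large estimator bias (noise floor ≈ 0.6) and should be interpreted
  relatively, as the modularity null model does.
- Inter-layer coupling is uniform and ordinal only; no all-to-all or
  weighted coupling variants.
- One quality function (Newman–Girvan multilayer modularity); no
  Potts/CPM variants, no overlapping communities.
- The exhaustive maximiser is limited to N ≤ 6, L ≤ 2 by design.
- Group tests assume at least two participants; the pipeline records and
  skips them otherwise.
- Statistical calibration is certified under the generator's Gaussian,
  stationary-noise assumptions (see above), not under real fMRI noise.
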