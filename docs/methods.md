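# Methods

## Point-process GLM with Laguerre kernels

Spike trains are binned into half-open 10 ms bins (configurable); a bin
holds 1 if the neuron spiked at least once. For output neuron *i* the
per-bin conditional intensity is modeled as

    λ_i(t) = k₀ + Σ_n Σ_{τ=0}^{M−1} k⁽ⁿ⁾(τ) · x_n(t−1−τ),

a linear (identity-link, Gaussian-error) model of every neuron's recent
history, including the output's own (the self-kernel supports
validation but never produces a graph edge). The one-bin minimum
latency keeps the regression strictly causal. Each kernel is expanded
on J discrete Laguerre functions, k⁽ⁿ⁾(τ) = Σ_j c_j⁽ⁿ⁾ b_j(τ), built by
the standard recursion

    b₀(τ) = √(1−α)·α^{τ/2},
    b_j(τ) = √α·b_j(τ−1) + √α·b_{j−1}(τ) − b_{j−1}(τ−1),

whose rows are orthonormal (checked to 1e−6 in tests; exact to machine
precision in practice). α ∈ (0,1) sets the kernel decay time; J=3 and
M=50 bins (0.5 s of history) are the defaults, trading kernel
resolution against parameter count N·J+1.

**Sparsity and model selection.** Coefficients minimize
(1/2T)·RSS + ζ·Σ|c| (lasso; ζ is a per-sample penalty so its useful
range, 1e−5 to 1e−1 on a 20-point log grid, does not depend on
recording length). ζ — and jointly the basis decay α over a 0.2–0.9
grid — is selected by 5-fold cross-validated Gaussian deviance with
*contiguous time blocks* as folds, since shuffled folds would leak the
serial dependence of spike trains. Ties go to the larger (sparser)
penalty; a paired one-standard-error rule is available
(`selection="1se"`).

**Edge rule.** An edge n → i exists when input n retains any nonzero
coefficient in neuron i's model — after a significance screen. The CV
deviance curve is nearly flat around its optimum, so the
prediction-optimal ζ admits inputs whose contribution is noise (the
classic over-selection of cross-validated lasso); moreover the F
statistics of lasso-selected groups are biased upward because the same
data chose them. The screen therefore refits OLS on the selected
columns and keeps only input groups passing a partial F-test at level
0.01 Bonferroni-corrected over *all* candidate inputs, which compensates
for the selection scan. On planted 10-neuron networks at 10⁴ bins this
yields precision and recall ≥ 0.8 in ~90% of runs (measured by the test
suite); without the screen precision drops to 0.2–0.5. Isolated nodes
are removed from the final graph, as is every neuron below the 0.5 Hz
firing-rate floor before fitting.

## Validation

The time-rescaling theorem maps spikes of a correctly specified model
to a unit-rate Poisson process. For binned data the exact discrete-time
construction is used: per-bin hazard mass −ln(1−λ), intervals restart
at the bin after each spike, and the terminating spike contributes a
randomized truncated-exponential partial mass −ln(1−U·λ). Under this
construction the rescaled values of a Bernoulli train with the true
per-bin probabilities are *exactly* uniform; naive rectangle-rule
integration leaves a granularity floor of about one bin's intensity
mass in the K-S statistic, which fails even perfect models once λ per
bin exceeds ≈1.36/√n_spikes (a 5 Hz neuron at 10 ms bins). The K-S
95% band is ±1.36/√n around the diagonal; serial dependence is screened
by lag-1..10 autocorrelations against ±1.96/√n; spike/no-spike
prediction is summarized at the Youden-optimal ROC threshold
(TP = sensitivity, TN = specificity). Negative intensities from the
identity link are clipped at 1e−8 before integration.

## Small-world metrics

All small-world quantities use the binarized, symmetrized graph;
direction is kept only for controllability. L̄ averages shortest-path
lengths over unordered pairs of the largest connected component
(flagged when the graph is disconnected); C̄ averages local clustering
with degree-<2 nodes contributing 0. References: C_r and L_r are means
over 20 seeded Erdős–Rényi G(N,E) draws; C_l comes from a deterministic
ring lattice with matched N and E, filled ring-wise by increasing
neighbor offset. S_w > 1 suggests small-world structure but grows with
network size; ω = L_r/L̄ − C̄/C_l is size-stable and bounded near
[−1, 1]. When the lattice has no triangles (too few edges) ω is
reported as NaN with a flag.

## 3D tissue simulation and electrode sampling

Neurons are uniform in a 780×320×100 µm cuboid — the tissue block
spanned by a 4-shank probe with ~200 µm shank spacing and ~50 µm
recording columns, which at whole-brain averages (9.2×10⁴ neurons/mm³,
7.2×10⁸ synapses/mm³) holds ≈2296 neurons at ≈8.5% edge density.
Connection models:

* threshold: Bernoulli(P_in) within distance l, Bernoulli(P_out)
  beyond; l is calibrated as the pairwise-distance quantile solving
  P_in·F(l) + P_out·(1−F(l)) = target density (8.32% at
  P_in=0.25/P_out=0.05) and is always recorded in the output;
* model 1: P(d) = P₀ + α·λ^{d/d₀} (geometric decay to baseline);
* model 2: P(d) = P₁ + γ/(1 + β·d/d₀) (hyperbolic, heavier tail).

The distance unit d₀ defaults to 50 µm (electrode-column scale); the
parametric forms are each isolated behind one function and chosen to
satisfy the qualitative constraints that define them (initial state set
by α/γ, monotone decay, model 2 strictly above its asymptote at finite
d). Biases P₀, P₁ default to 0. Six electrodes are placed uniformly at
random; the sampled network is the vertex-induced subgraph of all
neurons within radius l′ (default 50 µm) of any electrode.

**Pattern fitting.** A small generational GA (population 40, 60
generations, tournament-of-3 selection, blend crossover, Gaussian
mutation, elitism) fits the threshold model to an observed (L̄, C̄)
pattern, minimizing squared deviation of the realization-averaged
pattern (5 graphs per candidate, common random numbers so the surface
is deterministic). Genes are (P_in, P_out, l-quantile); the local-region
size must be free alongside the probabilities for both L̄ and C̄ to be
matched at arbitrary geometry. P_in ≥ P_out is enforced by repair.

## Subsampling bias and correction

The relative bias of the sampled metric, σ = (ω_ON − ω_SN)/ω_SN, is
positive for small samples (overestimated small-world-ness) and decays
with the number of sampled neurons N. `simulate_error_curve` regenerates
the (N, σ) scatter from scratch: threshold networks at several sizes,
electrode radii calibrated to target sampling fractions, ω on original
and induced subgraph. A two-term exponential σ(N) = a·e^{bN} + c·e^{dN}
is fit by multi-start nonlinear least squares (base start (1.5, −0.1,
0.3, −0.01) plus 9 seeded perturbations; b, d constrained negative);
the correction is then ω_ON = ω_SN·(1 + σ(N)) — this multiplicative
inversion is the algebraic inverse of σ and was cross-checked against
the reference adjusted values before adoption. The packaged
`REFERENCE_FIT` (a=1.564, b=−0.080, c=0.279, d=−0.006) describes
simulations at ~8.3% edge density, the estimated cortical value; a
density sweep (5.8%–23% endpoints) yields an adjustment interval via
`adjust_range`. A zero sampled ω stays zero; a negative sampled ω
(lattice side) is adjusted on its magnitude with sign preserved and a
warning, since the bias curve was measured on positive ω only.

## Controllability

The minimum driver-node count is N_i = max(N − M*, 1) with M* the
maximum matching of the digraph, computed by Hopcroft–Karp on the
out/in bipartite expansion (networkx implementation; verified in tests
against brute-force enumeration on all suite digraphs ≤ 8 nodes).
Self-loops participate in the matching by default — a node retaining
its own history term can match itself — behind a flag. Driver sets are
reported sorted for determinism; with a perfect matching any single
node suffices and the smallest label is reported.

## Synthetic ground truth

The generator emits Bernoulli spikes bin-by-bin from the same clipped
linear intensity and the same Laguerre kernel expansion the estimator
assumes, making parameter recovery well-posed: the model family and
generative family coincide, and an OLS refit with the true design
recovers the planted coefficients (tested). Defaults: baselines uniform
in 0.02–0.10 per 10 ms bin (2–10 Hz, typical of entorhinal-hippocampal
units), excitatory edge kernels with dominant first-order coefficient
uniform in [0.5, 1]·kernel_scale (kernel_scale 0.1 roughly doubles the
target's rate after a presynaptic spike), optional inhibitory fraction.
What it does *not* emulate: refractoriness, bursting, oscillatory
common drive, nonstationary rates, and spike-sorting errors — passing
recovery tests therefore demonstrates estimator correctness under the
model's own assumptions, not robustness to real-data violations of
them.

## Problem sizes and determinism

Test-suite and acceptance runs use deliberately moderate sizes chosen
as the smallest that make the statistical claims stable: 10-neuron
ground truths at 10⁴ bins for GLM recovery, 500-neuron spatial networks
with 30 electrode placements for the overestimation experiment, 20
seeds for density calibration, 8–20 random-reference replicates inside
ω. Every stochastic routine takes an explicit seed and is bit-exact
reproducible given one; the GA evaluates candidates under common random
numbers so its objective surface is deterministic per seed.

## Known limitations

The Gaussian/identity GLM treats binary bins as continuous; a logistic
link would be the natural refinement and negative predicted intensities
must be clipped for validation. The ω reference uses sampled ER graphs,
so ω carries O(1/√reps) estimation noise. The reference error curve was
fitted at one edge-density regime; corrections for networks far from
~8% density should refit the curve via `simulate_error_curve`.
Corrections for negative sampled ω are extrapolations. The parametric
forms of the two distance-decay models are representative members of
their qualitative families, not uniquely determined laws.
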