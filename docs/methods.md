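# Methods

## Generative model

Neurons follow a grid-discretized leaky integrate-and-fire model. Time
advances in bins of `dt_ms` (default 1 ms); the membrane potential of
neuron *i* at bin *t* is

    h_i(t) = h0 + Σ_j g_ij K_j(t) + drive_i(t) + v_i(t),

where each pre-synaptic spike of neuron *j* contributes
`g_ij · exp(-(t - t_f - d_ij)/τ_m)` after its per-edge propagation
delay `d_ij` (rounded **up** to whole bins, minimum one bin, so grid
semantics are exact), `drive` is an optional background Poisson input
filtered through the same membrane kernel, and `v` is additive noise
(white Gaussian by default; a moving-average colored option with window
`Δ_v` exists for experiments on vanishing correlation). A deterministic
neuron fires when `h ≥ θ`; a stochastic neuron fires with probability
`σ(β(h − θ))`. After an own spike the membrane resets: all kernel and
drive accumulation clears, and in-transit arrivals emitted at or before
the spike bin are dropped, so only pre-synaptic spikes emitted
*strictly after* the neuron's last own spike contribute. This strict
semantics is what makes the generative-consistency oracle exact: for
noiseless deterministic dynamics, the constraint system built from the
true kernel (same delays, same reset rule) is feasible row by row,
which the test suite verifies to a 1e-9 float tolerance.

Defaults: `h0 = 0`, `θ = 20 mV`, `τ_m = 20 ms`. A spike occupies one
bin; spikes are reported at the bin's left edge.

### Network generator

`generate_network` draws a directed Erdős–Rényi graph (each ordered
pair connected with probability `p_conn`), assigns
`round(frac_exc · n)` excitatory neurons (default 80/20), sets
excitatory edges to +1 mV and inhibitory edges to −δ mV with
δ = n_exc_edges / n_inh_edges computed from the *realized* edge counts,
and draws delays uniformly on (0, d_max]. Dale's principle holds by
construction (edge sign is a property of the pre-synaptic neuron). The
total weight is zero by construction; in float64 the computed sum lands
at ~1e-15 · n_edges rather than exactly 0, and tests assert
|Σw| ≤ 1e-9.

### Background drive

An isolated noiseless network is silent, so sustained activity comes
from a per-neuron independent Poisson drive. The reference conditions
use 1600 events/s of +0.5 mV, chosen by shot-noise arithmetic
(stationary mean λ·w/(1−ρ) ≈ 16.4 mV, std ≈ 1.8 mV against the 20 mV
threshold) to put single-neuron rates near 5 Hz; realized network rates
are 4–8 Hz. The drive can be mean-centered (`center_drive`) when a
strictly zero-mean disturbance is wanted; the reference conditions
leave it uncentered and let the inference-side intercept absorb the
mean. The drive is deliberately *unobserved* by the inference stage —
it plays the role of hidden traffic plus intrinsic noise.

### What the generator does not emulate

Real recordings have refractory dynamics beyond reset, adaptive
thresholds, conduction-speed heterogeneity, non-exponential synapses,
spike-sorting errors and nonstationary rates. Passing tests on this
generator show that the estimator recovers connection types when the
generative assumptions hold approximately; they do not certify
performance on physiological data.

## Constraint system

For one target neuron, labels are `ŷ_t = +1` in firing bins and −1
elsewhere. The inference kernel K′ filters every *other* neuron's spike
train with a decaying exponential of time constant `τ′ = 20 ms` —
either the sum over all past spikes (default) or only the most recent
spike (`mode="last"`). No delays are modeled at inference time. Bins
are half-open and 0-based; a spike influences K′ strictly after its own
bin. With `reset_on_post` (default on, mirroring the generative reset)
pre-spikes emitted at or before the target's most recent spike are
excluded. Rows stream in M contiguous blocks with O(n) carried state,
and the concatenation of streamed blocks is bit-identical to the
one-shot construction (asserted in tests), so results are independent
of M at the data level.

Decorrelated row subsampling keeps every Δ-th row and, optionally, all
firing rows (`keep_spike_rows`). The default `KernelConfig` keeps every
row (Δ = 1); the reference experiment opts into Δ = 20 bins (one kernel
time constant) with spike rows retained. This serves two purposes:
neighboring rows are strongly correlated (the decorrelation argument),
and quiet bins outnumber firing bins by ~200:1 at 5 Hz — without
rebalancing, the regularized hinge problem is dominated by the majority
class (see "Operating point" below).

## Solvers

**Primal (`neuinf`).** Rows are visited in a seeded random permutation;
a violated row updates `w += γ · L(A_t w) · A_t` — the update is scaled
by the loss *value* as formulated, with a `subgradient` switch for the
classical constant-step variant — followed by elementwise
soft-thresholding `F(x, η)` after every update (iterative shrinkage).
Defaults `γ = 0.05`, `η = 0.01`. Non-finite weights raise with advice
to reduce γ.

**Dual (`dual`).** Stochastic dual coordinate ascent on
`E(λ) = −c‖Aᵀλ‖² + Σλ`, box `[0,1]^T`. Each visited coordinate is moved
to its exact interval-clipped maximizer (no learning rate), `u = Aᵀλ`
is maintained incrementally, and the objective is non-decreasing across
every step (asserted). Zero-norm rows take λ = 1 (the objective is
linear there) without touching `u`. The returned estimate is
`w* = Aᵀλ*` soft-thresholded at η. A relative-improvement tolerance
(`tol`) can stop sweeps early; the default is a fixed number of epochs.

**Intercept.** The formulation normalizes `h0 = 0, θ = 0`; data
generated at θ = 20 mV cannot satisfy that normalization without a bias
term, and without one every weight shifts negative (the solver buys the
quiet-bin margins with the neuron columns) and sign identification
fails. All solvers therefore append a constant column (`fit_intercept`,
default on) scaled by `intercept_scale = 5` — the scaling weakens the
bias's share of the ℓ2 penalty so the threshold is absorbed cheaply —
and the bias is exempt from soft-thresholding. The reported weight
vector excludes the bias, which is exposed as `estimate.intercept`.

**Block-parallel variants.** The parallel dual performs, per outer
round, one local sweep per block on copies of (λ_b, u) and merges with
conservative 1/M scaling; M = 1 reduces bit-exactly to the sequential
algorithm. The parallel primal shards each block's permuted rows across
workers, each shard starting from the block-entry weights, and merges
per-shard deltas by averaging; workers = 1 reduces bit-exactly to the
sequential pass. The conservative 1/M merge is provably safe but slow
to converge at large T; the streaming-equivalence checks therefore use
the sequential blockwise solver run to convergence, where the optimum
is unique and independent of the blocking.

**Operating point and converged degeneracy.** At full convergence on
the reference data the dual optimum has `Aᵀλ* ≈ 0` for every
regularization level tried (c from 1 down to 0.001): spikes are not
perfectly predictable from the visible inputs (the drive is hidden), so
the exact regularized-hinge solution prefers a bias-only explanation,
and the informative weight estimate lives on the optimization *path*.
The pipeline therefore operates at a fixed small epoch count (5 sweeps,
matching the algorithm's max-iteration formulation), where the iterate
behaves like an averaged perceptron/correlation statistic and sign
recovery is empirically stable across 2–30 epochs. A consequence is
that at the finite-epoch operating point different row-visit orders
(e.g. different block counts) can flip one or two borderline void
labels; at convergence the solution is unique and blocking-independent.

**Aggregation.** The multi-run protocol fits five times with different
soft-threshold levels and seeds and averages the weight vectors
entrywise before any ternarization. The grid is *relative* —
{0, 0.01, 0.02, 0.05, 0.1} × max|w| of each run — so the sparsity
levels stay meaningful regardless of the solver's scale.

## Evaluation

Per-type weight means/variances partition candidates by the true type.
ROC curves standardize the incoming-weight vector to zero mean and unit
variance, then sweep an upper threshold for excitatory detection and a
lower threshold for inhibitory detection; AUC is verified against a
brute-force pairwise (Mann–Whitney) computation in tests. Ternarization
is a deterministic 1-D K-means (k = 3) with centroids initialized at
(min, 0, max), Lloyd iterations, ties to the lower-indexed sorted
center, and two guards: fewer than three distinct values → all void,
and values below 1e-12 × max(max|w|, 1) are snapped to exact zero so a
cluster boundary can never fall inside float-noise residuals. Neuron
typing counts outgoing-weight peaks beyond ±2σ of each column and
declares a type when one count exceeds twice the other; both thresholds
are configurable since only the counting rule itself is prescribed.

The spectral diagnostics report (never enforce) the sign-recovery
conditions: invertibility of KᵀK and (K′)ᵀK′, the minimum eigenvalue of
the symmetric part of KᵀK′, the minimum per-neuron rate in spikes/bin,
and the maximum of `log f_s(x) + L(x)` on a margin grid (the
loss-equivalence condition; the standard hinge violates it near x = 0,
which the diagnostic makes visible).

## Reference experiment sizes

The benchmark study uses n = 50 neurons, p_conn = 0.2, d_max = 2 ms,
recordings of 60–600 s at 1 ms resolution, three seeds, and the Δ = 20
rebalanced kernel with the five-run aggregated parallel-dual solver.
These sizes keep a full test run in minutes while leaving all measured
effects far from their noise floors (sign-match rates, AUCs and type
ordering are stable across seeds). The hidden-neuron sweep hides 20% of
the neurons five times per seed and scores precision/recall of
excitatory+inhibitory detection on the visible subgraph.

## Known limitations

- At this scale the hidden-neuron experiment does **not** reproduce the
  qualitative claim that precision suffers less than recall: recall
  stays at ceiling (true edges are strong, +1/−δ mV on ~10 inputs) and
  the dominant error mode is common-input confounding, which creates
  false positives and lowers precision (~3% relative at 20% hidden,
  600 s). The direction reverses only in noisier regimes, and there it
  is seed-dependent. The corresponding acceptance test asserts the
  original claim and fails honestly; the mechanism is scale-dependent
  (many weak inputs vs. few strong ones), not a solver defect.
- Exact weight magnitudes are not recovered and are not a goal; only
  signs and types are meaningful.
- The converged dual is degenerate on this data (see above); results
  depend on the documented operating point.
- Formats are plain text; the binary containers of public spike
  datasets are out of scope (a generic two-column exporter suffices to
  convert them).
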