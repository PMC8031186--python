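# Methods

This note documents the models, estimators, parameter choices and known
limitations of `spikeconn`, in the order the pipeline applies them.

## Data model

Spike data are per-neuron event times in milliseconds, converted to a
binary raster at 1 ms bins (half-open bins [t, t+1), multiple spikes per
bin collapse to 1). Neurons below 0.2 Hz are removed before any estimation
(strict `<`; the boundary rate survives) — sub-0.2 Hz units are typically
sorting noise and their TE estimates are dominated by plug-in bias.
Duration, when not given, is the maximum spike time rounded up to the next
whole millisecond so that every event lies strictly inside the recording.

## Delayed transfer entropy

For an ordered pair J → I and delay d (bins), the estimator is the plug-in
evaluation of first-order transfer entropy on the binary triple
(i_t, i_{t−1}, j_{t−d}): one past bin of the target, one delayed bin of the
source. Conventions, all fixed here and surfaced as function arguments:

- logarithm base 2 (bits) throughout;
- sums run over t = max(1, d) … n_bins − 1 so all three indices exist
  (no padding);
- cells with zero joint count contribute 0;
- the delay grid is d = 0 … 30 ms (synchronous coupling d = 0 is an
  admissible peak), τ = 4 ms;
- Sharpness = Σ_{d=0}^{min(peak+τ, 30)} TE(d) / Σ_{d=0}^{30} TE(d), with
  value 0 for an identically zero curve. A `peak_centered` mode
  (max(peak−τ,0) … peak+τ) is available for compatibility with the older
  coincidence-index convention; the from-zero window is the default.
- TE_nor = TE_peak / |p log₂ p + (1−p) log₂(1−p)| with p the **target**
  neuron's per-bin spike probability, clipped to [1/n_bins, 1 − 1/n_bins].
  The absolute value makes larger mean stronger (the raw binary entropy
  expression is negative).

The all-pairs path counts joint events with sparse spike-event matrix
products, which scales with the number of spikes rather than the raster
area and is exactly equal (bitwise) to the per-pair path; both are checked
against a loop-based histogram oracle in the tests.

SLTE weighs each local term by (−1)^(i_t − j_{t−d}) (+1 when source and
target events agree, −1 otherwise), so excitatory coupling accumulates
positive and inhibitory coupling negative sums. The *E-I bias* of a pair
is SLTE at the TE-peak delay.

## E/I classification

Per presynaptic neuron, candidate outputs (all ordered pairs with positive
strength) are ranked by TE_nor descending; the lowest 10% of the ranking
is discarded (floor(0.9 n) retained, minimum 1 — the rounding is a
convention of this implementation) and the E-I biases of the rest are
summed. The feature pair (ΣSLTE, log₁₀ firing rate) is z-scored per axis —
so any monotone affine rescaling of either axis is immaterial — and cut
into two Ward clusters; the cluster with the larger mean ΣSLTE is labeled
E. Neurons with no candidate outputs are reported `unlabeled` rather than
guessed. Classification runs **before** connection selection because the
surrogate null must be built separately per connection category.

## Connection selection

Surrogates relocate every presynaptic spike independently and uniformly
into a currently-silent bin within ±10 bins (own bin excluded; a spike
with no silent target stays put, which preserves spike counts exactly).
Each of the `n_surrogates` (default 100) surrogates jitters all neurons as
sources while targets keep the original trains.

Real and surrogate (Strength, Sharpness) points are pooled to set axis
bounds (log₁₀ for Strength, whose distribution is log-normal; linear for
Sharpness; 1% padding), divided 25×25, and each pixel receives
RT = N_jitt / (N_real + N_jitt) with **raw** counts — a pixel is accepting
only where surrogate samples are rare in absolute terms, which with ≥20
surrogates makes acceptance strict. Empty pixels reject. Pairs with
RT ≤ 0.34 are accepted; selection is run independently for the EE, EI, IE
and II categories, and accepted edges carry the bias-adjusted strength
TE_peak(real) − mean TE_peak(surrogates) and the presynaptic sign.

## Topology

- **k-core**: iterative peeling on the undirected simple projection using
  total degree (configurable to in/out degree on the directed graph);
  survivors of the deepest peel share its core level. Cross-checked
  against an independent core-number computation.
- **Log-normality**: Anderson–Darling normality test (estimated-parameter
  case) on log-transformed values, with fitted log-space μ, σ.
- **Triad motifs**: every connected 3-node induced subgraph is classified
  into the standard 13-class directed-triad taxonomy. Class ids are
  assigned by first appearance in a fixed enumeration of the 64 labeled
  patterns; `triad_class_table()` prints the adjacency pattern, edge count
  and reciprocal-dyad count behind every id, so references to "clustered"
  high classes are unambiguous. Expected counts come from the empirical
  dyad probabilities (null / asymmetric / reciprocal) under independent
  dyads, by exact enumeration of the 64 labeled patterns; the
  observed/expected ratio is reported without asserting a significance
  test, since the comparison is descriptive.
- **Group comparison**: Wilcoxon signed-rank on paired per-dataset E and I
  summaries (`zsplit` zero handling; all-tied input returns p = 1).

## Controllability

MFVS is solved exactly with the ordering ILP (binary removal indicator
x_v, integer level l_v ∈ [1, n], l_v ≥ l_u + 1 − n(x_u + x_v) per edge,
minimize Σ x_v) using the HiGHS mixed-integer solver. Self-loop nodes are
forced into the set before solving. A timeout raises an explicit error —
no heuristic fallback. Node classes need up to two re-solves per node:
critical ⇔ forcing x_v = 0 raises the optimum (or is infeasible); member
of some MFVS ⇔ forcing x_v = 1 keeps it. The critical/intermittent/
redundant decomposition is invariant to which particular optimum the
solver reports. Ratios are |FVS ∩ E|/|E| and |FVS ∩ I|/|I|; the k-core
overlap pair is (|FVS ∩ KCmax|/|FVS|, |FVS ∩ KCmax|/|KCmax|).

## Layer boundaries

The layer module consumes an already-extracted 1-D density profile
(normalized depth, pial surface = 0); image processing is out of scope.
After moving-average smoothing (default window 5% of the profile length)
the three most prominence-ranked maxima and the minimum between each
consecutive pair are located, each refined by a local least-squares
parabola — the refinement stabilizes the shallow dips under noise without
moving exact symmetric extrema. Rules: L1/L2-3 at one third of the way
from the surface to the first maximum ("1/3 from the surface" is read as a
fraction of the surface-to-first-convex-point distance); L2-3/L4 at the
first minimum; L4/L5 and L5/L6 at the midpoints (second maximum, second
minimum) and (second minimum, third maximum). Fewer than three maxima is
an explicit failure. Depth labels use half-open intervals.

## Synthetic generator

The generator is the validation substrate, so its defaults are fixed study
conditions, not tuning knobs:

- Populations ~80% regular-spiking excitatory / ~20% fast-spiking
  inhibitory, with the canonical two-variable quadratic
  integrate-and-fire parameters (exc: a=0.02, b=0.2, c=−65+15r²,
  d=8−6r²; inh: a=0.02+0.08r, b=0.25−0.05r, c=−65, d=2; r uniform per
  neuron), 1 ms Euler steps with two 0.5 ms substeps for v.
- Sparse Erdős–Rényi connectivity (default p = 0.1), no self-loops,
  integer conduction delays uniform on 1–10 ms, current-based synapses
  with log-normal weights (median 5 mV excitatory, −20 mV inhibitory,
  log-sd 0.5) obeying Dale's principle.
- Independent Gaussian "thalamic" drive per neuron per step, sd 5.0 mV
  (exc) / 5.5 mV (inh). These were calibrated once so the population sits
  in the realistic cortical regime — excitatory ~6 Hz, inhibitory ~18 Hz,
  log-normal-like rate spread, every neuron above the 0.2 Hz floor — and
  then frozen.

What the generator does *not* emulate: conductance-based synapses,
synaptic depression/facilitation, bursty population events, distance-
dependent connectivity, electrode subsampling, or spike-sorting errors.
Passing recovery tests on this model therefore demonstrates correctness of
the estimation chain under known ground truth, not performance bounds on
real MEA recordings. Inhibitory STDP variants of the validation model are
not implemented; the plain current-based model was sufficient to exercise
every pipeline stage.

## Problem sizes

The validation protocol uses 80E/20I networks recorded 60 simulated
minutes, five seeds, the package's standard scale for classifier scoring.
Connection-selection calibration (null false-positive rate, ground-truth
recovery) runs 40E/10I networks for 20 minutes with 20 surrogates, and
integration/determinism checks use 16E/4I for 2 minutes — sizes chosen so
the whole suite completes on a laptop while keeping every estimate in its
asymptotic regime (≥10⁶ bins per run). The surrogate default of 100
remains the production setting; reductions are always explicit arguments.

## Known limitations

- First-order TE only (one past bin each side); higher-order embeddings
  are out of scope.
- The plug-in TE estimator is biased upward for short recordings; the
  pipeline relies on the surrogate comparison, not analytic bias
  correction, and recordings well under ~10 minutes will inflate both
  real and surrogate strengths.
- The RT map uses raw surrogate counts; with very large surrogate
  ensembles acceptance becomes increasingly conservative. Comparisons
  across different `n_surrogates` should hold it fixed.
- HiGHS MFVS solves are exact but worst-case exponential; networks with
  thousands of nodes and dense recurrent cores may need generous time
  limits, and per-node classification multiplies that cost by 2n.
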