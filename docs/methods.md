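# Methods

`gclnet` models how the synaptic connectivity of the cerebellar input layer
(granule cell layer, GCL) sets the trade-off between transmitting
information and sparsifying it. It contains three linked model families: an
anatomically constrained generator of the local mossy-fiber (MF) rosette to
granule cell (GC) circuit, a noise-free uniform binary network (UBN) whose
GC-population entropy can be measured over event ensembles, and a
conductance-based integrate-and-fire network whose output is decoded with a
k-means classifier to estimate mutual information (MI).

## Anatomical network generator

GCs are placed uniformly at random inside a sphere of radius 40 um at
density 1.9e6 mm^-3; MF rosettes fill a larger sphere (default margin 20 um)
at 6.6e5 mm^-3, so that GCs near the edge of the central field still have
complete rosette neighborhoods. Counts are Poisson draws around density x
volume (expectations: 509 GCs, ~177 rosettes in the central field); a
fixed-count mode pins the counts, and explicit pinning
(`pinned_gc_count` / `pinned_rosette_count`) reproduces a specific
instantiation such as the 509/176 local circuit used by the spiking model.

Each GC is wired to `d` distinct rosettes within 30 um (dendrites longer
than that are anatomically rare). Candidates are drawn without replacement
with weight `exp(-(len - 15)^2 / (2 sigma^2))`. Because the number of
candidate rosettes grows with the square of distance, the selection width
matters: sigma = 5 um would put roughly 40% of dendrites beyond 20 um,
contradicting the observation that they rarely exceed 20 um. The default is
sigma = 2 um, which yields a length mode near 15-16 um with ~2% of dendrites
above 20 um; sigma is a configuration knob. A GC with fewer than `d`
reachable rosettes is resampled to a fresh position up to 50 times before
the generator raises (`unwireable cell`).

Connectivity statistics count rosettes in the *central* field (inside the GC
sphere) for the expansion ratio and the mean-GCs-per-rosette figure, which
is how the local circuit is characterized anatomically (~2.9 GCs per
rosette; ~12 distinct GCs per rosette at d = 4); the dendrites-per-rosette
histogram covers every rosette in the model, so its mass equals the total
edge count `n_gc * d` exactly.

## Uniform binary network

The UBN is a random bipartite graph: `n_gc` binary threshold units, each
connected to `d` MF inputs drawn uniformly without replacement,
independently across GCs (defaults 176 MFs, 509 GCs, matching the local
circuit). A GC outputs 1 when at least `phi` of its inputs are active. The
activation probability has the closed form `P(Binom(d, p_MF) >= phi)`.

Threshold policies:

* **absolute** — a fixed integer.
* **fixed relative** — `phi = ceil(0.75 d)`, the regime where ~3 of 4 inputs
  are needed, as set physiologically by tonic inhibition.
* **NADT** (network-activity-dependent threshold) — mimics Golgi-cell
  inhibition: `phi(p) = clamp(ceil(d * min(NADT * p, 1)), 1, d)`, a
  right-continuous piecewise-constant ramp rising from 1 to `d` over the
  first `1/NADT` of the activity range (NADT = 2 reaches `d` at p = 0.5).
* **HIT + NADT** — high initial threshold `phi0 = ceil(0.75 d)` with the
  same ceil-discretized ramp running from `phi0` to `d`:
  `phi(p) = ceil(phi0 + (d - phi0) * min(NADT * p, 1))`. The exact
  discretization of both ramps is a package choice; only the endpoints are
  empirically constrained.

## Entropy of the GC population

The UBN is noise-free, so the information between events and GC states is
the entropy of the GC pattern distribution, `H = -sum_k p(k) log2 p(k)`.
Two estimators are implemented:

* **Exact enumeration** (n_mf <= 20): all `2^n_mf` inputs are enumerated
  with Bernoulli(p) weights and the induced GC-pattern distribution summed
  exactly. This is the infinite-event limit.
* **Monte-Carlo event sampling**: `N` input patterns are drawn at
  Bernoulli(p). By default events are *distinct* (sensory-motor events are
  non-repeating), so the event information is exactly `log2 N` and any
  entropy deficit is information lost in the GC map. Duplicate draws are
  rejected; if fewer than `N` distinct patterns can be collected within a
  30N-draw budget (near p = 0 or 1 the achievable support is small), the
  achievable set is used, which is what truncates the entropy curve at the
  ends of the activity range. Estimates are reported as mean +/- sd over
  repetitions, each with a fresh random graph instantiation. The plug-in
  estimator carries a small downward bias at finite N; an optional
  Miller-Madow correction `(G-1)/(2 N ln 2)` is available and is used when
  comparing Monte-Carlo estimates against exact enumeration.

Desk-scale analyses use `N = 2^14` events (the reference analysis used 1e9
events with an N-independent analytic method not reproduced here; with
sampling, cost grows with N, and 2^14 preserves every qualitative
comparison). The evaluation grid is 101 equally spaced p values by default;
sweeps in the tests use 51 or 21 points.

A **lossless region** is a maximal run of grid points where entropy >= 0.99
x log2 N. The **sparse encodable range** additionally requires
p(GC) < p(MF), evaluated on the exact binomial-tail p(GC) (noise-free, so
an identity relay yields an exactly empty range). **Output sparseness** is
`1 - Avg[p(GC)]` over the whole activity range; the average is computed by
per-segment Gauss-Legendre quadrature of the analytic p(GC), which is exact
for the polynomial binomial tails. This matters because different
connectivities can tie exactly (at the 0.75 relative threshold the average
p(GC) is `(d - phi + 1)/(d + 1)`, identical for d = 3, 7, 11, ...): a
grid-mean average breaks such ties by discretization noise and can park a
strictly-worse configuration on the Pareto front. Pareto dominance likewise
treats sub-1e-9 differences as ties. At p = 0 and p = 1 a
single input pattern exists and entropy is zero for *any* network, so
coverage statistics (e.g. for the unity-NADT policy) consider only
non-degenerate grid points.

A caveat on averaged sparseness: for the fixed relative threshold the grid
average of p(GC) is analytically `(d - phi + 1)/(d + 1)`, so d = 2
(phi = 2, an AND gate) is on average *sparser* than d = 4 (phi = 3):
averaged sparseness is not monotone in d across d = 2..4, even though at
low-to-intermediate activity sparseness does grow with d and the lossless
range shrinks monotonically. The Pareto analysis (maximize sparse-range
measure and averaged sparseness jointly) is unaffected: the non-dominated
set sits at low connectivity (d = 2-3 for the fixed threshold).

## Stimulus patterns and spike trains

Binary stimulus patterns activate an exact count `round(p * n_mf)` of MFs,
drawn uniformly and pairwise distinct (the UBN instead uses iid Bernoulli
weighting; both conventions are documented and selectable by using the
respective module). Spatially correlated patterns activate clusters: an
inactive seed rosette plus its 4 nearest neighbors (3D Euclidean distance),
repeated until the target count is reached, so the active count is within
one group of the target. Active MFs fire homogeneous Poisson trains at
80 Hz, inactive at 10 Hz, independently across fibers.

## Spiking granule cell model

Each GC is a single-compartment conductance-based integrate-and-fire
neuron: C = 3.22 pF, R_in = 0.94 GOhm, V_rest = -79.9 mV, tonic GABA_A
conductance 438 pS reversing at -79.1 mV (all measured values). Spike
threshold (-40 mV), reset (to rest) and refractory period (2 ms) are not
experimentally pinned and are package defaults.

Each presynaptic spike triggers three biexponential conductances (peak
normalized): a fast direct AMPAR component (rise 0.17 ms, decay 1.5 ms), a
slow spillover AMPAR component (0.5 / 8 ms) and an NMDAR component
(1 / 50 ms) gated by a single-Boltzmann Mg block
`1/(1 + [Mg]/3.57 exp(-0.062 V))` at 1 mM Mg (block < 0.05 at -70 mV).
Short-term plasticity follows the standard utilization/recovery update,
depression-dominated at the MF-GC synapse (AMPAR U = 0.45, tau_rec = 50 ms;
NMDAR U = 0.25, tau_rec = 50 ms); amplitudes are normalized so an isolated
spike has amplitude 1. The published fits for these kinetics are not
available, so the values are literature-plausible defaults exposed in the
configuration; reproducing specific conductance-train fits is out of scope.

Peak amplitudes are set by a seeded calibration routine
(`calibrate_excitation`): the common scale on AMPAR+NMDAR peaks is bisected
until the probability of firing within a 30-ms window crosses one half at
3 of 4 active 80-Hz inputs. With the shipped defaults the firing
probability for 1/2/3/4 active inputs is approximately 0.1/0.3/0.5/0.9 —
i.e. three or more rate-coded inputs are typically required, the measured
GC regime. For networks with `d` inputs per GC, all synaptic peaks are
scaled by `4/d`, conserving the total excitatory conductance (verified to
<1% on fixed trains).

Network-activity-dependent inhibition scales the tonic conductance linearly,
`g_tonic * (1 + NADT * p_MF)`; the linear form is a package choice (only
"scaled as a function of p(MF) from the tonic level" is constrained).

Integration is exponential Euler at dt = 0.025 ms (halving dt changes spike
counts by at most one spike per cell on 60-ms inputs). The inner loop is
numba-JIT-compiled with a semantically identical vectorized numpy fallback;
the two engines are cross-checked in the tests. Each pattern is simulated
for 60 ms and decoded over the final 30 ms (the GC synaptic integration
time), discarding the onset transient.

## Decoder and information estimate

Spike-count vectors from `trials_train = 10` independent realizations per
pattern are clustered with k-means (k = N patterns, scikit-learn, 10
restarts, seeded); `trials_test = 10` fresh realizations are assigned to
the nearest centroid (ties to the lowest index). MI between pattern labels
and assigned classes is the plug-in MI of the N x N confusion matrix under
a flat prior (maximum log2 N bits). Undersampling bias is corrected by
subtracting the mean MI of 20 label-shuffled surrogates (default); a
first-order Panzeri-Treves analytic correction is available, valid when
trials per pattern are large relative to the class count.

Population sparseness is the Treves-Rolls measure
`S = (C - (sum r)^2 / sum r^2) / (C - 1)`; an all-silent vector is defined
as S = 1 (the limit of one vanishing active cell).

## Problem sizes

Reduced-scale runs used throughout the examples and tests: UBN sweeps at
N = 2^14 events, 2-5 repetitions, 21- or 51-point grids; the spiking
pipeline at N = 64 patterns, 176 MFs / 509 GCs, d in {4, 16}, 10 train + 10
test trials per pattern on a 4-5 point activity grid. These sizes preserve
every qualitative comparison made at full scale (the full-scale spiking
study used 1,024 patterns and is far beyond a single workstation).

## What the synthetic data does and does not capture

All inputs are generated: the stimulus generator emulates the two-level
rate coding of sustained MF activity (80/10 Hz) and optional spatial
correlation in groups of five neighbors. It does not model bursting or
temporally patterned MF input, multi-rosette MF axons (each rosette is an
independent input), Golgi-cell spiking (inhibition is tonic plus an
activity-scaled term), unipolar brush cells, or synaptic stochasticity
(release fluctuations average over multiple sites). Passing tests therefore
demonstrate the connectivity-dependent transmission/sparsification
trade-off under these idealizations, not a full account of in-vivo GCL
dynamics.

## Known limitations

* The instantiation-averaged entropy is estimated by sampling rather than a
  closed form, so event counts far beyond ~2^20 are impractical here.
* The plug-in MI at 64 classes x 10 trials is deeply undersampled; the
  shuffle correction removes the bulk of the bias but corrected values near
  zero remain noisy at the +/-0.05-bit level.
* LIF threshold/reset and STP parameters are plausible defaults, not fits;
  absolute firing rates should not be over-interpreted, only comparisons
  across connectivities and inhibition settings.
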