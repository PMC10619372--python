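# Methods

This note documents the models, estimators, statistical machinery and
design choices behind `docm`, in the order the pipeline applies them, along
with the numerical conventions and known limitations a user should be aware
of before interpreting results.

## The multiplex coupling model

Band-limited neurophysiological signals interact in two ways the package
quantifies: within-frequency phase coupling and phase-to-amplitude
cross-frequency coupling (PAC). Eight canonical bands are analysed
(δ 1–4, θ 4–8, α1 8–10, α2 10–13, β1 13–20, β2 20–30, γ1 30–45,
γ2 55–90 Hz; the δ lower edge is configurable down to 0.5 Hz, the default
matches a 1-Hz acquisition high-pass). This gives 8 within-frequency modes
plus C(8,2) = 28 ordered cross-frequency modes — 36 candidate coupling
modes per region pair per time window, labelled 1–36 with 0 meaning "no
significant coupling". Cross modes are enumerated lexicographically with
the low band major (9 = δ–θ, …, 36 = γ1–γ2).

**Estimators.** Within-frequency coupling is the imaginary phase-locking
value, `iPLV = |Im mean_t exp(i(φx − φy))|`, with φ the analytic-signal
phase of the band-passed series. Taking the imaginary part discards
zero-lag locking, the signature of instantaneous field spread. PAC uses an
envelope-phase-locking construction: the high-band Hilbert envelope of the
target is band-passed at the modulating band and the iPLV between the
driver's low-band phase and the envelope's low-band phase is taken. PAC is
directed (phase-of-i onto amplitude-of-j); both directions are estimated.

**Filtering.** Third-order Butterworth band-pass applied forward–backward
(zero phase, effectively sixth-order magnitude). Signals are filtered and
Hilbert-transformed once on the full recording and windowed afterwards, so
1-s windows carry no per-window filter edge artifacts.

**Windows.** Default 1-s width sliding in 100-ms steps; a 300-s recording
yields 2991 windows, 60 s yields 591. When the width is a multiple of the
step the windowed all-pairs estimator reduces to per-step chunk sums and a
sliding aggregation, which is what makes cohort-scale runs tractable on one
CPU.

## Statistical filtering and the dominant mode

Each (window, directed pair, mode) value is referenced to a surrogate null
built by cutting a series at one random point and exchanging the two
segments. A single cut is exactly a circular shift, so surrogates preserve
the amplitude distribution, spectrum and autocorrelation of the original.
For within-frequency modes one of the phase series is shifted; for PAC the
amplitude-derived envelope series is shifted.

**Pooled null.** At cohort scale the engine draws `n_shifts` (default 4)
whole-series circular shifts per (pair, mode) and pools the windowed
surrogate values across windows, giving `n_shifts × n_windows` null samples
(≈2400 at 60 s) per comparison at a small constant factor over the observed
computation. Pooling across windows is exact for stationary signals and a
good approximation for the generator's piecewise-stationary output; a
literal per-window surrogate path (`surrogate_swap`, `surrogate_pvalue`)
is exposed for small problems and for calibration studies. One-sided
p-values use the positively biased estimator `(1 + #{s ≥ obs})/(1 + n)` so
p is never 0.

**Selection.** Per (window, directed pair), modes with `p < α/36`
(Bonferroni over the mode family; desk default α = 0.05) survive; among
survivors the highest coupling strength wins (ties: lowest p, then lowest
mode index); no survivor means label 0. The two orientations of a pair are
reconciled by lowest p (tie: highest strength), making the integrated graph
undirected. Finally Benjamini–Hochberg FDR (q = 0.01) is applied per
window across the network's dominant-mode p-values, and failing edges are
reset to 0. The result is the integrated dynamic graph: one strength and
one label per pair per window.

**Calibration caveats.** Two interacting desk-scale effects deserve
explicit mention. First, the smallest attainable p equals `1/(n_null + 1)`;
α and the null depth must be chosen jointly so that `α/36` exceeds that
floor (with 10⁴ surrogates and the published α = 0.001, the floor ~1e-4
does *not* resolve 0.001/36 ≈ 2.8e-5 — the package exposes both knobs
rather than hiding the tension). Second, BH-FDR here runs on p-values that
are already minimised over 72 directed mode tests; on pure-noise input
this behaves like a branching process with offspring number ≈ 72q. At
q = 0.01 the factor is 0.72 — subcritical but close to 1 — so permissive
configurations (α = 0.05) label a few percent of pure-noise edge-windows,
while at α = 0.001 the Bonferroni floor binds and pure noise yields
(essentially) no labels. On data with genuine couplings the true edges
anchor the BH threshold and planted modes are recovered cleanly; the
false-label rate on undriven pairs in mixed networks is a few percent.
`null_calibration_pvalues` reproduces the underlying per-test calibration:
on independent 8-s signals the false-positive rate at α matches α and the
realised false-discovery proportion of BH on those p-values stays at q.

**Detectability physics.** Whether a planted coupling can beat its own
surrogate null *within a single window* is governed by the effective
phase-estimation degrees of freedom the modulating band offers per window
(roughly bandwidth × width). Narrow low-frequency bands (δ–α2, 2–4 Hz
wide) yield nulls whose extreme tail overlaps even perfect coupling at 1-s
windows, and a PAC modulation survives band-pass filtering only when the
modulated band is wider than twice the modulating frequency. Per-window
recovery of planted modes is therefore demonstrated on cleanly constructed
driven pairs (weak 1/f background), while full eight-band mixtures recover
wide-band modes (β2/γ intra, β→γ2 PAC) at 75–98% of windows and narrowband
modes only partially. This is a property of windowed phase statistics, not
of the implementation.

## Chronnectomic descriptors

The **comodulogram** of an edge is the 8×8 probability table of its
dominant modes over time (diagonal: within-frequency; off-diagonal (lo,hi):
cross-frequency), normalised over the windows with a nonzero label so the
table sums to 1 whenever the edge was ever coupled. The **flexibility
index** of an edge is the fraction of consecutive-window transitions at
which its label changes, `FI = (1/(T−1)) Σ 1[label_t ≠ label_{t+1}]`; the
global FI averages the upper triangle. (The prefactor is written with
T−1, and the δ-symbol of the defining sum is read as a change indicator —
an inequality — which is the only reading that keeps FI in [0, 1] and
matches its verbal definition.) Window-geometry optimisation scores each
(width, step) grid point by the Pearson correlation of pooled pairwise FI
between two sessions across subjects, with ICC(2,1) reported alongside.

## The synthetic cohort

No public source-space MEG accompanies the framework, so all claims are
exercised on generated data with known ground truth.

* **Oscillations** are band-passed Gaussian noise, unit variance — phases
  are non-degenerate and surrogate nulls realistic. Each ROI carries all
  eight bands plus 1/f-shaped background noise (default level 1.0, giving
  in-band SNR ≳3 everywhere).
* **Phase coupling** is planted by mixing an exactly lagged analytic-signal
  copy (lag default π/2, since zero-lag locking is invisible to iPLV) with
  an independent source, weighted by `strength`.
* **PAC** is planted as a constant-modulus random-phase carrier multiplied
  by `1 + depth·cos(φ_low − lag)`, again with lag default π/2 — for the
  same reason: the envelope-phase-locking estimator reads the imaginary
  part of the phase alignment, so a zero-lag modulation would be invisible
  by construction. The constant-modulus carrier makes the planted
  modulation, rather than the carrier's own amplitude fluctuations, the
  envelope.
* **Identity is the plan.** Each subject owns a `CouplingPlan`: a set of
  disjoint driven pairs, each with a two-mode menu drawn from the default
  universe {β2β2, γ1γ1, γ2γ2, β1→γ2, β2→γ2} and a subject-specific Markov
  switching schedule (segment resolution 0.5 s, stay-probabilities 0.75 to
  0.92, i.e. mean dwell 2–6 s). The default universe is restricted to
  modes that are recoverable at 1-s windows (see detectability above); any
  mode set can be planted explicitly. Sessions are independent
  realisations of the same plan — the generative counterpart of the claim
  that coupling dynamics, not signals, are the stable trait.
* **Two-cohort studies** regenerate a chosen subset of cohort-1 plans with
  fresh seeds inside a larger cohort-2; the overlap is recorded only in a
  manifest the pipeline never sees.

What the generator does **not** emulate: volume conduction / spatial
leakage between ROIs, heteroscedastic sensor noise, artifacts, inter-areal
delays beyond the planted lag, and non-Markovian mode dynamics. Passing
tests therefore demonstrate correctness and calibration of the machinery
under the stated generative assumptions, not performance on real
recordings.

## Fingerprinting

Each edge's label sequence is modelled per subject by a discrete-emission
HMM over the 37-symbol alphabet, trained with Baum–Welch (scaled
forward–backward; tolerance 1e-4 on log-likelihood, up to 200 iterations,
3 restarts for single fits). The state count is selected by BIC, with
emission parameters counted over the symbols a sequence actually uses;
cohort banks default to the grid {2, 3} with one restart and 50 iterations
— at ~2000 fits per cohort the larger grid buys no identification accuracy
at desk scale. Training on label *sequences* (rather than on the 6×36
epoch-probability matrices, which are kept as a reported descriptor,
`pd_feature_matrix`) is deliberate: discrete Baum–Welch is defined on
symbol sequences. Emission rows of cohort banks are smoothed with an
additive floor of 1e-3 so that a model scores another subject's sequences
finitely; single-sequence fits (`fit_dhmm`) default to no smoothing, which
preserves the exact EM monotonicity guarantee.

Classification assigns a test sequence to the model with the highest
forward log-likelihood. Edges are ranked by single-edge identification
accuracy; a greedy pass accumulates edges in rank order, keeping an edge
only when summed-log-likelihood accuracy strictly improves, and stops at
100% or after 5 consecutive non-improvements. Because desk-scale cohorts
saturate after very few edges, similarity-matrix moments and external
matching use the selected set padded with next-ranked edges to at least 10
— the small-cohort analogue of carrying a plateau-sized edge set into the
blind matching stage; with fewer edges the cross-subject score
distribution is too heavy-tailed for moment-based thresholds.

**External matching.** From the within-study similarity matrix (training
models × second-session sequences, summed over the matching edge set) the
decision cutoff is the midpoint between `off-diagonal mean + 3 SD` and
`diagonal mean − 3 SD`; overlapping intervals raise a "cohort not
separable" error rather than producing a cutoff. A known subject is
declared present in an external cohort when their maximal summed
log-likelihood over its members exceeds the cutoff; the argmax names the
match. **Differentiability** is the z-score of the self-match against the
non-self scores (sample SD); in blind matching, where no self entry
exists, the maximum plays that role.

**Baselines.** Welch-spectrum profiles (2-s Hann segments, 50% overlap,
constant detrend, 0.5-Hz resolution, per-band or 0–90 Hz), static iPLV
connectomes (whole-recording, upper triangle), Euclidean nearest-neighbour
matching on the integrated graph's strength dynamics, and random k-edge
subsets of the dHMM pipeline (1000 draws by default). These exist to
establish an ordering — dominant-mode dHMM identification should not be
beaten by any of them on the same cohort — not absolute percentages.

## Artifact-component screening

Windowed (2 s, non-overlapping) kurtosis, order-2 Rényi entropy (16-bin
histogram over ±4 SD — the "collision entropy" convention of ICA screening)
and skewness, z-scored to zero mean and unit variance, flag a window when
all three scores leave [−2, 2]; a component is artifactual when more than
20% of its windows are flagged. The z-scores are standardised over the
pooled (component × window) population by default: a within-component
z-score mathematically cannot place more than ~20% of windows beyond ±2
(for a two-cluster value distribution the outlier-cluster z-score tops out
at 2 exactly when that cluster holds 20% of the mass), so the pooled axis
is the only one under which the 20% rule can ever trigger. A
per-component axis remains available.

## ROI representatives

Within a region, every voxel is weighted by the sum of its absolute
Pearson correlations to the other voxels (self-terms excluded — they only
shift all weights by a constant), weights are normalised to unit sum, and
the representative is the weighted voxel sum. Weights are computed once
per session by default; fully uncorrelated voxels fall back to equal
weights, and a single voxel is returned unchanged.

## Problem sizes and numerics

Desk-scale defaults — 10–20 ROIs, 60-s sessions at 600 Hz, 10-subject
training cohorts, 20-subject external cohorts, 4 pooled null shifts, state
grid {2, 3} — were chosen so that a full two-cohort study (40 session
pipelines, ~2000 HMM fits, external matching and all baselines) runs end
to end on a single CPU core in well under half an hour; the 90-ROI / 300-s
/ 10⁴-surrogate scale of a real study is a configuration, not a different
code path, but its integrated 4-D arrays (36 × 2991 × 90 × 90) want tens
of gigabytes and a cluster. Windowed phasor sums use complex64 (agreement
with the float64 pairwise estimators to ~1e-5; the pairwise estimators
themselves match brute-force references to 1e-12). Forward/Baum–Welch
recursions are scaled per step, safe for sequences up to at least 1e5
symbols. Probability rows are floored at 1e-12 before renormalisation to
avoid division by zero on degenerate inputs.

## Known limitations

* Surrogate depth at desk scale caps attainable significance near the
  p-value floor; results at the published 0.001/36 stringency require the
  full 10⁴-surrogate depth per comparison.
* δ-band and other narrowband couplings are estimated but, at 1-s windows,
  cannot be window-wise separated from their own surrogate null — a
  statistics limit, flagged here rather than silently absorbed.
* The generator's identity model (disjoint driven pairs, two-mode menus)
  is deliberately simple; it makes identification easier than real
  inter-subject variability would.
* Subnetwork analyses require a user-supplied ROI → network map; no atlas
  assignment ships with the package.
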