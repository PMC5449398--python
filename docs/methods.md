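# Methods

This note records the models, numerical choices and known limitations
behind the package, in the order data flows through the pipeline.

## Simulators

The built-in systems generate every input used by the tests and the
acceptance script; no external data is required.

* **Lorenz**: σ=10, ρ=28, β=8/3, observing x. Default initial state
  (−8, 8, 27) with 10 time units of transient discarded, giving a
  generic on-attractor start; the pipeline additionally perturbs the
  initial state with seeded N(0, 0.1²) noise so that different seeds
  yield statistically independent trajectories on the same attractor.
* **Rössler**: a=b=0.2, c=5.7, observing x.
* **Double pendulum**: frictionless, equal unit masses and unit rod
  lengths, g=9.81, observing the first angle. Used mainly as an
  integrator stress test via energy conservation.
* **Dynamo stand-in**: a double-well Langevin system
  dx = (x − x³)dt + σ dW integrated by Euler–Maruyama with seeded noise,
  standing in for turbulently driven magnetic-polarity reversal: the
  field amplitude dwells in one well and noise triggers rare reversals.

Deterministic systems use classical fixed-step RK4 at the output Δt, so
samples fall exactly on the Hankel grid with local error O(Δt⁵); at the
default Δt=0.001 step-halving changes the Lorenz observable by <1e−4
over a time unit, and double-pendulum energy drifts by <1e−6 relative
over 10 time units. Blow-ups are reported with the time they occur.

**Limitation of the dynamo stand-in.** Because its driver is white
Gaussian noise, its HAVOK forcing coordinate inherits Gaussian
statistics (excess kurtosis ≈ 0) even though the reversals themselves
are rare. Fat-tailed forcing is a signature of *deterministic*
intermittency and is exhibited here by the Lorenz and Rössler systems
(excess kurtosis ≈ 30 and ≈ 27 under default settings); reproducing
fat-tailed reversal forcing would require a chaotic, not stochastic,
dynamo model.

## Delay embedding

The Hankel matrix is a strided view (q rows, p = m − q + 1 columns;
windows fully contained, no padding). Its SVD is computed by a direct
LAPACK economy decomposition by default. A method-of-snapshots variant
(eigendecomposition of the q×q Gram matrix H Hᵀ) is available for very
long series, but it squares the condition number and therefore corrupts
the trailing singular triplets — precisely the ones that carry the
forcing coordinate — so the direct path is the default even at p ~ 10⁶,
where it remains fast (<2 s) and memory-light (q×p doubles).

SVD signs are fixed by making the largest-magnitude entry of each U
column positive (V flipped accordingly), which makes all outputs
deterministic. H is not mean-centered. New data is projected by
v_k = Σ⁻¹ Uᵀ h_k over sliding windows; the coordinate of a window is
time-stamped at the window's **final** sample (causal convention), so
projected coordinates trail the raw measurement by (q−1)Δt — 0.1 time
units at the defaults — which is the irreducible reporting delay of any
online use.

Defaults follow the rule that the window should span qΔt = 0.1
nondimensional time units (q=100 at Δt=0.001); the pipeline warns when a
config deviates. Rank r=15 is used for structure and reconstruction
(the highest rank before roundoff corrupts the trailing coordinate:
σ₁₅/σ₁ ≈ 3e−13 is at the edge of double precision), r=11 for event
prediction. Nonlinear measurement functions g(x) are not implemented;
the loader/embedding interface accepts any scalar series, so applying g
upstream is the supported hook.

## Forced linear model

Derivatives are 4th-order central differences (exact through quartics;
two samples trimmed per end). Regression is ordinary least squares of
dV on V — operating on the unit-norm V columns directly, not on ΣV —
solved per equation, with sequentially thresholded least squares as the
sparse option (threshold 0 degenerates exactly to least squares). Rank
deficiency is reported and resolved by the pseudo-inverse.

A continuous-time model is fitted (regression on derivatives) rather
than a discrete one-step map; the discrete propagator exp(AΔt) is
exposed for diagnostics. Simulation integrates dv/dt = Av + Bv_r with
RK4, linearly interpolating the sampled forcing at half steps. Because
the forcing is known only at samples, interpolation error O(Δt²)
dominates the integrator's O(Δt⁴) and the observed global order is 2
(measured error ratio 4.0 under step halving); at Δt=0.001 this is far
below every tolerance used here.

Structure diagnostics: skew ratio ‖(A+Aᵀ)/2‖_F/‖A‖_F (0 for perfectly
skew-symmetric dynamics), spectral abscissa max Re λ(A), and the
fraction of large entries (|A_ij|>1) within 1.0 of an integer multiple
of 5. The stability check uses max Re λ ≤ 0.5 and the skew check <0.3 —
the underlying claims are qualitative, and these margins are
configurable. `integerize_model` snaps coefficients to the nearest
multiple of 5 to probe the near-integer structure; the snapped model
keeps the qualitative switching behavior.

## Event prediction

The forcing is "active" where |v_r| exceeds a threshold (strict
inequality; optional moving-average smoothing, off by default). The
default threshold 0.002 is matched to unit-norm V columns at the
standard training size (~2×10⁵ windows), where the forcing coordinate's
standard deviation is ~0.0024; it can be swept to trace an ROC curve.

**Orbit bookkeeping.** Lobe membership is the sign of an oscillatory
lobe signal — raw x(t) for Lorenz, or v₁ as its smoothed surrogate.
Orbit boundaries are the interior local extrema of the signal together
with its zero crossings; each boundary closes one orbit, and an orbit is
"switching" iff it ends at a crossing (the final partial revolution
before the switch). On a 1,000-time-unit Lorenz test stretch this yields
~570 switching events and ~2,080 quiet orbits (mean orbit ≈ 0.38 time
units; the long-run switch rate measured over 5,000 time units is
0.572 per time unit with a per-1,000-unit standard deviation of ~22, so
counts vary by a few percent across seeds).

**Scoring.** Warning activity comes in oscillatory micro-bursts that
span a sizable fraction of a lobe period around each switch, so scoring
is done at the level of events, not samples: a switch is *detected* if
any activity occurs within `pre_horizon` (default 1.5 time units — the
typical ~1-unit warning plus one mean orbit of dispersion) before it; a
contiguous burst is *attributed* to a switch it predicts within that
horizon or trails within `post_horizon` (default 0.5 time units, the
residue of the event while the trajectory re-enters a lobe through the
strongly nonlinear outer region); and a quiet orbit is a *false
positive* only if it overlaps a burst attributed to no switch — a
warning with no event. Lead time runs from the onset of the earliest
attributed burst to the crossing. A naive per-orbit mode (`mode="orbit"`:
any active sample in any quiet orbit is a false positive) is retained
for diagnostics and threshold sweeps; it brands genuine early warnings
as false positives and is monotone in the threshold by construction.

**Shuffle control.** Permuting the forcing preserves its distribution
but destroys its timing; re-simulating with shuffled forcing loses the
baseline switch times. Raw agreement is the fraction of baseline v₁
crossings matched by a shuffled-run crossing within a window of 0.1
time units — the analysis' own timing resolution qΔt. Raw agreement
alone is misleading, because shuffled runs cross zero often (~1–3 times
per unit, varying strongly between permutations) and chance coincidences
alone produce agreement 1−exp(−2wλ) at crossing density λ — measured
raw agreement tracks exactly this floor. The report therefore also
gives a chance-corrected score (agreement − chance)/(1 − chance): 1 for
perfect timing (identity permutation), ~0 for pure chance regardless of
the shuffled run's crossing density. Over a 200-time-unit control
stretch (~160 baseline events, standard error a few percent) shuffles
score between −0.05 and 0.4 while the identity scores exactly 1.

## Transfer operator

Ulam discretization on the first three embedded coordinates: per-axis
grids of 40 bins spanning the data ±1% (half-open bins, last bin
closed), box-to-box transition counts at a lag of q samples (one delay
window), and row normalization by exact division so counts/count rows
sum to 1 exactly. Boxes visited fewer than 5 times are merged into the
nearest well-sampled box (by center distance) before counting, which
stabilizes the empirical occupation measure π; rows left without an
outgoing transition are dropped (recorded) or self-looped when the drop
would cascade.

The additive reversibilization R = (P + P̂)/2 with P̂_ij = π_j P_ji/π_i
satisfies detailed balance π_i R_ij = π_j R_ji identically by
construction, so D^{1/2} R D^{−1/2} is symmetric and its spectrum real;
eigenpairs come from dense or Lanczos symmetric solvers depending on
size. Labels are the sign (level set at 0) of the second right
eigenvector — two almost-invariant sets; general n-set partitions are
out of scope. Disconnected chains are labeled by component with a
warning. On 100 test time units of the embedded Lorenz attractor the
second eigenvalue is ≈0.98 and each set straddles both lobes, matching
the geometry expected of the lobe-to-lobe transport sets; the package
also reports the best-matching per-sample agreement between this
partition and the HAVOK active/quiescent partition, plus a
boundary-distance statistic, without asserting a hard threshold (the
correspondence claim is qualitative).

## Problem sizes and determinism

The acceptance script and tests use: 200 training + 1,000 test time
units at Δt=0.001 for the headline prediction experiment; 50+50 time
units for out-of-sample reconstruction; 50 time units of forcing for the
shuffle control; and 100 time units (10⁵ points) for the Ulam partition.
Every stochastic element (initial-state perturbation, dynamo noise,
shuffles) flows from one seed fanned out by fixed offsets, so reruns
with the same config are bit-for-bit identical; the pipeline writes a
manifest with a config hash, per-stage wall times and artifact
checksums.

## Known limitations

* Single forcing coordinate only (no r−s/s splitting with s > 1).
* The event-scoring horizons (1.5/0.5 time units) are calibrated to the
  Lorenz lobe-switching timescales; other systems may need different
  horizons, exposed as parameters.
* The orbit segmentation assumes an oscillatory, zero-mean-between-lobes
  signal; monotone or constant signals are rejected rather than forced
  into the framework.
* Real-data loaders accept user CSVs (ECG, EEG, case counts), but no
  real datasets ship with the package and no claims are made about them.
* The synthetic generators emulate clean, uniformly sampled, noise-free
  (or white-noise-driven) measurements; passing tests here says nothing
  about robustness to measurement noise, missing samples or drift in
  real recordings.
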