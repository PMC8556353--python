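# Methods

This note documents the generative models, the dataset recipe, the
estimators and metrics, and the numerical and design choices behind
`anomdiff`. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; no empirical claim goes beyond what those runs
produce.

## Generative models

All five models are parameterized by the anomalous diffusion exponent
α ∈ [0.05, 2] (smaller exponents give practically immobile paths). The
admissible ranges differ by mechanism: CTRW and ATTM are strictly
subdiffusive (α ≤ 1), the Lévy walk superdiffusive (α ≥ 1), FBM excludes
the ballistic limit (α < 2), and SBM covers the full range. Trajectories
start at the origin and are delivered on the unit time grid t = 0 … L−1,
so sample index and time coincide.

**Power-law sampler.** Waiting and flight times are drawn from the Pareto
density ψ(t) = (σ−1) t^(−σ) on t ≥ 1 by inverse CDF,
t = (1 − u)^(−1/(σ−1)). The lower cutoff t_min = 1 is a choice: only the
tail behavior is physically prescribed, and with Δt = 1 a smaller cutoff
would be invisible after resampling.

**CTRW.** Waiting times with tail σ = α + 1; at each event the tracer
jumps by N(0, √D) and *holds* its position until the next event
(zero-order-hold resampling). At α = 1 the waiting time is fixed at 1 —
the degenerate limit of the one-sided stable density — which makes the
Brownian boundary case deterministic in its event times and easy to test.

**FBM.** Exact unit-variance fractional Gaussian noise with
autocovariance γ(k) = (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})/2, H = α/2,
cumulatively summed and scaled by √(2K_H). The default path is circulant
embedding (Davies–Harte): eigenvalues of the length-2(L−1) circulant are
obtained by FFT and the sample is the real part of the transformed
complex Gaussian spectrum. If the embedding has a meaningfully negative
eigenvalue (tolerance −10⁻⁹ relative to the largest; tiny negatives from
round-off are clipped), the generator falls back to the O(n²)
Durbin–Levinson recursion, which is also exposed directly and doubles as
an independent oracle in the tests. Axes are independent in 2D/3D.

**Lévy walk.** Flight durations with tail σ + 1 where σ = 3 − α for
α < 2; the ballistic case α = 2 corresponds to any σ ∈ (0, 1) and the
generator fixes σ = 0.5 there. Each flight moves at constant speed v,
drawn once per trajectory uniformly from (0, 10] (not per flight), in a
random sense: ± in 1D, a uniform direction on the circle/sphere in
2D/3D. Resampling interpolates linearly inside the current flight.

**ATTM.** The exponent pair is drawn by rejection: σ uniform on (0, 3],
γ = σ/α, accepted when σ < γ < σ + 1 (the subdiffusive regime; for
α = 0.5 this reduces to σ ∈ (0, 1)). Diffusivities follow
P(D) ∝ D^(σ−1) on (0, 1], sampled as D = u^(1/σ) — the support is a
choice, since only the small-D behavior and a fast large-D decay are
prescribed. Each Brownian segment has increments N(0, √(2D Δt)) and
lasts D^(−γ) steps; for very small D this duration overflows any finite
horizon, and only the part inside the horizon is realized (the tracer is
effectively immobile for the remainder). At α = 1 the rejection
condition is unsatisfiable (γ = σ), and the model degenerates to plain
Brownian motion with a single random D ∈ (0, 1).

**SBM.** Increment i is Gaussian with variance 2K_α(i^α − (i−1)^α), so
the ensemble MSD is 2K_α t^α *exactly* on the grid. The Gaussian deviate
is realized as √2·erfcinv(2u) applied to uniform draws (the argument is
clipped away from {0, 2} to avoid infinities); this matches the
construction used to generate the benchmark and is distributionally a
standard normal.

**Higher dimensions.** ATTM/CTRW/FBM/SBM in 2D, and FBM/SBM in 3D, are
compositions of independent per-axis 1D simulations. For ATTM/CTRW in 3D
and LW in 2D/3D the 1D recipe supplies the step *length* (|N(0,√D)| per
event, v·t per flight), which sets the radius of a uniformly random
direction on the circle or sphere, so the model's coupling between step
size and timing survives the lift.

## Dataset recipe

Tasks 1 and 2 simulate at L = 1000 and post-process in this order:

1. **standardize** — divide by the population s.d. of unit-lag
   displacements pooled over axes (one scale per trajectory, preserving
   isotropy), so σ_D = 1 exactly;
2. **localization noise** — i.i.d. N(0, σ_noise) on every coordinate,
   σ_noise drawn per axis from {0.1, 0.5, 1}, hence SNR = σ_D/σ_noise ∈
   {10, 2, 1}; the overall SNR (mean of per-axis ratios) is recorded;
3. **diffusivity scale** — multiply by |z|, z ~ N(0,1). The absolute
   value avoids the physically irrelevant sign and the degenerate zero.
   Scaling *after* the noise keeps the recorded SNR levels exact, since
   the factor multiplies signal and noise alike;
4. **cut** to a length drawn uniformly from [10, 1000].

T1 balances α over the grid {0.05, 0.10, …, 2.00} (model uniform among
those compatible with the drawn α); T2 balances the five models exactly
(α uniform on each model's admissible sub-grid). T3 trajectories have
length 200 with a changepoint t_GT uniform on {1, …, 199}: two segments
with independently drawn (model, α), redrawn until they differ in at
least one feature, are each simulated at full length 200 and
standardized (so standardization is well-defined even for changepoints
near the ends), then segment 2 is translated to continue from segment
1's position at t_GT; noise and the |z| scale are applied once to the
concatenated trajectory, preserving continuity at the changepoint.
Immobile draws (zero displacement s.d., possible for heavy-tailed CTRW
waits) are rejected and regenerated. Every dataset is a pure function of
(task, n, dim, seed, config).

## Estimators

EA-MSD, TA-MSD and TEA-MSD follow the standard definitions with squared
displacements summed over axes. The ergodicity-breaking parameter is
EB = ⟨ζ²⟩ − 1 with ζ = TA-MSD/TEA-MSD at a fixed lag (meaningful for
lag ≪ L); it vanishes for ergodic processes (Brownian, FBM) and is
positive under the weak ergodicity breaking of CTRW/ATTM/SBM.

The baseline exponent estimator fits ln TA-MSD against ln lag by
ordinary least squares over lags 1…k with k = max(10, round(0.1·L)),
additionally capped at L−1 so short trajectories (L ≤ 11) remain
fittable; rounding is Python's round-half-even. Zero TA-MSD points are
excluded from the log fit; the slope is clipped to the physical range
[0, 2]. Because CTRW/ATTM time averages scale near-linearly in the lag
regardless of α, this baseline is intentionally fallible — its negative
bias at SNR = 1 near α = 1 (localization noise flattens the short-lag
TA-MSD) is reproduced by the acceptance suite.

The closed-form RMSE of a uniform random changepoint predictor,
RMSE_random(t_GT) = √((t_GT³ + (L − t_GT)³)/(3L)), serves as the
no-skill reference for segmentation and is verified against 10⁶-draw
Monte Carlo.

## Metrics

T1 uses MAE (plus the signed bias θ); T2 uses micro-averaged
F1 = 2TP/(2TP + FP + FN) over argmax labels (ties broken by the fixed
model order ATTM, CTRW, FBM, LW, SBM), column-normalized confusion
matrices in percent, and one-vs-rest ROC/AUC with micro (pooled binary
decisions) and macro (unweighted class mean) averages; T3 uses the
changepoint RMSE (trajectories without an internal change carry a dummy
index, the nearer of {1, L−1}), segment MAE and F1 computed per segment
— paired positionally, first with first — and averaged, and MRR over the
three ranks. The ε-margin detection analysis (default ε = 20) classifies
each pair by whether prediction and truth fall inside (ε, L−ε): recall,
FPR and Jaccard similarity follow from the counts, RMSE_TP is restricted
to true-positive pairs, and ratios with empty denominators are reported
as not-applicable rather than zero.

Standard classification machinery (micro-F1, confusion counts, AUC) is
delegated to scikit-learn behind this module's interface; the test suite
checks those paths against brute-force enumerations (pairwise
Mann–Whitney ranking for AUC, hand counts for F1 and confusion).

## Problem sizes and what the tests show

The acceptance checks use 3000 noise-free length-1000 trajectories per
(model, α) for exponent recovery (slope over lags 10–999 within ±0.1 of
α), 2000 trajectories for the EB diagnostics, 500 repetitions for the
baseline estimator, and datasets of a few hundred trajectories for the
label-constraint checks — large enough that the Monte-Carlo error is
well inside each tolerance, small enough to run in seconds.

Passing these checks shows the generators realize the intended ensemble
statistics and the scorers agree with their definitions. The synthetic
data emulate finite localization precision and random diffusivity scales
but not other features of real experiments — drift, blinking and missed
detections, correlated noise, interactions between tracers — so
benchmark scores transfer to real data only insofar as those effects are
secondary.

## Known limitations

* ATTM's ensemble MSD converges to its asymptotic power law slowly; at
  observation windows of 10³ steps the fitted slope sits slightly above
  α (within the ±0.1 band at α = 0.6).
* The Lévy walk's exact time-averaged statistics differ from ensemble
  averages by a constant factor (ultraweak ergodicity breaking); no
  attempt is made to diagnose this beyond the EB parameter.
* The file dialect (semicolon-delimited, axis-major, dimension prefix)
  is this package's own, recorded and versioned in each manifest; other
  tools' dataset files may need trivial reshaping.
* Byte-identical reproduction of any previously published dataset is out
  of scope — RNG streams differ — but all statistical properties are
  matched and every run here is reproducible from its manifest.
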