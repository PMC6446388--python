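# Methods

## Model and assumptions

`microdbn` treats a longitudinal microbiome cohort as a set of per-subject
multivariate time series of relative abundances. Three modeling
assumptions drive the design:

* **Smoothness.** Community composition changes continuously, so an
  irregularly sampled taxon trajectory is represented by a cubic B-spline
  (FITPACK `splrep`/`BSpline`). The default smoothing factor is 0
  (interpolating spline): it is deterministic, reproduces observations
  exactly, and at the sampling densities targeted here tracks the data
  closely. A positive smoothing factor can be passed everywhere splines
  are fitted (`smoothing=` / `GridConfig.smoothing`) for noisier data.
* **Linear rate variation.** Subjects traverse the same program at
  different speeds and offsets, modeled by a first-degree warp
  τ(t) = (t − b)/a per subject (reference time → subject time). With the
  few time points available per subject, higher-order warps overfit.
* **Stationary two-slice dynamics.** Transitions between consecutive
  (uniformly resampled) time points are homogeneous in time, so a single
  two-slice conditional linear Gaussian network describes the whole
  series. Only taxon nodes at the current slice receive edges; discrete
  clinical covariates act through configuration-specific regression
  parameters, continuous ones as additional regressors.

## Alignment stage

The alignment error of taxon j between reference r and subject i is the
interval-normalized integrated squared difference between the reference
spline and the warped subject spline over their overlap [α, β], and the
cohort error E_M sums this over the contributing taxa S. The warp is found
by exhaustive search on a ∈ (0, 4] step 0.01, b ∈ [−50, 50] step 0.5
(80,400 candidates), subject to a > 0, α < β and
(β − α)/(t_max − t_min) ≥ ε with ε = 0.3; an unsatisfiable overlap
constraint yields "no alignment" for that pair.

Parameters that matter:

| parameter | default | meaning |
|---|---|---|
| `a_step`, `b_step` | 0.01, 0.5 d | grid resolution of the warp search |
| `epsilon` | 0.3 | minimum overlap fraction of the reference span |
| `min_abundance` | 0.001 | taxon eligibility floor (0.1 % mean abundance, fraction scale) |
| `quadrature_points` | 101 | trapezoid nodes for reported per-taxon errors |
| `smoothing` | 0 | FITPACK smoothing factor |

**Quadrature.** The reported per-taxon errors use a 101-point composite
trapezoid on [α, β]. The grid *scan* instead places quadrature nodes on a
fixed reference-time lattice with step equal to `b_step`, snapped inward
to [α, β]. Because t − b then stays on one lattice, the warped-sample
spline values depend only on (a, t − b) and are precomputed once per scale
a, reducing the scan to a windowed sum of squared differences evaluated by
a compiled kernel. For the smooth curves involved the two rules agree far
below grid resolution; the unit suite checks the scan against an
independent brute-force re-scan using plain loops.

**Determinism.** Ties in E_M are broken toward the near-identity warp
(smallest |a − 1|, then |b|, then scan order), so self-alignment returns
exactly (1, 0). Reference selection breaks ties by total error, number of
aligned subjects, then subject id; when no candidate aligns 90 % of the
cohort the longest-spanning subject (then most points, then id) is used.

**Outliers.** After alignment, subjects with E_M > μ + 2δ are removed in
one pass, with δ the *sample* (n − 1) standard deviation — a deliberate
choice for the small cohorts typical here. Equal errors (δ = 0) remove
nothing because the inequality is strict.

## DBN stage

Aligned subjects are mapped onto the reference axis via t = a·u + b,
re-splined, and resampled on the shared lattice t_ref_min + k·rate
restricted to each subject's aligned interval; consecutive pairs are
stacked into transition rows. Per taxon family, ordinary least squares
gives the MLE (λ₀, λ, σ² = mean squared residual). Numerical safeguards:

* `variance_floor = 1e-6` (fraction scale) keeps exact fits from producing
  infinite log-likelihoods;
* discrete-parent configurations observed with fewer than k + 2 rows share
  the pooled (configuration-free) regression instead of a singular fit;
* discrete CPDs use add-one smoothing, and unseen configurations score as
  uniform;
* predictions are conditional means clipped at 0, then renormalized to a
  composition when relative abundances are required.

The score is BIC with natural logarithm, d counting k + 2 parameters per
independently fitted Gaussian configuration and (levels − 1) per discrete
CPD row. AIC is available behind `score="aic"`. Hill climbing starts at
the baseline structure (self inter edges, fixed, counting toward
`max_parents`), adds the single best valid edge per step (intra subgraph
kept acyclic, lexicographic tie-breaks), and stops at the first step with
no positive gain — so the final BIC never falls below the baseline's.
Greedy search is not globally optimal; on small systems where exhaustive
enumeration is feasible the suite verifies it closes ≥ 95 % of the
baseline-to-optimum BIC gap.

Prediction for a held-out subject uses observed previous-slice values for
inter parents and observed current-slice values for intra parents (the
evaluation protocol predicts "from the previous and current time points");
a cascade mode that substitutes predicted intra parents in topological
order is deliberately not the default. Cross-validated MAE is averaged
over taxa and time points within a subject, then over subjects (the pooled
row-level average is also reported, since either aggregation is
defensible). Edge signs use the configuration-frequency-weighted
coefficient; |λ| below 1e−12 reports as "neutral".

**Bootstrap support** resamples whole subjects with replacement
(configurable B, seeded) and reports per-edge re-learn frequency. The
resampling unit and replicate count are this package's choice; subjects
are the natural exchangeable unit in a per-subject CV design.

## Synthetic data

`make_synthetic_reference` builds a 3-taxon, 43-point, 84-day reference —
the density of a well-sampled infant-gut series (one sample every ~2
days). Trajectories follow an ecological-succession template (early
colonizer declining, intermediate peaking, late rising, as in the
Bacilli → Gammaproteobacteria → Clostridia shift) as cubic splines through
6 seeded control points with random magnitudes and ±15 % wiggle, floored
at 0.05 and renormalized to sum to 1. The monotone/unimodal backbones make
the reference *identifiable*: an early design using unconstrained random
control points produced quasi-periodic curves on which distinct warps
matched different bumps equally well, a degeneracy real successional data
do not show.

`simulate_warped_cohort` draws warps uniformly **on the search lattice**
(a from {0.01, ..., 4.00}, b from {0, 0.5, ..., 50}) and sets each
subject's clock to u = (t − b*)/a*, so the aligner should recover (a*, b*)
exactly in the noise-free case. On-lattice draws make "exact recovery up
to search error" a meaningful property; off-lattice warps with small a*
would carry an irreducible b-quantization error of δa·|u| — days, for
compressed clocks — that says nothing about the search itself.

"p % Gaussian noise" is scaled to each channel's natural resolution:
abundance noise sd = (p/100) × the taxon trajectory's standard deviation,
time-stamp noise sd = (p/100) × the median sampling interval. Both are
invariant under the warp, so every subject suffers the same relative
corruption. Conventions tying time noise to the series *span* were
rejected: at 25 % they jitter time stamps by weeks, scramble the sampling
order wholesale, and make alignment impossible at noise levels the method
is known to tolerate. Noisy times are sorted, collisions separated by a
relative epsilon.

`simulate_dbn_cohort` forward-samples trajectories from a known
conditional Gaussian transition model (topological order within slice),
clips negatives and renormalizes each time point to a composition —
matching what a relative-abundance pipeline would see. The renormalization
induces weak compositional coupling between taxa, so parameter- and
structure-recovery tests use `simulate_transition_data`, the raw two-slice
sampler without clipping or closure, where fitted coefficients must
converge to the generating ones.

What passing simulations do **not** show about real data: sequencing
count noise (taxon-correlated, non-Gaussian), compositional bias, taxa
appearing/disappearing, non-stationary dynamics, and clinical covariates
that the warp cannot capture. The studies validate the machinery —
search correctness, estimator consistency, score behaviour — not
field-data performance.

## Problem sizes

The simulation studies run at: 10 warped subjects per condition ×
6 noise levels × 3 experiment types, averaged over 20 seeds (test suite)
or 5 seeds (`scripts/acceptance.py`); conditional Gaussian recovery at
N = 10⁴ rows; structure recovery on 20 (tests) / 10 (script) random
5-taxon systems at N = 2000 rows with `max_parents = 3`; CV comparisons on
20 / 10 replicate cohorts of 8 subjects × 15 time points. These sizes give
stable seed-averaged error measures while keeping a full run in the
minutes range on a single CPU.

## Known limitations

* The warp is linear; processes with locally varying rates (e.g. abrupt
  perturbations) are only approximated, and the alignment heuristic
  (pairwise to a chosen reference) carries no multiple-alignment
  optimality guarantee.
* Greedy hill climbing can miss the optimal structure; BIC asymptotics
  assume many more transitions than parameters, which short cohorts may
  violate.
* Conditional *linear* Gaussians cannot express saturating or switching
  interactions; discrete covariates mitigate this only per configuration.
* E_M is scale-dependent (squared abundance units); values are computed on
  the fraction scale and multiplied by 100 when quoted "in percent".
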