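# microdbn

Temporal alignment and dynamic Bayesian network (DBN) inference for
longitudinal microbiome studies.

Longitudinal 16S/metagenomic cohorts sample each subject's microbial
community at irregular times, and subjects move through the same biological
program (gut colonization after birth, menstrual cycling of the vaginal
community, ...) at different *rates*. Pooling subjects without correcting
for those rate differences blurs exactly the temporal signal one wants to
model. `microdbn` implements a pipeline for this situation:

1. **Spline smoothing.** Each taxon trajectory is fitted with a cubic
   B-spline, giving a continuous curve s<sup>j</sup>(t) that can be
   evaluated between observations.
2. **Temporal alignment.** Every subject *i* is warped onto a reference
   subject *r* with a linear map τ<sub>i</sub>(t) = (t − b)/a. The warp
   minimizes the microbiome alignment error

   E<sub>M</sub>(r, i) = Σ<sub>j∈S</sub> ∫<sub>α</sub><sup>β</sup>
   (s<sub>i</sub><sup>j</sup>(τ<sub>i</sub>(t)) − s<sub>r</sub><sup>j</sup>(t))²
   dt / (β − α)

   over an exhaustive grid a ∈ (0, 4] (step 0.01), b ∈ [−50, 50]
   (step 0.5), subject to a > 0, α < β and a minimum overlap fraction
   ε = 0.3 between the warped sample and the reference interval. The
   reference is chosen to align ≥ 90 % of subjects with minimal total
   E<sub>M</sub>; subjects with E<sub>M</sub> > μ + 2δ are filtered out as
   anomalies, and analysis is restricted to taxa contributing to at least
   half of the pairwise alignments.
3. **Two-slice DBN.** On the aligned, uniformly resampled cohort a dynamic
   Bayesian network over consecutive time slices (t<sub>i</sub>,
   t<sub>i+1</sub>) is learned. Taxon nodes are conditional linear
   Gaussians, y | u₁..u<sub>k</sub> ~ N(λ₀ + Σ λ<sub>i</sub>u<sub>i</sub>, σ²),
   with separate parameters per discrete-parent configuration. Structure
   search is greedy hill climbing from a baseline model (each taxon linked
   only to itself across slices), adding *inter* edges (t<sub>i</sub> →
   t<sub>i+1</sub>) or acyclic *intra* edges (within t<sub>i+1</sub>) that
   maximally improve BIC = log P(D | Θ, G) − (d/2) log N, up to
   `max_parents` ∈ {1, 3, 5} parents per taxon.
4. **Interpretation & evaluation.** Edge signs come from the regression
   coefficients (λ > 0 beneficial, λ < 0 harmful); display weights use the
   abundance-weighted normalization λ<sup>N</sup><sub>i</sub> =
   λ<sub>i</sub>ū<sub>i</sub> / Σ<sub>j</sub>|λ<sub>j</sub>ū<sub>j</sub>|;
   bootstrap support is the fraction of subject-resampled re-learns
   containing an edge. Predictive accuracy is measured by
   leave-one-subject-out cross-validation (MAE of normalized next-step
   predictions) against the naive carry-forward baseline.

A simulation module generates the synthetic cohorts used throughout the
test suite: warped, noisy copies of a smooth reference subject (for
alignment recovery studies) and cohorts forward-sampled from known
conditional Gaussian transition models (for parameter/structure recovery
and prediction benchmarks). No external data are required.

## Worked example

```python
import numpy as np
from microdbn import (LongitudinalDataset, SimulationConfig, TemporalAligner,
                      DynamicBayesianNetwork, build_transition_dataset,
                      make_synthetic_reference, per_subject_cv,
                      simulate_warped_cohort)

# a reference subject and 6 time-warped, noisy copies of it
ref = make_synthetic_reference(n_taxa=3, n_points=43, span_days=84, seed=1)
cfg = SimulationConfig(n_samples=6, seed=1)
cohort, truth = simulate_warped_cohort(ref, cfg, noise_pct=10,
                                       experiment_type=3,
                                       rng=np.random.default_rng(1))
ds = LongitudinalDataset([ref] + cohort.samples)

# align everyone onto the reference (dense grid: a in (0,4], b in [-50,50])
aligned = TemporalAligner(reference="reference").fit_transform(ds)

# two-slice DBN from transitions at a 3-day sampling rate
data = build_transition_dataset(aligned, rate=3.0)
dbn = DynamicBayesianNetwork(max_parents=3).fit(data)
```

Output (alignment report, learned edges, cross-validated MAE):

```
sim00: recovered a=1.91 (true 1.90), b=25.5 (true 25.5), E_M=0.0005
sim01: recovered a=0.09 (true 0.09), b=0.5 (true 0.5), E_M=0.0005
...
N=191 transitions, BIC=1319.7
  taxon_1 -> taxon_2 (intra, negative)
  taxon_1 -> taxon_1 (inter, positive)
  taxon_2 -> taxon_1 (inter, negative)
  ...
DBN LOSO MAE:      0.0158
baseline LOSO MAE: 0.0307
```

The aligner recovers each subject's warp to within one grid step despite
10 % noise on both time stamps and abundances, the hill climb augments the
baseline self-edges with signed cross-taxa interactions, and the learned
network halves the prediction error of the carry-forward baseline.
`export_network(dbn.model_, "net.graphml", ...)` writes the result with all
display attributes (role, slice, sign, λ, λᴺ, bootstrap support) for
Cytoscape or any GraphML viewer.

The same pipeline is available from the shell for real data in long-format
CSV (`subject,time,taxon,abundance` plus an optional metadata table):

```bash
microdbn align     --input cohort.csv --out alignment.tsv
microdbn learn-dbn --input cohort.csv --rate 3 --max-parents 3 --out model.json
microdbn cv        --input cohort.csv --rates 1,3,5,7 --out cv.tsv
microdbn export-network --model model.json --out network.graphml
```

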