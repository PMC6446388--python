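"""Synthetic cohort generators for alignment and network recovery studies.

Two families of generators:

*   **Warped cohorts** — a smooth synthetic reference subject is built from
    seeded random spline curves, and simulated subjects are produced by
    linearly warping its sampling clock (scale a, shift b) and adding a
    chosen percentage of Gaussian noise to the warped time points and/or the
    abundance values.  Recovering (a, b) by the grid-search aligner and
    comparing to the generating values measures alignment robustness.

*   **DBN cohorts** — trajectories forward-sampled from a known two-slice
    conditional linear Gaussian model, for parameter- and
    structure-recovery tests and for pipeline-level prediction benchmarks.

Noise convention: "p% noise" adds zero-mean Gaussian noise scaled to the
corrupted quantity's natural resolution — for abundances, sd equal to p%
of the taxon trajectory's own standard deviation (signal-relative noise);
for time stamps, sd equal to p% of the series' median sampling interval
(timing jitter relative to the sampling resolution).  Both scalings are
invariant under the time warp, so every simulated subject experiences the
same relative corruption regardless of its warp parameters.  Noisy time
points are sorted and de-duplicated to keep spline fitting well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .alignment import GridConfig, align_pair
from .dataset import LongitudinalDataset, SubjectSample, TaxonProfile
from .dbn import TransitionDataset


@dataclass
class SimulationConfig:
    """Study conditions of the alignment simulation experiments.

    Ten subjects per condition, warp parameters drawn uniformly from
    a in (0, 4], b in [0, 50], noise percentages {0, 5, 10, 15, 20, 25},
    and three experiment types: (1) noisy abundances with clean times,
    (2) noisy times with clean abundances, (3) both noisy.  The synthetic
    reference emulates a densely sampled infant-gut series: 3 taxa observed
    at 43 time points over 84 days (about one sample every two days).
    """

    n_samples: int = 10
    a_range: tuple[float, float] = (0.0, 4.0)
    b_range: tuple[float, float] = (0.0, 50.0)
    noise_levels: tuple[int, ...] = (0, 5, 10, 15, 20, 25)
    experiment_types: tuple[int, ...] = (1, 2, 3)
    seed: int = 0
    a_step: float = 0.01
    b_step: float = 0.5
    n_taxa: int = 3
    n_points: int = 43
    span_days: float = 84.0

    def __post_init__(self):
        if any(p < 0 for p in self.noise_levels):
            raise ValueError("noise levels are percentages >= 0")
        if self.a_range[0] < 0 or self.a_range[1] < self.a_range[0]:
            raise ValueError("invalid a_range")


@dataclass
class SimulationTruth:
    """Ground-truth warp per simulated sample."""

    records: pd.DataFrame  # sample_id, a, b, noise_pct, experiment_type

    def __len__(self) -> int:
        return len(self.records)

    def truth_for(self, sample_id: str) -> tuple[float, float]:
        row = self.records[self.records["sample_id"] == sample_id].iloc[0]
        return float(row["a"]), float(row["b"])


@dataclass
class RecoveryReport:
    """Alignment-recovery accuracy per (experiment type, noise level).

    ``mean_em`` is on the fraction-abundance scale; ``mean_em_percent``
    (x100) expresses it on the percent-abundance scale.
    """

    table: pd.DataFrame

    def get(self, experiment_type: int, noise_pct: int) -> pd.Series:
        t = self.table
        row = t[(t["experiment_type"] == experiment_type)
                & (t["noise_pct"] == noise_pct)]
        return row.iloc[0]


def make_synthetic_reference(n_taxa: int = 3, n_points: int = 43,
                             span_days: float = 84.0, seed: int = 0,
                             n_control: int = 6) -> SubjectSample:
    """Smooth, non-constant, sum-normalized reference subject.

    Taxa trajectories emulate an ecological succession (the pattern seen in
    the maturing infant gut, where early colonizers decline while
    intermediate and late colonizers peak and rise): each taxon is a cubic
    spline through ``n_control`` seeded control points following a
    decreasing, unimodal or increasing backbone with random magnitudes and
    wiggle.  The global trends make the reference identifiable under
    scale-and-shift warps (no repeating motifs a wrong warp could lock
    onto).  Curves are floored away from zero so every taxon passes the
    0.1% mean-abundance eligibility filter, then renormalized so the taxa
    sum to 1 at every sampled time.
    """
    if n_points < 9:
        raise ValueError("reference must survive the nine-point filter")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, span_days, n_points)
    control_t = np.linspace(0.0, span_days, n_control)
    curves = np.empty((n_taxa, n_points))
    backbones = ("early", "mid", "late")
    for j in range(n_taxa):
        high = rng.uniform(0.5, 1.0)
        low = rng.uniform(0.05, 0.2)
        shape = backbones[j % 3]
        if shape == "early":
            control_y = np.linspace(high, low, n_control)
        elif shape == "late":
            control_y = np.linspace(low, high, n_control)
        else:
            tri = 1.0 - np.abs(np.linspace(-1.0, 1.0, n_control))
            control_y = low + (high - low) * tri
        control_y = control_y * (1.0 + rng.uniform(-0.15, 0.15, n_control))
        curves[j] = np.clip(CubicSpline(control_t, control_y)(times), 0.05, None)
    curves /= curves.sum(axis=0, keepdims=True)
    profiles = {f"taxon_{j + 1}": TaxonProfile(f"taxon_{j + 1}", times.copy(),
                                               curves[j])
                for j in range(n_taxa)}
    return SubjectSample("reference", profiles)


def _strictly_increasing(t: np.ndarray) -> np.ndarray:
    t = np.sort(t)
    eps = 1e-9 * max(1.0, float(t[-1] - t[0]))
    for i in range(1, len(t)):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + eps
    return t


def simulate_warped_cohort(ref: SubjectSample, cfg: SimulationConfig,
                           noise_pct: float, experiment_type: int,
                           rng: np.random.Generator | None = None):
    """Generate ``cfg.n_samples`` warped, noisy copies of the reference.

    For each subject a warp (a*, b*) is drawn and its sampling clock is set
    to u_k = (t_k - b*) / a*, so that the aligner's map tau(t) = (t - b*) / a*
    reproduces the subject exactly and the grid search should recover
    (a*, b*).  Depending on ``experiment_type``, p% signal-relative Gaussian
    noise corrupts the abundances (1), the warped times (2), or both (3).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t_ref = ref.times
    taxa = sorted(ref.profiles)
    values = np.array([ref.profiles[j].values for j in taxa])
    sd = noise_pct / 100.0
    samples, rows = [], []
    for i in range(cfg.n_samples):
        # warps are drawn on the search lattice so that noise-free recovery
        # is limited only by the search itself, not by grid resolution
        a_lo, a_hi = cfg.a_range
        i_lo = max(1, int(np.ceil(a_lo / cfg.a_step)))
        i_hi = int(np.floor(a_hi / cfg.a_step))
        a_star = cfg.a_step * rng.integers(i_lo, i_hi + 1)
        j_lo = int(np.ceil(cfg.b_range[0] / cfg.b_step))
        j_hi = int(np.floor(cfg.b_range[1] / cfg.b_step))
        b_star = cfg.b_step * rng.integers(j_lo, j_hi + 1)
        u = (t_ref - b_star) / a_star
        y = values.copy()
        if experiment_type in (2, 3) and sd > 0:
            resolution = float(np.median(np.diff(u)))
            u = _strictly_increasing(u + rng.normal(0.0, sd * resolution, size=u.shape))
        if experiment_type in (1, 3) and sd > 0:
            sigma_y = sd * y.std(axis=1, keepdims=True)
            y = np.clip(y + rng.normal(0.0, 1.0, size=y.shape) * sigma_y, 0.0, None)
        sid = f"sim{i:02d}"
        profiles = {j: TaxonProfile(j, u.copy(), y[k])
                    for k, j in enumerate(taxa)}
        samples.append(SubjectSample(sid, profiles))
        rows.append({"sample_id": sid, "a": a_star, "b": b_star,
                     "noise_pct": noise_pct, "experiment_type": experiment_type})
    return (LongitudinalDataset(samples),
            SimulationTruth(pd.DataFrame(rows)))


def run_alignment_simulation(cfg: SimulationConfig,
                             grid: GridConfig | None = None,
                             ref: SubjectSample | None = None) -> RecoveryReport:
    """Full warp-recovery study: for every (experiment type, noise level),
    simulate a cohort, align every subject back to the reference with the
    exhaustive grid search, and report MAE of the recovered a and b and the
    mean residual alignment error E_M."""
    grid = grid or GridConfig()
    if ref is None:
        ref = make_synthetic_reference(cfg.n_taxa, cfg.n_points, cfg.span_days,
                                       seed=cfg.seed)
    rows = []
    for etype in cfg.experiment_types:
        for p in cfg.noise_levels:
            rng = np.random.default_rng([cfg.seed % (2 ** 31), etype, int(p)])
            cohort, truth = simulate_warped_cohort(ref, cfg, p, etype, rng)
            err_a, err_b, ems = [], [], []
            for sample in cohort.samples:
                al = align_pair(ref, sample, grid)
                if al is None:
                    continue
                a_true, b_true = truth.truth_for(sample.subject_id)
                err_a.append(abs(al.transform.a - a_true))
                err_b.append(abs(al.transform.b - b_true))
                ems.append(al.total_error)
            rows.append({
                "experiment_type": etype, "noise_pct": p,
                "n_aligned": len(err_a),
                "mae_a": float(np.mean(err_a)) if err_a else float("nan"),
                "mae_b": float(np.mean(err_b)) if err_b else float("nan"),
                "sd_a": float(np.std(err_a)) if err_a else float("nan"),
                "sd_b": float(np.std(err_b)) if err_b else float("nan"),
                "mean_em": float(np.mean(ems)) if ems else float("nan"),
                "mean_em_percent": 100.0 * float(np.mean(ems)) if ems else float("nan"),
            })
    return RecoveryReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# DBN generators


TrueCPDs = dict[str, tuple[float, dict[tuple[str, str], float], float]]
"""child -> (intercept, {(parent, 'prev'|'curr'): coefficient}, sigma2)."""


def _topological_taxa(cpds: TrueCPDs) -> list[str]:
    g = nx.DiGraph()
    g.add_nodes_from(cpds)
    for child, (_, parents, _) in cpds.items():
        for (p, slice_) in parents:
            if slice_ == "curr":
                g.add_edge(p, child)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("intra-slice dependencies must be acyclic")
    return list(nx.lexicographical_topological_sort(g))


def _one_step(cpds: TrueCPDs, order, prev: dict, rng, clip: bool) -> dict:
    curr: dict[str, float] = {}
    for child in order:
        lam0, parents, sigma2 = cpds[child]
        mean = lam0
        for (p, slice_), lam in parents.items():
            mean += lam * (prev[p] if slice_ == "prev" else curr[p])
        val = mean + rng.normal(0.0, np.sqrt(sigma2))
        curr[child] = max(0.0, val) if clip else val
    return curr


def simulate_dbn_cohort(cpds: TrueCPDs, n_subjects: int, n_timepoints: int,
                        seed: int = 0, init_means: dict[str, float] | None = None,
                        init_sd: float = 0.05, rate: float = 1.0) -> LongitudinalDataset:
    """Forward-sample taxa trajectories from a known transition model.

    At every step taxa are sampled in topological order of the intra-slice
    dependencies, negatives are clipped to 0 and the composition is
    renormalized to sum to 1 per time point.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    order = _topological_taxa(cpds)
    taxa = sorted(cpds)
    if init_means is None:
        init_means = {t: 1.0 / len(taxa) for t in taxa}
    samples = []
    times = rate * np.arange(n_timepoints)
    for s in range(n_subjects):
        state = {t: max(0.0, init_means[t] + rng.normal(0.0, init_sd))
                 for t in taxa}
        state = _renormalize(state)
        traj = {t: [state[t]] for t in taxa}
        for _ in range(n_timepoints - 1):
            state = _renormalize(_one_step(cpds, order, state, rng, clip=True))
            for t in taxa:
                traj[t].append(state[t])
        profiles = {t: TaxonProfile(t, times.copy(), np.array(traj[t]))
                    for t in taxa}
        samples.append(SubjectSample(f"subject_{s:02d}", profiles))
    return LongitudinalDataset(samples)


def _renormalize(state: dict[str, float]) -> dict[str, float]:
    total = sum(state.values())
    if total <= 0:
        return {t: 1.0 / len(state) for t in state}
    return {t: v / total for t, v in state.items()}


def simulate_transition_data(cpds: TrueCPDs, n_rows: int, seed: int = 0,
                             prev_means: dict[str, float] | None = None,
                             prev_sd: float = 0.15,
                             n_subjects: int = 10) -> TransitionDataset:
    """Raw two-slice sampler (no clipping, no renormalization).

    Previous-slice values are drawn i.i.d. Gaussian, current-slice values
    follow the conditional linear Gaussian model exactly — the generator for
    parameter- and structure-recovery tests where the fitted coefficients
    must converge to the generating ones.
    """
    rng = np.random.default_rng(seed)
    order = _topological_taxa(cpds)
    taxa = sorted(cpds)
    if prev_means is None:
        prev_means = {t: 0.5 for t in taxa}
    prev_rows, curr_rows = [], []
    for _ in range(n_rows):
        prev = {t: prev_means[t] + rng.normal(0.0, prev_sd) for t in taxa}
        curr = _one_step(cpds, order, prev, rng, clip=False)
        prev_rows.append(prev)
        curr_rows.append(curr)
    subjects = np.array([f"subject_{i % n_subjects:02d}" for i in range(n_rows)],
                        dtype=object)
    return TransitionDataset(pd.DataFrame(prev_rows), pd.DataFrame(curr_rows),
                             subjects, taxa)
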