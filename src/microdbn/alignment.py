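"""Linear temporal alignment of subjects onto a reference subject.

Subjects progress through the same underlying biological program at
different rates (gestational maturity, age, environment...).  Before any
cross-subject model is learned, every subject i is therefore warped onto a
common reference time axis with a first-degree map

    tau_i(t) = (t - b) / a,      a > 0,

which takes a reference time t to the corresponding time on subject i's own
clock.  The warp parameters minimize the microbiome alignment error

    E_M(r, i) = sum_{j in S} e^j(r, i),
    e^j(r, i) = int_alpha^beta (s_i^j(tau_i(t)) - s_r^j(t))^2 dt / (beta - alpha),

where s^j are the fitted spline curves, S the contributing taxa and
[alpha, beta] the overlap between the reference domain and the warped sample
domain.  The search is an exhaustive sweep of a dense (a, b) grid subject to
a > 0, alpha < beta and a minimum overlap fraction epsilon.

The module also selects the reference subject, filters outlying subjects by
the mu + 2*delta rule on E_M, and picks the taxa that contribute to at least
half of the pairwise alignments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._grid import scan_error_surface
from .dataset import LongitudinalDataset, SubjectSample, TaxonProfile
from .splines import SplineProfile, evaluate_spline

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentTransform:
    """Linear warp: reference time t -> sample time (t - b) / a, with a > 0."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scale a must be positive")

    def to_sample_time(self, t):
        return (np.asarray(t, float) - self.b) / self.a

    def to_reference_time(self, t_sample):
        return self.a * np.asarray(t_sample, float) + self.b

    @classmethod
    def identity(cls) -> "AlignmentTransform":
        return cls(1.0, 0.0)


@dataclass
class PairwiseAlignment:
    """Result of aligning one sample to the reference."""

    reference_id: str
    sample_id: str
    transform: AlignmentTransform
    interval: tuple[float, float]
    per_taxon_error: dict[str, float]
    total_error: float
    taxa_used: frozenset[str]

    @property
    def alpha(self) -> float:
        return self.interval[0]

    @property
    def beta(self) -> float:
        return self.interval[1]


@dataclass
class GridConfig:
    """Parameter grid and constraints of the alignment search.

    Defaults reproduce the standard sweep: a in (0, 4] step 0.01 (401 grid
    lines excluding 0, i.e. 400 values), b in [-50, 50] step 0.5 (201
    values), minimum overlap fraction epsilon = 0.3.  ``min_abundance`` is
    the taxon-eligibility floor on mean abundance, 0.001 on the fraction
    scale (= 0.1%).  ``quadrature_points`` is used when an individual taxon
    error is computed for a single transform; the grid scan itself uses a
    lattice trapezoid rule with step ``b_step`` (see :mod:`microdbn._grid`).
    """

    a_max: float = 4.0
    a_step: float = 0.01
    b_min: float = -50.0
    b_max: float = 50.0
    b_step: float = 0.5
    epsilon: float = 0.3
    quadrature_points: int = 101
    min_abundance: float = 0.001
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        if self.a_step <= 0 or self.b_step <= 0:
            raise ValueError("grid steps must be positive")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")

    @property
    def a_values(self) -> np.ndarray:
        n = int(round(self.a_max / self.a_step))
        return self.a_step * np.arange(1, n + 1)

    @property
    def b_values(self) -> np.ndarray:
        n = int(round((self.b_max - self.b_min) / self.b_step))
        return self.b_min + self.b_step * np.arange(n + 1)


def alignment_interval(transform: AlignmentTransform,
                       ref_domain: tuple[float, float],
                       sample_domain: tuple[float, float]):
    """Overlap [alpha, beta] of the reference domain with the warped sample
    domain, on the reference time scale.  ``None`` if they do not overlap."""
    t_min, t_max = ref_domain
    alpha = max(t_min, transform.to_reference_time(sample_domain[0]))
    beta = min(t_max, transform.to_reference_time(sample_domain[1]))
    if alpha >= beta:
        return None
    return (float(alpha), float(beta))


def taxon_alignment_error(ref_spline: SplineProfile, sample_spline: SplineProfile,
                          transform: AlignmentTransform,
                          interval: tuple[float, float],
                          quadrature_points: int = 101) -> float:
    """e^j: mean squared difference between warped sample and reference curves
    over [alpha, beta], by composite trapezoid on ``quadrature_points`` nodes."""
    alpha, beta = interval
    if beta <= alpha:
        raise ValueError("alignment interval must satisfy alpha < beta")
    t = np.linspace(alpha, beta, quadrature_points)
    ref_vals = evaluate_spline(ref_spline, np.clip(t, *ref_spline.domain))
    warped = np.clip(transform.to_sample_time(t), *sample_spline.domain)
    smp_vals = evaluate_spline(sample_spline, warped)
    integrand = (smp_vals - ref_vals) ** 2
    return float(np.trapezoid(integrand, t) / (beta - alpha))


def microbiome_alignment_error(ref: SubjectSample, sample: SubjectSample,
                               transform: AlignmentTransform,
                               taxa: set[str] | frozenset[str],
                               cfg: GridConfig | None = None) -> float:
    """E_M: sum of per-taxon alignment errors over the contributing taxa."""
    cfg = cfg or GridConfig()
    if not taxa:
        raise ValueError("taxa set must be nonempty")
    interval = alignment_interval(transform, ref.domain, sample.domain)
    if interval is None:
        raise ValueError("no overlap between reference and warped sample")
    return float(sum(
        taxon_alignment_error(ref.spline(j, cfg.smoothing),
                              sample.spline(j, cfg.smoothing),
                              transform, interval, cfg.quadrature_points)
        for j in sorted(taxa)))


def eligible_taxa(ref: SubjectSample, sample: SubjectSample,
                  min_abundance: float = 0.001) -> frozenset[str]:
    """Taxa usable for aligning ``sample`` to ``ref``: present in both, mean
    abundance >= 0.1% and nonzero variance in both (over original points)."""
    out = []
    for taxon in set(ref.profiles) & set(sample.profiles):
        ok = True
        for subj in (ref, sample):
            v = subj.profiles[taxon].values
            if v.mean() < min_abundance or v.var() == 0:
                ok = False
                break
        if ok:
            out.append(taxon)
    return frozenset(out)


def align_pair(ref: SubjectSample, sample: SubjectSample,
               cfg: GridConfig | None = None):
    """Exhaustive grid search for the warp minimizing E_M.

    Returns a :class:`PairwiseAlignment`, or ``None`` when no grid point
    satisfies the overlap constraint or no taxon is eligible.  Ties on E_M
    are broken toward the near-identity warp (smallest |a - 1|, then |b|,
    then scan order), so self-alignment deterministically returns (1, 0).
    """
    cfg = cfg or GridConfig()
    taxa = eligible_taxa(ref, sample, cfg.min_abundance)
    if not taxa:
        logger.info("no eligible taxa for %s vs %s", ref.subject_id, sample.subject_id)
        return None
    order = sorted(taxa)
    ref_splines = [ref.spline(j, cfg.smoothing) for j in order]
    smp_splines = [sample.spline(j, cfg.smoothing) for j in order]
    a_vals, b_vals = cfg.a_values, cfg.b_values
    surface = scan_error_surface(ref_splines, smp_splines, a_vals, b_vals,
                                 cfg.b_step, ref.domain, sample.domain,
                                 cfg.epsilon)
    finite = np.isfinite(surface)
    if not finite.any():
        logger.info("no feasible alignment for %s vs %s", ref.subject_id,
                    sample.subject_id)
        return None
    e_min = surface[finite].min()
    ai_all, bi_all = np.nonzero(surface == e_min)
    keys = [(abs(a_vals[ai] - 1.0), abs(b_vals[bi]), i)
            for i, (ai, bi) in enumerate(zip(ai_all, bi_all))]
    best = min(range(len(keys)), key=keys.__getitem__)
    ai, bi = int(ai_all[best]), int(bi_all[best])
    transform = AlignmentTransform(float(a_vals[ai]), float(b_vals[bi]))
    interval = alignment_interval(transform, ref.domain, sample.domain)
    per_taxon = {
        j: taxon_alignment_error(ref.spline(j, cfg.smoothing),
                                 sample.spline(j, cfg.smoothing),
                                 transform, interval, cfg.quadrature_points)
        for j in order}
    return PairwiseAlignment(ref.subject_id, sample.subject_id, transform,
                             interval, per_taxon, float(sum(per_taxon.values())),
                             taxa)


def select_reference(ds: LongitudinalDataset, cfg: GridConfig | None = None,
                     min_fraction: float = 0.9):
    """Pick the reference subject and return its pairwise alignments.

    Every subject is tried as candidate reference; a candidate qualifies if
    it aligns at least ``min_fraction`` (default 90%) of the other subjects,
    and among qualifying candidates the one with the smallest summed E_M
    wins (ties: more aligned samples, then lexicographic id).  If nobody
    qualifies, the subject with the longest time span is used (ties: more
    measured points, then lexicographic id).
    """
    cfg = cfg or GridConfig()
    if len(ds) < 2:
        raise ValueError("reference selection needs at least two subjects")
    all_alignments: dict[str, dict[str, PairwiseAlignment | None]] = {}
    stats = []
    for cand in ds.samples:
        al = {other.subject_id: align_pair(cand, other, cfg)
              for other in ds.samples if other.subject_id != cand.subject_id}
        all_alignments[cand.subject_id] = al
        ok = [a for a in al.values() if a is not None]
        stats.append((cand.subject_id, len(ok), sum(a.total_error for a in ok)))
    n_others = len(ds) - 1
    qualifying = [(sid, n_ok, tot) for sid, n_ok, tot in stats
                  if n_ok >= min_fraction * n_others]
    if qualifying:
        ref_id = min(qualifying, key=lambda s: (s[2], -s[1], s[0]))[0]
    else:
        spans = {s.subject_id: (s.domain[1] - s.domain[0], s.n_points)
                 for s in ds.samples}
        ref_id = min(spans, key=lambda sid: (-spans[sid][0], -spans[sid][1], sid))
        logger.info("no candidate aligned >= %.0f%% of samples; "
                    "falling back to longest-span subject %s",
                    100 * min_fraction, ref_id)
    return ref_id, all_alignments[ref_id]


def filter_outliers(alignments: list[PairwiseAlignment]):
    """One-pass mu + 2*delta filter on E_M (sample standard deviation).

    Returns ``(kept, removed)``.  Strict inequality: when all errors are
    equal nothing is removed.
    """
    if len(alignments) < 2:
        raise ValueError("outlier filtering needs at least two alignments")
    errors = np.array([a.total_error for a in alignments])
    mu = errors.mean()
    delta = errors.std(ddof=1)
    threshold = mu + 2.0 * delta
    kept = [a for a, e in zip(alignments, errors) if e <= threshold]
    removed = [a for a, e in zip(alignments, errors) if e > threshold]
    return kept, removed


def select_taxa_from_alignments(alignments: list[PairwiseAlignment]) -> frozenset[str]:
    """Taxa contributing to at least half (>= ceil(n/2)) of the alignments."""
    if not alignments:
        raise ValueError("need at least one alignment")
    n = len(alignments)
    need = math.ceil(n / 2)
    counts: dict[str, int] = {}
    for a in alignments:
        for t in a.taxa_used:
            counts[t] = counts.get(t, 0) + 1
    return frozenset(t for t, c in counts.items() if c >= need)


@dataclass
class AlignedDataset:
    """A cohort placed on the reference time axis.

    ``samples`` hold each kept subject with its times mapped through the
    inverse warp t = a*t' + b onto the reference scale; the reference is
    included unchanged.  ``alignments`` records each subject's warp and
    aligned interval; ``taxa`` is the selected contributing-taxa set.
    """

    reference_id: str
    samples: list[SubjectSample]
    alignments: dict[str, PairwiseAlignment]
    removed: list[PairwiseAlignment]
    taxa: list[str]
    variables: dict[str, str] = field(default_factory=dict)
    unit: str = "fraction"

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.samples]

    def get_sample(self, subject_id: str) -> SubjectSample:
        for s in self.samples:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def interval(self, subject_id: str) -> tuple[float, float]:
        return self.alignments[subject_id].interval


def _warp_sample(sample: SubjectSample, al: PairwiseAlignment) -> SubjectSample:
    mapped = al.transform.to_reference_time(sample.times)
    profiles = {t: TaxonProfile(t, mapped.copy(), p.values.copy())
                for t, p in sample.profiles.items()}
    return SubjectSample(sample.subject_id, profiles, dict(sample.clinical))


def align_dataset(ds: LongitudinalDataset, cfg: GridConfig | None = None,
                  reference: str | None = None) -> AlignedDataset:
    """Full alignment stage: reference selection (unless ``reference`` is
    given), pairwise warps, outlier removal, taxon selection, and mapping of
    every kept subject onto the reference time axis."""
    cfg = cfg or GridConfig()
    if reference is None:
        ref_id, alignments = select_reference(ds, cfg)
    else:
        ref_id = reference
        ref_sample = ds.get_sample(ref_id)
        alignments = {other.subject_id: align_pair(ref_sample, other, cfg)
                      for other in ds.samples if other.subject_id != ref_id}
    successful = [a for a in alignments.values() if a is not None]
    if len(successful) >= 2:
        kept, removed = filter_outliers(successful)
    else:
        kept, removed = successful, []
    taxa = sorted(select_taxa_from_alignments(kept)) if kept else []

    ref_sample = ds.get_sample(ref_id)
    t_min, t_max = ref_sample.domain
    ident = PairwiseAlignment(ref_id, ref_id, AlignmentTransform.identity(),
                              (t_min, t_max), {j: 0.0 for j in taxa}, 0.0,
                              frozenset(taxa))
    out_samples = [ref_sample]
    out_alignments = {ref_id: ident}
    for al in sorted(kept, key=lambda a: a.sample_id):
        out_samples.append(_warp_sample(ds.get_sample(al.sample_id), al))
        out_alignments[al.sample_id] = al
    return AlignedDataset(ref_id, out_samples, out_alignments, removed, taxa,
                          dict(ds.variables), ds.unit)


class TemporalAligner(BaseEstimator):
    """Estimator wrapper around the alignment stage.

    ``fit`` selects the reference (or uses the one given), computes all
    pairwise warps, filters outliers and selects taxa; ``transform`` returns
    the :class:`AlignedDataset`.  Parameters mirror :class:`GridConfig`.
    """

    def __init__(self, a_max=4.0, a_step=0.01, b_min=-50.0, b_max=50.0,
                 b_step=0.5, epsilon=0.3, quadrature_points=101,
                 min_abundance=0.001, smoothing=0.0, reference=None):
        self.a_max = a_max
        self.a_step = a_step
        self.b_min = b_min
        self.b_max = b_max
        self.b_step = b_step
        self.epsilon = epsilon
        self.quadrature_points = quadrature_points
        self.min_abundance = min_abundance
        self.smoothing = smoothing
        self.reference = reference

    def _config(self) -> GridConfig:
        return GridConfig(self.a_max, self.a_step, self.b_min, self.b_max,
                          self.b_step, self.epsilon, self.quadrature_points,
                          self.min_abundance, self.smoothing)

    def fit(self, X: LongitudinalDataset, y=None):
        aligned = align_dataset(X, self._config(), reference=self.reference)
        self.reference_id_ = aligned.reference_id
        self.alignments_ = aligned.alignments
        self.removed_ = aligned.removed
        self.selected_taxa_ = list(aligned.taxa)
        self.aligned_ = aligned
        return self

    def transform(self, X: LongitudinalDataset | None = None) -> AlignedDataset:
        if not hasattr(self, "aligned_"):
            raise RuntimeError("TemporalAligner is not fitted")
        return self.aligned_

    def fit_transform(self, X: LongitudinalDataset, y=None) -> AlignedDataset:
        return self.fit(X).transform(X)
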