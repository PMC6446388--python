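"""Per-subject cross-validated prediction accuracy.

The learned DBN is evaluated by leave-one-subject-out cross-validation:
the held-out subject's abundances are predicted from the second grid point
onward, using the previous slice's observations (and observed intra-parent
values at the current slice), normalized to relative abundances, and scored
by mean absolute error against the observed values.  The naive baseline —
predicting that nothing changes between consecutive time points — is the
reference competitor.

MAE is averaged over taxa and time points within each subject, then over
subjects (the pooled average over all rows is also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignedDataset, GridConfig, align_dataset
from .dataset import LongitudinalDataset
from .dbn import (TransitionDataset, build_transition_dataset, hill_climb,
                  normalize_predictions, predict_next)


def naive_baseline_predict(obs_prev):
    """Carry-forward predictor: next abundances equal the previous ones."""
    if isinstance(obs_prev, dict):
        return dict(obs_prev)
    return np.asarray(obs_prev, dtype=float).copy()


def mae(pred, obs) -> float:
    """Mean absolute error over all taxa and predicted time points."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {o.shape}")
    return float(np.mean(np.abs(p - o)))


@dataclass
class CVResult:
    """Cross-validation summary for one method at one sampling rate."""

    method: str
    rate: float
    per_subject: dict[str, float] = field(default_factory=dict)
    pooled: float = float("nan")

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_subject.values())))

    @property
    def std(self) -> float:
        vals = list(self.per_subject.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def _predict_subject(method: str, model, test: TransitionDataset,
                     taxa: list[str]) -> tuple[np.ndarray, np.ndarray]:
    preds, obs = [], []
    for i in range(test.n):
        row_prev, row_curr = test.prev.iloc[i], test.curr.iloc[i]
        if method == "baseline":
            pred = {t: float(row_prev[t]) for t in taxa}
        else:
            pred = predict_next(model, row_prev, row_curr)
            pred = normalize_predictions(pred)
        preds.append([pred[t] for t in taxa])
        obs.append([float(row_curr[t]) for t in taxa])
    return np.asarray(preds), np.asarray(obs)


def per_subject_cv(ds: AlignedDataset | LongitudinalDataset, rate: float,
                   max_parents: int = 3, method: str = "dbn",
                   score: str = "bic", allow_intra: bool = True,
                   taxa=None) -> CVResult:
    """Leave-one-subject-out cross-validation of next-step prediction.

    ``method`` is ``'dbn'`` (learned network, normalized conditional-mean
    predictions) or ``'baseline'`` (carry-forward).  Requires at least two
    subjects.
    """
    if method not in ("dbn", "baseline"):
        raise ValueError("method must be 'dbn' or 'baseline'")
    data = build_transition_dataset(ds, rate, taxa=taxa)
    subjects = sorted(set(map(str, data.subjects)))
    if len(subjects) < 2:
        raise ValueError("per-subject CV needs at least two subjects")
    per_subject: dict[str, float] = {}
    abs_errors = []
    for held_out in subjects:
        train = data.subset([s for s in subjects if s != held_out])
        test = data.subset([held_out])
        if test.n == 0:
            continue
        model = None
        if method == "dbn":
            model = hill_climb(train, max_parents=max_parents, score=score,
                               allow_intra=allow_intra)
        preds, obs = _predict_subject(method, model, test, data.taxa)
        per_subject[held_out] = mae(preds, obs)
        abs_errors.append(np.abs(preds - obs).ravel())
    pooled = float(np.mean(np.concatenate(abs_errors))) if abs_errors else float("nan")
    return CVResult(method, rate, per_subject, pooled)


def compare_aligned_vs_unaligned(ds_raw: LongitudinalDataset, rates,
                                 max_parents: int = 3,
                                 cfg: GridConfig | None = None,
                                 reference: str | None = None,
                                 methods=("baseline", "dbn")) -> pd.DataFrame:
    """Run the CV for each rate and method on the aligned and the unaligned
    variant of the same cohort.

    Both variants contain the same kept subjects (membership decided once by
    the alignment-based outlier filter); the unaligned variant simply skips
    the time warp.  Returns one row per (variant, method, rate).
    """
    aligned = align_dataset(ds_raw, cfg, reference=reference)
    kept_ids = set(aligned.subject_ids)
    unaligned = LongitudinalDataset(
        [s for s in ds_raw.samples if s.subject_id in kept_ids],
        dict(ds_raw.variables), ds_raw.unit)
    rows = []
    for variant, dataset in (("unaligned", unaligned), ("aligned", aligned)):
        for rate in rates:
            for method in methods:
                res = per_subject_cv(dataset, rate, max_parents=max_parents,
                                     method=method, taxa=aligned.taxa)
                rows.append({"variant": variant, "method": method,
                             "rate": rate, "mae_mean": res.mean,
                             "mae_std": res.std, "mae_pooled": res.pooled,
                             "n_subjects": len(res.per_subject)})
    return pd.DataFrame(rows)
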