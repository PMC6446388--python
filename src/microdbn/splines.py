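"""Cubic B-spline representation of abundance trajectories.

Sampling in longitudinal studies is discrete and often non-uniform, while
temporal alignment needs values at arbitrary intermediate times.  Each
taxon trajectory is therefore represented by a cubic B-spline
(knots, coefficients, degree), fitted with FITPACK via
:func:`scipy.interpolate.splrep` and evaluated with
:class:`scipy.interpolate.BSpline`.

The default smoothing factor is 0, i.e. an interpolating spline; a positive
smoothing factor is accepted for noisier data.  Evaluation is restricted to
the observed domain — no extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, splrep

from .dataset import InputError, SubjectSample, TaxonProfile


class SplineFitError(ValueError):
    """Too few points (or otherwise unusable data) for a cubic fit."""


class DomainError(ValueError):
    """Evaluation requested outside the spline's fitted domain."""


@dataclass
class SplineProfile:
    """Cubic B-spline for one taxon trajectory, valid on ``domain`` only."""

    taxon_id: str
    knots: np.ndarray
    coefficients: np.ndarray
    degree: int
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if self.degree != 3:
            raise ValueError("only cubic (degree 3) splines are supported")
        self._bspline = BSpline(self.knots, self.coefficients, self.degree,
                                extrapolate=False)

    def __call__(self, t):
        return evaluate_spline(self, t)


def fit_spline(profile: TaxonProfile, smoothing: float = 0.0) -> SplineProfile:
    """Fit a cubic B-spline to an observed abundance profile.

    With ``smoothing=0`` the spline interpolates the observations exactly;
    larger values trade fidelity for smoothness (FITPACK's ``s``).
    """
    t, y = profile.times, profile.values
    if len(t) < 4:
        raise SplineFitError(
            f"{profile.taxon_id}: cubic spline needs >= 4 points, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise InputError(f"{profile.taxon_id}: duplicate or unordered times")
    knots, coefs, degree = splrep(t, y, k=3, s=smoothing)
    return SplineProfile(profile.taxon_id, knots, coefs, degree,
                         (float(t[0]), float(t[-1])))


def evaluate_spline(s: SplineProfile, t):
    """Evaluate a spline at time(s) ``t`` (days) within its domain."""
    t_arr = np.asarray(t, dtype=float)
    lo, hi = s.domain
    tol = 1e-9 * max(1.0, abs(hi - lo))
    if np.any(t_arr < lo - tol) or np.any(t_arr > hi + tol):
        raise DomainError(
            f"{s.taxon_id}: evaluation at t={t} outside domain [{lo}, {hi}]")
    out = s._bspline(np.clip(t_arr, lo, hi))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def resample_uniform(sample: SubjectSample, rate: float,
                     smoothing: float = 0.0) -> SubjectSample:
    """Resample a subject on a uniform grid ``t_min, t_min+rate, ... <= t_max``.

    Values come from the fitted splines; negative spline excursions are
    clipped to 0 (abundances are nonnegative).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t_min, t_max = sample.domain
    if rate > t_max - t_min:
        raise ValueError(
            f"rate {rate} exceeds domain span {t_max - t_min} of {sample.subject_id}")
    n = int(np.floor((t_max - t_min) / rate + 1e-9)) + 1
    grid = t_min + rate * np.arange(n)
    profiles = {}
    for taxon in sample.profiles:
        spline = sample.spline(taxon, smoothing)
        values = np.clip(evaluate_spline(spline, grid), 0.0, None)
        profiles[taxon] = TaxonProfile(taxon, grid.copy(), values)
    return SubjectSample(sample.subject_id, profiles, dict(sample.clinical))
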