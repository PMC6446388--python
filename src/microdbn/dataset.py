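"""Containers and readers for longitudinal relative-abundance studies.

A study is a :class:`LongitudinalDataset`: one :class:`SubjectSample` per
subject, each holding the subject's sampling grid (days), one
:class:`TaxonProfile` per taxon on that grid, and any clinical/demographic
covariates (static or time-varying, declared discrete or continuous).

Abundances are stored internally as fractions (0-1).  Input tables may use
either the percent (0-100) or fraction convention; the reader detects or is
told the convention and records it so outputs can be emitted in kind.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """The input table does not have the declared/required layout."""


class InputError(ValueError):
    """The input table layout is fine but its content is invalid."""


@dataclass
class TaxonProfile:
    """One taxon's abundance trajectory for one subject.

    ``times`` are days, strictly increasing; ``values`` are nonnegative
    relative abundances on a consistent scale.
    """

    taxon_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        # silently drop incomplete pairs: splines need complete (t, y) pairs
        keep = ~(np.isnan(self.times) | np.isnan(self.values))
        if not keep.all():
            self.times = self.times[keep]
            self.values = self.values[keep]
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InputError(f"{self.taxon_id}: times and values must be 1-D and equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise InputError(f"{self.taxon_id}: times must be strictly increasing")
        if np.any(self.values < 0):
            raise InputError(f"{self.taxon_id}: negative abundance")

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass
class SubjectSample:
    """All measurements for one subject: taxa profiles on a shared time grid
    plus clinical covariates.

    ``clinical`` maps a variable name either to a scalar (static covariate) or
    to a ``(times, values)`` pair (time-varying covariate).
    """

    subject_id: str
    profiles: dict[str, TaxonProfile]
    clinical: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._splines: dict = {}

    @property
    def times(self) -> np.ndarray:
        """The subject's shared sampling grid (taken from any profile)."""
        first = next(iter(self.profiles.values()))
        return first.times

    @property
    def domain(self) -> tuple[float, float]:
        t = self.times
        t_min, t_max = float(t[0]), float(t[-1])
        if not t_min < t_max:
            raise InputError(f"{self.subject_id}: degenerate time domain")
        return t_min, t_max

    @property
    def n_points(self) -> int:
        return len(self.times)

    def spline(self, taxon_id: str, smoothing: float = 0.0):
        """Fitted (and cached) cubic B-spline for one taxon."""
        from .splines import fit_spline

        key = (taxon_id, smoothing)
        if key not in self._splines:
            self._splines[key] = fit_spline(self.profiles[taxon_id], smoothing=smoothing)
        return self._splines[key]

    def clinical_at(self, name: str, t: float):
        """Covariate value at time ``t`` (nearest observation if time-varying)."""
        value = self.clinical[name]
        if isinstance(value, tuple) and len(value) == 2 and np.ndim(value[1]) == 1:
            vt, vv = np.asarray(value[0], float), np.asarray(value[1])
            return vv[int(np.argmin(np.abs(vt - t)))]
        return value


@dataclass
class LongitudinalDataset:
    """A cohort of :class:`SubjectSample` with a shared taxa/variable registry.

    ``variables`` maps clinical variable name to ``"discrete"`` or
    ``"continuous"``.  ``unit`` records the convention of the source data
    (``"fraction"`` or ``"percent"``); values are stored as fractions.
    """

    samples: list[SubjectSample]
    variables: dict[str, str] = field(default_factory=dict)
    unit: str = "fraction"

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise InputError("duplicate subject ids")
        for kind in self.variables.values():
            if kind not in ("discrete", "continuous"):
                raise SchemaError(f"unknown variable kind {kind!r}")

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            for t in s.profiles:
                seen.setdefault(t, None)
        return list(seen)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.samples]

    def get_sample(self, subject_id: str) -> SubjectSample:
        for s in self.samples:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# reading


_LONG_COLUMNS = ("subject", "time", "taxon", "abundance")


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def _load_schema(schema) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, (str, os.PathLike)):
        with open(schema) as fh:
            return yaml.safe_load(fh) or {}
    return dict(schema)


def _detect_unit(df: pd.DataFrame) -> str:
    totals = df.groupby(["subject", "time"])["abundance"].sum()
    return "percent" if float(totals.median()) > 1.5 else "fraction"


def read_dataset(abundance_path, metadata_path=None, schema=None) -> LongitudinalDataset:
    """Read a long-format abundance table (+ optional metadata) into a dataset.

    Parameters
    ----------
    abundance_path
        CSV/TSV with columns ``subject, time, taxon, abundance`` (long format)
        or, with ``schema={"format": "wide", ...}``, a per-subject wide table
        (rows = taxa, columns = times).
    metadata_path
        Optional CSV/TSV keyed by ``subject`` (and optionally ``time``) with
        clinical/demographic covariates.
    schema
        Dict or YAML path declaring ``format`` (``long``/``wide``), ``unit``
        (``auto``/``percent``/``fraction``), ``time_scale`` (multiplier
        converting the table's time unit into days, default 1), ``columns``
        (renames), and ``variables`` (name -> ``discrete``/``continuous``).
    """
    cfg = _load_schema(schema)
    fmt = cfg.get("format", "long")
    time_scale = float(cfg.get("time_scale", 1.0))

    if fmt == "wide":
        wide = _read_table(abundance_path)
        subject = cfg.get("subject", os.path.splitext(os.path.basename(str(abundance_path)))[0])
        taxa = wide.iloc[:, 0].astype(str)
        times = [float(c) for c in wide.columns[1:]]
        df = wide.iloc[:, 1:].set_axis(times, axis=1).set_axis(taxa, axis=0)
        df = df.stack().rename("abundance").reset_index()
        df.columns = ["taxon", "time", "abundance"]
        df["subject"] = subject
    elif fmt == "long":
        df = _read_table(abundance_path)
        renames = {v: k for k, v in cfg.get("columns", {}).items()}
        df = df.rename(columns=renames)
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    else:
        raise SchemaError(f"unknown table format {fmt!r}")

    if df["abundance"].isna().all():
        raise InputError("abundance column is empty")
    if df.duplicated(subset=["subject", "time", "taxon"]).any():
        raise InputError("duplicate (subject, time, taxon) rows")
    if (df["abundance"].dropna() < 0).any():
        raise InputError("negative abundances")

    df = df.copy()
    df["time"] = df["time"].astype(float) * time_scale
    unit = cfg.get("unit", "auto")
    if unit == "auto":
        unit = _detect_unit(df)
    if unit not in ("percent", "fraction"):
        raise SchemaError(f"unknown unit convention {unit!r}")
    if unit == "percent":
        df["abundance"] = df["abundance"] / 100.0

    meta = None
    if metadata_path is not None:
        meta = _read_table(metadata_path)
        if "subject" not in meta.columns:
            raise SchemaError("metadata table must have a 'subject' column")

    declared = dict(cfg.get("variables", {}))
    variables: dict[str, str] = {}
    samples = []
    for subject_id, grp in df.groupby("subject", sort=True):
        profiles = {}
        for taxon, tg in grp.groupby("taxon", sort=True):
            tg = tg.sort_values("time")
            profiles[str(taxon)] = TaxonProfile(str(taxon), tg["time"].to_numpy(),
                                                tg["abundance"].to_numpy())
        clinical = {}
        if meta is not None:
            rows = meta[meta["subject"].astype(str) == str(subject_id)]
            for col in meta.columns:
                if col in ("subject", "time"):
                    continue
                if "time" in meta.columns and len(rows) > 1:
                    clinical[col] = (rows["time"].to_numpy(float) * time_scale,
                                     rows[col].to_numpy())
                elif len(rows):
                    clinical[col] = rows[col].iloc[0]
                kind = declared.get(col)
                if kind is None:
                    kind = "continuous" if pd.api.types.is_numeric_dtype(meta[col]) else "discrete"
                variables[col] = kind
        samples.append(SubjectSample(str(subject_id), profiles, clinical))

    return LongitudinalDataset(samples, variables, unit=unit)


def filter_short_samples(ds: LongitudinalDataset, min_points: int = 9) -> LongitudinalDataset:
    """Drop subjects with fewer than ``min_points`` measured time points.

    Sparse series cannot support a trustworthy cubic smoothing fit, so they
    are excluded before spline fitting.  The input dataset is left unchanged.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    kept = [s for s in ds.samples if s.n_points >= min_points]
    return replace(ds, samples=list(kept))
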