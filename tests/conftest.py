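import numpy as np
import pandas as pd
import pytest

from microdbn import LongitudinalDataset, SubjectSample, TaxonProfile


def make_profile(taxon="t1", times=None, values=None):
    if times is None:
        times = np.arange(10, dtype=float)
    if values is None:
        values = np.full(len(times), 0.5)
    return TaxonProfile(taxon, np.asarray(times, float), np.asarray(values, float))


def make_sample(subject_id="s1", n_taxa=2, times=None, rng=None, clinical=None):
    """Subject with smooth, distinct, positive taxon trajectories."""
    if times is None:
        times = np.linspace(0.0, 27.0, 10)
    times = np.asarray(times, float)
    rng = rng or np.random.default_rng(0)
    profiles = {}
    for j in range(n_taxa):
        phase = rng.uniform(0, np.pi)
        vals = 0.3 + 0.1 * np.sin(2 * np.pi * times / (times[-1] + 1) + phase)
        profiles[f"taxon_{j + 1}"] = TaxonProfile(f"taxon_{j + 1}", times.copy(), vals)
    return SubjectSample(subject_id, profiles, clinical or {})


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(1)
    samples = [make_sample(f"s{i}", n_taxa=3, rng=rng) for i in range(3)]
    return LongitudinalDataset(samples)


@pytest.fixture
def long_table(tmp_path):
    """Long-format CSV: 2 subjects x 3 taxa x 10 times, fraction scale."""
    rng = np.random.default_rng(3)
    rows = []
    for s in ("a", "b"):
        for taxon in ("t1", "t2", "t3"):
            base = rng.uniform(0.1, 0.5)
            for t in range(10):
                rows.append({"subject": s, "time": float(3 * t), "taxon": taxon,
                             "abundance": base + 0.01 * t})
    path = tmp_path / "abund.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
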