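"""Two-slice dynamic Bayesian network with conditional linear Gaussian nodes.

The model couples two consecutive time slices t_i and t_{i+1} of a uniformly
resampled, aligned cohort.  Nodes are microbial taxa (continuous) and
clinical covariates (continuous or discrete); only taxon nodes at t_{i+1}
receive edges, either *inter* edges from any node at t_i or *intra* edges
from nodes at t_{i+1} (kept acyclic within the slice).

Each taxon node y with continuous parents u_1..u_k is modeled as

    y | u_1..u_k  ~  N(lambda_0 + sum_i lambda_i * u_i, sigma^2),

with a separate coefficient set per configuration of its discrete parents.
Parameters are maximum-likelihood (ordinary least squares, MLE residual
variance).  Structure search is greedy hill climbing from a *baseline*
structure (each taxon linked only to itself across slices), adding one edge
at a time — the one with the largest gain of the network score

    BIC(G, D) = log P(D | Theta, G) - d/2 * log N,

until no addition improves it.  d is the free-parameter count and N the
number of transitions.  AIC is available as an alternative score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .alignment import AlignedDataset
from .dataset import LongitudinalDataset

__all__ = [
    "NodeSpec", "DBNStructure", "GaussianCPD", "DiscreteCPD", "DBNModel",
    "TransitionDataset", "DynamicBayesianNetwork", "build_transition_dataset",
    "fit_gaussian_cpd", "log_likelihood", "bic_score", "baseline_structure",
    "hill_climb", "predict_next", "normalize_predictions",
    "bootstrap_edge_support", "infer_edge_signs", "build_nodes", "fit_model",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class NodeSpec:
    """One variable of the study (instantiated at both slices)."""

    name: str
    role: str  # 'taxon' | 'clinical'
    kind: str  # 'continuous' | 'discrete'

    def __post_init__(self):
        if self.role == "taxon" and self.kind != "continuous":
            raise ValueError("taxon nodes must be continuous")


def build_nodes(taxa: list[str], variables: dict[str, str] | None = None) -> dict[str, NodeSpec]:
    nodes = {t: NodeSpec(t, "taxon", "continuous") for t in taxa}
    for name, kind in (variables or {}).items():
        nodes[name] = NodeSpec(name, "clinical", kind)
    return nodes


@dataclass
class DBNStructure:
    """Two-slice graph: inter edges (t_i -> taxon@t_{i+1}) and intra edges
    (t_{i+1} -> taxon@t_{i+1}), with a per-child parent cap."""

    nodes: dict[str, NodeSpec]
    inter_edges: set[tuple[str, str]] = field(default_factory=set)
    intra_edges: set[tuple[str, str]] = field(default_factory=set)
    max_parents: int = 3

    @property
    def taxa(self) -> list[str]:
        return sorted(n for n, s in self.nodes.items() if s.role == "taxon")

    def parents(self, child: str) -> list[tuple[str, str]]:
        """Ordered parent list of a current-slice taxon: (name, slice)."""
        inter = sorted(p for p, c in self.inter_edges if c == child)
        intra = sorted(p for p, c in self.intra_edges if c == child)
        return [(p, "prev") for p in inter] + [(p, "curr") for p in intra]

    def n_parents(self, child: str) -> int:
        return len(self.parents(child))

    def intra_is_acyclic(self) -> bool:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.intra_edges)
        return nx.is_directed_acyclic_graph(g)

    def would_create_intra_cycle(self, parent: str, child: str) -> bool:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.intra_edges)
        g.add_edge(parent, child)
        return not nx.is_directed_acyclic_graph(g)

    def copy(self) -> "DBNStructure":
        return DBNStructure(dict(self.nodes), set(self.inter_edges),
                            set(self.intra_edges), self.max_parents)

    def edges(self) -> list[tuple[str, str, str]]:
        """All edges as (parent, parent_slice, child) triples, sorted."""
        out = [(p, "prev", c) for p, c in self.inter_edges]
        out += [(p, "curr", c) for p, c in self.intra_edges]
        return sorted(out)


def baseline_structure(nodes: dict[str, NodeSpec], max_parents: int = 3) -> DBNStructure:
    """The self-dynamics starting point: each taxon at t_{i+1} depends only on
    itself at t_i; clinical nodes neither emit nor receive edges."""
    taxa = [n for n, s in nodes.items() if s.role == "taxon"]
    return DBNStructure(dict(nodes), {(t, t) for t in taxa}, set(), max_parents)


@dataclass
class TransitionDataset:
    """Stacked consecutive-slice observation pairs across subjects.

    ``prev`` and ``curr`` are row-aligned DataFrames over the same columns
    (taxa + clinical variables); ``subjects`` labels each row's subject.
    """

    prev: pd.DataFrame
    curr: pd.DataFrame
    subjects: np.ndarray
    taxa: list[str]
    variables: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.prev) != len(self.curr):
            raise ValueError("prev/curr row mismatch")
        self.subjects = np.asarray(self.subjects)
        self.prev = self.prev.reset_index(drop=True)
        self.curr = self.curr.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.prev)

    def column(self, name: str, slice_: str) -> pd.Series:
        frame = self.prev if slice_ == "prev" else self.curr
        return frame[name]

    def subset(self, subject_ids) -> "TransitionDataset":
        mask = np.isin(self.subjects, list(subject_ids))
        return TransitionDataset(self.prev[mask], self.curr[mask],
                                 self.subjects[mask], list(self.taxa),
                                 dict(self.variables))

    def resample_subjects(self, rng: np.random.Generator) -> "TransitionDataset":
        """Bootstrap replicate: subjects drawn with replacement."""
        uniq = sorted(set(map(str, self.subjects)))
        chosen = rng.choice(len(uniq), size=len(uniq), replace=True)
        prev_parts, curr_parts, subj_parts = [], [], []
        for i, ui in enumerate(chosen):
            mask = self.subjects.astype(str) == uniq[ui]
            prev_parts.append(self.prev[mask])
            curr_parts.append(self.curr[mask])
            subj_parts.append(np.full(int(mask.sum()), f"{uniq[ui]}#{i}"))
        return TransitionDataset(pd.concat(prev_parts), pd.concat(curr_parts),
                                 np.concatenate(subj_parts), list(self.taxa),
                                 dict(self.variables))


def build_transition_dataset(aligned, rate: float, taxa=None,
                             smoothing: float = 0.0) -> TransitionDataset:
    """Resample every kept subject at ``rate`` days on the shared time axis
    and stack consecutive pairs.

    For an :class:`AlignedDataset` the grid is anchored on the reference
    lattice (t_ref_min + k*rate) restricted to each subject's aligned
    interval, so rows line up across subjects.  A plain
    :class:`LongitudinalDataset` is resampled on each subject's own domain
    (the unaligned variant).  Subjects yielding fewer than two grid points
    are excluded with a warning.
    """
    if isinstance(aligned, AlignedDataset):
        samples = aligned.samples
        taxa = list(taxa if taxa is not None else aligned.taxa)
        variables = dict(aligned.variables)
        origin = aligned.get_sample(aligned.reference_id).domain[0]
        intervals = {s.subject_id: aligned.interval(s.subject_id) for s in samples}
    elif isinstance(aligned, LongitudinalDataset):
        samples = aligned.samples
        taxa = list(taxa if taxa is not None else aligned.taxa)
        variables = dict(aligned.variables)
        origin = None
        intervals = {s.subject_id: s.domain for s in samples}
    else:
        raise TypeError("expected AlignedDataset or LongitudinalDataset")

    prev_rows, curr_rows, subj = [], [], []
    tol = 1e-9
    for sample in samples:
        lo, hi = intervals[sample.subject_id]
        base = lo if origin is None else origin
        k_lo = int(np.ceil((lo - base) / rate - tol))
        k_hi = int(np.floor((hi - base) / rate + tol))
        grid = base + rate * np.arange(k_lo, k_hi + 1)
        if len(grid) < 2:
            warnings.warn(f"subject {sample.subject_id}: fewer than two grid "
                          f"points at rate {rate}; excluded")
            continue
        cols: dict[str, np.ndarray] = {}
        for taxon in taxa:
            spline = sample.spline(taxon, smoothing)
            d0, d1 = spline.domain
            vals = np.clip(spline._bspline(np.clip(grid, d0, d1)), 0.0, None)
            cols[taxon] = vals
        for var in variables:
            cols[var] = np.array([sample.clinical_at(var, t) for t in grid])
        frame = pd.DataFrame(cols)
        prev_rows.append(frame.iloc[:-1])
        curr_rows.append(frame.iloc[1:])
        subj.append(np.full(len(grid) - 1, sample.subject_id, dtype=object))

    if not prev_rows:
        empty = pd.DataFrame(columns=list(taxa) + list(variables))
        return TransitionDataset(empty, empty.copy(), np.array([]), taxa, variables)
    return TransitionDataset(pd.concat(prev_rows), pd.concat(curr_rows),
                             np.concatenate(subj), taxa, variables)


# ---------------------------------------------------------------------------
# conditional probability distributions


@dataclass
class GaussianCPD:
    """Conditional linear Gaussian density of one continuous node.

    ``configs`` maps each discrete-parent configuration to
    ``(lambda0, coefficients, sigma2)``; configurations observed with too few
    rows share the ``pooled`` (configuration-free) fit.  With no discrete
    parents there is a single empty-tuple configuration.
    """

    child: str
    continuous_parents: list[tuple[str, str]]
    discrete_parents: list[tuple[str, str]]
    configs: dict[tuple, tuple[float, np.ndarray, float]]
    pooled: tuple[float, np.ndarray, float]
    config_counts: dict[tuple, int]
    n_param_sets: int
    variance_floor: float = 1e-6

    @property
    def n_params(self) -> int:
        # intercept + k slopes + variance, per independently fitted config
        return self.n_param_sets * (len(self.continuous_parents) + 2)

    def _params_for(self, config: tuple):
        return self.configs.get(config, self.pooled)

    def mean(self, config: tuple, u: np.ndarray) -> float:
        lam0, coefs, _ = self._params_for(config)
        return float(lam0 + (coefs @ u if len(coefs) else 0.0))

    def weighted_coefficients(self) -> np.ndarray:
        """Configuration-frequency-weighted regression coefficients."""
        total = sum(self.config_counts.values()) or 1
        acc = np.zeros(len(self.continuous_parents))
        for cfg, cnt in self.config_counts.items():
            _, coefs, _ = self._params_for(cfg)
            acc += (cnt / total) * coefs
        if not self.config_counts:
            acc = self.pooled[1].copy()
        return acc


@dataclass
class DiscreteCPD:
    """Conditional probability table of a discrete node, Laplace-smoothed."""

    child: str
    discrete_parents: list[tuple[str, str]]
    levels: list
    table: dict[tuple, np.ndarray]

    @property
    def n_params(self) -> int:
        return max(1, len(self.table)) * (len(self.levels) - 1)

    def prob(self, config: tuple, value) -> float:
        probs = self.table.get(config)
        if probs is None:  # unseen configuration: uniform (Laplace prior)
            return 1.0 / len(self.levels)
        try:
            return float(probs[self.levels.index(value)])
        except ValueError:  # unseen level
            return 1.0 / (len(self.levels) + 1)


def _design(data: TransitionDataset, parents: list[tuple[str, str]]):
    cont, disc = [], []
    for name, slice_ in parents:
        spec = data.variables.get(name)
        kind = "continuous" if name in data.taxa else spec
        (disc if kind == "discrete" else cont).append((name, slice_))
    X = (np.column_stack([data.column(n, s).to_numpy(float) for n, s in cont])
         if cont else np.empty((data.n, 0)))
    if disc:
        cfg_cols = [data.column(n, s).astype(str).to_numpy() for n, s in disc]
        configs = list(zip(*cfg_cols))
    else:
        configs = [()] * data.n
    return cont, disc, X, configs


def _ols(X: np.ndarray, y: np.ndarray, variance_floor: float):
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sigma2 = max(float(np.mean(resid ** 2)), variance_floor)
    return float(beta[0]), beta[1:].copy(), sigma2


def fit_gaussian_cpd(child: str, parents: list[tuple[str, str]],
                     data: TransitionDataset,
                     variance_floor: float = 1e-6) -> GaussianCPD:
    """Maximum-likelihood conditional linear Gaussian fit for ``child`` at
    the current slice given ``parents`` (list of (name, 'prev'|'curr'))."""
    cont, disc, X, configs = _design(data, parents)
    y = data.curr[child].to_numpy(float)
    pooled = _ols(X, y, variance_floor) if len(y) else (0.0, np.zeros(X.shape[1]), variance_floor)
    config_params: dict[tuple, tuple] = {}
    counts: dict[tuple, int] = {}
    n_sets = 1 if not disc else 0
    if disc:
        arr = np.array(configs, dtype=object)
        uniq = sorted(set(configs))
        used_pooled = False
        for cfg in uniq:
            mask = np.all(arr == np.array(cfg, dtype=object), axis=1)
            counts[cfg] = int(mask.sum())
            if counts[cfg] >= len(cont) + 2:
                config_params[cfg] = _ols(X[mask], y[mask], variance_floor)
                n_sets += 1
            else:  # sparse configuration: share the pooled fit
                used_pooled = True
        if used_pooled or not config_params:
            n_sets += 1
    else:
        config_params[()] = pooled
        counts[()] = len(y)
    return GaussianCPD(child, cont, disc, config_params, pooled, counts,
                       n_sets, variance_floor)


def fit_discrete_cpd(child: str, parents: list[tuple[str, str]],
                     data: TransitionDataset) -> DiscreteCPD:
    _, disc, _, configs = _design(data, parents)
    y = data.curr[child].astype(str).to_numpy()
    levels = sorted(set(y))
    table: dict[tuple, np.ndarray] = {}
    arr = np.array(configs, dtype=object) if disc else None
    for cfg in sorted(set(configs)):
        if disc:
            mask = np.all(arr == np.array(cfg, dtype=object), axis=1)
        else:
            mask = np.ones(len(y), bool)
        counts = np.array([np.sum(y[mask] == lv) for lv in levels], float)
        table[cfg] = (counts + 1.0) / (counts.sum() + len(levels))
    return DiscreteCPD(child, disc, levels, table)


def _gaussian_ll(cpd: GaussianCPD, data: TransitionDataset) -> float:
    if data.n == 0:
        return 0.0
    _, _, X, configs = _design(data, cpd.continuous_parents + cpd.discrete_parents)
    y = data.curr[cpd.child].to_numpy(float)
    ll = 0.0
    arr = np.array(configs, dtype=object)
    for cfg in sorted(set(configs)):
        mask = (np.all(arr == np.array(cfg, dtype=object), axis=1)
                if cpd.discrete_parents else np.ones(len(y), bool))
        lam0, coefs, sigma2 = cpd._params_for(cfg)
        mu = lam0 + (X[mask] @ coefs if len(coefs) else 0.0)
        r = y[mask] - mu
        ll += float(-0.5 * mask.sum() * (LOG2PI + np.log(sigma2))
                    - np.sum(r ** 2) / (2.0 * sigma2))
        if not cpd.discrete_parents:
            break
    return ll


def _discrete_ll(cpd: DiscreteCPD, data: TransitionDataset) -> float:
    if data.n == 0:
        return 0.0
    _, _, _, configs = _design(data, cpd.discrete_parents)
    y = data.curr[cpd.child].astype(str).to_numpy()
    return float(sum(np.log(cpd.prob(cfg, val)) for cfg, val in zip(configs, y)))


@dataclass
class DBNModel:
    """A fitted two-slice DBN: structure, one CPD per current-slice node,
    and its likelihood/score on the training transitions."""

    structure: DBNStructure
    cpds: dict[str, object]
    n_transitions: int
    log_likelihood: float
    bic: float

    @property
    def n_params(self) -> int:
        return int(sum(c.n_params for c in self.cpds.values()))


def fit_model(structure: DBNStructure, data: TransitionDataset,
              variance_floor: float = 1e-6) -> DBNModel:
    """Fit every CPD of ``structure`` by MLE and score the model with BIC.

    Modeled nodes are the current-slice variables: taxa with their structure
    parents, clinical variables as parentless marginals.
    """
    cpds: dict[str, object] = {}
    for taxon in structure.taxa:
        cpds[taxon] = fit_gaussian_cpd(taxon, structure.parents(taxon), data,
                                       variance_floor)
    for name, spec in structure.nodes.items():
        if spec.role == "clinical":
            if spec.kind == "discrete":
                cpds[name] = fit_discrete_cpd(name, [], data)
            else:
                cpds[name] = fit_gaussian_cpd(name, [], data, variance_floor)
    model = DBNModel(structure, cpds, data.n, 0.0, 0.0)
    model.log_likelihood = log_likelihood(model, data)
    model.bic = bic_score(model, data) if data.n else float("nan")
    return model


def log_likelihood(model: DBNModel, data: TransitionDataset) -> float:
    """Joint log-likelihood: sum over rows and modeled nodes of the log
    conditional density/probability.  Empty data gives 0."""
    if data.n == 0:
        return 0.0
    total = 0.0
    for cpd in model.cpds.values():
        total += (_discrete_ll(cpd, data) if isinstance(cpd, DiscreteCPD)
                  else _gaussian_ll(cpd, data))
    return float(total)


def bic_score(model: DBNModel, data: TransitionDataset) -> float:
    """BIC = LL - (d/2) * ln N over the transition rows."""
    if data.n == 0:
        raise ValueError("BIC undefined for empty data")
    ll = log_likelihood(model, data)
    return float(ll - 0.5 * model.n_params * np.log(data.n))


# ---------------------------------------------------------------------------
# structure search


def _family_score(child: str, parents: tuple, data: TransitionDataset,
                  penalty_per_param: float, variance_floor: float,
                  cache: dict) -> float:
    key = (child, parents)
    if key not in cache:
        cpd = fit_gaussian_cpd(child, list(parents), data, variance_floor)
        ll = _gaussian_ll(cpd, data)
        cache[key] = ll - penalty_per_param * cpd.n_params
    return cache[key]


def hill_climb(data: TransitionDataset, max_parents: int = 3,
               score: str = "bic", allow_intra: bool = True,
               variance_floor: float = 1e-6,
               start: DBNStructure | None = None) -> DBNModel:
    """Greedy forward search over edges, starting from the baseline model.

    At each step every legal candidate edge (node@t_i -> taxon@t_{i+1}, or
    node@t_{i+1} -> taxon@t_{i+1} keeping the intra slice acyclic, child
    below ``max_parents``) is scored, and the single edge with the largest
    score gain is added; the search stops when no gain is positive.
    Baseline self-edges are fixed and count toward ``max_parents``.
    Deterministic: ties break lexicographically on (child, parent, inter
    before intra).
    """
    if data.n == 0:
        raise ValueError("cannot learn from empty data")
    if score not in ("bic", "aic"):
        raise ValueError("score must be 'bic' or 'aic'")
    penalty = 0.5 * np.log(data.n) if score == "bic" else 1.0
    nodes = build_nodes(data.taxa, data.variables)
    structure = (start.copy() if start is not None
                 else baseline_structure(nodes, max_parents))
    structure.max_parents = max_parents
    cache: dict = {}
    all_vars = sorted(nodes)

    def fam(child, parents_list):
        return _family_score(child, tuple(parents_list), data, penalty,
                             variance_floor, cache)

    while True:
        best = None  # (gain, child, parent, kind)
        for child in structure.taxa:
            current = structure.parents(child)
            if len(current) >= max_parents:
                continue
            base = fam(child, current)
            for parent in all_vars:
                for kind in ("inter", "intra"):
                    if kind == "intra" and not allow_intra:
                        continue
                    if kind == "inter":
                        if (parent, child) in structure.inter_edges:
                            continue
                        cand = current + [(parent, "prev")]
                    else:
                        if parent == child or (parent, child) in structure.intra_edges:
                            continue
                        if structure.would_create_intra_cycle(parent, child):
                            continue
                        cand = current + [(parent, "curr")]
                    gain = fam(child, sorted(cand, key=lambda p: (p[1], p[0]))) - base
                    entry = (-gain, child, parent, 0 if kind == "inter" else 1)
                    if gain > 1e-9 and (best is None or entry < best):
                        best = entry
        if best is None:
            break
        _, child, parent, kind_i = best
        if kind_i == 0:
            structure.inter_edges.add((parent, child))
        else:
            structure.intra_edges.add((parent, child))
        assert structure.intra_is_acyclic()
    return fit_model(structure, data, variance_floor)


# ---------------------------------------------------------------------------
# prediction & inspection


def _lookup(obs_prev, obs_curr, name: str, slice_: str, child: str):
    source = obs_prev if slice_ == "prev" else obs_curr
    try:
        return source[name]
    except (KeyError, TypeError, IndexError):
        raise ValueError(
            f"missing value for parent {name}@{'t_i' if slice_ == 'prev' else 't_i+1'}"
            f" required to predict {child}") from None


def predict_next(model: DBNModel, obs_prev, obs_curr=None) -> dict[str, float]:
    """Conditional-mean prediction of every taxon at t_{i+1}.

    Inter parents are read from ``obs_prev`` (values at t_i), intra parents
    from ``obs_curr`` (observed values at t_{i+1}).  Negative means are
    clipped to 0.  Mappings/Series keyed by variable name are accepted.
    """
    obs_curr = obs_curr if obs_curr is not None else {}
    out: dict[str, float] = {}
    for taxon in model.structure.taxa:
        cpd: GaussianCPD = model.cpds[taxon]
        config = tuple(str(_lookup(obs_prev, obs_curr, n, s, taxon))
                       for n, s in cpd.discrete_parents)
        u = np.array([float(_lookup(obs_prev, obs_curr, n, s, taxon))
                      for n, s in cpd.continuous_parents])
        out[taxon] = max(0.0, cpd.mean(config, u))
    return out


def normalize_predictions(values) -> np.ndarray:
    """Rescale nonnegative predictions to relative abundances (sum to 1).

    An all-zero vector maps to the uniform composition, with a warning.
    """
    arr = np.asarray(list(values.values()) if isinstance(values, dict) else values,
                     dtype=float)
    total = arr.sum()
    if total == 0:
        warnings.warn("all predictions are zero; returning uniform composition")
        out = np.full(arr.shape, 1.0 / len(arr))
    else:
        out = arr / total
    if isinstance(values, dict):
        return dict(zip(values.keys(), out))
    return out


def bootstrap_edge_support(data: TransitionDataset, max_parents: int = 3,
                           B: int = 50, seed: int = 0,
                           **hill_climb_kwargs) -> dict[tuple[str, str, str], float]:
    """Fraction of subject-resampled replicates in which each edge is
    re-learned.  Edges are (parent, slice, child) triples."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str, str], int] = {}
    for _ in range(B):
        rep = data.resample_subjects(rng)
        model = hill_climb(rep, max_parents=max_parents, **hill_climb_kwargs)
        for edge in model.structure.edges():
            counts[edge] = counts.get(edge, 0) + 1
    return {e: c / B for e, c in sorted(counts.items())}


def infer_edge_signs(model: DBNModel, tie_tol: float = 1e-12) -> dict[tuple[str, str, str], str]:
    """Sign of each continuous-parent edge from its regression coefficient.

    With several discrete-parent configurations the sign of the
    configuration-frequency-weighted coefficient is used; magnitudes below
    ``tie_tol`` are reported as ``'neutral'``.
    """
    signs: dict[tuple[str, str, str], str] = {}
    for taxon in model.structure.taxa:
        cpd: GaussianCPD = model.cpds[taxon]
        coefs = cpd.weighted_coefficients()
        for (name, slice_), lam in zip(cpd.continuous_parents, coefs):
            if abs(lam) < tie_tol:
                sign = "neutral"
            else:
                sign = "positive" if lam > 0 else "negative"
            signs[(name, slice_, taxon)] = sign
    return signs


def model_to_dict(model: DBNModel, supports=None) -> dict:
    """JSON-serializable description of a fitted model (structure, CPD
    parameters, score, optional bootstrap supports)."""
    cpds = {}
    for name, cpd in model.cpds.items():
        if isinstance(cpd, DiscreteCPD):
            cpds[name] = {
                "kind": "discrete",
                "discrete_parents": [list(p) for p in cpd.discrete_parents],
                "levels": list(cpd.levels),
                "table": {"|".join(k): list(map(float, v))
                          for k, v in cpd.table.items()},
            }
        else:
            cpds[name] = {
                "kind": "gaussian",
                "continuous_parents": [list(p) for p in cpd.continuous_parents],
                "discrete_parents": [list(p) for p in cpd.discrete_parents],
                "configs": {"|".join(k): [c[0], list(map(float, c[1])), c[2]]
                            for k, c in cpd.configs.items()},
                "pooled": [cpd.pooled[0], list(map(float, cpd.pooled[1])),
                           cpd.pooled[2]],
                "config_counts": {"|".join(k): v
                                  for k, v in cpd.config_counts.items()},
                "n_param_sets": cpd.n_param_sets,
                "variance_floor": cpd.variance_floor,
            }
    return {
        "nodes": {n: [s.role, s.kind] for n, s in model.structure.nodes.items()},
        "inter_edges": sorted(map(list, model.structure.inter_edges)),
        "intra_edges": sorted(map(list, model.structure.intra_edges)),
        "max_parents": model.structure.max_parents,
        "cpds": cpds,
        "n_transitions": model.n_transitions,
        "log_likelihood": model.log_likelihood,
        "bic": model.bic,
        "bootstrap_support": {" ".join(k): v for k, v in (supports or {}).items()},
    }


def _split_key(key: str) -> tuple:
    return tuple(key.split("|")) if key else ()


def model_from_dict(payload: dict) -> DBNModel:
    """Inverse of :func:`model_to_dict`."""
    nodes = {n: NodeSpec(n, role, kind)
             for n, (role, kind) in payload["nodes"].items()}
    structure = DBNStructure(nodes,
                             {tuple(e) for e in payload["inter_edges"]},
                             {tuple(e) for e in payload["intra_edges"]},
                             payload["max_parents"])
    cpds: dict[str, object] = {}
    for name, spec in payload["cpds"].items():
        if spec["kind"] == "discrete":
            cpds[name] = DiscreteCPD(
                name, [tuple(p) for p in spec["discrete_parents"]],
                list(spec["levels"]),
                {_split_key(k): np.asarray(v) for k, v in spec["table"].items()})
        else:
            cpds[name] = GaussianCPD(
                name, [tuple(p) for p in spec["continuous_parents"]],
                [tuple(p) for p in spec["discrete_parents"]],
                {_split_key(k): (v[0], np.asarray(v[1]), v[2])
                 for k, v in spec["configs"].items()},
                (spec["pooled"][0], np.asarray(spec["pooled"][1]),
                 spec["pooled"][2]),
                {_split_key(k): v for k, v in spec["config_counts"].items()},
                spec["n_param_sets"], spec["variance_floor"])
    return DBNModel(structure, cpds, payload["n_transitions"],
                    payload["log_likelihood"], payload["bic"])


class DynamicBayesianNetwork(BaseEstimator):
    """Estimator interface to two-slice DBN learning.

    ``fit`` expects a :class:`TransitionDataset`; fitted attributes are
    ``model_``, ``structure_``, ``log_likelihood_``, ``bic_``,
    ``edge_signs_`` and (if ``bootstrap > 0``) ``bootstrap_support_``.
    """

    def __init__(self, max_parents: int = 3, score: str = "bic",
                 allow_intra: bool = True, variance_floor: float = 1e-6,
                 bootstrap: int = 0, seed: int = 0):
        self.max_parents = max_parents
        self.score = score
        self.allow_intra = allow_intra
        self.variance_floor = variance_floor
        self.bootstrap = bootstrap
        self.seed = seed

    def fit(self, X: TransitionDataset, y=None):
        self.model_ = hill_climb(X, max_parents=self.max_parents,
                                 score=self.score, allow_intra=self.allow_intra,
                                 variance_floor=self.variance_floor)
        self.structure_ = self.model_.structure
        self.log_likelihood_ = self.model_.log_likelihood
        self.bic_ = self.model_.bic
        self.n_transitions_ = self.model_.n_transitions
        self.edge_signs_ = infer_edge_signs(self.model_)
        if self.bootstrap:
            self.bootstrap_support_ = bootstrap_edge_support(
                X, max_parents=self.max_parents, B=self.bootstrap,
                seed=self.seed, score=self.score, allow_intra=self.allow_intra,
                variance_floor=self.variance_floor)
        return self

    def predict(self, prev: pd.DataFrame, curr: pd.DataFrame | None = None,
                normalize: bool = False) -> pd.DataFrame:
        """Row-wise next-slice taxa predictions (conditional means)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("DynamicBayesianNetwork is not fitted")
        rows = []
        for i in range(len(prev)):
            obs_prev = prev.iloc[i]
            obs_curr = curr.iloc[i] if curr is not None else None
            pred = predict_next(self.model_, obs_prev, obs_curr)
            if normalize:
                pred = normalize_predictions(pred)
            rows.append(pred)
        return pd.DataFrame(rows, index=prev.index)
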