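"""Attributed network export for visualization tools.

The learned two-slice network is written as GraphML (default) or XGMML so
that viewers such as Cytoscape can style it: node size by in-degree, taxon
transparency by mean abundance, edge color by interaction sign, thickness by
the normalized regression coefficient and transparency by bootstrap support.

Edge thickness uses the abundance-weighted, L1-normalized coefficients

    lambda^N_i = (lambda_i * u_bar_i) / sum_j |lambda_j * u_bar_j|,

where u_bar_i is the parent taxon's mean abundance across all training
rows, so that per child the absolute normalized coefficients sum to 1.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET

import networkx as nx
import numpy as np

from .dbn import DBNModel, GaussianCPD, infer_edge_signs


def normalize_edge_coefficients(cpd: GaussianCPD,
                                mean_abundances: dict[str, float]) -> dict[tuple[str, str], float]:
    """Abundance-weighted L1 normalization of one child's coefficients.

    Returns {(parent, slice): lambda^N}.  If every product lambda*u_bar is
    zero, all normalized coefficients are 0 and a warning is issued.
    """
    coefs = cpd.weighted_coefficients()
    products = np.array([lam * mean_abundances.get(name, 0.0)
                         for (name, _), lam in zip(cpd.continuous_parents, coefs)])
    denom = np.sum(np.abs(products))
    if denom == 0:
        warnings.warn(f"{cpd.child}: all weighted coefficients are zero")
        normalized = np.zeros_like(products)
    else:
        normalized = products / denom
    return {parent: float(v)
            for parent, v in zip(cpd.continuous_parents, normalized)}


def _model_graph(model: DBNModel, supports=None, mean_abundances=None) -> nx.DiGraph:
    supports = supports or {}
    mean_abundances = mean_abundances or {}
    signs = infer_edge_signs(model)
    g = nx.DiGraph()
    slices = {"prev": "t_i", "curr": "t_i+1"}
    for name, spec in model.structure.nodes.items():
        for slice_ in ("prev", "curr"):
            g.add_node(f"{name}@{slices[slice_]}", name=name, role=spec.role,
                       slice=slices[slice_],
                       mean_abundance=float(mean_abundances.get(name, 0.0)),
                       in_degree=0)
    lam_norm: dict[tuple[str, str, str], float] = {}
    lam_raw: dict[tuple[str, str, str], float] = {}
    for taxon in model.structure.taxa:
        cpd: GaussianCPD = model.cpds[taxon]
        coefs = cpd.weighted_coefficients()
        # without mean abundances there is nothing to weight by; leave
        # normalized coefficients at 0 rather than warn per child
        norms = normalize_edge_coefficients(cpd, mean_abundances) \
            if cpd.continuous_parents and mean_abundances else {}
        for (parent, lam) in zip(cpd.continuous_parents, coefs):
            lam_raw[(parent[0], parent[1], taxon)] = float(lam)
            lam_norm[(parent[0], parent[1], taxon)] = norms.get(parent, 0.0)
    for parent, slice_, child in model.structure.edges():
        key = (parent, slice_, child)
        u = f"{parent}@{slices[slice_]}"
        v = f"{child}@{slices['curr']}"
        g.add_edge(u, v,
                   type="inter" if slice_ == "prev" else "intra",
                   sign=signs.get(key, "neutral"),
                   lam=lam_raw.get(key, 0.0),
                   lam_norm=lam_norm.get(key, 0.0),
                   bootstrap_support=float(supports.get(key, 0.0)))
    for node in g.nodes:
        g.nodes[node]["in_degree"] = g.in_degree(node)
    return g


def export_network(model: DBNModel, path, supports=None, mean_abundances=None,
                   fmt: str = "graphml") -> None:
    """Write the learned network with all display attributes.

    ``fmt`` is ``'graphml'`` (losslessly re-importable with
    :func:`import_network`) or ``'xgmml'`` (Cytoscape legacy format).
    """
    g = _model_graph(model, supports, mean_abundances)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "xgmml":
        _write_xgmml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network(path) -> nx.DiGraph:
    """Read a previously exported GraphML network back."""
    return nx.read_graphml(path)


def _write_xgmml(g: nx.DiGraph, path) -> None:
    root = ET.Element("graph", {
        "label": "microdbn", "directed": "1",
        "xmlns": "http://www.cs.rpi.edu/XGMML"})
    ids = {n: str(i) for i, n in enumerate(g.nodes)}
    for n, attrs in g.nodes(data=True):
        node = ET.SubElement(root, "node", {"id": ids[n], "label": str(n)})
        for k, v in attrs.items():
            t = "real" if isinstance(v, float) else ("integer" if isinstance(v, int) else "string")
            ET.SubElement(node, "att", {"name": k, "value": str(v), "type": t})
    for u, v, attrs in g.edges(data=True):
        edge = ET.SubElement(root, "edge", {"source": ids[u], "target": ids[v],
                                            "label": f"{u} -> {v}"})
        for k, val in attrs.items():
            t = "real" if isinstance(val, float) else ("integer" if isinstance(val, int) else "string")
            ET.SubElement(edge, "att", {"name": k, "value": str(val), "type": t})
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
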