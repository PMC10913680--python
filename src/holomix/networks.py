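"""Cross-block feature association scores and network exports.

The association between feature i of block A and feature j of block B in a
fitted latent model is the similarity

    M[i, j] = sum_{h <= ncomp} cor(x_i, t_h^A) * cor(y_j, t_h^B)

where t^A, t^B are the component scores of each feature's *own* block (t
and u for a PLS pair). With orthogonal within-block scores the value is
bounded by 1 in absolute value. Thresholding |M| strictly above a cutoff
yields the relevance network; isolated nodes are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import MetadataTable, ValidationError
from .models import LatentModel


@dataclass
class SimilarityNetwork:
    """Thresholded cross-block feature association graph."""

    nodes: list            # (feature_id, block_name)
    edges: list            # (node_a, node_b, weight)
    cutoff: float
    node_attributes: dict = field(default_factory=dict)  # node -> dict

    def __post_init__(self) -> None:
        connected = set()
        for a, b, w in self.edges:
            if abs(w) <= self.cutoff:
                raise ValidationError(
                    f"edge weight {w} does not exceed cutoff {self.cutoff}")
            connected.add(a)
            connected.add(b)
        dangling = [n for n in self.nodes if n not in connected]
        if dangling:
            raise ValidationError(f"isolated nodes present: {dangling[:3]}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for feat, block in self.nodes:
            attrs = dict(self.node_attributes.get((feat, block), {}))
            g.add_node(f"{block}::{feat}", feature=feat, block=block, **attrs)
        for (fa, ba), (fb, bb), w in self.edges:
            g.add_edge(f"{ba}::{fa}", f"{bb}::{fb}", weight=float(w))
        return g


def _score_correlations(model: LatentModel, block: str, ncomp: int) -> np.ndarray:
    """p x ncomp matrix of cor(feature column, component score) within a block."""
    blk = model.block(block)
    X = blk.X
    T = blk.scores[:, :ncomp]
    Xc = X - X.mean(axis=0)
    Tc = T - T.mean(axis=0)
    xs = np.sqrt((Xc ** 2).sum(axis=0))
    ts = np.sqrt((Tc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (Xc.T @ Tc) / np.outer(xs, ts)
    return np.nan_to_num(C, nan=0.0)


def similarity_matrix(model: LatentModel, block_a: str, block_b: str,
                      ncomp: int | None = None) -> pd.DataFrame:
    """Cross-block similarity (summed products of feature-score
    correlations) between all features of `block_a` and `block_b`."""
    H = model.ncomp if ncomp is None else ncomp
    if H > model.ncomp:
        raise ValidationError(f"ncomp {H} exceeds the model's {model.ncomp}")
    Ca = _score_correlations(model, block_a, H)
    Cb = _score_correlations(model, block_b, H)
    return pd.DataFrame(Ca @ Cb.T,
                        index=model.block(block_a).feature_ids,
                        columns=model.block(block_b).feature_ids)


def build_network(sim, cutoff: float, blocks: tuple[str, str] | None = None
                  ) -> SimilarityNetwork:
    """Threshold one similarity matrix (or a mapping of block-pair ->
    matrix) at |weight| > cutoff and drop isolated nodes."""
    if not 0 <= cutoff <= 1:
        raise ValidationError(f"cutoff must lie in [0, 1], got {cutoff}")
    if isinstance(sim, pd.DataFrame):
        sims = {(blocks or ("X", "Y")): sim}
    else:
        sims = dict(sim)
    nodes: list = []
    seen = set()
    edges = []
    for (ba, bb), mat in sims.items():
        arr = mat.to_numpy()
        ii, jj = np.nonzero(np.abs(arr) > cutoff)
        for i, j in zip(ii, jj):
            na, nb = (str(mat.index[i]), ba), (str(mat.columns[j]), bb)
            for node in (na, nb):
                if node not in seen:
                    seen.add(node)
                    nodes.append(node)
            edges.append((na, nb, float(arr[i, j])))
    return SimilarityNetwork(nodes=nodes, edges=edges, cutoff=cutoff)


def class_mean_profiles(model: LatentModel, block: str) -> dict:
    """Per-feature class means of the standardized block values (the outer
    'expression' lines of a circos display)."""
    if model.class_labels is None:
        return {}
    blk = model.block(block)
    labels = np.asarray(model.class_labels, dtype=object)
    out = {}
    for k, feat in enumerate(blk.feature_ids):
        out[feat] = {str(c): float(blk.X[labels == c, k].mean())
                     for c in model.classes_}
    return out


def circos_edges(model: LatentModel, cutoff: float = 0.8,
                 ncomp: int | None = None) -> SimilarityNetwork:
    """Union of thresholded similarity networks over all data-block pairs of
    a multiblock model, with per-feature class-mean profiles attached."""
    names = model.data_block_names
    sims = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sims[(a, b)] = similarity_matrix(model, a, b, ncomp=ncomp)
    net = build_network(sims, cutoff)
    profiles = {blk: class_mean_profiles(model, blk) for blk in names}
    for feat, blk in net.nodes:
        prof = profiles.get(blk, {}).get(feat)
        if prof:
            net.node_attributes[(feat, blk)] = {"class_means": prof}
    return net


def export_network(net: SimilarityNetwork, path, format: str = "graphml",
                   metadata: MetadataTable | None = None) -> None:
    """Write the network as GraphML or JSON (node-link), with block names,
    optional class colors, and full-precision edge weights."""
    g = net.to_networkx()
    if metadata is not None and metadata.class_to_color:
        for node, data in g.nodes(data=True):
            means = data.get("class_means")
            if isinstance(means, dict) and means:
                top = max(means, key=lambda c: means[c])
                g.nodes[node]["color"] = metadata.class_to_color.get(top, "")
    if format == "graphml":
        for node, data in g.nodes(data=True):
            if isinstance(data.get("class_means"), dict):
                data["class_means"] = json.dumps(data["class_means"])
        nx.write_graphml(g, path)
    elif format == "json":
        payload = {
            "cutoff": net.cutoff,
            "nodes": [{"feature": f, "block": b,
                       **net.node_attributes.get((f, b), {})}
                      for f, b in net.nodes],
            "edges": [{"source": {"feature": a[0], "block": a[1]},
                       "target": {"feature": b[0], "block": b[1]},
                       "weight": w} for a, b, w in net.edges],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValidationError(f"unknown format {format!r}")


def read_network(path, format: str = "graphml") -> SimilarityNetwork:
    """Read back a network written by :func:`export_network`."""
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes, attrs = [], {}
        for _, data in g.nodes(data=True):
            node = (data["feature"], data["block"])
            nodes.append(node)
            if "class_means" in data:
                attrs[node] = {"class_means": json.loads(data["class_means"])}
        edges = [((g.nodes[a]["feature"], g.nodes[a]["block"]),
                  (g.nodes[b]["feature"], g.nodes[b]["block"]),
                  float(d["weight"])) for a, b, d in g.edges(data=True)]
        cutoff = min((abs(w) for *_, w in edges), default=1.0)
        return SimilarityNetwork(nodes=nodes, edges=edges,
                                 cutoff=min(cutoff - 1e-12, 1.0) if edges else 1.0,
                                 node_attributes=attrs)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        nodes = [(d["feature"], d["block"]) for d in payload["nodes"]]
        attrs = {(d["feature"], d["block"]): {"class_means": d["class_means"]}
                 for d in payload["nodes"] if "class_means" in d}
        edges = [((e["source"]["feature"], e["source"]["block"]),
                  (e["target"]["feature"], e["target"]["block"]),
                  float(e["weight"])) for e in payload["edges"]]
        return SimilarityNetwork(nodes=nodes, edges=edges,
                                 cutoff=payload["cutoff"], node_attributes=attrs)
    raise ValidationError(f"unknown format {format!r}")
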