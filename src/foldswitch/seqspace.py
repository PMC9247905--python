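"""Sequence-space graphs and prediction-string clustering.

Identity clusters become nodes of a force-directed graph whose edges join
node pairs with mean inter-node aligned identity >= 24%; nodes are
coloured by the share of confident fold-switch calls (>=50% inclusive).
Prediction strings are clustered by affinity propagation on a custom
dissimilarity (identical states 0, coil/structure conflicts 0.5,
helix/strand conflicts 10) to isolate the RfaH-like prediction cluster
used for coevolutionary analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .comparator import FOLD_SWITCHING, SINGLE_FOLDING
from .seqcore import IdentityMatrix, SequenceClusterSet
from .sspred import SSPrediction

logger = logging.getLogger(__name__)

DEFAULT_EDGE_MIN = 0.24
COLOR_FOLD_SWITCHING = "fold_switching"   # teal in the published rendering
COLOR_SINGLE_FOLDING = "single_folding"   # red
COLOR_NO_PREDICTION = "no_prediction"     # gray

# per-column dissimilarity of two prediction states
_STATE_COST = {}
for _a in "HE-":
    for _b in "HE-":
        if _a == _b:
            _STATE_COST[_a + _b] = 0.0
        elif "-" in (_a, _b):
            _STATE_COST[_a + _b] = 0.5
        else:
            _STATE_COST[_a + _b] = 10.0


@dataclass
class SpaceNode:
    cluster_id: int
    members: frozenset[str]
    fraction_fold_switching: float | None
    color_class: str

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SpaceGraph:
    nodes: list[SpaceNode]
    edges: list[tuple[int, int, float]]      # (node a, node b, mean identity)
    layout: dict[int, tuple[float, float]] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.cluster_id, size=node.size,
                       color=node.color_class,
                       fraction=node.fraction_fold_switching)
        for a, b, ident in self.edges:
            g.add_edge(a, b, identity=ident)
        return g

    def write_tsv(self, node_path: str | Path, edge_path: str | Path) -> None:
        with open(node_path, "w") as fh:
            fh.write("cluster_id\tsize\tfraction\tcolor\tx\ty\n")
            for n in self.nodes:
                x, y = self.layout.get(n.cluster_id, (float("nan"),) * 2)
                frac = ("-" if n.fraction_fold_switching is None
                        else f"{n.fraction_fold_switching:.4f}")
                fh.write(f"{n.cluster_id}\t{n.size}\t{frac}\t"
                         f"{n.color_class}\t{x:.6f}\t{y:.6f}\n")
        with open(edge_path, "w") as fh:
            fh.write("a\tb\tidentity\n")
            for a, b, ident in self.edges:
                fh.write(f"{a}\t{b}\t{ident:.4f}\n")


def internode_identity(node_a: Iterable[str], node_b: Iterable[str],
                       matrix: IdentityMatrix) -> float:
    """Mean identity over all cross pairs between two disjoint member sets."""
    a, b = list(node_a), list(node_b)
    if not a or not b:
        raise ValueError("empty node")
    if set(a) & set(b):
        raise ValueError("nodes must be disjoint (self-edges forbidden)")
    idx = {name: k for k, name in enumerate(matrix.ids)}
    vals = [matrix.values[idx[i], idx[j]] for i in a for j in b]
    return float(np.mean(vals))


def build_graph(clusters: SequenceClusterSet, matrix: IdentityMatrix,
                calls: Mapping[str, str],
                edge_min: float = DEFAULT_EDGE_MIN) -> SpaceGraph:
    """One node per identity cluster; edges at mean inter-node identity >= edge_min.

    ``calls`` maps sequence id to its aggregate call; nodes with >=50%
    (inclusive) confident fold-switch calls take the fold-switching colour,
    nodes with no confident calls are 'no_prediction'.
    """
    nodes = []
    for k, members in enumerate(clusters.clusters):
        confident = [calls.get(m) for m in members
                     if calls.get(m) in (FOLD_SWITCHING, SINGLE_FOLDING)]
        if not confident:
            frac, color = None, COLOR_NO_PREDICTION
        else:
            frac = sum(1 for c in confident if c == FOLD_SWITCHING) / len(confident)
            color = COLOR_FOLD_SWITCHING if frac >= 0.5 else COLOR_SINGLE_FOLDING
        nodes.append(SpaceNode(cluster_id=k, members=members,
                               fraction_fold_switching=frac, color_class=color))
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            ident = internode_identity(nodes[i].members, nodes[j].members, matrix)
            if ident >= edge_min:
                edges.append((i, j, ident))
    return SpaceGraph(nodes=nodes, edges=edges)


def layout_graph(graph: SpaceGraph, spring_constant: float = 0.3,
                 iterations: int = 1000, seed: int = 0) -> dict[int, tuple[float, float]]:
    """Fruchterman-Reingold spring layout, normalised to the unit square.

    Deterministic for a fixed seed; the coordinates are stored on the graph
    and returned.
    """
    if not graph.nodes:
        raise ValueError("empty graph")
    g = graph.to_networkx()
    pos = nx.spring_layout(g, k=spring_constant, iterations=iterations,
                           seed=seed)
    xy = np.array([pos[n] for n in g.nodes])
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    layout = {}
    for n, p in zip(g.nodes, xy):
        q = (p - lo) / span
        layout[n] = (float(q[0]), float(q[1]))
    graph.layout = layout
    return layout


def prediction_dissimilarity(a: str, b: str) -> float:
    """Position-wise prediction dissimilarity.

    Identical states cost 0, coil-vs-structure conflicts cost 0.5 and
    helix-vs-strand conflicts cost 10; the score is the sum over positions.
    """
    if len(a) != len(b):
        raise ValueError("prediction strings differ in length")
    return sum(_STATE_COST[x + y] for x, y in zip(a, b))


@dataclass
class PredictionClusterSet:
    ids: list[str]
    labels: np.ndarray
    exemplars: list[int]          # indices into ids
    damping: float
    max_iter: int
    converged: bool

    def members_of(self, label: int) -> list[str]:
        return [i for i, lab in zip(self.ids, self.labels) if lab == label]

    @property
    def n_clusters(self) -> int:
        return len(set(int(x) for x in self.labels))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cluster_id\tmember_id\texemplar_id\n")
            for i, lab in zip(self.ids, self.labels):
                ex = self.ids[self.exemplars[int(lab)]] if self.exemplars else "-"
                fh.write(f"{int(lab)}\t{i}\t{ex}\n")


def cluster_predictions(preds: list[SSPrediction], damping: float = 0.99,
                        max_iter: int = 10000, convergence_iter: int = 100,
                        random_state: int = 0) -> PredictionClusterSet:
    """Affinity propagation on similarity = -dissimilarity.

    Preference defaults to the median similarity (the sklearn default).
    Exactly tied similarities (identical prediction strings are common)
    stall message passing at high damping, so a seeded jitter of 1e-6 cost
    units is added to break ties; it is orders of magnitude below the
    smallest real cost step (0.5).  Non-convergence is flagged, not raised;
    in that degenerate case all predictions fall into a single cluster.
    """
    if len(preds) < 2:
        raise ValueError("need at least 2 predictions to cluster")
    ids = [p.seq_id for p in preds]
    n = len(preds)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = prediction_dissimilarity(preds[i].states, preds[j].states)
            sim[i, j] = sim[j, i] = -d
    rng = np.random.default_rng(random_state)
    jitter = rng.normal(scale=1e-6, size=(n, n))
    sim = sim + (jitter + jitter.T) / 2.0
    np.fill_diagonal(sim, 0.0)
    # heavy damping moves messages ~1% per step, so exemplar choices must be
    # stable for a long window before they are trusted as converged
    model = AffinityPropagation(damping=damping, max_iter=max_iter,
                                affinity="precomputed",
                                convergence_iter=convergence_iter,
                                random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = model.fit_predict(sim)
    converged = model.n_iter_ < max_iter and len(model.cluster_centers_indices_) > 0
    if len(model.cluster_centers_indices_) == 0:
        logger.warning("affinity propagation did not converge; "
                       "returning a single cluster")
        labels = np.zeros(n, dtype=int)
        exemplars = [0]
        converged = False
    else:
        exemplars = [int(k) for k in model.cluster_centers_indices_]
    return PredictionClusterSet(ids=ids, labels=np.asarray(labels, dtype=int),
                                exemplars=exemplars, damping=damping,
                                max_iter=max_iter, converged=converged)


def select_seed_cluster(cluster_set: PredictionClusterSet,
                        seed_id: str) -> list[str]:
    """Members of the cluster containing ``seed_id`` (e.g. E. coli RfaH)."""
    if seed_id not in cluster_set.ids:
        raise KeyError(f"seed {seed_id!r} not among clustered predictions")
    label = int(cluster_set.labels[cluster_set.ids.index(seed_id)])
    return cluster_set.members_of(label)
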