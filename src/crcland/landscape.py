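"""Mutation-landscape analyses on the binary matrix: PCA and the
median-joining network.

PCA is a centered (unscaled — binary columns share a scale) singular value
decomposition; component signs follow the convention that each component's
largest-magnitude gene loading is positive.

The median-joining network generalises the minimum spanning tree over the
observed 0/1 profiles under Hamming distance: candidate "median" vectors
(per-column majority of connected triplets, the Steiner points of binary
characters) are added greedily while they reduce the total connection
cost, then medians not needed on any shortest path between observed
profiles are pruned. With ``epsilon=0`` the network is the most
parsimonious one and contains a minimum spanning tree of the observed
vectors; larger ``epsilon`` admits alternative near-minimal links. The
all-zero "healthy" profile can be injected as an explicit root node.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import BinaryMatrix, collapse_identical_profiles

__all__ = [
    "PcaResult",
    "run_pca",
    "build_mj_network",
    "annotate_network",
    "plot_pca",
]


# --------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    scores: pd.DataFrame                 # samples x components
    explained_variance_fraction: np.ndarray
    loadings: pd.DataFrame               # original columns x components


def run_pca(matrix: BinaryMatrix | pd.DataFrame, n_components: int = 2) -> PcaResult:
    """Centered PCA of the binary matrix via SVD.

    ``explained_variance_fraction`` is each kept component's share of the
    TOTAL variance, so the fractions are non-increasing and sum to at most
    one. Deterministic: each component is oriented so that its
    largest-|loading| entry is positive (first such entry on ties).
    """
    df = matrix.data if isinstance(matrix, BinaryMatrix) else matrix
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, cols)={min(n - 1, p)}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-magnitude loading positive
    for j in range(Vt.shape[0]):
        k = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, k] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    total_var = float((s ** 2).sum())
    frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    scores = pd.DataFrame(
        (U[:, :n_components] * s[:n_components]), index=df.index, columns=comp_names
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=df.columns, columns=comp_names)
    return PcaResult(scores=scores, explained_variance_fraction=frac, loadings=loadings)


def plot_pca(result: PcaResult, path, color_by: Mapping[str, str] | None = None) -> None:
    """Scatter of the first two components, optionally coloured by a
    per-sample categorical annotation (e.g. MSI status)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xs = result.scores.iloc[:, 0]
    ys = result.scores.iloc[:, 1] if result.scores.shape[1] > 1 else 0 * xs
    if color_by:
        cats = sorted({color_by.get(s, "NA") for s in result.scores.index})
        for cat in cats:
            mask = [color_by.get(s, "NA") == cat for s in result.scores.index]
            ax.scatter(xs[mask], ys[mask], label=cat, s=25)
        ax.legend(frameon=False)
    else:
        ax.scatter(xs, ys, s=25)
    evf = result.explained_variance_fraction
    ax.set_xlabel(f"PC1 ({evf[0] * 100:.1f}% var)")
    if len(evf) > 1:
        ax.set_ylabel(f"PC2 ({evf[1] * 100:.1f}% var)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --------------------------------------------------------------------------
# Median-joining network

Vector = tuple[int, ...]


def _hamming(a: Vector, b: Vector) -> int:
    return sum(x != y for x, y in zip(a, b))


def _dist_matrix(vectors: Sequence[Vector]) -> np.ndarray:
    A = np.asarray(vectors, dtype=np.uint8)
    return (A[:, None, :] != A[None, :, :]).sum(axis=2).astype(int)


def _kruskal_from(D: np.ndarray) -> tuple[int, list[tuple[int, int, int]]]:
    """MST of the complete Hamming graph given its distance matrix. Edges
    are processed in (weight, lexicographic endpoint) order — deterministic.
    Returns (total weight, edges as (i, j, w))."""
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, D[iu, ju]))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    total = 0
    mst: list[tuple[int, int, int]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            w = int(D[i, j])
            total += w
            mst.append((i, j, w))
            if len(mst) == n - 1:
                break
    return total, mst


def _kruskal(vectors: Sequence[Vector]) -> tuple[int, list[tuple[int, int, int]]]:
    if len(vectors) <= 1:
        return 0, []
    return _kruskal_from(_dist_matrix(vectors))


def _minimax_distances(n: int, mst: list[tuple[int, int, int]]) -> np.ndarray:
    """Minimax (bottleneck) distance between all pairs: the largest edge on
    the unique MST path."""
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for i, j, w in mst:
        adj[i].append((j, w))
        adj[j].append((i, w))
    mm = np.zeros((n, n), dtype=int)
    for src in range(n):
        stack = [(src, 0)]
        seen = {src}
        while stack:
            node, mx = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    mm[src, nxt] = max(mx, w)
                    stack.append((nxt, max(mx, w)))
    return mm


def _msn_edges(vectors: Sequence[Vector], epsilon: int) -> list[tuple[int, int, int]]:
    """Epsilon-relaxed minimum spanning network: the edge (u, v) is feasible
    iff its Hamming distance is within epsilon of the minimax distance
    between u and v. epsilon=0 yields the union of all minimum spanning
    trees (and always contains one)."""
    n = len(vectors)
    if n <= 1:
        return []
    D = _dist_matrix(vectors)
    _, mst = _kruskal_from(D)
    mm = _minimax_distances(n, mst)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] <= mm[i, j] + epsilon:
                out.append((i, j, int(D[i, j])))
    return out


def _median_vector(u: Vector, v: Vector, w: Vector) -> Vector:
    """Per-column majority of three binary vectors — the (unique) vector
    minimising the total Hamming distance to the triplet."""
    return tuple(1 if (a + b + c) >= 2 else 0 for a, b, c in zip(u, v, w))


def _candidate_medians(vectors: list[Vector], epsilon: int) -> set[Vector]:
    """Majority vectors of all connected triplets (two network links sharing
    a node) that are not already present."""
    edges = _msn_edges(vectors, epsilon)
    neigh: dict[int, set[int]] = {}
    for i, j, _ in edges:
        neigh.setdefault(i, set()).add(j)
        neigh.setdefault(j, set()).add(i)
    present = set(vectors)
    cands: set[Vector] = set()
    for u, nb in neigh.items():
        for v, w in itertools.combinations(sorted(nb), 2):
            m = _median_vector(vectors[u], vectors[v], vectors[w])
            if m not in present:
                cands.add(m)
    return cands


def build_mj_network(
    matrix: BinaryMatrix | pd.DataFrame,
    epsilon: int = 0,
    root_vector: Vector | None = None,
    include_root: bool = True,
    root_label: str = "healthy",
    max_iterations: int = 1000,
) -> nx.Graph:
    """Construct the median-joining network of the cohort's binary profiles.

    Parameters
    ----------
    matrix
        Binary samples x gene-instance matrix; identical profiles are
        collapsed into one node carrying every member sample.
    epsilon
        Relaxation of the minimum spanning network (0 = most parsimonious).
    root_vector, include_root
        The explicit root profile; defaults to the all-zero (mutation-free,
        "healthy") vector. It is treated as an observed node.

    Returns
    -------
    networkx.Graph
        Nodes carry ``vector`` (tuple), ``is_median`` (bool), ``samples``
        (list of sample ids, empty for medians and the root) and ``label``;
        edges carry ``weight`` = Hamming distance. Graph attributes record
        ``epsilon`` and the column labels.
    """
    df = matrix.data if isinstance(matrix, BinaryMatrix) else matrix
    if df.shape[0] == 0:
        raise ValueError("cannot build a network from an empty matrix")
    uniq, _mult, members = collapse_identical_profiles(df)
    observed: dict[Vector, list[str]] = {v: m for v, m in zip(uniq, members)}
    if include_root:
        root = root_vector if root_vector is not None else tuple([0] * df.shape[1])
        if root not in observed:
            observed[root] = []
    else:
        root = None

    obs_vectors = sorted(observed)          # lexicographic — determinism
    vectors: list[Vector] = list(obs_vectors)
    medians: list[Vector] = []

    # -- median generation: greedily add majority vectors while they lower
    #    the minimum connection (MST) cost of the current vector set
    for _ in range(max_iterations):
        D = _dist_matrix(vectors)
        base_cost, _ = _kruskal_from(D)
        A = np.asarray(vectors, dtype=np.uint8)
        n = len(vectors)
        best: tuple[int, Vector] | None = None
        for cand in sorted(_candidate_medians(vectors, epsilon)):
            row = (A != np.asarray(cand, dtype=np.uint8)).sum(axis=1).astype(int)
            Dx = np.zeros((n + 1, n + 1), dtype=int)
            Dx[:n, :n] = D
            Dx[n, :n] = row
            Dx[:n, n] = row
            cost, _ = _kruskal_from(Dx)
            if cost < base_cost and (best is None or cost < best[0]):
                best = (cost, cand)
        if best is None:
            break
        medians.append(best[1])
        vectors.append(best[1])

    # -- prune: medians must sit on a shortest path between two observed
    #    profiles and retain degree >= 3 (a Steiner point of lower degree
    #    never shortens the network)
    while True:
        graph = _as_graph(vectors, observed, medians, epsilon, root, root_label,
                          list(df.columns))
        if not medians:
            break
        lengths = dict(nx.all_pairs_dijkstra_path_length(graph, weight="weight"))
        node_of = {tuple(d["vector"]): n for n, d in graph.nodes(data=True)}
        obs_nodes = [node_of[v] for v in obs_vectors if v in node_of]
        drop: list[Vector] = []
        for m in medians:
            mn = node_of[m]
            if graph.degree(mn) < 3:
                drop.append(m)
                continue
            on_path = any(
                lengths[a][mn] + lengths[mn][b] == lengths[a][b]
                for a, b in itertools.combinations(obs_nodes, 2)
            )
            if not on_path:
                drop.append(m)
        if not drop:
            break
        medians = [m for m in medians if m not in set(drop)]
        vectors = list(obs_vectors) + medians
    return graph


def _as_graph(
    vectors: list[Vector],
    observed: dict[Vector, list[str]],
    medians: list[Vector],
    epsilon: int,
    root: Vector | None,
    root_label: str,
    columns: list[str],
) -> nx.Graph:
    graph = nx.Graph(epsilon=epsilon, columns=columns)
    labels: dict[Vector, str] = {}
    median_rank = {m: k + 1 for k, m in enumerate(medians)}
    for vec in vectors:
        if vec in observed:
            samples = observed[vec]
            if not samples and root is not None and vec == root:
                label = root_label
            else:
                label = "|".join(samples) if samples else "obs"
            graph.add_node(label, vector=vec, is_median=False, samples=list(samples),
                           label=label)
            labels[vec] = label
        else:
            label = f"median_{median_rank[vec]}"
            graph.add_node(label, vector=vec, is_median=True, samples=[], label=label)
            labels[vec] = label
    for i, j, w in _msn_edges(vectors, epsilon):
        graph.add_edge(labels[vectors[i]], labels[vectors[j]], weight=int(w))
    return graph


def annotate_network(
    network: nx.Graph,
    msi_status: Mapping[str, str] | None = None,
    gene_status: Mapping[str, Mapping[str, object]] | None = None,
) -> nx.Graph:
    """Attach per-sample annotations to network nodes (in place).

    ``msi_status`` maps sample id -> status string; ``gene_status`` maps an
    attribute name (e.g. ``"ras_mutated"``) to a per-sample mapping. A node
    hosting several samples gets the "|"-joined sorted unique values; nodes
    without samples (medians, root) get ``"NA"``.
    """
    attrs: dict[str, Mapping[str, object]] = {}
    if msi_status is not None:
        attrs["msi_status"] = msi_status
    for name, mapping in (gene_status or {}).items():
        attrs[name] = mapping
    for node, data in network.nodes(data=True):
        samples = data.get("samples", [])
        for name, mapping in attrs.items():
            vals = sorted({str(mapping[s]) for s in samples if s in mapping})
            network.nodes[node][name] = "|".join(vals) if vals else "NA"
    return network
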