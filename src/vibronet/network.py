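"""Residue/fragment interaction networks: community detection by greedy
modularity maximization, classical-scaling + stress-minimization layouts, and
lossless export.

The community search is a deterministic agglomerative merge: starting from
singletons, the pair of communities with the largest modularity gain ΔQ is
merged (ties broken by the lexicographically smallest representative node
pair) until no merge increases Q.  A node-moving refinement phase then
relocates single nodes between communities (best strictly improving move
first, ties to the smallest node) until Q is locally optimal under both
merges and single-node moves.  Q is the weighted Newman modularity with an
optional resolution parameter γ (γ = 1 reproduces standard modularity).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "modularity",
    "communities",
    "layout",
    "export",
    "import_graph",
]


def _edge_weight(data: dict) -> float:
    return float(data.get("weight", 1.0))


def modularity(graph: nx.Graph, partition: dict, resolution: float = 1.0) -> float:
    """Weighted Newman modularity Q of a node→community-label partition."""
    m2 = 2.0 * sum(_edge_weight(d) for _, _, d in graph.edges(data=True))
    if m2 == 0:
        raise ValueError("graph has no edge weight")
    labels = set(partition.values())
    e = {c: 0.0 for c in labels}  # internal weight fraction
    a = {c: 0.0 for c in labels}  # incident weight fraction
    for u, v, d in graph.edges(data=True):
        w = _edge_weight(d)
        cu, cv = partition[u], partition[v]
        if cu == cv:
            e[cu] += 2.0 * w / m2
        a[cu] += w / m2
        a[cv] += w / m2
    return sum(e[c] - resolution * a[c] ** 2 for c in labels)


def communities(graph: nx.Graph, resolution: float = 1.0) -> tuple[dict, float]:
    """Deterministic greedy modularity maximization.

    Returns ``(labels, Q)`` where ``labels`` maps each node to an integer
    community (communities numbered by their smallest member in sorted node
    order).  The result's Q is never below that of the all-singletons
    partition, and merging stops as soon as no pairwise merge has ΔQ > 0.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    nodes = sorted(graph.nodes, key=lambda n: (str(type(n)), n))
    node_key = {n: i for i, n in enumerate(nodes)}
    m2 = 2.0 * sum(_edge_weight(d) for _, _, d in graph.edges(data=True))
    # community state: representative = min node_key member
    comm_of = {n: node_key[n] for n in nodes}
    members: dict[int, set] = {node_key[n]: {n} for n in nodes}
    a = {c: 0.0 for c in members}
    e = {}  # symmetric dict of inter/intra community weight fractions
    for u, v, d in graph.edges(data=True):
        w = _edge_weight(d) / m2
        cu, cv = comm_of[u], comm_of[v]
        a[cu] += w
        a[cv] += w
        key = (min(cu, cv), max(cu, cv))
        e[key] = e.get(key, 0.0) + (2.0 * w if cu == cv else w)

    def delta_q(ci, cj):
        key = (min(ci, cj), max(ci, cj))
        return 2.0 * (e.get(key, 0.0) - resolution * a[ci] * a[cj])

    while True:
        best = None
        for (ci, cj), _w in e.items():
            if ci == cj:
                continue
            dq = delta_q(ci, cj)
            if best is None or dq > best[0] + 1e-15 or (
                abs(dq - best[0]) <= 1e-15 and (ci, cj) < (best[1], best[2])
            ):
                best = (dq, ci, cj)
        if best is None or best[0] <= 1e-12:
            break
        _, ci, cj = best
        # merge cj into ci (ci < cj)
        members[ci] |= members.pop(cj)
        a[ci] += a.pop(cj)
        new_e = {}
        for (x, y), w in e.items():
            x2 = ci if x == cj else x
            y2 = ci if y == cj else y
            key = (min(x2, y2), max(x2, y2))
            new_e[key] = new_e.get(key, 0.0) + w
        e = new_e
        for n in members[ci]:
            comm_of[n] = ci
    agglomerated = {n: comm_of[n] for n in graph.nodes}
    # two deterministic starts: the agglomerated partition and all-singletons;
    # node-moving refinement of each, keeping the better final Q
    candidates = []
    for start in (agglomerated, {n: node_key[n] for n in nodes}):
        refined = _refine_by_node_moves(graph, start, resolution, nodes, node_key)
        candidates.append((modularity(graph, refined, resolution), refined))
    q_best, labels = max(candidates, key=lambda c: c[0])
    reps = sorted({labels[n] for n in graph.nodes})
    renum = {rep: i for i, rep in enumerate(reps)}
    labels = {n: renum[labels[n]] for n in graph.nodes}
    return labels, q_best


def _refine_by_node_moves(graph, labels, resolution, nodes, node_key):
    """Deterministic local-move sweeps, then aggregation, repeated to a
    fixed point.

    Each sweep visits the nodes in sorted order and immediately moves the
    node to the strictly best improving community among its neighbours'
    communities and a fresh singleton (ties to the smallest target label).
    When a level converges, communities are collapsed into super-nodes and
    the procedure recurses on the aggregated graph.
    """
    labels = _move_sweeps(graph, dict(labels), resolution, nodes, node_key)
    # aggregation level: collapse communities and re-optimize
    comms = sorted({labels[n] for n in nodes})
    if len(comms) < len(nodes):
        agg = nx.Graph()
        agg.add_nodes_from(comms)
        for u, v, d in graph.edges(data=True):
            cu, cv = labels[u], labels[v]
            w = _edge_weight(d)
            if agg.has_edge(cu, cv):
                agg[cu][cv]["weight"] += w
            else:
                agg.add_edge(cu, cv, weight=w)
        agg_nodes = comms
        agg_key = {c: i for i, c in enumerate(comms)}
        agg_labels = _move_sweeps(
            agg, {c: agg_key[c] for c in comms}, resolution, agg_nodes, agg_key
        )
        if len({agg_labels[c] for c in comms}) < len(comms):
            merged = {n: agg_labels[labels[n]] for n in nodes}
            if modularity(graph, merged, resolution) > modularity(
                graph, labels, resolution
            ) + 1e-12:
                return _refine_by_node_moves(graph, merged, resolution, nodes, node_key)
    return labels


def _move_sweeps(graph, labels, resolution, nodes, node_key):
    """Sweep-based single-node relocation until no sweep changes anything.

    Self-loop weights (from aggregated graphs) count fully toward a node's
    internal weight and strength.
    """
    m2 = 0.0
    strength = {n: 0.0 for n in nodes}
    self_w = {n: 0.0 for n in nodes}
    for u, v, d in graph.edges(data=True):
        w = _edge_weight(d)
        m2 += 2.0 * w
        if u == v:
            strength[u] += 2.0 * w
            self_w[u] += w
        else:
            strength[u] += w
            strength[v] += w
    a = {}
    for n in nodes:
        a[labels[n]] = a.get(labels[n], 0.0) + strength[n] / m2
    fresh = max(node_key.values()) + 1
    for _ in range(20 * len(nodes) + 20):
        changed = False
        for n in nodes:
            c_old = labels[n]
            k_in = {}
            for nb, d in graph[n].items():
                if nb == n:
                    continue
                k_in[labels[nb]] = k_in.get(labels[nb], 0.0) + _edge_weight(d)
            s = strength[n] / m2
            best_dq, best_c = 0.0, c_old
            for c_new in sorted(k_in) + [fresh]:
                if c_new == c_old:
                    continue
                dq = (
                    2.0 * (k_in.get(c_new, 0.0) - k_in.get(c_old, 0.0)) / m2
                    + 2.0 * resolution * s * (a[c_old] - s - a.get(c_new, 0.0))
                )
                if dq > best_dq + 1e-12:
                    best_dq, best_c = dq, c_new
            if best_c != c_old:
                labels[n] = best_c
                a[c_old] -= s
                a[best_c] = a.get(best_c, 0.0) + s
                if best_c == fresh:
                    fresh += 1
                changed = True
        if not changed:
            break
    return labels


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


def _classical_scaling(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((n, 2 - coords.shape[1]))])
    return coords


def _stress(X: np.ndarray, D: np.ndarray) -> float:
    diff = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    iu = np.triu_indices(len(X), k=1)
    return float(((diff[iu] - D[iu]) ** 2).sum())


def _smacof(X: np.ndarray, D: np.ndarray, tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Uniform-weight stress majorization (Guttman transform updates)."""
    n = len(X)
    if n <= 2:
        return X
    stress = _stress(X, D)
    for _ in range(max_iter):
        dist = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 1e-12, D / dist, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X_new = B @ X / n
        new_stress = _stress(X_new, D)
        X = X_new
        if stress > 0 and (stress - new_stress) / stress < tol:
            stress = new_stress
            break
        stress = new_stress
    return X


def layout(graph: nx.Graph, method: str = "stress") -> dict:
    """2-D node coordinates from graph-theoretic distances.

    Distances are shortest weighted paths (edge weights read as lengths).
    ``classical_scaling`` uses the spectral embedding alone; ``stress``
    refines it by stress majorization to a relative stress change of 1e-6.
    Disconnected graphs are laid out per component with a horizontal offset.
    """
    if method not in ("classical_scaling", "stress"):
        raise ValueError("method must be 'classical_scaling' or 'stress'")
    pos: dict = {}
    x_offset = 0.0
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(map(str, c))):
        nodes = sorted(comp, key=str)
        if len(nodes) == 1:
            pos[nodes[0]] = np.array([x_offset, 0.0])
            x_offset += 1.0
            continue
        sub = graph.subgraph(nodes)
        D = np.zeros((len(nodes), len(nodes)))
        idx = {n: i for i, n in enumerate(nodes)}
        for src, dists in nx.shortest_path_length(sub, weight="weight"):
            for dst, d in dists.items():
                D[idx[src], idx[dst]] = d
        X = _classical_scaling(D)
        if method == "stress":
            X = _smacof(X, D)
        X = X - X.min(axis=0)
        span = X[:, 0].max() if len(nodes) > 1 else 0.0
        for n in nodes:
            pos[n] = X[idx[n]] + np.array([x_offset, 0.0])
        x_offset += span + 1.0
    return pos


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def export(graph: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write a network as GraphML, TSV edge list, or JSON.

    All formats round-trip nodes, edges, weights and community labels; the
    JSON form also round-trips layout coordinates (node attributes ``x``,
    ``y``) at full precision.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".graphml": "graphml", ".tsv": "tsv", ".json": "json"}.get(path.suffix)
    if fmt == "graphml":
        nx.write_graphml(graph, str(path))
        return
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\tcommunity_source\tcommunity_target\n")
            for u, v, d in graph.edges(data=True):
                cu = graph.nodes[u].get("community", "")
                cv = graph.nodes[v].get("community", "")
                fh.write(f"{u}\t{v}\t{_edge_weight(d):.10g}\t{cu}\t{cv}\n")
        return
    if fmt == "json":
        data = {
            "nodes": [
                {"id": _json_safe(n), **{k: _json_safe(v) for k, v in graph.nodes[n].items()}}
                for n in graph.nodes
            ],
            "edges": [
                {
                    "source": _json_safe(u),
                    "target": _json_safe(v),
                    "weight": _edge_weight(d),
                }
                for u, v, d in graph.edges(data=True)
            ],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
        return
    raise ValueError(f"unknown export format {fmt!r}")


def _json_safe(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def import_graph(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read back a network written by :func:`export`."""
    path = Path(path)
    if fmt is None:
        fmt = {".graphml": "graphml", ".tsv": "tsv", ".json": "json"}.get(path.suffix)
    if fmt == "graphml":
        return nx.read_graphml(str(path))
    if fmt == "tsv":
        g = nx.Graph()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                src, dst, w, cs, ct = line.rstrip("\n").split("\t")
                g.add_edge(src, dst, weight=float(w))
                if cs != "":
                    g.nodes[src]["community"] = int(cs)
                if ct != "":
                    g.nodes[dst]["community"] = int(ct)
        return g
    if fmt == "json":
        with open(path) as fh:
            data = json.load(fh)
        g = nx.Graph()
        for node in data["nodes"]:
            attrs = {k: v for k, v in node.items() if k != "id"}
            g.add_node(node["id"], **attrs)
        for edge in data["edges"]:
            g.add_edge(edge["source"], edge["target"], weight=edge["weight"])
        return g
    raise ValueError(f"unknown import format {fmt!r}")
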