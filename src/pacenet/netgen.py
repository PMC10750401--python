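"""Modular small-world network generation for SAN tissue models.

Cells are scattered in 3D around per-module attractor points and wired by
an iterative algorithm whose edge probability follows a saw-shaped density
over distance: a tall, short-range peak at each attractor (dense wiring
within a module) and a low, long-range component between modules (sparse
bridges).  The result is a connected simple graph with degrees capped at a
small maximum, high clustering within modules, and the short path lengths
characteristic of small-world topology (sigma > 1).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "GeneratorParams",
    "NetworkMetrics",
    "generate_network",
    "clustering_coefficient",
    "characteristic_path_length",
    "small_world_sigma",
    "degree_histogram",
    "write_graphml",
    "read_graphml",
    "write_edge_list",
    "read_edge_list",
    "write_node_table",
]

#: Per-edge gap-junctional resistance, MOhm
DEFAULT_RESISTANCE = 3750.0


def scaled_reference_params(n_cells: int = 100, seed: int = 0
                            ) -> "GeneratorParams":
    """Generator parameters for a scaled-down two-module reference network.

    Keeps the number of inter-module bridges proportional to the cell
    count (the cross-module probability amplitude is rescaled to offset
    the quadratic drop in cross pairs).
    """
    full = GeneratorParams()
    n0 = sum(full.module_sizes)
    half = n_cells // 2
    sizes = (n_cells - half, half)
    cross_full = full.module_sizes[0] * full.module_sizes[1]
    cross_new = sizes[0] * sizes[1]
    scale = (n_cells / n0) * (cross_full / cross_new)
    return GeneratorParams(module_sizes=sizes,
                           valley_amplitude=full.valley_amplitude * scale,
                           seed=seed)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the attractor-point network generator.

    Distances are in arbitrary length units consistent with
    ``attractor_centers``; with the defaults, module clouds have spatial
    SD ``scatter`` = 2 and module centers sit 10 units apart, so
    ``lambda_within`` controls neighborhood wiring inside a cloud and
    ``lambda_between`` the rare long bridges between clouds.
    """

    module_sizes: tuple[int, ...] = (243, 242)
    attractor_centers: tuple[tuple[float, float, float], ...] | None = None
    scatter: float = 2.0              # SD of node scatter around its center
    peak_amplitude: float = 0.9       # A, same-module edge probability at d=0
    valley_amplitude: float = 0.0022  # B, cross-module edge probability at d=0
    lambda_within: float = 1.2        # decay length of the within-module peak
    lambda_between: float = 6.0       # decay length of the between-module tail
    degree_cap: int = 5
    triadic_closure: float = 0.2      # probability of closing open triangles
    max_iterations: int = 500
    resistance: float = DEFAULT_RESISTANCE  # MOhm per edge
    seed: int = 0

    def centers(self) -> np.ndarray:
        if self.attractor_centers is not None:
            c = np.asarray(self.attractor_centers, dtype=float)
            if c.shape != (len(self.module_sizes), 3):
                raise ValueError("need one 3D attractor center per module")
            return c
        # default: modules on a line, 10 units apart
        m = len(self.module_sizes)
        return np.array([[10.0 * i, 0.0, 0.0] for i in range(m)])


@dataclass(frozen=True)
class NetworkMetrics:
    """Small-world characterization of one network realization."""
    C: float        # mean clustering coefficient
    L: float        # characteristic path length (hops)
    C_r: float      # ensemble mean clustering of equivalent random graphs
    L_r: float      # ensemble mean path length of equivalent random graphs
    sigma: float    # (C/C_r)/(L/L_r)

    def __post_init__(self):
        expect = (self.C / self.C_r) / (self.L / self.L_r)
        if not np.isclose(self.sigma, expect, rtol=1e-9):
            raise ValueError("sigma inconsistent with its components")


def _edge_probability(d: float, same_module: bool, gp: GeneratorParams) -> float:
    if same_module:
        return gp.peak_amplitude * float(np.exp(-d / gp.lambda_within))
    return gp.valley_amplitude * float(np.exp(-d / gp.lambda_between))


def generate_network(gp: GeneratorParams) -> nx.Graph:
    """Generate a modular small-world cell network.

    Deterministic given ``gp.seed``.  Iteratively (i) scatters nodes
    around the attractor centers, (ii) proposes edges by the saw-shaped
    distance density (pairs visited in sorted-id order), rejecting
    proposals that would exceed ``degree_cap``, (iii) closes open
    same-module triangles with probability ``triadic_closure``, and
    (iv) repairs connectivity by joining the smallest component to the
    rest through the spatially closest low-degree node pair.  Raises if
    the graph cannot be connected within ``max_iterations`` repair
    rounds.
    """
    n_total = int(sum(gp.module_sizes))
    if n_total < 2:
        raise ValueError("need at least 2 cells")
    if gp.degree_cap < 1:
        raise ValueError("degree_cap must be >= 1")
    rng = np.random.default_rng(gp.seed)
    centers = gp.centers()

    module_of = np.concatenate([
        np.full(sz, m, dtype=int) for m, sz in enumerate(gp.module_sizes)])
    pos = np.empty((n_total, 3))
    for m, sz in enumerate(gp.module_sizes):
        sel = module_of == m
        pos[sel] = centers[m] + gp.scatter * rng.standard_normal((sz, 3))

    g = nx.Graph()
    for i in range(n_total):
        g.add_node(i, module=int(module_of[i]),
                   x=float(pos[i, 0]), y=float(pos[i, 1]), z=float(pos[i, 2]))

    deg = np.zeros(n_total, dtype=int)
    # pairwise distances once; proposal order sorted by (min id, max id)
    for i in range(n_total - 1):
        if deg[i] >= gp.degree_cap:
            continue
        d_row = np.linalg.norm(pos[i + 1:] - pos[i], axis=1)
        same = module_of[i + 1:] == module_of[i]
        p_row = np.where(
            same,
            gp.peak_amplitude * np.exp(-d_row / gp.lambda_within),
            gp.valley_amplitude * np.exp(-d_row / gp.lambda_between))
        draws = rng.random(n_total - i - 1)
        for k in np.nonzero(draws < p_row)[0]:
            j = i + 1 + int(k)
            if deg[i] >= gp.degree_cap:
                break
            if deg[j] >= gp.degree_cap:
                continue
            g.add_edge(i, j, resistance=gp.resistance)
            deg[i] += 1
            deg[j] += 1

    # triadic closure within modules: neighboring cells tend to share
    # neighbors in tightly packed tissue, and the closed triangles carry
    # the high clustering of the small-world architecture
    if gp.triadic_closure > 0:
        for i in sorted(g.nodes):
            nbrs = sorted(g.neighbors(i))
            for a_i in range(len(nbrs) - 1):
                a = nbrs[a_i]
                for b in nbrs[a_i + 1:]:
                    if (module_of[a] != module_of[b] or g.has_edge(a, b)
                            or deg[a] >= gp.degree_cap
                            or deg[b] >= gp.degree_cap):
                        continue
                    if rng.random() < gp.triadic_closure:
                        g.add_edge(a, b, resistance=gp.resistance)
                        deg[a] += 1
                        deg[b] += 1

    # connectivity repair: join the smallest component to the rest through
    # the spatially closest low-degree node pair (keeps repair edges local,
    # so stray cross-module bridges stay rare)
    for _ in range(gp.max_iterations):
        comps = sorted(nx.connected_components(g), key=len)
        if len(comps) == 1:
            break
        small = sorted(comps[0])
        rest = sorted(set(g.nodes) - comps[0])
        d = np.linalg.norm(pos[small][:, None, :] - pos[rest][None, :, :],
                           axis=2)
        # penalize saturated endpoints so the degree cap is respected
        # whenever any unsaturated pair exists
        pen = (np.where(deg[small] >= gp.degree_cap, 1e6, 0.0)[:, None]
               + np.where(deg[rest] >= gp.degree_cap, 1e6, 0.0)[None, :])
        ia, ib = np.unravel_index(np.argmin(d + pen), d.shape)
        a, b = small[int(ia)], rest[int(ib)]
        g.add_edge(a, b, resistance=gp.resistance)
        deg[a] += 1
        deg[b] += 1
    else:
        ncomp = nx.number_connected_components(g)
        if ncomp > 1:
            raise RuntimeError(
                f"could not connect network within {gp.max_iterations} "
                f"repair rounds; {ncomp} components remain")
    # isolated-node sweep is covered by repair (components of size 1)
    return g


def clustering_coefficient(g: nx.Graph) -> float:
    """Mean local clustering coefficient (nodes with degree < 2 count 0)."""
    return float(nx.average_clustering(g))


def _to_igraph(g: nx.Graph):
    import igraph as ig
    idx = {v: i for i, v in enumerate(g.nodes)}
    return ig.Graph(n=g.number_of_nodes(),
                    edges=[(idx[a], idx[b]) for a, b in g.edges])


def characteristic_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length in hops over all unordered node pairs."""
    if not nx.is_connected(g):
        raise ValueError("characteristic path length needs a connected graph")
    return float(_to_igraph(g).average_path_length())


def small_world_sigma(g: nx.Graph, n_random: int = 20, seed: int = 0,
                      equivalent: str = "gnm") -> NetworkMetrics:
    """Small-world coefficient sigma = (C/C_r)/(L/L_r).

    ``C_r`` and ``L_r`` are means over ``n_random`` equivalent random
    graphs with the same node and edge count (``equivalent="gnm"``,
    matching the degree on average) or the same degree sequence
    (``equivalent="rewire"``).  Sparse random graphs below the
    connectivity threshold are almost always disconnected, so ``L_r`` is
    measured on the largest connected component of each realization;
    realizations whose largest component has fewer than 2 nodes are
    excluded, and it is an error if that leaves none.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    n, m = g.number_of_nodes(), g.number_of_edges()
    C = clustering_coefficient(g)
    L = characteristic_path_length(g)
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_random):
        s = int(rng.integers(0, 2 ** 31 - 1))
        if equivalent == "gnm":
            r = nx.gnm_random_graph(n, m, seed=s)
        elif equivalent == "rewire":
            r = nx.Graph(g)
            nx.double_edge_swap(r, nswap=4 * m, max_tries=40 * m, seed=s)
        else:
            raise ValueError(f"unknown equivalent-ensemble kind {equivalent!r}")
        # igraph computes the same quantities orders of magnitude faster,
        # which matters for ensembles over ~500-node graphs
        ri = _to_igraph(r)
        cs.append(ri.transitivity_avglocal_undirected(mode="zero"))
        giant = ri.components().giant()
        if giant.vcount() >= 2:
            ls.append(giant.average_path_length())
    if not ls:
        raise RuntimeError("all random realizations were disconnected")
    C_r, L_r = float(np.mean(cs)), float(np.mean(ls))
    if C_r == 0.0:
        raise RuntimeError("random ensemble has no triangles; sigma undefined")
    sigma = (C / C_r) / (L / L_r)
    return NetworkMetrics(C=C, L=L, C_r=C_r, L_r=L_r, sigma=float(sigma))


def degree_histogram(g: nx.Graph) -> dict[int, int]:
    """Counts of nodes per degree; counts sum to the node count."""
    h: dict[int, int] = {}
    for _, d in g.degree():
        h[d] = h.get(d, 0) + 1
    return dict(sorted(h.items()))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(str(path), node_type=int)
    for _, _, data in g.edges(data=True):
        data["resistance"] = float(data["resistance"])
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """3-column CSV: id_a, id_b, resistance_MOhm."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id_a", "id_b", "resistance_MOhm"])
        for a, b, data in sorted(g.edges(data=True)):
            w.writerow([a, b, data.get("resistance", DEFAULT_RESISTANCE)])


def read_edge_list(path: str | Path, node_attrs: dict | None = None) -> nx.Graph:
    g = nx.Graph()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            g.add_edge(int(row["id_a"]), int(row["id_b"]),
                       resistance=float(row["resistance_MOhm"]))
    if node_attrs:
        nx.set_node_attributes(g, node_attrs)
    return g


def write_node_table(g: nx.Graph, path: str | Path) -> None:
    """CSV with one row per cell: id, module, x, y, z."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "module", "x", "y", "z"])
        for i in sorted(g.nodes):
            nd = g.nodes[i]
            w.writerow([i, nd.get("module", 0),
                        nd.get("x", 0.0), nd.get("y", 0.0), nd.get("z", 0.0)])
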