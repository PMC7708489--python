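"""Object reconstruction from eigen-pattern cross-correlations (memory effect).

Within one memory-effect patch, the fluorescent eigen-patterns of two
emitters are translated copies of each other; the translation equals their
physical separation in camera pixels.  Cross-correlating pattern pairs
therefore yields relative displacement vectors ``u_ij``.  A displacement
graph over all confidently-correlated pairs can span several ME patches:
as long as patches overlap somewhere along a chain of emitters, a global
least-squares solve of ``x_j - x_i = u_ij`` recovers every connected
emitter's position (up to one translation per connected component), well
beyond a single patch.  Isolated emitters (no correlation with any other)
cannot be located and are reported as such, never silently placed.

A classical multidimensional-scaling (MDS) alternative embeds the emitters
from the pairwise distance matrix ``|u_ij|`` (missing entries completed by
graph shortest path); it trades the vector information of the shifts for
extra robustness to noisy distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numpy.fft import fft2, ifft2
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "DisplacementGraph",
    "ObjectMap",
    "cross_correlate",
    "build_displacement_graph",
    "stitch_positions",
    "assemble_image",
    "mds_localize",
    "align_positions",
]


def cross_correlate(
    pattern_i: np.ndarray, pattern_j: np.ndarray, exclude_radius: int = 2
) -> tuple[np.ndarray, float]:
    """Estimate the displacement of pattern_j relative to pattern_i.

    Both patterns are mean-subtracted and norm-normalized; the circular FFT
    cross-correlation peak location gives the integer-pixel shift ``u_ij``
    (wrapped to the signed range) such that ``pattern_j ~ shift(pattern_i,
    u_ij)``.  The score is the peak height over the robust (MAD-based)
    standard deviation of the off-peak correlation plane.
    """
    a = np.asarray(pattern_i, dtype=float)
    b = np.asarray(pattern_j, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("patterns must be two same-shape 2-D images")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("flat pattern: cross-correlation undefined")
    plane = ifft2(fft2(b / nb) * np.conj(fft2(a / na))).real
    peak_idx = np.unravel_index(np.argmax(plane), plane.shape)
    peak = plane[peak_idx]
    mask = np.ones_like(plane, dtype=bool)
    rr = (np.arange(plane.shape[0])[:, None] - peak_idx[0]) % plane.shape[0]
    cc = (np.arange(plane.shape[1])[None, :] - peak_idx[1]) % plane.shape[1]
    rr = np.minimum(rr, plane.shape[0] - rr)
    cc = np.minimum(cc, plane.shape[1] - cc)
    mask[(rr <= exclude_radius) & (cc <= exclude_radius)] = False
    off = plane[mask]
    robust_sd = 1.4826 * np.median(np.abs(off - np.median(off)))
    score = float(peak / max(robust_sd, np.finfo(float).tiny))
    u = np.array(
        [
            ((peak_idx[0] + plane.shape[0] // 2) % plane.shape[0]) - plane.shape[0] // 2,
            ((peak_idx[1] + plane.shape[1] // 2) % plane.shape[1]) - plane.shape[1] // 2,
        ],
        dtype=int,
    )
    return u, score


@dataclass
class DisplacementGraph:
    """Pairwise displacement constraints between eigen-patterns.

    Edges store the shift ``u_ij`` oriented from the lower to the higher node
    id; :meth:`displacement` returns the correctly signed vector for either
    orientation, so antisymmetry ``u_ij = -u_ji`` holds exactly.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, i: int) -> None:
        self.graph.add_node(int(i))

    def add_edge(self, i: int, j: int, u_ij: np.ndarray, score: float) -> None:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError("self-edges are not allowed")
        u_ij = np.asarray(u_ij, dtype=int)
        if i > j:
            i, j = j, i
            u_ij = -u_ij
        self.graph.add_edge(i, j, u=u_ij, score=float(score))

    def displacement(self, i: int, j: int) -> np.ndarray:
        data = self.graph.edges[int(i), int(j)]
        u = data["u"]
        return u.copy() if i < j else -u

    def edges(self) -> list[tuple[int, int, np.ndarray, float]]:
        return [
            (i, j, d["u"].copy(), d["score"]) for i, j, d in self.graph.edges(data=True)
        ]

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def connected_components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def build_displacement_graph(
    eigenpatterns: np.ndarray | list[np.ndarray],
    theta_edge: float = 5.0,
    node_ids: np.ndarray | None = None,
    max_cycle_residual: float = 2.0,
) -> DisplacementGraph:
    """All-pairs displacement estimation with score thresholding.

    Each unordered pair is correlated once; an edge is created only when the
    correlation peak stands more than ``theta_edge`` robust standard
    deviations above the off-peak background.  Edges whose triangles are
    predominantly cycle-inconsistent (median residual ``|u_ij + u_jk + u_ki|``
    above ``max_cycle_residual`` pixels) are spurious correlation peaks and
    are dropped, so retained triangles close to within that tolerance.
    """
    patterns = [np.asarray(p, dtype=float) for p in eigenpatterns]
    if len(patterns) < 2:
        raise ValueError("need at least two eigen-patterns")
    ids = list(range(len(patterns))) if node_ids is None else [int(k) for k in node_ids]
    g = DisplacementGraph()
    for i in ids:
        g.add_node(i)
    for a in range(len(patterns)):
        for b in range(a + 1, len(patterns)):
            u, score = cross_correlate(patterns[a], patterns[b])
            if score > theta_edge:
                g.add_edge(ids[a], ids[b], u, score)
    _prune_inconsistent_edges(g, max_cycle_residual)
    return g


def _prune_inconsistent_edges(g: DisplacementGraph, max_cycle_residual: float) -> None:
    """Drop edges whose triangle cycle sums are predominantly inconsistent."""
    gr = g.graph
    to_drop = []
    for i, j in gr.edges:
        common = set(gr.neighbors(i)) & set(gr.neighbors(j))
        if not common:
            continue
        residuals = [
            float(
                np.linalg.norm(
                    g.displacement(i, j) + g.displacement(j, k) + g.displacement(k, i)
                )
            )
            for k in common
        ]
        if np.median(residuals) > max_cycle_residual:
            to_drop.append((i, j))
    gr.remove_edges_from(to_drop)


@dataclass
class ObjectMap:
    """Recovered emitter geometry: positions per node (reference at origin per
    connected component), unlocatable singleton nodes, component labels."""

    positions: dict[int, np.ndarray]
    unlocated: list[int]
    component_of: dict[int, int]
    brightness: dict[int, float] | None = None


def _solve_component(
    comp: set[int], edges: list[tuple[int, int, np.ndarray]], ref: int
) -> tuple[dict[int, np.ndarray], list[float]]:
    """Least-squares positions for one connected component and per-edge residuals."""
    free = [n for n in sorted(comp) if n != ref]
    index = {n: k for k, n in enumerate(free)}
    A = np.zeros((len(edges), len(free)))
    B = np.zeros((len(edges), 2))
    for row, (i, j, u) in enumerate(edges):
        if i in index:
            A[row, index[i]] = -1.0
        if j in index:
            A[row, index[j]] = 1.0
        B[row] = u
    sol, *_ = np.linalg.lstsq(A, B, rcond=None)
    positions = {ref: np.zeros(2)}
    for n, k in index.items():
        positions[n] = sol[k]
    residuals = list(np.linalg.norm(A @ sol - B, axis=1))
    return positions, residuals


def stitch_positions(
    graph: DisplacementGraph,
    reference: int | None = None,
    max_residual: float = 2.0,
) -> ObjectMap:
    """Least-squares solve of all edge constraints x_j - x_i = u_ij.

    Positions are solved per connected component with the reference node (or
    the smallest node id of each component) pinned at the origin; solving all
    constraints jointly avoids the drift a sequential walk along a chain
    would accumulate.  Occasional false correlation peaks survive the
    triangle check when they happen to be mutually consistent, so the solve
    is trimmed: while the worst edge misfit exceeds ``max_residual`` pixels,
    that edge is discarded and the component re-solved.  Singleton nodes are
    reported in ``unlocated``.
    """
    if graph.graph.number_of_edges() == 0:
        raise ValueError("displacement graph has no edges: nothing to stitch")
    work = nx.Graph(graph.graph)
    while True:
        positions: dict[int, np.ndarray] = {}
        worst: tuple[float, tuple[int, int]] | None = None
        for comp in nx.connected_components(work):
            if len(comp) == 1:
                continue
            ref = reference if reference in comp else min(comp)
            edges = [(i, j, d["u"]) for i, j, d in work.edges(comp, data=True)]
            # edge orientation in DisplacementGraph storage is i < j
            edges = [(min(i, j), max(i, j), u if i < j else -u) for i, j, u in edges]
            pos, residuals = _solve_component(comp, edges, ref)
            positions.update(pos)
            for (i, j, _), r in zip(edges, residuals):
                if worst is None or r > worst[0]:
                    worst = (r, (i, j))
        if worst is not None and worst[0] > max_residual:
            work.remove_edge(*worst[1])
            continue
        break
    unlocated = [n for n in work.nodes if n not in positions]
    component_of = {}
    for ci, comp in enumerate(sorted(nx.connected_components(work), key=min)):
        for n in comp:
            component_of[n] = ci
    return ObjectMap(positions=positions, unlocated=unlocated, component_of=component_of)


def assemble_image(
    object_map: ObjectMap,
    weights: dict[int, float] | np.ndarray | None,
    grid_shape: tuple[int, int],
    spot_sigma: float = 1.0,
    offset: np.ndarray | None = None,
) -> np.ndarray:
    """Render brightness-weighted Gaussian spots at the recovered positions.

    ``offset`` places the component reference frame on the camera grid
    (default: grid centre).  Nodes without a recovered position (unlocated)
    are skipped — they are reported, not guessed.
    """
    rows, cols = grid_shape
    if offset is None:
        offset = np.array([rows / 2.0, cols / 2.0])
    image = np.zeros(grid_shape)
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    for node, pos in object_map.positions.items():
        if weights is None:
            w = 1.0
        elif isinstance(weights, dict):
            w = float(weights.get(node, 1.0))
        else:
            w = float(weights[node])
        pr, pc = pos + offset
        image += w * np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * spot_sigma**2))
    return image


def mds_localize(distance_matrix: np.ndarray, dim: int = 2) -> np.ndarray:
    """Classical multidimensional scaling of a pairwise distance matrix.

    Missing distances (NaN) are completed by shortest-path lengths over the
    known entries.  The matrix must be symmetric and non-negative.  Returns
    an (n, dim) embedding defined up to a rigid transform and reflection;
    use :func:`align_positions` to compare with ground truth.
    """
    D = np.asarray(distance_matrix, dtype=float).copy()
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    known = ~np.isnan(D)
    if not np.array_equal(known, known.T) or not np.allclose(
        np.where(known, D, 0.0), np.where(known, D, 0.0).T, atol=1e-9
    ):
        raise ValueError("distance matrix must be symmetric")
    if np.nanmin(D) < 0:
        raise ValueError("distances must be non-negative")
    np.fill_diagonal(D, 0.0)
    if np.isnan(D).any():
        adj = np.where(np.isnan(D), 0.0, D)
        D = shortest_path(adj, method="D", directed=False, unweighted=False)
        if np.isinf(D).any():
            raise ValueError("distance matrix cannot be completed: disconnected nodes")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def align_positions(
    X: np.ndarray, ref: np.ndarray, allow_scale: bool = False
) -> tuple[np.ndarray, float]:
    """Procrustes alignment (rotation/reflection + translation, optional scale)
    of ``X`` onto ``ref``; returns the aligned coordinates and the RMS error."""
    X = np.asarray(X, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if X.shape != ref.shape:
        raise ValueError("position sets must have the same shape")
    xc = X - X.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    R, s = orthogonal_procrustes(xc, rc)
    scale = s / (xc**2).sum() if allow_scale else 1.0
    aligned = scale * (xc @ R) + ref.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1))))
    return aligned, rms
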