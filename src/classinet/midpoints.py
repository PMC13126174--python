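"""Node-position inference from link-midpoint-labeled cluster sets.

When the fluorescent label sits at link midpoints (e.g. the spectrin
C-terminus) rather than at nodes, approximate node positions can still be
recovered: candidate nodes are the vertices of the Voronoi tessellation of
the midpoint centroids (equivalently, circumcenters of the Delaunay
triangles), which — like true nodes — are equidistant from their
surrounding midpoints.  Candidates whose distance to their defining
midpoints falls outside the plausible half-link range are discarded,
candidates closer together than the effective image resolution are merged,
and an iterative assembly pass starting from the highest-confidence nodes
enforces the constraint that every link midpoint connects exactly two
nodes, adding a reflected partner node where one side is missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .structures import ClusterSet

DEFAULT_HALF_LINK_RANGE = (80.0, 110.0)
DEFAULT_MERGE_RADIUS = 50.0


@dataclass
class MidpointAssembly:
    predicted_nodes: np.ndarray                 # (M, 2) nm
    midpoint_assignments: dict                  # midpoint idx -> (n1, n2)
    confidence: np.ndarray                      # supporting midpoints / node
    degenerate: bool = False                    # collinear fallback used


def _circumcenters(points: np.ndarray):
    """Circumcenters and circumradii of the Delaunay triangles (these are
    exactly the Voronoi vertices of the point set)."""
    tri = Delaunay(points)
    a = points[tri.simplices[:, 0]]
    b = points[tri.simplices[:, 1]]
    c = points[tri.simplices[:, 2]]
    d = 2.0 * ((a[:, 0] - c[:, 0]) * (b[:, 1] - c[:, 1]) - (b[:, 0] - c[:, 0]) * (a[:, 1] - c[:, 1]))
    ok = np.abs(d) > 1e-12
    a2 = (a**2).sum(axis=1) - (c**2).sum(axis=1)
    b2 = (b**2).sum(axis=1) - (c**2).sum(axis=1)
    ux = (a2 * (b[:, 1] - c[:, 1]) - b2 * (a[:, 1] - c[:, 1])) / np.where(ok, d, 1.0)
    uy = (b2 * (a[:, 0] - c[:, 0]) - a2 * (b[:, 0] - c[:, 0])) / np.where(ok, d, 1.0)
    centers = np.column_stack([ux, uy])[ok]
    radii = np.linalg.norm(centers - a[ok], axis=1)
    return centers, radii


def _merge_close(points: np.ndarray, radius: float) -> np.ndarray:
    """Consolidate points closer than ``radius`` into connected-component
    means."""
    if len(points) == 0:
        return points
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius)
    parent = np.arange(len(points))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        parent[find(a)] = find(b)
    roots = np.array([find(i) for i in range(len(points))])
    return np.array([points[roots == r].mean(axis=0) for r in np.unique(roots)])


def _collinear_fallback(
    midpoints: np.ndarray, half_link_range: tuple[float, float]
) -> MidpointAssembly:
    """Reflection-only assembly along the local axis for (near-)collinear
    midpoint sets: nodes are placed halfway between consecutive midpoints
    whose gap is consistent with twice the half-link range."""
    lo, hi = half_link_range
    if len(midpoints) < 2:
        return MidpointAssembly(
            np.zeros((0, 2)), {}, np.zeros(0, dtype=int), degenerate=True
        )
    centered = midpoints - midpoints.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    order = np.argsort(centered @ axis)
    nodes = []
    assignments = {}
    for a, b in zip(order[:-1], order[1:]):
        gap = np.linalg.norm(midpoints[a] - midpoints[b])
        if 2 * lo <= gap <= 2 * hi:
            idx = len(nodes)
            nodes.append(0.5 * (midpoints[a] + midpoints[b]))
            assignments.setdefault(int(a), []).append(idx)
            assignments.setdefault(int(b), []).append(idx)
    nodes_arr = np.asarray(nodes).reshape(-1, 2)
    conf = np.zeros(len(nodes_arr), dtype=int)
    pairs = {}
    for m, ns in assignments.items():
        for nidx in ns:
            conf[nidx] += 1
        if len(ns) >= 2:
            pairs[m] = (ns[0], ns[1])
    return MidpointAssembly(nodes_arr, pairs, conf, degenerate=True)


def infer_nodes(
    midpoints: ClusterSet | np.ndarray,
    half_link_range: tuple[float, float] = DEFAULT_HALF_LINK_RANGE,
    merge_radius: float = DEFAULT_MERGE_RADIUS,
) -> MidpointAssembly:
    """Infer node positions from link-midpoint centroids.

    Fewer than 3 midpoints, or a collinear set, triggers the degenerate
    reflection-only fallback (flagged on the result).
    """
    pts = (
        midpoints.centroids if isinstance(midpoints, ClusterSet) else
        np.asarray(midpoints, dtype=float).reshape(-1, 2)
    )
    lo, hi = half_link_range
    if len(pts) == 0:
        return MidpointAssembly(np.zeros((0, 2)), {}, np.zeros(0, dtype=int))
    if len(pts) < 3:
        return _collinear_fallback(pts, half_link_range)
    try:
        centers, radii = _circumcenters(pts)
    except Exception:
        return _collinear_fallback(pts, half_link_range)
    if len(centers) == 0:
        return _collinear_fallback(pts, half_link_range)

    keep = (radii >= lo) & (radii <= hi)
    candidates = _merge_close(centers[keep], merge_radius)
    if len(candidates) == 0:
        return MidpointAssembly(np.zeros((0, 2)), {}, np.zeros(0, dtype=int))

    # iterative assembly: every retained midpoint must connect exactly two
    # nodes; missing partners are added by reflecting the assigned node
    # through the midpoint where geometrically feasible
    nodes = [c for c in candidates]
    tree = cKDTree(np.asarray(nodes))
    support = np.zeros(len(nodes), dtype=int)
    near: list[list[int]] = []
    for m in pts:
        idx = tree.query_ball_point(m, hi)
        idx = [i for i in idx if np.linalg.norm(np.asarray(nodes[i]) - m) >= lo]
        near.append(idx)
        for i in idx:
            support[i] += 1

    # process midpoints in order of their best candidate's confidence
    # (highest first; ties by midpoint index)
    order = sorted(
        range(len(pts)),
        key=lambda m: (-max((support[i] for i in near[m]), default=0), m),
    )
    support_list = list(support)
    assignments: dict[int, tuple[int, int]] = {}
    for m_idx in order:
        m = pts[m_idx]

        def dist(i):
            return np.linalg.norm(np.asarray(nodes[i]) - m)

        cand = [i for i in range(len(nodes)) if lo <= dist(i) <= hi]
        cand.sort(key=lambda i: (-support_list[i], dist(i)))
        if len(cand) >= 2:
            n1 = cand[0]
            # the second node must sit on the opposite side of the midpoint
            v1 = np.asarray(nodes[n1]) - m
            opp = [i for i in cand[1:] if np.dot(np.asarray(nodes[i]) - m, v1) < 0]
            if opp:
                assignments[m_idx] = (n1, opp[0])
                support_list[n1] += 1
                support_list[opp[0]] += 1
                continue
            cand = [n1]
        if len(cand) == 1:
            n1 = cand[0]
            reflected = 2.0 * m - np.asarray(nodes[n1])
            nodes.append(reflected)
            support_list.append(1)
            assignments[m_idx] = (n1, len(nodes) - 1)
            support_list[n1] += 1
        # no candidates: midpoint is not retained

    nodes_arr = np.asarray(nodes).reshape(-1, 2)
    # drop nodes supporting no midpoint
    used = np.zeros(len(nodes_arr), dtype=bool)
    for n1, n2 in assignments.values():
        used[n1] = used[n2] = True
    remap = -np.ones(len(nodes_arr), dtype=int)
    remap[used] = np.arange(used.sum())
    final_assign = {
        m: (int(remap[a]), int(remap[b])) for m, (a, b) in assignments.items()
    }
    conf = np.zeros(int(used.sum()), dtype=int)
    for a, b in final_assign.values():
        conf[a] += 1
        conf[b] += 1
    return MidpointAssembly(nodes_arr[used], final_assign, conf)


def inferred_cluster_set(assembly: MidpointAssembly) -> ClusterSet:
    """Wrap predicted node positions as a node-role cluster set."""
    return ClusterSet(centroids=assembly.predicted_nodes, role="node")
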