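"""Integration of homologue maps into one consensus map per chromosome.

The eight homologue maps of a chromosome share "bridging" markers (markers
mapped on more than one homologue).  Maps are first oriented consistently: a
maximum-spanning-tree walk over the bridging-marker-count graph compares each
map with an already-oriented neighbour and flips it when the position
correlation of shared markers is negative.  The oriented maps are then merged
by linear programming: consensus positions minimise the mean absolute
deviation from the component positions subject to the order constraints of
every component map within a window of ``K`` markers; a minimal set of
conflicting constraints is removed greedily to make the system feasible.  The
merge is repeated for K = 1..K_max and for both global input orientations
(the LP solution is not invariant under flipping all inputs), and the
solution with the smallest mean absolute error delta is returned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy import stats

from tetramap.mapbuild import HomologueMap

__all__ = [
    "OrientationPlan",
    "IntegratedMap",
    "ConcordanceReport",
    "orient_maps",
    "merge_maps",
    "concordance",
    "write_consensus",
]


@dataclass
class OrientationPlan:
    path: list[int]  # order in which maps were compared
    flipped: list[bool]
    bridging_counts: np.ndarray
    unoriented: list[int] = field(default_factory=list)


def _shared(a: HomologueMap, b: HomologueMap) -> list[str]:
    return [m for m in a.marker_ids if m in set(b.marker_ids)]


def orient_maps(maps: Sequence[HomologueMap]) -> tuple[OrientationPlan, list[HomologueMap]]:
    """Orient homologue maps consistently using bridging markers.

    The comparison order is a traversal of the maximum spanning tree of the
    bridging-marker-count graph, so each map is compared with the neighbour it
    shares most markers with.  A negative correlation of shared-marker
    positions means the map runs in reverse: it is flipped.  Maps sharing no
    markers with any other are left unoriented and reported.
    """
    if len(maps) < 2:
        return OrientationPlan(list(range(len(maps))), [False] * len(maps),
                               np.zeros((len(maps), len(maps)))), list(maps)
    k = len(maps)
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            counts[i, j] = counts[j, i] = len(_shared(maps[i], maps[j]))
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if counts[i, j] > 0:
                g.add_edge(i, j, weight=counts[i, j])
    mst = nx.maximum_spanning_tree(g)
    comps = list(nx.connected_components(mst))
    main = max(comps, key=len)
    unoriented = sorted(set(range(k)) - main)

    flipped = [False] * k
    oriented: list[Optional[HomologueMap]] = [None] * k
    start = max(main, key=lambda n: counts[n].sum())
    oriented[start] = maps[start]
    path = [start]
    order = list(nx.bfs_edges(mst.subgraph(main), start))
    for parent, child in order:
        shared = _shared(oriented[parent], maps[child])
        flip = False
        if len(shared) >= 2:
            xa = [oriented[parent].position_of(m) for m in shared]
            xb = [maps[child].position_of(m) for m in shared]
            if np.std(xa) > 0 and np.std(xb) > 0:
                flip = np.corrcoef(xa, xb)[0, 1] < 0
        flipped[child] = bool(flip)
        oriented[child] = maps[child].reversed() if flip else maps[child]
        path.append(child)
    out = [oriented[i] if oriented[i] is not None else maps[i] for i in range(k)]
    return OrientationPlan(path, flipped, counts, unoriented), out


@dataclass
class IntegratedMap:
    """Consensus positions with the merge diagnostics."""

    marker_ids: list[str]
    positions: np.ndarray
    delta: float  # mean absolute error vs component maps
    k_interval: int
    orientation: str  # "forward" | "reversed"
    eliminated_constraints: list[tuple[str, str]] = field(default_factory=list)
    candidates: list[tuple[int, str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker": self.marker_ids, "position": self.positions})

    def position_of(self, marker_id: str) -> float:
        return float(self.positions[self.marker_ids.index(marker_id)])


def _order_constraints(maps: Sequence[HomologueMap], k_interval: int) -> dict:
    """Aggregate within-window order constraints a-before-b with support counts."""
    con: dict[tuple[str, str], int] = {}
    for hm in maps:
        ids = hm.marker_ids
        for i in range(len(ids)):
            for j in range(i + 1, min(i + k_interval + 1, len(ids))):
                a, b = ids[i], ids[j]
                if a == b:
                    continue
                con[(a, b)] = con.get((a, b), 0) + 1
    return con


def _make_feasible(con: dict) -> tuple[dict, list[tuple[str, str]]]:
    """Greedily remove conflicting order constraints until the digraph is acyclic.

    Within each strongly connected component the constraint on the most cycles
    (approximated by the weakest-supported edge of successively found cycles)
    is dropped first.
    """
    g = nx.DiGraph()
    for (a, b), wt in con.items():
        g.add_edge(a, b, weight=wt)
    removed = []
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        edge = min(cycle, key=lambda e: g.edges[e[0], e[1]]["weight"])
        g.remove_edge(edge[0], edge[1])
        removed.append((edge[0], edge[1]))
    kept = {(a, b): con[(a, b)] for a, b in g.edges if (a, b) in con}
    return kept, removed


def _solve_lp(maps: Sequence[HomologueMap], con: dict) -> tuple[list[str], np.ndarray, float]:
    """Minimise mean |consensus - component| subject to order constraints."""
    markers = sorted({m for hm in maps for m in hm.marker_ids})
    idx = {m: i for i, m in enumerate(markers)}
    n = len(markers)
    incid = [(idx[m], hm.position_of(m)) for hm in maps for m in hm.marker_ids]
    t = len(incid)
    # variables: y (n consensus positions), e (t absolute deviations)
    c = np.concatenate([np.zeros(n), np.ones(t) / t])
    a_ub, b_ub = [], []
    for row, (mi, x) in enumerate(incid):
        r1 = np.zeros(n + t); r1[mi] = 1.0; r1[n + row] = -1.0
        a_ub.append(r1); b_ub.append(x)        # y - e <= x
        r2 = np.zeros(n + t); r2[mi] = -1.0; r2[n + row] = -1.0
        a_ub.append(r2); b_ub.append(-x)       # -y - e <= -x
    for (a, b) in con:
        r = np.zeros(n + t); r[idx[a]] = 1.0; r[idx[b]] = -1.0
        a_ub.append(r); b_ub.append(0.0)       # y_a <= y_b
    res = linprog(c, A_ub=np.array(a_ub), b_ub=np.array(b_ub),
                  bounds=[(0, None)] * n + [(0, None)] * t, method="highs")
    if not res.success:
        raise RuntimeError(f"LP merge infeasible: {res.message}")
    y = res.x[:n]
    delta = float(res.fun)
    order = np.argsort(y, kind="stable")
    return [markers[i] for i in order], y[order], delta


def merge_maps(maps: Sequence[HomologueMap], k_max: int = 8) -> IntegratedMap:
    """Merge consistently oriented homologue maps into a consensus map.

    Runs the LP for every maximum interval K in 1..k_max and for both global
    input orientations (forward and all-reversed), returning the candidate with
    the minimum mean absolute error delta; all candidate deltas are recorded.
    """
    if not maps:
        raise ValueError("no maps to merge")
    best = None
    candidates = []
    for orientation in ("forward", "reversed"):
        use = list(maps) if orientation == "forward" else [m.reversed() for m in maps]
        for k in range(1, k_max + 1):
            con = _order_constraints(use, k)
            kept, removed = _make_feasible(con)
            try:
                ids, pos, delta = _solve_lp(use, kept)
            except RuntimeError:
                continue
            if orientation == "reversed":
                # mirror back so all candidates share the forward frame
                pos = pos.max() - pos[::-1]
                ids = ids[::-1]
            candidates.append((k, orientation, delta))
            if best is None or delta < best.delta - 1e-12:
                best = IntegratedMap(list(ids), np.asarray(pos) - np.min(pos), delta,
                                     k, orientation, removed)
    if best is None:
        raise RuntimeError("LP merge failed for every (K, orientation) candidate")
    best.candidates = candidates
    return best


@dataclass
class ConcordanceReport:
    table: pd.DataFrame  # per component: slope, r2_adj, n_shared, flagged

    @property
    def min_r2_adj(self) -> float:
        return float(self.table["r2_adj"].min())

    @property
    def mean_r2_adj(self) -> float:
        return float(self.table["r2_adj"].mean())


def concordance(consensus: IntegratedMap, components: Sequence[HomologueMap],
                slope_tol: float = 0.2) -> ConcordanceReport:
    """Regress consensus positions on each component map's positions.

    Per component the slope and adjusted R^2 are reported; slopes far from 1
    (|slope - 1| > slope_tol) are flagged as possible map distortion, and
    components sharing fewer than 3 markers are undefined and flagged.
    """
    rows = []
    cons = dict(zip(consensus.marker_ids, consensus.positions))
    for i, hm in enumerate(components):
        shared = [m for m in hm.marker_ids if m in cons]
        if len(shared) < 3:
            rows.append((i, np.nan, np.nan, len(shared), True))
            continue
        x = np.array([hm.position_of(m) for m in shared])
        y = np.array([cons[m] for m in shared])
        if np.std(x) == 0:
            rows.append((i, np.nan, np.nan, len(shared), True))
            continue
        fit = stats.linregress(x, y)
        n = len(shared)
        r2 = fit.rvalue**2
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        flagged = abs(fit.slope - 1.0) > slope_tol
        rows.append((i, float(fit.slope), float(r2_adj), n, bool(flagged)))
    table = pd.DataFrame(rows, columns=["component", "slope", "r2_adj", "n_shared",
                                        "flagged"])
    return ConcordanceReport(table)


def write_consensus(integrated: IntegratedMap, path, chromosome=""):
    df = integrated.to_frame()
    df.insert(1, "chromosome", chromosome)
    df.to_csv(path, sep="\t", index=False)


def write_merge_log(integrated: IntegratedMap, path):
    """Structured log of the merge: every (K, orientation) candidate's delta."""
    with open(path, "w") as fh:
        fh.write(f"# selected: K={integrated.k_interval} "
                 f"orientation={integrated.orientation} "
                 f"delta={integrated.delta:.6f}\n")
        fh.write("# eliminated constraints: "
                 + ("; ".join(f"{a}<{b}" for a, b in integrated.eliminated_constraints)
                    or "none") + "\n")
        fh.write("K\torientation\tdelta\n")
        for k, orientation, delta in integrated.candidates:
            fh.write(f"{k}\t{orientation}\t{delta:.6f}\n")
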