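"""Marker binning and homologue map ordering.

Cosegregating markers are binned before ordering: a pair qualifies when its
recombination-frequency estimate falls below the threshold of minimum
resolution ``r_min = 1/(2 N_a)`` (with ``N_a = (1 - mu) N`` the population
size adjusted for missing values) *and* its LOD exceeds the calibrated
binning threshold ``LOD = 23.43 + 0.1158 N_a``, which keeps the estimation
error in r below ~0.01.  Bins are single-linkage closures of qualifying pairs;
the simplex x nulliplex member with fewest missing values represents the bin.

Each homologue is then ordered by weighted least squares on Haldane-transformed
pairwise distances (weights = LOD), using greedy best-insertion seeded by the
strongest-linked triplet and refined by a window ripple, over three rounds with
poorly fitting pairs down-weighted between rounds (JoinMap-style "jumps").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "haldane_cM",
    "haldane_inverse",
    "BinningThresholds",
    "binning_thresholds",
    "MarkerBin",
    "bin_markers",
    "HomologueMap",
    "wls_positions",
    "wls_criterion",
    "order_homologue",
    "order_exhaustive",
    "reinsert_binned",
    "write_map",
]

_RMAX = 0.49  # cap before the Haldane transform diverges


def haldane_cM(r) -> np.ndarray | float:
    """Map distance in cM for a recombination fraction (Haldane, no interference)."""
    r = np.clip(np.asarray(r, dtype=float), 0.0, _RMAX)
    return -50.0 * np.log(1.0 - 2.0 * r)


def haldane_inverse(d_cM) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cM, dtype=float) / 50.0))


@dataclass(frozen=True)
class BinningThresholds:
    """Population-size dependent binning criteria."""

    N: int
    mu: float
    N_a: float
    r_min: float
    lod_min: float


def binning_thresholds(N: int, mu: float = 0.0,
                       lod_intercept: float = 23.43,
                       lod_slope: float = 0.1158) -> BinningThresholds:
    """Compute r_min and the binning LOD threshold from N and the missing rate."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 <= mu < 1.0:
        raise ValueError("mu must lie in [0, 1)")
    n_a = (1.0 - mu) * N
    return BinningThresholds(N, mu, n_a, 1.0 / (2.0 * n_a),
                             lod_intercept + lod_slope * n_a)


@dataclass
class MarkerBin:
    representative: str
    members: list[str]  # includes the representative
    max_internal_r: float


def bin_markers(rf: pd.DataFrame, lod: pd.DataFrame, thresholds: BinningThresholds,
                types: Optional[Mapping[str, object]] = None,
                n_missing: Optional[Mapping[str, int]] = None,
                ) -> tuple[list[MarkerBin], list[str]]:
    """Single-linkage binning of cosegregating markers.

    A pair qualifies when r < r_min and LOD > lod_min; bins are the connected
    components of qualifying pairs (nearest-neighbour chaining is possible, so
    the within-bin maximum r is reported as a guardrail).  The representative
    is the S x N member with fewest missing values, else the member with fewest
    missing values.  Returns the bins (singletons included) and the reduced
    marker list (representatives only).
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    ids = list(rf.index)
    r = rf.to_numpy()
    l = np.nan_to_num(lod.to_numpy(), nan=0.0)
    qual = (r < thresholds.r_min) & (l > thresholds.lod_min)
    np.fill_diagonal(qual, True)
    qual &= np.isfinite(r) | np.eye(len(ids), dtype=bool)
    n_comp, labels = connected_components(csr_matrix(qual), directed=False)

    def _miss(m):
        return n_missing.get(m, 0) if n_missing else 0

    def _is_sxn(m):
        if types is None:
            return False
        t = types.get(m)
        name = getattr(t, "name", str(t))
        return name in ("SxN", "NxS")

    bins, reduced = [], []
    for c in range(n_comp):
        members = [ids[i] for i in np.nonzero(labels == c)[0]]
        sxn = [m for m in members if _is_sxn(m)]
        pool = sxn if sxn else members
        rep = min(pool, key=lambda m: (_miss(m), m))
        if len(members) > 1:
            sub = rf.loc[members, members].to_numpy()
            max_r = float(np.nanmax(sub[np.triu_indices(len(members), 1)]))
        else:
            max_r = 0.0
        bins.append(MarkerBin(rep, sorted(members), max_r))
        reduced.append(rep)
    bins.sort(key=lambda b: b.representative)
    return bins, sorted(reduced)


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------

@dataclass
class HomologueMap:
    """Ordered markers with cM positions on one parental homologue."""

    marker_ids: list[str]
    positions: np.ndarray
    homologue: object = None
    parent: Optional[int] = None
    fragments: list["HomologueMap"] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.size:
            self.positions = self.positions - self.positions[0]
        if np.any(np.diff(self.positions) < -1e-9):
            raise ValueError("positions must be nondecreasing")

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if self.positions.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker": self.marker_ids, "position": self.positions,
                             "homologue": self.homologue, "parent": self.parent})

    def position_of(self, marker_id: str) -> float:
        return float(self.positions[self.marker_ids.index(marker_id)])

    def reversed(self) -> "HomologueMap":
        pos = self.positions.max() - self.positions[::-1] if self.positions.size else self.positions
        return HomologueMap(list(self.marker_ids[::-1]), pos, self.homologue, self.parent)


def _pair_arrays(order: Sequence[int], dist: np.ndarray, weight: np.ndarray):
    """Design matrix over inter-marker steps for all finite pairs."""
    k = len(order)
    rows, tgt, wts, pairs = [], [], [], []
    for a in range(k):
        for b in range(a + 1, k):
            i, j = order[a], order[b]
            if not np.isfinite(dist[i, j]) or weight[i, j] <= 0:
                continue
            row = np.zeros(k - 1)
            row[a:b] = 1.0
            rows.append(row)
            tgt.append(dist[i, j])
            wts.append(weight[i, j])
            pairs.append((i, j))
    if not rows:
        return None
    return np.array(rows), np.array(tgt), np.array(wts), pairs


def wls_positions(order: Sequence[int], dist: np.ndarray, weight: np.ndarray
                  ) -> tuple[np.ndarray, float, list, np.ndarray]:
    """Weighted least-squares positions for a fixed order.

    Solves for nonnegative inter-marker steps (so positions are monotone) that
    minimise sum w_ij (x_j - x_i - d_ij)^2.  Returns positions (first = 0), the
    criterion value, the contributing pairs and their residuals.
    """
    arrays = _pair_arrays(order, dist, weight)
    k = len(order)
    if arrays is None:
        return np.zeros(k), 0.0, [], np.zeros(0)
    A, d, w, pairs = arrays
    sw = np.sqrt(w)
    steps, _ = nnls(A * sw[:, None], d * sw)
    x = np.concatenate([[0.0], np.cumsum(steps)])
    resid = A @ steps - d
    sse = float(np.sum(w * resid**2))
    return x, sse, pairs, resid


def wls_criterion(order: Sequence[int], dist: np.ndarray, weight: np.ndarray) -> float:
    return wls_positions(order, dist, weight)[1]


def _greedy_order(dist: np.ndarray, weight: np.ndarray, nodes: list[int]) -> list[int]:
    """Seed with the strongest-linked triplet, then insert by best position."""
    if len(nodes) <= 2:
        return list(nodes)
    w = weight.copy()
    sub = np.ix_(nodes, nodes)
    wsub = w[sub]
    np.fill_diagonal(wsub, 0)
    a_i, b_i = np.unravel_index(np.argmax(wsub), wsub.shape)
    a, b = nodes[a_i], nodes[b_i]
    rest = [n for n in nodes if n not in (a, b)]
    c = max(rest, key=lambda n: w[a, n] + w[b, n])
    order = min((list(p) for p in itertools.permutations([a, b, c])),
                key=lambda o: wls_criterion(o, dist, weight))
    remaining = [n for n in rest if n != c]
    remaining.sort(key=lambda n: -max(w[n, m] for m in order))
    for n in remaining:
        best, best_sse = None, np.inf
        for pos in range(len(order) + 1):
            cand = order[:pos] + [n] + order[pos:]
            sse = wls_criterion(cand, dist, weight)
            if sse < best_sse:
                best, best_sse = cand, sse
        order = best
    return order


def _ripple(order: list[int], dist: np.ndarray, weight: np.ndarray,
            window: int = 3, max_passes: int = 5) -> list[int]:
    best_sse = wls_criterion(order, dist, weight)
    for _ in range(max_passes):
        improved = False
        for start in range(0, len(order) - window + 1):
            seg = order[start:start + window]
            for perm in itertools.permutations(seg):
                if list(perm) == seg:
                    continue
                cand = order[:start] + list(perm) + order[start + window:]
                sse = wls_criterion(cand, dist, weight)
                if sse < best_sse - 1e-12:
                    order, best_sse = cand, sse
                    improved = True
        if not improved:
            break
    return order


def _connected_groups(finite: np.ndarray) -> list[list[int]]:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    n_comp, labels = connected_components(csr_matrix(finite), directed=False)
    groups = [list(np.nonzero(labels == c)[0]) for c in range(n_comp)]
    groups.sort(key=len, reverse=True)
    return groups


def order_homologue(rf: pd.DataFrame, lod: pd.DataFrame,
                    homologue=None, parent: Optional[int] = None,
                    jump_threshold: float = 5.0, rounds: int = 3) -> HomologueMap:
    """Order one homologue's markers and fit cM positions.

    Pairwise r is converted to Haldane cM; LOD scores are the regression
    weights.  Three rounds are run: after each, pairs whose weighted squared
    residual exceeds ``jump_threshold`` are down-weighted (x0.1) before
    re-ordering, which protects the fit from high-variance estimates.  If the
    linkage graph is disconnected the largest component forms the returned map
    and the other components are ordered separately in ``fragments``.
    """
    ids = list(rf.index)
    r = rf.to_numpy().astype(float)
    w0 = np.nan_to_num(lod.to_numpy().astype(float), nan=0.0)
    dist = np.where(np.isfinite(r) & (w0 > 0), haldane_cM(np.nan_to_num(r, nan=0.0)), np.nan)
    np.fill_diagonal(dist, np.nan)

    finite = np.isfinite(dist) & (w0 > 0)
    groups = _connected_groups(finite | np.eye(len(ids), dtype=bool))

    maps = []
    for nodes in groups:
        if len(nodes) == 1:
            maps.append(HomologueMap([ids[nodes[0]]], np.zeros(1), homologue, parent))
            continue
        weight = w0.copy()
        order = None
        for rnd in range(rounds):
            order = _greedy_order(dist, weight, nodes) if order is None else order
            order = _ripple(order, dist, weight)
            x, sse, pairs, resid = wls_positions(order, dist, weight)
            if rnd < rounds - 1:
                for (i, j), res in zip(pairs, resid):
                    if weight[i, j] * res**2 > jump_threshold:
                        weight[i, j] *= 0.1
                        weight[j, i] *= 0.1
        x, _, _, _ = wls_positions(order, dist, weight)
        maps.append(HomologueMap([ids[i] for i in order], x, homologue, parent))
    main = maps[0]
    main.fragments = maps[1:]
    return main


def order_exhaustive(rf: pd.DataFrame, lod: pd.DataFrame) -> tuple[list[str], float]:
    """Exact WLS-optimal order by exhaustive search (oracle; <= 8 markers)."""
    ids = list(rf.index)
    if len(ids) > 8:
        raise ValueError("exhaustive search limited to 8 markers")
    r = rf.to_numpy().astype(float)
    w = np.nan_to_num(lod.to_numpy().astype(float), nan=0.0)
    dist = np.where(np.isfinite(r) & (w > 0), haldane_cM(np.nan_to_num(r, nan=0.0)), np.nan)
    np.fill_diagonal(dist, np.nan)
    n = len(ids)
    best, best_sse = None, np.inf
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:  # skip mirror images
            continue
        sse = wls_criterion(list(perm), dist, w)
        if sse < best_sse:
            best, best_sse = list(perm), sse
    return [ids[i] for i in best], best_sse


def reinsert_binned(hmap: HomologueMap, bins: Sequence[MarkerBin]) -> HomologueMap:
    """Re-add binned markers at their representative's position."""
    rep_pos = {m: p for m, p in zip(hmap.marker_ids, hmap.positions)}
    out_ids, out_pos = [], []
    by_rep = {b.representative: b for b in bins}
    for m, p in zip(hmap.marker_ids, hmap.positions):
        b = by_rep.get(m)
        members = b.members if b else [m]
        if b and b.representative not in rep_pos:
            raise KeyError(f"bin representative {b.representative} not on the map")
        for mem in sorted(members, key=lambda x: (x != m, x)):
            out_ids.append(mem)
            out_pos.append(p)
    for b in bins:
        if b.representative not in rep_pos and any(m in rep_pos for m in b.members):
            raise KeyError(f"bin representative {b.representative} not on the map")
    return HomologueMap(out_ids, np.array(out_pos), hmap.homologue, hmap.parent,
                        fragments=hmap.fragments)


def write_map(hmap: HomologueMap, path):
    hmap.to_frame().to_csv(path, sep="\t", index=False)
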