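"""Clustering of markers into chromosomes and homologues.

Linkage groups are identified from the 1:1 segregating (simplex x nulliplex)
markers of one parent: connected components of the graph with edges wherever
the pairwise LOD exceeds a threshold (single linkage, mirroring the JoinMap
grouping).  Scanning a ladder of increasing LOD thresholds makes chromosomal
clusters split into (ideally) four homologue subclusters; anomalies are
resolved using cross-cluster coupling/repulsion phase information.  All other
marker types are then assigned to their carrier homologues through
coupling-phase linkage with the simplex framework markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from tetramap.markers import FundamentalType
from tetramap.pairwise import estimate_pair

__all__ = [
    "ClusterTree",
    "HomologueAssignment",
    "cluster_at_lod",
    "build_lod_ladder",
    "resolve_subclusters",
    "assign_to_homologues",
    "write_assignments",
]


def cluster_at_lod(lod: pd.DataFrame, threshold: float) -> list[frozenset]:
    """Partition markers into connected components at a LOD threshold.

    Edges join marker pairs with LOD >= threshold (single linkage).  Returns
    the partition sorted by decreasing size then lexicographically.
    """
    ids = list(lod.index)
    adj = np.nan_to_num(lod.to_numpy(), nan=0.0) >= threshold
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = [frozenset(np.array(ids, dtype=object)[labels == c]) for c in range(n_comp)]
    clusters.sort(key=lambda c: (-len(c), sorted(c)))
    return clusters


@dataclass
class ClusterTree:
    """Nested partitions of a marker set across an increasing LOD ladder."""

    thresholds: list[float]
    levels: list[list[frozenset]]  # one partition per threshold

    def subclusters(self, cluster: frozenset, level: int) -> list[frozenset]:
        return [c for c in self.levels[level] if c <= cluster]

    def flagged(self, expected: int = 4, base_level: int = 0,
                top_level: int = -1) -> list[tuple[frozenset, int]]:
        """Base-level clusters whose top-level subcluster count != expected.

        In a tetrasomic species a chromosomal cluster is expected to resolve
        into four homologue subclusters; anything else needs resolution.
        """
        top = len(self.levels) - 1 if top_level == -1 else top_level
        out = []
        for cl in self.levels[base_level]:
            k = len(self.subclusters(cl, top))
            if k != expected:
                out.append((cl, k))
        return out


def build_lod_ladder(lod: pd.DataFrame, thresholds: Sequence[float]) -> ClusterTree:
    """Cluster at each threshold of an increasing ladder.

    Single-linkage components at a higher threshold always refine those at a
    lower one, so the result is a nested cluster tree.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if lod.empty:
        return ClusterTree(thresholds, [[] for _ in thresholds])
    return ClusterTree(thresholds, [cluster_at_lod(lod, t) for t in thresholds])


def _cross_cluster_stat(a: frozenset, b: frozenset, lod: pd.DataFrame,
                        phase: pd.DataFrame, want: str) -> float:
    """Max LOD among cross-cluster pairs whose phase label matches ``want``."""
    best = 0.0
    for ma in a:
        row_l = lod.loc[ma]
        row_p = phase.loc[ma]
        for mb in b:
            if row_p[mb] == want and np.isfinite(row_l[mb]):
                best = max(best, float(row_l[mb]))
    return best


def resolve_subclusters(subclusters: Sequence[frozenset], lod: pd.DataFrame,
                        phase: pd.DataFrame, target: int = 4
                        ) -> tuple[list[frozenset], dict]:
    """Merge homologue fragments until ``target`` clusters remain.

    Fragments of one homologue are joined by the strongest cross-cluster
    coupling linkage; a fragment with no coupling evidence is attached to the
    cluster with which it conflicts least in repulsion.  If the count cannot be
    brought to ``target`` the failure is reported, never silently merged.
    """
    clusters = [frozenset(c) for c in subclusters]
    report: dict = {"merges": [], "failure": None}
    while len(clusters) > target:
        best = None  # (stat, i, j, kind)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                s = _cross_cluster_stat(clusters[i], clusters[j], lod, phase, "coupling")
                if s > 0 and (best is None or s > best[0]):
                    best = (s, i, j, "coupling")
        if best is None:
            # no coupling evidence anywhere: attach the smallest cluster where
            # repulsion conflict is weakest
            sizes = sorted(range(len(clusters)), key=lambda k: len(clusters[k]))
            i = sizes[0]
            weakest = None
            for j in range(len(clusters)):
                if j == i:
                    continue
                s = _cross_cluster_stat(clusters[i], clusters[j], lod, phase, "repulsion")
                if weakest is None or s < weakest[0]:
                    weakest = (s, j)
            if weakest is None:
                report["failure"] = f"cannot reduce {len(clusters)} clusters to {target}"
                return clusters, report
            best = (weakest[0], min(i, weakest[1]), max(i, weakest[1]), "repulsion-fallback")
        s, i, j, kind = best
        report["merges"].append((sorted(clusters[i])[0], sorted(clusters[j])[0], kind, s))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    if len(clusters) < target:
        report["failure"] = f"only {len(clusters)} clusters, expected {target}"
    clusters.sort(key=lambda c: (-len(c), sorted(c)))
    return clusters, report


@dataclass
class HomologueAssignment:
    """Carrier homologues of one marker in one parent.

    ``homologues`` are the reference-allele carriers (1 per simplex dosage,
    2 for duplex, 3 for triplex); for a duplex allele the complementary pair
    carries exactly the mirrored linkage information and is reported in
    ``complement``.  ``evidence`` counts significant coupling linkages with
    framework simplex markers per homologue.
    """

    marker_id: str
    parent: int
    homologues: tuple
    complement: tuple
    evidence: dict

    @property
    def n_mapped(self) -> int:
        return len(self.homologues) + len(self.complement)


def assign_to_homologues(
    offspring: Mapping[str, np.ndarray],
    types: Mapping[str, FundamentalType],
    framework: Mapping[int, Mapping[Hashable, Sequence[str]]],
    lod_threshold: float = 3.0,
    strategy: str = "MLL",
) -> tuple[list[HomologueAssignment], list[str]]:
    """Assign every marker to its carrier homologues via the simplex framework.

    ``framework[parent][homologue_key]`` lists the 1:1 framework markers of one
    homologue (S x N clusters for parent 1, N x S for parent 2).  For each
    candidate marker and each parent in which it segregates, coupling-phase
    linkages (selected phase "coupling" in that parent, LOD > threshold) with
    framework markers are counted per homologue; the dosage-many homologues
    with the most evidence win, ties broken by summed LOD.  Markers with no
    qualifying linkage in any parent are returned as unplaced.
    """
    from tetramap.pairwise import overlap_label

    assignments: list[HomologueAssignment] = []
    placed: dict[str, int] = {}
    for mid, t in types.items():
        dos = t.parental_dosages
        for parent in (1, 2):
            d = dos[parent - 1]
            if d == 0 or parent not in framework:
                continue
            counts: dict = {}
            lodsum: dict = {}
            for hom_key, members in framework[parent].items():
                c, s = 0, 0.0
                for f in members:
                    if f == mid:
                        c += 10**6  # a framework marker tags its own homologue
                        continue
                    est, _ = estimate_pair(offspring[mid], offspring[f],
                                           types[mid], types[f], strategy)
                    if not est.estimated or est.sentinel or est.phase is None:
                        continue
                    m = est.phase.m1 if parent == 1 else est.phase.m2
                    if m is None:
                        continue
                    a = t.parental_dosages[parent - 1]
                    b = types[f].parental_dosages[parent - 1]
                    if overlap_label(a, b, m) == "coupling" and est.lod > lod_threshold:
                        c += 1
                        s += est.lod
                counts[hom_key] = c
                lodsum[hom_key] = s
            ranked = sorted(counts, key=lambda h: (-counts[h], -lodsum[h], str(h)))
            chosen = tuple(h for h in ranked[:d] if counts[h] > 0)
            if not chosen:
                continue
            if d == 2 and chosen:
                # complementary allele: the other homologues of the same
                # chromosome (keys may be (chromosome, homologue) tuples)
                def _chrom(k):
                    return k[0] if isinstance(k, tuple) else None
                chroms = {_chrom(h) for h in chosen}
                comp = tuple(h for h in framework[parent]
                             if h not in chosen and _chrom(h) in chroms)
            else:
                comp = ()
            assignments.append(HomologueAssignment(mid, parent, chosen, comp,
                                                   {h: counts[h] for h in chosen}))
            placed[mid] = placed.get(mid, 0) + 1

    # Rescue pass: markers with an incomplete (or no) assignment in a parent
    # are linked against all already-assigned markers of any type; only pairs
    # whose coupling overlap covers the partner's full homologue set give
    # unambiguous per-homologue evidence.
    assigned_sets: dict[int, dict[str, tuple]] = {1: {}, 2: {}}
    for parent, fw in framework.items():
        for hom_key, members in fw.items():
            for f in members:
                assigned_sets[parent][f] = (hom_key,)
    for a in assignments:
        assigned_sets[a.parent][a.marker_id] = a.homologues
    by_key = {(a.marker_id, a.parent): a for a in assignments}
    for mid, t in types.items():
        for parent in (1, 2):
            d = t.parental_dosages[parent - 1]
            if d == 0 or parent not in framework:
                continue
            existing = by_key.get((mid, parent))
            if existing is not None and len(existing.homologues) >= d:
                continue
            counts2: dict = {}
            lodsum2: dict = {}
            for other, homs in assigned_sets[parent].items():
                if other == mid:
                    continue
                est, _ = estimate_pair(offspring[mid], offspring[other],
                                       types[mid], types[other], strategy)
                if not est.estimated or est.sentinel or est.phase is None:
                    continue
                m = est.phase.m1 if parent == 1 else est.phase.m2
                if m is None or est.lod <= lod_threshold:
                    continue
                if m == len(homs):  # full coupling: every carrier tags M
                    for h in homs:
                        counts2[h] = counts2.get(h, 0) + 1
                        lodsum2[h] = lodsum2.get(h, 0.0) + est.lod
            ranked = sorted(counts2, key=lambda h: (-counts2[h], -lodsum2[h], str(h)))
            chosen = tuple(sorted(ranked[:d], key=str))
            if not chosen or (existing is not None
                              and len(chosen) <= len(existing.homologues)):
                continue
            if d == 2:
                def _chrom(k):
                    return k[0] if isinstance(k, tuple) else None
                chroms = {_chrom(h) for h in chosen}
                comp = tuple(h for h in framework[parent]
                             if h not in chosen and _chrom(h) in chroms)
            else:
                comp = ()
            new = HomologueAssignment(mid, parent, chosen, comp,
                                      {h: counts2[h] for h in chosen})
            if existing is not None:
                assignments[assignments.index(existing)] = new
            else:
                assignments.append(new)
                placed[mid] = placed.get(mid, 0) + 1
            by_key[(mid, parent)] = new
            assigned_sets[parent][mid] = chosen
    unplaced = [m for m in types if m not in placed]
    return assignments, unplaced


def write_assignments(assignments: Sequence[HomologueAssignment], path):
    rows = []
    for a in assignments:
        rows.append((a.marker_id, a.parent,
                     ",".join(str(h) for h in a.homologues),
                     ",".join(str(h) for h in a.complement),
                     ",".join(str(v) for v in a.evidence.values())))
    pd.DataFrame(rows, columns=["marker", "parent", "homologues", "complement",
                                "evidence"]).to_csv(path, sep="\t", index=False)
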