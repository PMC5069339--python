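"""Tetraploid meiosis simulator for F1 mapping populations.

Each parent carries four homologous chromosomes.  Per meiosis, with
probability ``q`` the four homologues form a cross-type quadrivalent (partner
switching along the chromosome, which permits double reduction); otherwise
they form two bivalents, the preferred partition {(0,1),(2,3)} being chosen
with probability ``p + (1-p)/3`` and each other partition with ``(1-p)/3``.
Crossovers follow a Poisson process on genetic distance (Haldane's model, no
interference), so the chromatid-level recombination fraction between loci at
distance ``d`` cM is ``(1 - exp(-2d/100))/2``.

Populations are returned together with full ground truth (carrier homologues
per marker, transmitted founder segments, pairing structures, double-reduction
flags), which drives the validation of every downstream mapping stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from tetramap.markers import MISSING, DosageMatrix, FundamentalType, MarkerRecord
from tetramap.pairwise import PAIRINGS

__all__ = [
    "MeiosisModel",
    "ParentGenome",
    "PopulationTruth",
    "SimulatedPopulation",
    "haldane_rf",
    "random_marker_layout",
    "simulate_cross",
]

QUADRIVALENT = 3  # pairing code; 0..2 index the bivalent partitions


def haldane_rf(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MeiosisModel:
    """Meiotic behaviour: quadrivalent fraction q, preferential pairing p.

    ``p = 0`` gives fully random (polysomic) bivalent pairing, ``p = 1`` fully
    preferential (disomic) pairing of the partition {(0,1),(2,3)}.  The
    centromere sits at ``centromere_cM`` (default 0, the left end).
    """

    q: float = 0.0
    p: float = 0.0
    centromere_cM: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.q <= 1.0 and 0.0 <= self.p <= 1.0):
            raise ValueError("q and p must lie in [0, 1]")

    @property
    def pairing_probs(self) -> np.ndarray:
        base = (1.0 - self.p) / 3.0
        return np.array([self.p + base, base, base])


@dataclass
class ParentGenome:
    """Four phased homologues over a shared marker list.

    ``homologues`` is a (4, M) 0/1 array; several markers may share a genetic
    position (e.g. one locus carrying all nine segregation types).
    """

    marker_ids: list[str]
    positions: np.ndarray  # cM per marker, nondecreasing
    homologues: np.ndarray  # (4, M) int8
    marker_types: Optional[list[FundamentalType]] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.homologues = np.asarray(self.homologues, dtype=np.int8)
        if self.homologues.shape != (4, len(self.marker_ids)):
            raise ValueError("homologues must be 4 x n_markers")
        if np.any(np.diff(self.positions) < 0) or not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite and nondecreasing")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def carrier_set(self, marker_index: int) -> frozenset:
        return frozenset(np.nonzero(self.homologues[:, marker_index])[0].tolist())

    def dosage(self, marker_index: int) -> int:
        return int(self.homologues[:, marker_index].sum())


def random_marker_layout(
    n_loci: int,
    spacing_cM: float = 1.0,
    types: Iterable[FundamentalType] = tuple(FundamentalType),
    seed=None,
) -> tuple[ParentGenome, ParentGenome]:
    """Regularly spaced loci, each carrying one marker per requested type.

    For every locus and type the carrier homologues in each parent are drawn
    uniformly at random among the subsets of the right size (e.g. D x S: a
    random pair of P1 homologues and a random single P2 homologue).  Marker ids
    encode locus and type.  Deterministic given the seed.
    """
    if n_loci < 2:
        raise ValueError("need at least 2 loci")
    rng = _as_rng(seed)
    types = list(types)
    ids, pos, t_list = [], [], []
    h1_cols, h2_cols = [], []
    for i in range(n_loci):
        for t in types:
            a, b = t.parental_dosages
            col1 = np.zeros(4, dtype=np.int8)
            col2 = np.zeros(4, dtype=np.int8)
            col1[rng.choice(4, size=a, replace=False)] = 1
            col2[rng.choice(4, size=b, replace=False)] = 1
            ids.append(f"L{i:04d}_{t.name}")
            pos.append(i * spacing_cM)
            t_list.append(t)
            h1_cols.append(col1)
            h2_cols.append(col2)
    h1 = np.column_stack(h1_cols)
    h2 = np.column_stack(h2_cols)
    positions = np.array(pos)
    return (ParentGenome(ids, positions, h1, t_list),
            ParentGenome(list(ids), positions.copy(), h2, list(t_list)))


@dataclass
class PopulationTruth:
    """Ground truth of a simulated population.

    ``founders_p1``/``founders_p2``: (n, 2, U) founder-homologue ids of the two
    transmitted chromatids at each of the U unique positions.  ``pairing_*``:
    per meiosis, the bivalent partition index 0-2 or 3 for a quadrivalent.
    ``dr_*``: double-reduction flags (both transmitted chromatids carry the
    same founder segment).
    """

    unique_positions: np.ndarray
    position_index: np.ndarray  # marker -> unique-position index
    founders_p1: np.ndarray
    founders_p2: np.ndarray
    pairing_p1: np.ndarray
    pairing_p2: np.ndarray

    @property
    def dr_p1(self) -> np.ndarray:
        return self.founders_p1[:, 0, :] == self.founders_p1[:, 1, :]

    @property
    def dr_p2(self) -> np.ndarray:
        return self.founders_p2[:, 0, :] == self.founders_p2[:, 1, :]

    def crossover_counts(self, parent: int = 1) -> np.ndarray:
        """Number of founder switches along each transmitted chromatid."""
        f = self.founders_p1 if parent == 1 else self.founders_p2
        return (np.diff(f, axis=2) != 0).sum(axis=(1, 2))


@dataclass
class SimulatedPopulation:
    """Offspring dosages plus per-marker and per-meiosis truth."""

    marker_ids: list[str]
    marker_types: list[FundamentalType]
    positions: np.ndarray
    dosages: np.ndarray  # (M, n) int16, MISSING = -1
    parent1: ParentGenome
    parent2: ParentGenome
    truth: PopulationTruth

    @property
    def n_offspring(self) -> int:
        return self.dosages.shape[1]

    def offspring_dict(self) -> dict[str, np.ndarray]:
        return {m: self.dosages[i] for i, m in enumerate(self.marker_ids)}

    def types_dict(self) -> dict[str, FundamentalType]:
        return dict(zip(self.marker_ids, self.marker_types))

    def carrier_sets(self, marker_id: str) -> tuple[frozenset, frozenset]:
        i = self.marker_ids.index(marker_id)
        return self.parent1.carrier_set(i), self.parent2.carrier_set(i)

    def true_overlaps(self, marker_a: str, marker_b: str) -> tuple[Optional[int], Optional[int]]:
        """True per-parent allele-set overlaps (the true phase) of a pair."""
        ia = self.marker_ids.index(marker_a)
        ib = self.marker_ids.index(marker_b)
        out = []
        for genome in (self.parent1, self.parent2):
            sa, sb = genome.carrier_set(ia), genome.carrier_set(ib)
            out.append(len(sa & sb) if sa and sb else None)
        return tuple(out)

    def true_rf(self, marker_a: str, marker_b: str) -> float:
        ia = self.marker_ids.index(marker_a)
        ib = self.marker_ids.index(marker_b)
        return float(haldane_rf(abs(self.positions[ia] - self.positions[ib])))

    def apply_missingness(self, rate: float, seed=None) -> "SimulatedPopulation":
        """Return a copy with entries set missing independently at ``rate``."""
        rng = _as_rng(seed)
        d = self.dosages.copy()
        d[rng.random(d.shape) < rate] = MISSING
        return SimulatedPopulation(self.marker_ids, self.marker_types, self.positions,
                                   d, self.parent1, self.parent2, self.truth)

    def to_dosage_matrix(self) -> DosageMatrix:
        recs = []
        for i, mid in enumerate(self.marker_ids):
            recs.append(MarkerRecord(mid, self.parent1.dosage(i), self.parent2.dosage(i),
                                     self.dosages[i]))
        return DosageMatrix(recs)

    def write_truth(self, path):
        """Tab-separated truth: marker, parent, carrier homologues (1-based)."""
        with open(path, "w") as fh:
            fh.write("marker\tparent\thomologues\n")
            for i, mid in enumerate(self.marker_ids):
                for pnum, g in ((1, self.parent1), (2, self.parent2)):
                    hs = ",".join(str(h + 1) for h in sorted(g.carrier_set(i)))
                    fh.write(f"{mid}\t{pnum}\t{hs}\n")


# ---------------------------------------------------------------------------
# Gamete generation
# ---------------------------------------------------------------------------

def _bivalent_gametes(u: np.ndarray, pairing_idx: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Transmitted founder ids for bivalent meioses, vectorised.

    One chromatid per bivalent follows a two-state Markov walk along the unique
    positions, switching between the bivalent's two homologues with the
    Haldane recombination fraction of each inter-locus interval.
    """
    n = pairing_idx.size
    n_u = u.size
    r_adj = haldane_rf(np.diff(u))
    starts = rng.integers(0, 2, size=(n, 2))
    switches = rng.random((n, 2, n_u - 1)) < r_adj
    cum = np.concatenate([np.zeros((n, 2, 1), dtype=np.int64),
                          np.cumsum(switches, axis=2)], axis=2)
    state = (starts[:, :, None] + cum) % 2  # (n, 2, U)
    biv = np.array(PAIRINGS)  # (3, 2, 2)
    chosen = biv[pairing_idx]  # (n, 2, 2): [meiosis, bivalent, homologue-slot]
    founders = np.empty((n, 2, n_u), dtype=np.int8)
    for c in range(2):
        pair = chosen[:, c, :]  # (n, 2)
        founders[:, c, :] = np.take_along_axis(pair, state[:, c, :], axis=1).astype(np.int8)
    return founders


def _quadrivalent_gamete(u: np.ndarray, centromere: float,
                         rng: np.random.Generator) -> np.ndarray:
    """One gamete (2 chromatids of founder ids over u) from a quadrivalent.

    Cross-type model: the chromosome is cut into three segments by two
    partner-switch points; each segment pairs the four chromosomes as one of
    the three partitions (a random permutation of the partitions across
    segments).  Chiasmata form within each segment between current partners at
    rate 2 per Morgan; each chiasma exchanges the content of one random
    chromatid per chromosome on the far side of the chiasma from the
    centromere.  Anaphase I splits the four chromosomes 2:2 at random; the
    gamete takes one random chromatid from each chromosome of one pole.
    """
    n_u = u.size
    lo, hi = float(u[0]), float(u[-1])
    chromatids = np.repeat(np.arange(4, dtype=np.int8), 2).reshape(8, 1) * np.ones((1, n_u), dtype=np.int8)
    if hi > lo:
        cuts = np.sort(rng.uniform(lo, hi, size=2))
        seg_bounds = [(lo, cuts[0]), (cuts[0], cuts[1]), (cuts[1], hi)]
        seg_pairings = rng.permutation(3)
        events = []  # (position, chromA, chromB)
        for (x0, x1), pi in zip(seg_bounds, seg_pairings):
            length = x1 - x0
            for (ca, cb) in PAIRINGS[pi]:
                n_cx = rng.poisson(2.0 * length / 100.0)
                for x in rng.uniform(x0, x1, size=n_cx):
                    events.append((x, ca, cb))
        events.sort(key=lambda e: e[0])
        for x, ca, cb in events:
            i = 2 * ca + rng.integers(0, 2)
            j = 2 * cb + rng.integers(0, 2)
            if x >= centromere:
                k = int(np.searchsorted(u, x, side="right"))
                sl = slice(k, n_u)
            else:
                k = int(np.searchsorted(u, x, side="left"))
                sl = slice(0, k)
            tmp = chromatids[i, sl].copy()
            chromatids[i, sl] = chromatids[j, sl]
            chromatids[j, sl] = tmp
    pole_partition = PAIRINGS[rng.integers(0, 3)]
    pole = pole_partition[rng.integers(0, 2)]
    out = np.empty((2, n_u), dtype=np.int8)
    for c, chrom in enumerate(pole):
        out[c] = chromatids[2 * chrom + rng.integers(0, 2)]
    return out


def _parent_gametes(u: np.ndarray, n: int, model: MeiosisModel,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Founder ids (n, 2, U) and pairing codes (n,) for n meioses of one parent."""
    founders = np.empty((n, 2, u.size), dtype=np.int8)
    is_quad = rng.random(n) < model.q
    pairing = np.full(n, QUADRIVALENT, dtype=np.int8)
    n_biv = int((~is_quad).sum())
    if n_biv:
        idx = rng.choice(3, size=n_biv, p=model.pairing_probs)
        founders[~is_quad] = _bivalent_gametes(u, idx, rng)
        pairing[~is_quad] = idx
    for i in np.nonzero(is_quad)[0]:
        founders[i] = _quadrivalent_gamete(u, model.centromere_cM, rng)
    return founders, pairing


def simulate_cross(parent1: ParentGenome, parent2: ParentGenome,
                   model: MeiosisModel, n_offspring: int,
                   seed=None) -> SimulatedPopulation:
    """Simulate an F1 population: one gamete per parent per offspring.

    The offspring dosage of a marker is the number of tracked-allele copies on
    the two transmitted chromatids of each parent, summed over parents.
    """
    if parent1.marker_ids != parent2.marker_ids:
        raise ValueError("parent genomes must share the marker list")
    rng = _as_rng(seed)
    pos = parent1.positions
    u, pos_idx = np.unique(pos, return_inverse=True)
    f1, pair1 = _parent_gametes(u, n_offspring, model, rng)
    f2, pair2 = _parent_gametes(u, n_offspring, model, rng)
    m = len(parent1.marker_ids)
    cols = np.arange(m)

    def _contrib(founders: np.ndarray, genome: ParentGenome) -> np.ndarray:
        fm = founders[:, :, pos_idx]  # (n, 2, M)
        return (genome.homologues[fm[:, 0, :], cols] +
                genome.homologues[fm[:, 1, :], cols])  # (n, M)

    dosages = (_contrib(f1, parent1) + _contrib(f2, parent2)).T.astype(np.int16)
    truth = PopulationTruth(u, pos_idx, f1, f2, pair1, pair2)
    return SimulatedPopulation(list(parent1.marker_ids), list(parent1.marker_types or []),
                               pos.copy(), dosages, parent1, parent2, truth)
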