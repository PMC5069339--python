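"""Tetraploid SNP dosage data: validation, conversion and filtering.

A biparental F1 population of an autotetraploid is genotyped with bi-allelic
markers whose scores are allele *dosages* 0-4 (nulliplex, simplex, duplex,
triplex, quadruplex).  Every segregating parental dosage combination can be
recoded to one of nine *fundamental segregation types* (S x N ... D x D) by a
deterministic score conversion in the offspring; all linkage analysis then only
needs to handle those nine types.  This module implements that conversion, the
expected offspring segregation of each type under random bivalent pairing, and
the marker quality filters (missingness, invalid scores, segregation skew).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FundamentalType",
    "MarkerRecord",
    "DosageMatrix",
    "GAMETE_DOSAGE_DIST",
    "convert_to_fundamental",
    "expected_marginal_segregation",
    "expected_offspring_distribution",
    "reachable_offspring_dosages",
    "filter_markers",
    "impute_parent_dosage",
    "read_dosage_table",
    "write_dosage_table",
    "write_rejection_log",
]


class FundamentalType(enum.Enum):
    """The nine fundamental segregation types of a tetraploid cross.

    The value of each member is the canonical (P1, P2) dosage pair.
    """

    SxN = (1, 0)
    NxS = (0, 1)
    DxN = (2, 0)
    NxD = (0, 2)
    SxS = (1, 1)
    SxT = (1, 3)
    DxS = (2, 1)
    SxD = (1, 2)
    DxD = (2, 2)

    @property
    def parental_dosages(self) -> tuple[int, int]:
        return self.value

    @classmethod
    def from_dosages(cls, p1: int, p2: int) -> "FundamentalType":
        for t in cls:
            if t.value == (p1, p2):
                return t
        raise ValueError(f"({p1},{p2}) is not a canonical parental dosage pair")


#: Gamete dosage distribution (dosage 0,1,2) of a tetraploid parent under
#: random bivalent pairing, indexed by parental dosage 0..4.
GAMETE_DOSAGE_DIST: dict[int, tuple[Fraction, Fraction, Fraction]] = {
    0: (Fraction(1), Fraction(0), Fraction(0)),
    1: (Fraction(1, 2), Fraction(1, 2), Fraction(0)),
    2: (Fraction(1, 6), Fraction(4, 6), Fraction(1, 6)),
    3: (Fraction(0), Fraction(1, 2), Fraction(1, 2)),
    4: (Fraction(0), Fraction(0), Fraction(1)),
}

MISSING = -1  # internal sentinel for a missing dosage in integer arrays


@dataclass
class MarkerRecord:
    """One marker row: parental dosages plus offspring dosages.

    ``offspring`` is an integer array with ``-1`` for missing values.
    ``n_invalid`` counts offspring scores that were unreachable under the
    (converted) parental dosage pair and were therefore set to missing.
    """

    marker_id: str
    p1_dosage: Optional[int]
    p2_dosage: Optional[int]
    offspring: np.ndarray
    n_invalid: int = 0

    def __post_init__(self):
        self.offspring = np.asarray(self.offspring, dtype=np.int16)
        for d in (self.p1_dosage, self.p2_dosage):
            if d is not None and not (0 <= d <= 4):
                raise ValueError(f"parental dosage {d} outside 0-4 for {self.marker_id}")
        bad = (self.offspring != MISSING) & ((self.offspring < 0) | (self.offspring > 4))
        if bad.any():
            raise ValueError(f"offspring dosage outside 0-4 for {self.marker_id}")

    @property
    def n_individuals(self) -> int:
        return self.offspring.size

    @property
    def n_missing(self) -> int:
        return int((self.offspring == MISSING).sum())

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / max(self.n_individuals, 1)

    def observed_counts(self) -> np.ndarray:
        """Counts of offspring dosages 0..4 (missing excluded)."""
        obs = self.offspring[self.offspring != MISSING]
        return np.bincount(obs, minlength=5)[:5]


@dataclass
class DosageMatrix:
    """A set of markers sharing one offspring panel."""

    records: list[MarkerRecord] = field(default_factory=list)

    def __post_init__(self):
        sizes = {r.n_individuals for r in self.records}
        if len(sizes) > 1:
            raise ValueError(f"inconsistent offspring panel sizes: {sorted(sizes)}")

    @property
    def n_individuals(self) -> int:
        return self.records[0].n_individuals if self.records else 0

    @property
    def n_markers(self) -> int:
        return len(self.records)

    @property
    def missing_rate(self) -> float:
        """Observed fraction of missing offspring entries (mu)."""
        if not self.records:
            return 0.0
        total = sum(r.n_individuals for r in self.records)
        miss = sum(r.n_missing for r in self.records)
        return miss / total

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, marker_id: str) -> MarkerRecord:
        for r in self.records:
            if r.marker_id == marker_id:
                return r
        raise KeyError(marker_id)


def reachable_offspring_dosages(p1: int, p2: int) -> set[int]:
    """Offspring dosages reachable from a parental pair under bivalent meiosis."""
    g1 = [g for g in range(3) if GAMETE_DOSAGE_DIST[p1][g] > 0]
    g2 = [g for g in range(3) if GAMETE_DOSAGE_DIST[p2][g] > 0]
    return {a + b for a in g1 for b in g2}


def _flag_invalid(offspring: np.ndarray, p1: int, p2: int) -> tuple[np.ndarray, int]:
    reach = reachable_offspring_dosages(p1, p2)
    out = offspring.copy()
    mask = (out != MISSING) & ~np.isin(out, sorted(reach))
    out[mask] = MISSING
    return out, int(mask.sum())


def convert_to_fundamental(record: MarkerRecord) -> Optional[tuple[FundamentalType, MarkerRecord]]:
    """Recode a marker to its fundamental segregation type.

    Returns ``(type, converted_record)``, or ``None`` when the marker does not
    segregate (both parents nulliplex or quadruplex).  Parental dosages must be
    known; impute first (:func:`impute_parent_dosage`) if one is missing.

    The conversion is deterministic and information preserving:

    * both parents segregating (dosage 1-3): the whole record is replaced by its
      allele complement ``(a, b, d) -> (4-a, 4-b, 4-d)`` iff ``a == 3`` or
      ``(a, b) == (2, 3)``, which maps every pair onto a canonical one;
    * exactly one parent segregating, the other fixed at ``b in {0, 4}``: the
      fixed parent's constant gametic contribution ``b/2`` is subtracted from
      the offspring, and a triplex segregating parent is recoded to the
      complementary allele (parent dosage ``3 -> 1``, gamete ``g -> 2 - g``).

    Offspring scores unreachable under the *raw* parental pair are flagged as
    invalid (set to missing, counted in ``n_invalid``), never silently recoded.
    """
    a, b = record.p1_dosage, record.p2_dosage
    if a is None or b is None:
        raise ValueError(f"parental dosage missing for {record.marker_id}; impute first")
    if a in (0, 4) and b in (0, 4):
        return None

    offspring, n_invalid = _flag_invalid(record.offspring, a, b)
    n_invalid += record.n_invalid
    valid = offspring != MISSING

    if a not in (0, 4) and b not in (0, 4):
        # both parents segregating
        if a == 3 or (a == 2 and b == 3):
            a, b = 4 - a, 4 - b
            offspring = offspring.copy()
            offspring[valid] = 4 - offspring[valid]
    else:
        # one segregating parent; the other contributes a constant b/2 per gamete
        if a in (0, 4):
            seg_is_p1 = False
            seg, fixed = b, a
        else:
            seg_is_p1 = True
            seg, fixed = a, b
        offspring = offspring.copy()
        offspring[valid] = offspring[valid] - fixed // 2
        if seg == 3:
            seg = 1
            offspring[valid] = 2 - offspring[valid]
        a, b = (seg, 0) if seg_is_p1 else (0, seg)

    ftype = FundamentalType.from_dosages(a, b)
    return ftype, replace(record, p1_dosage=a, p2_dosage=b, offspring=offspring,
                          n_invalid=n_invalid)


def expected_marginal_segregation(t: FundamentalType | tuple[int, int]) -> np.ndarray:
    """Expected offspring dosage distribution (length 5, dosages 0..4).

    Computed as the convolution of the two parents' bivalent gamete dosage
    distributions; exact as rationals, returned as a Fraction array so that the
    classical integer ratios (e.g. duplex x duplex 1:8:18:8:1) are recovered
    without rounding.
    """
    p1, p2 = t.parental_dosages if isinstance(t, FundamentalType) else t
    return expected_offspring_distribution(p1, p2)


def expected_offspring_distribution(p1: int, p2: int) -> np.ndarray:
    """Offspring dosage distribution for an arbitrary (raw) parental pair."""
    out = np.array([Fraction(0)] * 5, dtype=object)
    for g1 in range(3):
        for g2 in range(3):
            out[g1 + g2] += GAMETE_DOSAGE_DIST[p1][g1] * GAMETE_DOSAGE_DIST[p2][g2]
    return out


def segregation_ratio(t: FundamentalType) -> list[int]:
    """Smallest-whole-number offspring segregation ratio over reachable dosages."""
    probs = expected_marginal_segregation(t)
    nz = [p for p in probs if p > 0]
    denom = np.lcm.reduce([p.denominator for p in nz])
    return [int(p * denom) for p in nz]


@dataclass
class Rejection:
    marker_id: str
    reason: str  # "missing" | "invalid" | "skewed" | "non_segregating"
    statistic: float


def chi2_segregation_test(record: MarkerRecord, ftype: FundamentalType) -> tuple[float, float]:
    """Goodness-of-fit chi2 of the observed offspring counts vs the expected ratio.

    Classes with expected count < 1 are pooled into their nearest reachable
    neighbour for small-class stability.  Returns ``(chi2, p)``.
    """
    expected = np.array([float(p) for p in expected_marginal_segregation(ftype)])
    observed = record.observed_counts().astype(float)
    n = observed.sum()
    if n == 0:
        return np.nan, np.nan
    reach = sorted(np.nonzero(expected)[0])
    obs = observed[reach]
    exp = expected[reach] * n
    # pool classes with expected < 1 into adjacent class
    while len(exp) > 1 and exp.min() < 1.0:
        i = int(np.argmin(exp))
        j = i - 1 if i > 0 else i + 1
        exp[j] += exp[i]
        obs[j] += obs[i]
        exp = np.delete(exp, i)
        obs = np.delete(obs, i)
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), float(p)


def filter_markers(
    matrix: DosageMatrix,
    max_missing: float = 0.10,
    skew_alpha: float = 0.001,
    max_invalid: float = 0.03,
    convert: bool = True,
) -> tuple[DosageMatrix, dict[str, FundamentalType], list[Rejection]]:
    """Convert and quality-filter a dosage matrix.

    Markers are rejected when non-segregating, when their offspring missing
    fraction exceeds ``max_missing``, when more than ``max_invalid`` of scores
    are unreachable under the model, or when a chi-square goodness-of-fit test
    against the type's expected segregation ratio gives p < ``skew_alpha``.

    Returns the retained (converted) matrix, a marker_id -> type map, and the
    rejection log.  An empty result is reported, not fatal.
    """
    kept: list[MarkerRecord] = []
    types: dict[str, FundamentalType] = {}
    log: list[Rejection] = []
    for rec in matrix:
        conv = convert_to_fundamental(rec) if convert else None
        if convert and conv is None:
            log.append(Rejection(rec.marker_id, "non_segregating", np.nan))
            continue
        ftype, crec = conv if convert else (None, rec)
        if crec.missing_fraction > max_missing:
            log.append(Rejection(crec.marker_id, "missing", crec.missing_fraction))
            continue
        if crec.n_invalid / max(crec.n_individuals, 1) > max_invalid:
            log.append(Rejection(crec.marker_id, "invalid",
                                 crec.n_invalid / crec.n_individuals))
            continue
        chi2, p = chi2_segregation_test(crec, ftype)
        if np.isfinite(p) and p < skew_alpha:
            log.append(Rejection(crec.marker_id, "skewed", chi2))
            continue
        kept.append(crec)
        types[crec.marker_id] = ftype
    return DosageMatrix(kept), types, log


def impute_parent_dosage(record: MarkerRecord, margin: float = 3.0) -> Optional[MarkerRecord]:
    """Impute a single missing parental dosage from the offspring segregation.

    Each candidate dosage 0..4 is scored by the multinomial log-likelihood of
    the observed offspring under the expected segregation of the completed
    parental pair (offspring classes impossible under a candidate are heavily
    penalised).  The best candidate is returned only if it beats the runner-up
    by ``margin`` natural-log units; otherwise the marker is left unresolved
    (returns ``None``).  Both parents missing is always unresolved.
    """
    p1, p2 = record.p1_dosage, record.p2_dosage
    if (p1 is None) == (p2 is None):
        return None  # both missing (unresolved) or nothing to do
    known = p1 if p1 is not None else p2
    counts = record.observed_counts().astype(float)
    if counts.sum() == 0:
        return None
    logliks = np.empty(5)
    for cand in range(5):
        pair = (cand, known) if p1 is None else (known, cand)
        probs = np.array([float(x) for x in expected_offspring_distribution(*pair)])
        logliks[cand] = float(counts @ np.log(np.maximum(probs, 1e-9)))
    order = np.argsort(logliks)[::-1]
    if logliks[order[0]] - logliks[order[1]] < margin:
        return None
    best = int(order[0])
    if p1 is None:
        return replace(record, p1_dosage=best)
    return replace(record, p2_dosage=best)


# ---------------------------------------------------------------------------
# I/O: tab-separated dosage tables
# ---------------------------------------------------------------------------

def read_dosage_table(path) -> DosageMatrix:
    """Read a tab-separated dosage table.

    Layout: header row of individual ids; one marker per row; first column the
    marker id, then the two parental dosages (columns ``P1`` and ``P2``), then
    one column per F1 individual.  "NA" or empty cells denote missing values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df = df.apply(pd.to_numeric, errors="raise").astype(float)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["P1", "P2"]:
        raise ValueError("dosage table must start with columns P1 and P2")
    records = []
    for mid, row in df.iterrows():
        p1 = None if np.isnan(row.iloc[0]) else int(row.iloc[0])
        p2 = None if np.isnan(row.iloc[1]) else int(row.iloc[1])
        off = row.iloc[2:].to_numpy()
        offspring = np.where(np.isnan(off), MISSING, off).astype(np.int16)
        records.append(MarkerRecord(str(mid), p1, p2, offspring))
    return DosageMatrix(records)


def write_dosage_table(matrix: DosageMatrix, path, individual_ids: Optional[Sequence[str]] = None):
    """Write a dosage matrix in the same tab-separated dialect as the reader."""
    n = matrix.n_individuals
    ids = list(individual_ids) if individual_ids is not None else [f"F1_{i+1:03d}" for i in range(n)]
    rows = {}
    for rec in matrix:
        vals = [rec.p1_dosage, rec.p2_dosage] + [
            (None if v == MISSING else int(v)) for v in rec.offspring
        ]
        rows[rec.marker_id] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["P1", "P2"] + ids)
    df.index.name = "marker"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def write_rejection_log(log: Iterable[Rejection], path):
    df = pd.DataFrame([(r.marker_id, r.reason, r.statistic) for r in log],
                      columns=["marker", "reason", "statistic"])
    df.to_csv(path, sep="\t", index=False)
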