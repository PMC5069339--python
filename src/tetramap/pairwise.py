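"""Two-point recombination-frequency estimation under random bivalent pairing.

For a pair of bi-allelic markers in a tetraploid parent, the phase is encoded
by the homologue sets ``S_A, S_B`` (subsets of the four homologues) carrying
each marker's tracked allele.  Under bivalent meiosis the four homologues form
one of three pairings; each bivalent transmits either locus-A/locus-B alleles
of the same homologue (probability ``(1-r)/2`` each) or a recombinant
combination (``r/2`` each).  Enumerating pairings x transmissions yields the
exact joint gamete-dosage distribution as a polynomial in ``r``; convolving the
two parents' tables gives the 5x5 offspring dosage distribution from which the
multinomial likelihood of an observed F1 is computed.

Phase classes within a parent are determined solely by the overlap
``m = |S_A & S_B|``: maximal overlap is "coupling", zero/minimal overlap is
"repulsion", and the intermediate case (duplex-duplex only) is "mixed".  For
each marker pair all admissible phase combinations are fitted by maximising
the log-likelihood for ``r`` on [0, 0.5] (Brent), and the phase is selected
either by maximum log-likelihood (MLL) or by minimum r-estimate (MINR).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from tetramap.markers import FundamentalType, MISSING

__all__ = [
    "PAIRINGS",
    "PhaseClass",
    "PairwiseEstimate",
    "admissible_overlaps",
    "overlap_label",
    "enumerate_phases",
    "canonical_sets",
    "gamete_joint_distribution",
    "gamete_table_poly",
    "offspring_table_poly",
    "offspring_joint_distribution",
    "estimate_rf",
    "select_phase",
    "estimate_pair",
    "indistinguishable_groups",
    "pairwise_matrix",
    "PairwiseResult",
    "write_pwd",
]

#: The three bivalent pairings of homologues {0,1,2,3}; the first is the
#: "preferred" partition used when preferential pairing strength p > 0.
PAIRINGS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)

_LOG10 = np.log(10.0)
_PFLOOR = 1e-12  # optimiser-only probability floor, never in reported tables
_SENTINEL_R = 0.499


# ---------------------------------------------------------------------------
# Phase bookkeeping
# ---------------------------------------------------------------------------

def admissible_overlaps(a: int, b: int) -> list[int]:
    """Admissible overlap sizes |S_A & S_B| for per-parent dosages a, b."""
    if a == 0 or b == 0:
        return []
    return list(range(max(0, a + b - 4), min(a, b) + 1))


def overlap_label(a: int, b: int, m: int) -> str:
    ms = admissible_overlaps(a, b)
    if not ms:
        return ""
    if m == ms[-1]:
        return "coupling"
    if m == ms[0]:
        return "repulsion"
    return "mixed"


@dataclass(frozen=True)
class PhaseClass:
    """Combined phase of a marker pair: one overlap per informative parent.

    ``m1``/``m2`` are the allele-set overlaps in P1/P2 (``None`` where a parent
    carries no segregating allele for one of the markers, hence no phase).
    """

    dosages1: tuple[int, int]  # (dosage marker A, dosage marker B) in P1
    dosages2: tuple[int, int]
    m1: Optional[int]
    m2: Optional[int]

    @property
    def label(self) -> str:
        parts = []
        if self.m1 is not None:
            parts.append(overlap_label(*self.dosages1, self.m1))
        if self.m2 is not None:
            parts.append(overlap_label(*self.dosages2, self.m2))
        return " ".join(parts) if parts else "none"

    @property
    def overlaps(self) -> tuple[Optional[int], Optional[int]]:
        return (self.m1, self.m2)


def enumerate_phases(type_a: FundamentalType, type_b: FundamentalType) -> list[PhaseClass]:
    """All admissible phase combinations for a marker-type pair.

    Ordered coupling-most first (descending total overlap) so that ties in
    selection break deterministically towards coupling.
    """
    a1, a2 = type_a.parental_dosages
    b1, b2 = type_b.parental_dosages
    m1s = admissible_overlaps(a1, b1) or [None]
    m2s = admissible_overlaps(a2, b2) or [None]
    phases = [PhaseClass((a1, b1), (a2, b2), m1, m2)
              for m1 in m1s for m2 in m2s]
    phases.sort(key=lambda ph: -((ph.m1 or 0) + (ph.m2 or 0)))
    return phases


def canonical_sets(a: int, b: int, m: int) -> tuple[frozenset, frozenset]:
    """A canonical pair of homologue sets with |S_A|=a, |S_B|=b, overlap m."""
    s_a = frozenset(range(a))
    s_b = frozenset(range(a - m, a - m + b))
    assert len(s_a & s_b) == m and max(s_b, default=0) <= 3
    return s_a, s_b


# ---------------------------------------------------------------------------
# Exact joint distributions (polynomials in r)
# ---------------------------------------------------------------------------

def _bivalent_outcomes(h: int, k: int):
    """Two-locus transmissions of a bivalent (h, k) with their r-polynomials.

    Each outcome is ((homologue at locus A, homologue at locus B),
    (c0, c1)) where the probability is c0 + c1*r.
    """
    half = Fraction(1, 2)
    return (
        ((h, h), (half, -half)),
        ((k, k), (half, -half)),
        ((h, k), (Fraction(0), half)),
        ((k, h), (Fraction(0), half)),
    )


def gamete_table_poly(s_a: frozenset, s_b: frozenset, p: Fraction = Fraction(0)):
    """Gamete joint dosage table as polynomial coefficients in r.

    Returns an object array of Fractions, shape (3, 3, 3): ``C[d, gA, gB]`` is
    the coefficient of ``r**d`` for gamete dosages ``(gA, gB)``.  Pairing
    weights are ``p + (1-p)/3`` for the preferred pairing and ``(1-p)/3``
    otherwise.
    """
    coeffs = np.zeros((3, 3, 3), dtype=object)
    coeffs[:] = Fraction(0)
    for idx, (biv1, biv2) in enumerate(PAIRINGS):
        w = p + (1 - p) / 3 if idx == 0 else (1 - p) / 3
        if w == 0:
            continue
        for (t1, poly1) in _bivalent_outcomes(*biv1):
            for (t2, poly2) in _bivalent_outcomes(*biv2):
                g_a = (t1[0] in s_a) + (t2[0] in s_a)
                g_b = (t1[1] in s_b) + (t2[1] in s_b)
                # (c0 + c1 r)(d0 + d1 r), scaled by the pairing weight
                c0, c1 = poly1
                d0, d1 = poly2
                coeffs[0, g_a, g_b] += w * c0 * d0
                coeffs[1, g_a, g_b] += w * (c0 * d1 + c1 * d0)
                coeffs[2, g_a, g_b] += w * c1 * d1
    return coeffs


def _poly_eval(coeffs, r):
    out = np.zeros(coeffs.shape[1:], dtype=float)
    for d in range(coeffs.shape[0]):
        out += coeffs[d].astype(float) * r**d
    return out


def gamete_joint_distribution(s_a: Iterable[int], s_b: Iterable[int], r: float,
                              p: float = 0.0) -> np.ndarray:
    """3x3 joint gamete-dosage distribution P(gA, gB) for one parent.

    ``s_a``/``s_b`` are the homologue sets (subsets of {0,1,2,3}) carrying the
    tracked alleles of markers A and B; ``r`` the recombination frequency and
    ``p`` the preferential pairing strength for the partition {(0,1),(2,3)}.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("r must lie in [0, 0.5]")
    pf = Fraction(p).limit_denominator(10**6)
    coeffs = gamete_table_poly(frozenset(s_a), frozenset(s_b), pf)
    return _poly_eval(coeffs, r)


@lru_cache(maxsize=None)
def offspring_table_poly(key: tuple) -> np.ndarray:
    """5x5 offspring table polynomial coefficients (float), cached.

    ``key = (a1, b1, m1, a2, b2, m2)``: per-parent dosages of markers A and B
    and allele-set overlaps (``m`` ignored where a dosage is 0).  Returns a
    float array of shape (5, 5, 5): ``C[d]`` is the coefficient of ``r**d``.
    """
    a1, b1, m1, a2, b2, m2 = key
    g1 = gamete_table_poly(*canonical_sets(a1, b1, m1 or 0))
    g2 = gamete_table_poly(*canonical_sets(a2, b2, m2 or 0))
    out = np.zeros((5, 5, 5), dtype=object)
    out[:] = Fraction(0)
    for d1 in range(3):
        for d2 in range(3):
            if d1 + d2 > 4:
                continue
            # 2-D convolution over gamete dosages
            block = out[d1 + d2]
            t1, t2 = g1[d1], g2[d2]
            for i in range(3):
                for j in range(3):
                    if t1[i, j] == 0:
                        continue
                    for k in range(3):
                        for l in range(3):
                            if t2[k, l] == 0:
                                continue
                            block[i + k, j + l] += t1[i, j] * t2[k, l]
    return out.astype(float)


def _phase_key(type_a: FundamentalType, type_b: FundamentalType, phase: PhaseClass) -> tuple:
    a1, a2 = type_a.parental_dosages
    b1, b2 = type_b.parental_dosages
    return (a1, b1, phase.m1, a2, b2, phase.m2)


def offspring_joint_distribution(type_a: FundamentalType, type_b: FundamentalType,
                                 phase: PhaseClass, r: float) -> np.ndarray:
    """Exact 5x5 offspring dosage distribution P(dA, dB) for a phased pair."""
    coeffs = offspring_table_poly(_phase_key(type_a, type_b, phase))
    powers = np.array([r**d for d in range(5)])
    return np.tensordot(powers, coeffs, axes=1)


# ---------------------------------------------------------------------------
# Maximum-likelihood estimation
# ---------------------------------------------------------------------------

@dataclass
class PairwiseEstimate:
    """Recombination-frequency estimate for one marker pair (one phase).

    ``rf`` is constrained to [0, 0.5]; the sentinel 0.499 with ``lod = 0`` and
    ``phase = None`` (label "unknown") marks pairs whose unconstrained optimum
    was negative.  ``estimated`` is False when no informative data existed.
    """

    rf: float
    lod: float
    loglik: float
    phase: Optional[PhaseClass]
    n: int = 0
    sentinel: bool = False
    excluded: bool = False  # excluded from selection (forced LOD = 0)
    estimated: bool = True

    @property
    def phase_label(self) -> str:
        return "unknown" if self.phase is None or self.sentinel else self.phase.label


def _loglik_fn(counts_flat: np.ndarray, coeffs: np.ndarray):
    cmat = coeffs.reshape(5, 25)

    def ll(r: float) -> float:
        powers = np.array([1.0, r, r * r, r**3, r**4])
        probs = powers @ cmat
        return float(counts_flat @ np.log(np.maximum(probs, _PFLOOR)))

    return ll


def _reachable_mask(type_a: FundamentalType, type_b: FundamentalType) -> np.ndarray:
    from tetramap.markers import reachable_offspring_dosages
    ra = reachable_offspring_dosages(*[d for d in _marginal_pair(type_a)])
    rb = reachable_offspring_dosages(*[d for d in _marginal_pair(type_b)])
    mask = np.zeros((5, 5), dtype=bool)
    for i in ra:
        for j in rb:
            mask[i, j] = True
    return mask


def _marginal_pair(t: FundamentalType) -> tuple[int, int]:
    return t.parental_dosages


def estimate_rf(counts: np.ndarray, type_a: FundamentalType, type_b: FundamentalType,
                phase: PhaseClass, xtol: float = 1e-6) -> PairwiseEstimate:
    """Maximise the multinomial log-likelihood of a 5x5 count table over r.

    Counts in cells unreachable under the two marker types are excluded as
    invalid scores.  A closed form (recombinants / total) is used for the fully
    informative simplex-simplex coupling case in a single parent; otherwise
    Brent search on [0, 0.5].  If the likelihood extends smoothly to negative r
    (all model probabilities nonnegative) and keeps increasing there, the
    unconstrained optimum is negative: the estimate is the sentinel
    ``(0.499, LOD 0, phase unknown)``.
    """
    counts = np.asarray(counts, dtype=float)
    mask = _reachable_mask(type_a, type_b)
    counts = np.where(mask, counts, 0.0)
    n = counts.sum()
    if n == 0:
        return PairwiseEstimate(np.nan, 0.0, np.nan, phase, 0, estimated=False)

    coeffs = offspring_table_poly(_phase_key(type_a, type_b, phase))
    flat = counts.ravel()
    ll = _loglik_fn(flat, coeffs)

    # the likelihood is exactly flat in r when every populated cell has a
    # constant model probability (e.g. duplex-simplex pairs under fully
    # preferential pairing where the duplex alleles span one bivalent):
    # no information on r exists and the pair is not estimated
    populated = counts > 0
    if not np.any(np.abs(coeffs[1:]).sum(axis=0)[populated] > 1e-12):
        return PairwiseEstimate(np.nan, 0.0, ll(0.25), phase, int(n), estimated=False)

    r_hat = _closed_form_rf(counts, type_a, type_b, phase)
    if r_hat is None:
        res = minimize_scalar(lambda r: -ll(r), bounds=(0.0, 0.5), method="bounded",
                              options={"xatol": xtol})
        r_hat = float(res.x)
        # bounded Brent can stall a hair inside the boundary
        if r_hat < xtol * 10:
            if ll(0.0) >= ll(r_hat):
                r_hat = 0.0
    loglik = ll(r_hat)

    sentinel = False
    if r_hat <= 1e-4:
        eps = 0.02
        probs_neg = np.tensordot(np.array([(-eps) ** d for d in range(5)]), coeffs, axes=1)
        if probs_neg.min() >= -1e-12 and ll(-eps) > ll(0.0) + 1e-9:
            sentinel = True
    if sentinel:
        return PairwiseEstimate(_SENTINEL_R, 0.0, ll(_SENTINEL_R), None, int(n),
                                sentinel=True)

    lod = max((loglik - ll(0.5)) / _LOG10, 0.0)
    return PairwiseEstimate(r_hat, lod, loglik, phase, int(n))


def _closed_form_rf(counts: np.ndarray, type_a: FundamentalType,
                    type_b: FundamentalType, phase: PhaseClass) -> Optional[float]:
    """Closed-form r-hat = recombinants/total for 1:1 x 1:1 coupling in one parent."""
    d1 = phase.dosages1
    d2 = phase.dosages2
    informative1 = d1[0] > 0 and d1[1] > 0
    informative2 = d2[0] > 0 and d2[1] > 0
    if informative1 and not informative2 and d1 == (1, 1) and phase.m1 == 1:
        sub = counts[:2, :2]
    elif informative2 and not informative1 and d2 == (1, 1) and phase.m2 == 1:
        sub = counts[:2, :2]
    else:
        return None
    total = sub.sum()
    if total == 0:
        return None
    rec = sub[0, 1] + sub[1, 0]
    return min(float(rec / total), 0.5)


# ---------------------------------------------------------------------------
# Phase selection
# ---------------------------------------------------------------------------

def _is_sxs_sxt(type_a: FundamentalType, type_b: FundamentalType) -> bool:
    return {type_a, type_b} == {FundamentalType.SxS, FundamentalType.SxT}


def _sxs_sxt_excluded(type_a: FundamentalType, type_b: FundamentalType,
                      phase: PhaseClass) -> bool:
    """The essentially inestimable repulsion/coupling phase of S x S with S x T.

    In P1 both markers are simplex (repulsion = zero overlap); in P2 the
    simplex-triplex overlap 1 is coupling.  Estimates of r in this phase are
    essentially random, so its LOD is forced to 0 and it is never selected.
    """
    if not _is_sxs_sxt(type_a, type_b):
        return False
    return phase.m1 == 0 and phase.m2 == 1


def select_phase(estimates: Sequence[PairwiseEstimate], strategy: str = "MLL") -> PairwiseEstimate:
    """Select the most likely phase from per-phase estimates.

    ``strategy`` is "MLL" (maximum log-likelihood) or "MINR" (minimum r-hat).
    Estimates flagged ``excluded`` never win; if every candidate is a sentinel
    or excluded, the sentinel (phase unknown) is returned.  Ties break towards
    the first candidate, which by construction is the coupling-most phase.
    """
    if not estimates:
        raise ValueError("no phase estimates to select from")
    candidates = [e for e in estimates if not e.excluded and not e.sentinel and e.estimated]
    if not candidates:
        for e in estimates:
            if e.sentinel:
                return e
        return estimates[0]
    if strategy.upper() == "MLL":
        best = max(candidates, key=lambda e: e.loglik)
    elif strategy.upper() == "MINR":
        best = min(candidates, key=lambda e: e.rf)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return best


def estimate_pair(offspring_a: np.ndarray, offspring_b: np.ndarray,
                  type_a: FundamentalType, type_b: FundamentalType,
                  strategy: str = "MLL") -> tuple[PairwiseEstimate, list[PairwiseEstimate]]:
    """Estimate r, LOD and phase for one marker pair from offspring dosages.

    Only individuals scored at both markers enter the 5x5 count table.  Returns
    the selected estimate and the full per-phase list.
    """
    counts = cross_tabulate(offspring_a, offspring_b)
    phases = enumerate_phases(type_a, type_b)
    if not phases or all(ph.m1 is None and ph.m2 is None for ph in phases):
        est = PairwiseEstimate(np.nan, 0.0, np.nan, None, 0, estimated=False)
        return est, []
    per_phase = []
    for ph in phases:
        e = estimate_rf(counts, type_a, type_b, ph)
        if _sxs_sxt_excluded(type_a, type_b, ph):
            e.lod = 0.0
            e.excluded = True
        per_phase.append(e)
    return select_phase(per_phase, strategy), per_phase


def cross_tabulate(offspring_a: np.ndarray, offspring_b: np.ndarray) -> np.ndarray:
    """5x5 joint dosage counts over individuals complete at both markers."""
    a = np.asarray(offspring_a)
    b = np.asarray(offspring_b)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(np.int64), b[ok].astype(np.int64)
    return np.bincount(a * 5 + b, minlength=25).reshape(5, 5).astype(float)


def indistinguishable_groups(type_a: FundamentalType, type_b: FundamentalType
                             ) -> list[list[PhaseClass]]:
    """Group phases whose likelihood curves are identical.

    Some phase combinations (e.g. S x S with D x D coupling-repulsion vs
    repulsion-coupling) produce exactly the same offspring table for every r
    and can never be told apart; for phasing accuracy both count as correct.
    Detected by comparing tables at probe values of r.
    """
    phases = enumerate_phases(type_a, type_b)
    probes = (0.0731, 0.2173, 0.4211)
    sigs = []
    for ph in phases:
        coeffs = offspring_table_poly(_phase_key(type_a, type_b, ph))
        sig = tuple((np.round(np.tensordot(np.array([r**d for d in range(5)]), coeffs, axes=1),
                              12) + 0.0).ravel().tobytes() for r in probes)
        sigs.append(sig)
    groups: dict[tuple, list[PhaseClass]] = {}
    for ph, sig in zip(phases, sigs):
        groups.setdefault(sig, []).append(ph)
    return list(groups.values())


# ---------------------------------------------------------------------------
# All-pairs matrices
# ---------------------------------------------------------------------------

@dataclass
class PairwiseResult:
    """Symmetric r / LOD / phase matrices over a marker panel."""

    marker_ids: list[str]
    rf: np.ndarray
    lod: np.ndarray
    phase: np.ndarray  # object array of phase labels ("" where absent)
    not_estimated: np.ndarray  # boolean

    def to_frames(self):
        import pandas as pd
        ids = self.marker_ids
        return (pd.DataFrame(self.rf, index=ids, columns=ids),
                pd.DataFrame(self.lod, index=ids, columns=ids),
                pd.DataFrame(self.phase, index=ids, columns=ids))


def _simplex_repulsion_pair(type_a, type_b, est: PairwiseEstimate) -> bool:
    """S x N - S x N (or N x S) pairs whose selected phase is repulsion.

    Their repulsion-phase estimates have very high variance and are not worth
    exploiting in homologue mapping; they are recorded as absent.
    """
    one_to_one = {FundamentalType.SxN, FundamentalType.NxS}
    if type_a not in one_to_one or type_b not in one_to_one:
        return False
    if est.phase is None:
        return False
    return "repulsion" in est.phase.label


def pairwise_matrix(offspring: dict[str, np.ndarray],
                    types: dict[str, FundamentalType],
                    strategy: str = "MLL",
                    exclude_simplex_repulsion: bool = True,
                    pairs: Optional[Sequence[tuple[str, str]]] = None) -> PairwiseResult:
    """Estimate r/LOD/phase for every marker pair of a panel.

    ``offspring`` maps marker id -> dosage vector over the shared panel.
    Diagonal r is 0; pairs with no informative parent in common, not-estimated
    pairs and (optionally) simplex-simplex repulsion linkages are NaN/absent.
    """
    ids = list(offspring)
    k = len(ids)
    rf = np.full((k, k), np.nan)
    lod = np.zeros((k, k))
    phase = np.full((k, k), "", dtype=object)
    not_est = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(rf, 0.0)
    index = {m: i for i, m in enumerate(ids)}
    it = pairs if pairs is not None else itertools.combinations(ids, 2)
    for ma, mb in it:
        i, j = index[ma], index[mb]
        est, _ = estimate_pair(offspring[ma], offspring[mb], types[ma], types[mb], strategy)
        if not est.estimated or est.sentinel:
            not_est[i, j] = not_est[j, i] = True
            continue
        if exclude_simplex_repulsion and _simplex_repulsion_pair(types[ma], types[mb], est):
            continue
        rf[i, j] = rf[j, i] = est.rf
        lod[i, j] = lod[j, i] = est.lod
        phase[i, j] = phase[j, i] = est.phase_label
    return PairwiseResult(ids, rf, lod, phase, not_est)


def write_pwd(result: PairwiseResult, path, population_name: str = "F1",
              population_size: int = 0):
    """Export pairwise estimates in the JoinMap pairwise-data (.pwd) dialect."""
    with open(path, "w") as fh:
        fh.write(f"; pairwise data\nname = {population_name}\n"
                 f"popt = CP\nnloc = {len(result.marker_ids)}\n"
                 f"nind = {population_size}\n\n")
        ids = result.marker_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if np.isfinite(result.rf[i, j]):
                    fh.write(f"{ids[i]}\t{ids[j]}\t{result.rf[i, j]:.4f}\t"
                             f"{result.lod[i, j]:.2f}\n")
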