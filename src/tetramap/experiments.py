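"""Scripted simulation studies validating the mapping assumptions.

Three studies, all seeded and reproducible:

* ``phasing_accuracy_study`` -- compare the maximum-log-likelihood (MLL) and
  minimum-r (MINR) phase selection strategies on simulated populations
  (100 loci spaced 1 cM, all nine segregation types per locus, random
  homologue assignment) across population sizes.
* ``binning_calibration_study`` -- calibrate the binning LOD threshold: for
  estimates below the threshold of minimum resolution, find the LOD above
  which the estimation error in r stays below a cap (0.01), across population
  sizes and missing rates, and regress the thresholds on the adjusted
  population size N_a.
* ``pairing_robustness_study`` -- estimate r and phase under the random
  bivalent model while the simulated populations deviate from it
  (quadrivalent fraction q or preferential pairing p), recording the
  regression of estimated on true r, the fraction of pairs not estimated and
  the fraction correctly phased.

Population counts can be large; the studies therefore subsample marker pairs
uniformly at random per replicate (an unbiased estimate of the all-pairs
average) with the sample size as a parameter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tetramap.markers import FundamentalType
from tetramap.meiosis import MeiosisModel, random_marker_layout, simulate_cross
from tetramap.pairwise import (PhaseClass, enumerate_phases, estimate_pair,
                               indistinguishable_groups)

__all__ = [
    "StudyGrid",
    "score_population",
    "phasing_accuracy_study",
    "accuracy_summary",
    "binning_calibration_study",
    "pairing_robustness_study",
]


@dataclass
class StudyGrid:
    """Grid of the pairing robustness study."""

    sizes: tuple = (100, 200, 400)
    replicates: int = 100
    q_levels: tuple = tuple(np.round(np.arange(0, 1.01, 0.1), 1))
    p_levels: tuple = tuple(np.round(np.arange(0, 1.01, 0.1), 1))
    strategy: str = "MLL"

    @property
    def n_populations(self) -> int:
        return (len(self.q_levels) + len(self.p_levels)) * len(self.sizes) * self.replicates


def _informative(t_a: FundamentalType, t_b: FundamentalType) -> bool:
    (a1, a2), (b1, b2) = t_a.parental_dosages, t_b.parental_dosages
    return (a1 > 0 and b1 > 0) or (a2 > 0 and b2 > 0)


def _sample_pairs(pop, rng: np.random.Generator, max_pairs: Optional[int],
                  pair_filter: Optional[Callable] = None) -> list[tuple[int, int]]:
    m = len(pop.marker_ids)
    tlist = pop.marker_types

    def ok(i, j):
        if not _informative(tlist[i], tlist[j]):
            return False
        if pair_filter is not None and not pair_filter(i, j):
            return False
        return True

    if max_pairs is None:
        return [(i, j) for i, j in itertools.combinations(range(m), 2) if ok(i, j)]
    pairs: set = set()
    attempts = 0
    while len(pairs) < max_pairs and attempts < max_pairs * 60:
        i, j = rng.integers(0, m, size=2)
        attempts += 1
        if i == j:
            continue
        i, j = (int(min(i, j)), int(max(i, j)))
        if (i, j) in pairs or not ok(i, j):
            continue
        pairs.add((i, j))
    return sorted(pairs)


def _truth_group_lookup(t_a: FundamentalType, t_b: FundamentalType):
    """Map true overlaps -> set of overlap tuples counted as correct."""
    groups = indistinguishable_groups(t_a, t_b)
    lookup = {}
    for grp in groups:
        keys = {ph.overlaps for ph in grp}
        for k in keys:
            lookup[k] = keys
    return lookup


_GROUP_CACHE: dict = {}


def score_population(pop, strategies: Sequence[str] = ("MLL", "MINR"),
                     max_pairs: Optional[int] = 500, seed=None,
                     pair_filter: Optional[Callable] = None) -> pd.DataFrame:
    """Estimate sampled marker pairs of a population and score against truth.

    One row per (pair, strategy) with the estimate, the true r, whether the
    pair was estimable and whether the selected phase is correct (phases with
    identical likelihood curves both count as correct).  Pairs for which every
    admissible phase is inestimable are flagged ``not_estimated``; those rows
    carry no phase-correctness information.
    """
    rng = np.random.default_rng(seed)
    pairs = _sample_pairs(pop, rng, max_pairs, pair_filter)
    tlist = pop.marker_types
    rows = []
    for i, j in pairs:
        t_a, t_b = tlist[i], tlist[j]
        truth = pop.true_overlaps(pop.marker_ids[i], pop.marker_ids[j])
        r_true = pop.true_rf(pop.marker_ids[i], pop.marker_ids[j])
        key = (t_a, t_b)
        if key not in _GROUP_CACHE:
            _GROUP_CACHE[key] = _truth_group_lookup(t_a, t_b)
        lookup = _GROUP_CACHE[key]
        _, per_phase = estimate_pair(pop.dosages[i], pop.dosages[j], t_a, t_b,
                                     strategy=strategies[0])
        for strat in strategies:
            if per_phase:
                from tetramap.pairwise import select_phase
                est = select_phase(per_phase, strat)
                not_est = (not est.estimated) or est.sentinel
            else:
                est = None
                not_est = True
            # score per parental "pairing situation": each informative parent's
            # phase counts separately; a selection whose full phase lies in the
            # truth's indistinguishable group is entirely correct
            n_sit = sum(m is not None for m in truth)
            n_ok = np.nan
            if not not_est and est.phase is not None and truth in lookup:
                sel = est.phase.overlaps
                if sel in lookup[truth]:
                    n_ok = n_sit
                else:
                    n_ok = sum(1 for a, b in zip(sel, truth)
                               if a is not None and a == b)
            rows.append({
                "marker_a": pop.marker_ids[i], "marker_b": pop.marker_ids[j],
                "type_a": t_a.name, "type_b": t_b.name, "strategy": strat,
                "r_true": r_true,
                "r_hat": est.rf if est is not None else np.nan,
                "lod": est.lod if est is not None else np.nan,
                "not_estimated": not_est,
                "n_situations": n_sit,
                "n_correct": n_ok,
                "correct": (n_ok / n_sit) if n_sit and n_ok == n_ok else np.nan,
            })
    return pd.DataFrame(rows)


def phasing_accuracy_study(sizes: Sequence[int] = (100, 200, 400),
                           replicates: int = 100,
                           strategies: Sequence[str] = ("MLL", "MINR"),
                           seed: int = 0,
                           n_loci: int = 100, spacing_cM: float = 1.0,
                           types: Sequence[FundamentalType] = tuple(FundamentalType),
                           max_pairs: Optional[int] = 500,
                           restrict_type_pair: Optional[tuple[str, str]] = None
                           ) -> pd.DataFrame:
    """Phasing accuracy of MLL and MINR across population sizes.

    Per replicate a fresh marker layout is drawn, an F1 population simulated
    under random bivalent pairing (q = 0, p = 0), and sampled admissible pairs
    phased with each strategy.  ``restrict_type_pair`` (e.g. ("SxS", "SxS"))
    limits scoring to one marker-type combination.  Returns one row per
    (size, replicate, pair, strategy).
    """
    ss = np.random.SeedSequence(seed)
    out = []
    model = MeiosisModel(q=0.0, p=0.0)
    for size in sizes:
        for rep in range(replicates):
            child = ss.spawn(1)[0]
            rngs = [np.random.default_rng(s) for s in child.spawn(3)]
            g1, g2 = random_marker_layout(n_loci, spacing_cM, types, seed=rngs[0])
            pop = simulate_cross(g1, g2, model, size, seed=rngs[1])
            pair_filter = None
            if restrict_type_pair is not None:
                want = set(restrict_type_pair)
                tl = pop.marker_types
                pair_filter = (lambda i, j, tl=tl, want=want:
                               {tl[i].name, tl[j].name} <= want)
            df = score_population(pop, strategies, max_pairs, seed=rngs[2],
                                  pair_filter=pair_filter)
            df.insert(0, "size", size)
            df.insert(1, "replicate", rep)
            out.append(df)
    return pd.concat(out, ignore_index=True)


def accuracy_summary(results: pd.DataFrame, by=("size", "strategy")) -> pd.DataFrame:
    """Mean phasing accuracy (%) over parental pairing situations.

    Each informative parent of a pair is one situation; inestimable pairs are
    excluded from the denominator (they are tracked separately as the
    not-estimated fraction).
    """
    est = results[~results["not_estimated"] & results["correct"].notna()]
    g = est.groupby(list(by)).apply(
        lambda d: 100.0 * d["n_correct"].sum() / d["n_situations"].sum(),
        include_groups=False).rename("accuracy_pct")
    n = est.groupby(list(by))["correct"].size().rename("n_pairs")
    return pd.concat([g, n], axis=1).reset_index()


def binning_calibration_study(sizes: Sequence[int] = tuple(range(100, 1001, 100)),
                              mus: Sequence[float] = (0.0, 0.05, 0.10, 0.15, 0.20),
                              deviation_cap: float = 0.01,
                              seed: int = 0,
                              n_loci: int = 12, spacing_cM: float = 0.25,
                              max_pairs: Optional[int] = 400,
                              replicates: int = 3) -> dict:
    """Calibrate the binning LOD threshold as a function of N_a.

    For each (N, mu): simulate tightly spaced markers, collect estimates below
    r_min, and record the most stringent LOD needed so that every estimate
    above it deviates from the true r by less than ``deviation_cap`` (taken
    across marker-type combinations).  A linear regression of thresholds on
    N_a = (1 - mu) N returns the empirical intercept and slope.  A single-cell
    grid cannot support the regression and is flagged degenerate.
    """
    from tetramap.mapbuild import binning_thresholds

    ss = np.random.SeedSequence(seed)
    rows = []
    model = MeiosisModel()
    for size in sizes:
        for mu in mus:
            thr = binning_thresholds(size, mu)
            lods_bad, lods_good = {}, {}
            for rep in range(replicates):
                child = ss.spawn(1)[0]
                rngs = [np.random.default_rng(s) for s in child.spawn(4)]
                g1, g2 = random_marker_layout(n_loci, spacing_cM,
                                              tuple(FundamentalType), seed=rngs[0])
                pop = simulate_cross(g1, g2, model, size, seed=rngs[1])
                if mu > 0:
                    pop = pop.apply_missingness(mu, seed=rngs[2])
                df = score_population(pop, ("MLL",), max_pairs, seed=rngs[3])
                sub = df[~df["not_estimated"] & (df["r_hat"] < thr.r_min)]
                for _, row in sub.iterrows():
                    tp = tuple(sorted((row["type_a"], row["type_b"])))
                    dev = abs(row["r_hat"] - row["r_true"])
                    (lods_bad if dev >= deviation_cap else lods_good).setdefault(
                        tp, []).append(row["lod"])
            per_tp = []
            for tp in set(lods_bad) | set(lods_good):
                bad = lods_bad.get(tp, [])
                good = lods_good.get(tp, [])
                if bad:
                    per_tp.append(max(bad))
                elif good:
                    per_tp.append(min(good))
            if per_tp:
                rows.append({"N": size, "mu": mu, "N_a": thr.N_a,
                             "lod_threshold": max(per_tp)})
    table = pd.DataFrame(rows)
    out = {"table": table, "intercept": np.nan, "slope": np.nan, "degenerate": True}
    if len(table) and table["N_a"].nunique() >= 2:
        fit = stats.linregress(table["N_a"], table["lod_threshold"])
        out.update(intercept=float(fit.intercept), slope=float(fit.slope),
                   degenerate=False, r2=float(fit.rvalue**2))
    return out


def preferential_inestimable_study(n_populations: int = 6, size: int = 200,
                                   seed: int = 0, n_loci: int = 50,
                                   spacing_cM: float = 2.0,
                                   max_pairs_per_pop: int = 300) -> dict:
    """Fraction of duplex-simplex pairs inestimable under fully disomic pairing.

    Under fully preferential pairing (p = 1) a duplex allele whose two copies
    sit on the two homologues of one preferred bivalent is transmitted exactly
    once per gamete: the offspring dosage of the duplex marker is constant and
    the likelihood of any pair with a simplex marker in the same parent is
    exactly flat in r -- no estimate exists.  With carrier homologues assigned
    uniformly at random this happens for 2 of the 6 possible duplex
    configurations, so about a third of duplex-simplex combinations are
    inestimable.  Measured here on simulated DxN-vs-SxN (and NxD-vs-NxS)
    pairs, whose only information is the duplex/simplex parent.
    """
    ss = np.random.SeedSequence(seed)
    model = MeiosisModel(q=0.0, p=1.0)
    types = (FundamentalType.SxN, FundamentalType.DxN,
             FundamentalType.NxS, FundamentalType.NxD)
    total = not_est = 0
    for _ in range(n_populations):
        rngs = [np.random.default_rng(s) for s in ss.spawn(1)[0].spawn(3)]
        g1, g2 = random_marker_layout(n_loci, spacing_cM, types, seed=rngs[0])
        pop = simulate_cross(g1, g2, model, size, seed=rngs[1])
        tl = pop.marker_types

        def duplex_simplex(i, j, tl=tl):
            names = {tl[i].name, tl[j].name}
            return names in ({"SxN", "DxN"}, {"NxS", "NxD"})

        df = score_population(pop, ("MLL",), max_pairs_per_pop, seed=rngs[2],
                              pair_filter=duplex_simplex)
        total += len(df)
        not_est += int(df["not_estimated"].sum())
    frac = not_est / total if total else np.nan
    return {"fraction_inestimable": frac, "pct_inestimable": 100.0 * frac,
            "n_pairs": total}


def pairing_robustness_study(grid: StudyGrid, seed: int = 0,
                             n_loci: int = 100, spacing_cM: float = 1.0,
                             max_pairs: Optional[int] = 300) -> pd.DataFrame:
    """Robustness of r estimation and phasing to quadrivalents / preferential pairing.

    The estimator always assumes random bivalent pairing; the simulated
    populations deviate (q or p varied separately).  Per grid cell, pairs are
    pooled over replicates and summarised by the regression of estimated on
    true r (slope, intercept, adjusted R^2, residual SD), the fraction of
    pairs not estimated, and the fraction correctly phased.
    """
    ss = np.random.SeedSequence(seed)
    cells = ([("q", q) for q in grid.q_levels] + [("p", p) for p in grid.p_levels])
    rows = []
    for kind, level in cells:
        model = MeiosisModel(q=level if kind == "q" else 0.0,
                             p=level if kind == "p" else 0.0)
        for size in grid.sizes:
            dfs = []
            for rep in range(grid.replicates):
                child = ss.spawn(1)[0]
                rngs = [np.random.default_rng(s) for s in child.spawn(3)]
                g1, g2 = random_marker_layout(n_loci, spacing_cM,
                                              tuple(FundamentalType), seed=rngs[0])
                pop = simulate_cross(g1, g2, model, size, seed=rngs[1])
                dfs.append(score_population(pop, (grid.strategy,), max_pairs,
                                            seed=rngs[2]))
            df = pd.concat(dfs, ignore_index=True)
            est = df[~df["not_estimated"]]
            rec = {"vary": kind, "level": level, "size": size,
                   "n_pairs": len(df),
                   "frac_not_estimated": float(df["not_estimated"].mean()),
                   "frac_correct_phase": float(est["correct"].mean())
                   if est["correct"].notna().any() else np.nan}
            if len(est) >= 3 and est["r_true"].std() > 0:
                fit = stats.linregress(est["r_true"], est["r_hat"])
                resid = est["r_hat"] - (fit.intercept + fit.slope * est["r_true"])
                n = len(est)
                r2_adj = 1 - (1 - fit.rvalue**2) * (n - 1) / (n - 2)
                rec.update(slope=float(fit.slope), intercept=float(fit.intercept),
                           r2_adj=float(r2_adj), resid_sd=float(resid.std()))
            else:
                rec.update(slope=np.nan, intercept=np.nan, r2_adj=np.nan,
                           resid_sd=np.nan)
            rows.append(rec)
    return pd.DataFrame(rows)
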