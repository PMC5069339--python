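"""Joint dosage distributions, ML estimation of r, LOD and phase selection."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from tetramap.markers import FundamentalType, expected_marginal_segregation
from tetramap.pairwise import (
    PAIRINGS,
    admissible_overlaps,
    canonical_sets,
    cross_tabulate,
    enumerate_phases,
    estimate_pair,
    estimate_rf,
    gamete_joint_distribution,
    gamete_table_poly,
    indistinguishable_groups,
    offspring_joint_distribution,
    pairwise_matrix,
    select_phase,
    PairwiseEstimate,
)


# ---------------------------------------------------------------------------
# Independent brute-force oracle: enumerate transmissions of both bivalents
# ---------------------------------------------------------------------------

def oracle_gamete_table(s_a, s_b, r: Fraction):
    """Exact gamete joint distribution by direct enumeration (Fractions)."""
    table = np.zeros((3, 3), dtype=object)
    table[:] = Fraction(0)
    for (b1, b2) in PAIRINGS:
        for t1a, t1b in itertools.product(b1, repeat=2):
            p1 = (1 - r) / 2 if t1a == t1b else r / 2
            for t2a, t2b in itertools.product(b2, repeat=2):
                p2 = (1 - r) / 2 if t2a == t2b else r / 2
                ga = int(t1a in s_a) + int(t2a in s_a)
                gb = int(t1b in s_b) + int(t2b in s_b)
                table[ga, gb] += Fraction(1, 3) * p1 * p2
    return table


def _poly_at(coeffs, r: Fraction):
    out = np.zeros(coeffs.shape[1:], dtype=object)
    out[:] = Fraction(0)
    for d in range(coeffs.shape[0]):
        out = out + coeffs[d] * r**d
    return out


ALL_PARENT_CONFIGS = [
    (a, b, m)
    for a in range(1, 4) for b in range(1, 4)
    for m in admissible_overlaps(a, b)
]


class TestGameteTables:
    @pytest.mark.parametrize("a,b,m", ALL_PARENT_CONFIGS)
    @pytest.mark.parametrize("r", [Fraction(0), Fraction(1, 10), Fraction(1, 4), Fraction(1, 2)])
    def test_exact_equality_with_enumeration_oracle(self, a, b, m, r):
        s_a, s_b = canonical_sets(a, b, m)
        got = _poly_at(gamete_table_poly(s_a, s_b), r)
        want = oracle_gamete_table(s_a, s_b, r)
        assert np.array_equal(got, want)

    def test_simplex_coupling_closed_form(self):
        g = gamete_joint_distribution({0}, {0}, 0.2)
        assert g[1, 1] == pytest.approx(0.4) and g[0, 0] == pytest.approx(0.4)
        assert g[1, 0] == pytest.approx(0.1) and g[0, 1] == pytest.approx(0.1)

    def test_simplex_repulsion_closed_form(self):
        g = gamete_joint_distribution({0}, {1}, 0.2)
        assert g[1, 1] == pytest.approx(1.2 / 6) and g[0, 0] == pytest.approx(1.2 / 6)
        assert g[1, 0] == pytest.approx(1.8 / 6) and g[0, 1] == pytest.approx(1.8 / 6)

    def test_duplex_marginal_one_four_one(self):
        g = gamete_joint_distribution({0, 1}, {0, 2}, 0.3)
        np.testing.assert_allclose(g.sum(axis=1), [1 / 6, 4 / 6, 1 / 6])

    @pytest.mark.parametrize("s_b", [{0}, {1}])
    def test_independence_at_half_for_simplex_sets(self, s_b):
        """With a simplex set at one locus the loci decouple at r = 0.5."""
        g = gamete_joint_distribution({0}, s_b, 0.5)
        np.testing.assert_allclose(g, np.outer(g.sum(axis=1), g.sum(axis=0)), atol=1e-12)

    def test_duplex_sets_stay_correlated_at_half(self):
        """The shared pairing keeps duplex dosages dependent even at r = 0.5."""
        g = gamete_joint_distribution({0, 1}, {0, 1}, 0.5)
        assert abs(g[1, 1] - g.sum(axis=1)[1] * g.sum(axis=0)[1]) > 0.05

    def test_full_preferential_pairing_duplex_fixed(self):
        # duplex on one preferred bivalent transmits exactly one copy
        g = gamete_joint_distribution({0, 1}, {0}, 0.1, p=1.0)
        np.testing.assert_allclose(g.sum(axis=1), [0, 1, 0], atol=1e-12)


class TestOffspringTables:
    ALL_TYPE_PAIRS = list(itertools.combinations_with_replacement(FundamentalType, 2))

    @pytest.mark.parametrize("ta,tb", ALL_TYPE_PAIRS,
                             ids=lambda v: v.name if hasattr(v, "name") else str(v))
    def test_rows_sum_to_marginal_segregation(self, ta, tb):
        exp_a = np.array([float(p) for p in expected_marginal_segregation(ta)])
        exp_b = np.array([float(p) for p in expected_marginal_segregation(tb)])
        for phase in enumerate_phases(ta, tb):
            table = offspring_joint_distribution(ta, tb, phase, 0.17)
            assert table.min() >= -1e-12
            assert table.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(table.sum(axis=1), exp_a, atol=1e-10)
            np.testing.assert_allclose(table.sum(axis=0), exp_b, atol=1e-10)

    def test_sxn_coupling_r0_concentrates_on_diagonal(self):
        ta = tb = FundamentalType.SxN
        phase = enumerate_phases(ta, tb)[0]  # coupling first
        table = offspring_joint_distribution(ta, tb, phase, 0.0)
        assert table[0, 0] == pytest.approx(0.5)
        assert table[1, 1] == pytest.approx(0.5)
        assert table.sum() == pytest.approx(1.0)

    def test_dxd_all_coupling_r0_diagonal_is_duplex_ratio(self):
        ta = tb = FundamentalType.DxD
        phase = enumerate_phases(ta, tb)[0]
        table = offspring_joint_distribution(ta, tb, phase, 0.0)
        np.testing.assert_allclose(np.diag(table),
                                   np.array([1, 8, 18, 8, 1]) / 36, atol=1e-12)
        assert np.abs(table - np.diag(np.diag(table))).max() < 1e-12

    def test_coupling_and_repulsion_coincide_at_half(self):
        """Extreme phases (complement sets) are indistinguishable at r = 0.5."""
        for ta, tb in [(FundamentalType.SxS, FundamentalType.SxS),
                       (FundamentalType.DxN, FundamentalType.DxN)]:
            phases = enumerate_phases(ta, tb)
            tables = {ph.overlaps: offspring_joint_distribution(ta, tb, ph, 0.5)
                      for ph in phases}
            keys = sorted(k for k in tables if k[0] is not None)
            np.testing.assert_allclose(tables[keys[0]], tables[keys[-1]], atol=1e-12)


class TestEstimateRF:
    def _counts_sxn_coupling(self, parental, recomb):
        c = np.zeros((5, 5))
        c[0, 0] = c[1, 1] = parental / 2
        c[0, 1] = c[1, 0] = recomb / 2
        return c

    def test_closed_form_simplex_coupling(self):
        phase = enumerate_phases(FundamentalType.SxN, FundamentalType.SxN)[0]
        est = estimate_rf(self._counts_sxn_coupling(90, 10),
                          FundamentalType.SxN, FundamentalType.SxN, phase)
        assert est.rf == pytest.approx(0.10)
        assert est.lod > 0

    def test_identical_markers_rf_zero_max_lod(self):
        phase = enumerate_phases(FundamentalType.SxN, FundamentalType.SxN)[0]
        est = estimate_rf(self._counts_sxn_coupling(100, 0),
                          FundamentalType.SxN, FundamentalType.SxN, phase)
        assert est.rf == 0.0
        # maximal LOD for n=100: log10 L(0) - log10 L(0.5) = 100 log10 2
        assert est.lod == pytest.approx(100 * np.log10(2), rel=1e-6)

    def test_negative_optimum_sentinel(self):
        """Repulsion data favouring r < 0 return the sentinel estimate."""
        # SxN x SxN repulsion: r_hat = (2k - m)/(k + m) < 0 when m > 2k
        phases = enumerate_phases(FundamentalType.SxN, FundamentalType.SxN)
        rep = [p for p in phases if p.label == "repulsion"][0]
        c = np.zeros((5, 5))
        c[0, 0] = c[1, 1] = 10   # k = 20
        c[0, 1] = c[1, 0] = 45   # m = 90
        est = estimate_rf(c, FundamentalType.SxN, FundamentalType.SxN, rep)
        assert est.sentinel
        assert est.rf == pytest.approx(0.499)
        assert est.lod == 0.0
        assert est.phase_label == "unknown"

    def test_all_missing_not_estimated(self):
        phase = enumerate_phases(FundamentalType.SxN, FundamentalType.SxN)[0]
        est = estimate_rf(np.zeros((5, 5)), FundamentalType.SxN,
                          FundamentalType.SxN, phase)
        assert not est.estimated

    def test_repulsion_recovery_within_three_se(self):
        """Simulated SxN repulsion pair, n=200, true r=0.1: r_hat within 3 SE."""
        from tetramap.meiosis import MeiosisModel, ParentGenome, simulate_cross
        h1 = np.zeros((4, 2), dtype=np.int8)
        h1[0, 0] = 1  # marker A on homologue 0
        h1[1, 1] = 1  # marker B on homologue 1 (repulsion)
        g1 = ParentGenome(["a", "b"], [0.0, 11.157], h1)  # Haldane d(0.1)
        g2 = ParentGenome(["a", "b"], [0.0, 11.157], np.zeros((4, 2), dtype=np.int8))
        rng = np.random.default_rng(4242)
        rep = [p for p in enumerate_phases(FundamentalType.SxN, FundamentalType.SxN)
               if p.label == "repulsion"][0]
        # Fisher information of the repulsion likelihood at r = 0.1 (numeric)
        eps = 1e-5
        tables = [offspring_joint_distribution(FundamentalType.SxN,
                                               FundamentalType.SxN, rep, r)
                  for r in (0.1 - eps, 0.1, 0.1 + eps)]
        dp = (tables[2] - tables[0]) / (2 * eps)
        mask = tables[1] > 0
        info = float((dp[mask] ** 2 / tables[1][mask]).sum())
        se = 1.0 / np.sqrt(200 * info)
        pop = simulate_cross(g1, g2, MeiosisModel(), 200, seed=rng)
        counts = cross_tabulate(pop.dosages[0], pop.dosages[1])
        est = estimate_rf(counts, FundamentalType.SxN, FundamentalType.SxN, rep)
        assert abs(est.rf - 0.1) < 3 * se


class TestPhaseSelection:
    def _mk(self, rf, loglik, phase):
        return PairwiseEstimate(rf, 1.0, loglik, phase)

    def test_mll_vs_minr(self):
        phases = enumerate_phases(FundamentalType.SxS, FundamentalType.SxS)
        ests = [self._mk(0.4, -10.0, phases[0]), self._mk(0.1, -12.0, phases[1])]
        assert select_phase(ests, "MLL") is ests[0]
        assert select_phase(ests, "MINR") is ests[1]

    def test_excluded_phase_never_selected(self):
        ta, tb = FundamentalType.SxS, FundamentalType.SxT
        phases = enumerate_phases(ta, tb)
        ests = []
        for ph in phases:
            e = self._mk(0.25, -5.0, ph)
            if ph.m1 == 0 and ph.m2 == 1:  # repulsion/coupling
                e.loglik = 0.0  # would win MLL if admissible
                e.excluded = True
            ests.append(e)
        best = select_phase(ests, "MLL")
        assert not (best.phase.m1 == 0 and best.phase.m2 == 1)

    def test_sxs_sxt_exclusion_applied_in_estimate_pair(self, pop_all_types):
        tl = pop_all_types.marker_types
        ids = range(len(tl))
        pairs = [(i, j) for i, j in itertools.combinations(ids, 2)
                 if {tl[i].name, tl[j].name} == {"SxS", "SxT"}][:20]
        assert pairs
        for i, j in pairs:
            _, per_phase = estimate_pair(pop_all_types.dosages[i],
                                         pop_all_types.dosages[j], tl[i], tl[j])
            for e in per_phase:
                if e.phase is not None and (e.phase.m1, e.phase.m2) == (0, 1):
                    assert e.excluded and e.lod == 0.0

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            select_phase([])

    def test_indistinguishable_cross_parent_swap(self):
        groups = indistinguishable_groups(FundamentalType.SxS, FundamentalType.DxD)
        # coupling-repulsion vs repulsion-coupling fall in one group
        hit = False
        for grp in groups:
            keys = {ph.overlaps for ph in grp}
            if (1, 0) in keys:
                assert (0, 1) in keys
                hit = True
        assert hit


class TestPairwiseMatrix:
    def test_cosegregating_markers_zero_r(self):
        off = np.array([0, 1] * 50)
        offspring = {f"m{i}": off for i in range(3)}
        types = {f"m{i}": FundamentalType.SxN for i in range(3)}
        res = pairwise_matrix(offspring, types)
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(res.rf[iu], 0.0)
        assert (res.lod[iu] > 10).all()

    def test_matrix_matches_single_pair_calls(self, pop_all_types):
        ids = pop_all_types.marker_ids[:8]
        off = {m: pop_all_types.offspring_dict()[m] for m in ids}
        types = {m: pop_all_types.types_dict()[m] for m in ids}
        res = pairwise_matrix(off, types, exclude_simplex_repulsion=False)
        n_pairs = 8 * 7 // 2
        finite = np.isfinite(res.rf[np.triu_indices(8, 1)]).sum()
        ne = res.not_estimated[np.triu_indices(8, 1)].sum()
        uninformative = sum(
            1 for a, b in itertools.combinations(ids, 2)
            if not any(types[a].parental_dosages[k] and types[b].parental_dosages[k]
                       for k in (0, 1)))
        # uninformative pairs are a subset of the not-estimated ones
        assert finite + ne == n_pairs
        assert ne >= uninformative
        a, b = ids[0], ids[1]
        est, _ = estimate_pair(off[a], off[b], types[a], types[b])
        if est.estimated and not est.sentinel:
            assert res.rf[0, 1] == pytest.approx(est.rf)
        # symmetry
        np.testing.assert_array_equal(res.rf, res.rf.T)
        np.testing.assert_array_equal(res.lod, res.lod.T)
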