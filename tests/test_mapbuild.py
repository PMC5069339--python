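"""Binning thresholds, cosegregation bins, WLS ordering and the Haldane function."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tetramap.markers import FundamentalType, MISSING
from tetramap.meiosis import MeiosisModel, ParentGenome, random_marker_layout, simulate_cross
from tetramap.pairwise import pairwise_matrix
from tetramap.mapbuild import (
    HomologueMap,
    bin_markers,
    binning_thresholds,
    haldane_cM,
    haldane_inverse,
    order_exhaustive,
    order_homologue,
    reinsert_binned,
)


class TestHaldane:
    @given(r=st.floats(0.0, 0.49))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, r):
        assert haldane_inverse(haldane_cM(r)) == pytest.approx(r, abs=1e-12)

    def test_one_percent_recombination(self):
        assert haldane_cM(0.01) == pytest.approx(1.0101, abs=1e-4)


class TestBinningThresholds:
    def test_direct_arithmetic(self):
        thr = binning_thresholds(235, 0.0)
        assert thr.r_min == pytest.approx(1 / 470)
        assert thr.lod_min == pytest.approx(23.43 + 0.1158 * 235)

    def test_missing_adjustment(self):
        thr = binning_thresholds(100, 0.2)
        assert thr.N_a == pytest.approx(80)
        assert thr.r_min == pytest.approx(0.00625)
        assert thr.lod_min == pytest.approx(32.694)

    def test_realistic_filtered_population(self):
        # N = 235 with ~3% missing scores: the published working thresholds
        thr = binning_thresholds(235, 0.03)
        assert thr.r_min == pytest.approx(0.0022, abs=1e-4)
        assert thr.lod_min == pytest.approx(50.4, abs=1.0)

    def test_degenerate_missing_rate_rejected(self):
        with pytest.raises(ValueError):
            binning_thresholds(100, 1.0)


class TestBinning:
    def _matrices(self, offspring, types):
        res = pairwise_matrix(offspring, types)
        rdf, ldf, _ = res.to_frames()
        return rdf, ldf

    def test_duplicated_markers_one_bin(self):
        off = np.array([0, 1] * 120)
        offspring = {"a": off, "b": off.copy(), "c": off.copy()}
        types = {m: FundamentalType.SxN for m in offspring}
        rdf, ldf = self._matrices(offspring, types)
        thr = binning_thresholds(240, 0.0)
        bins, reduced = bin_markers(rdf, ldf, thr, types)
        assert len(bins) == 1
        assert bins[0].max_internal_r == 0.0
        assert reduced == [bins[0].representative]

    def test_representative_prefers_sxn_fewest_missing(self):
        off = np.array([0, 1] * 120)
        off_miss = off.copy()
        off_miss[:4] = MISSING
        offspring = {"dup": off.copy(), "clean_sxn": off, "missing_sxn": off_miss}
        types = {"dup": FundamentalType.DxN, "clean_sxn": FundamentalType.SxN,
                 "missing_sxn": FundamentalType.SxN}
        # force cosegregation of the duplex with the simplex scores
        offspring["dup"] = off + off  # duplex doubled dosage, r = 0 to both? keep simple
        offspring["dup"] = np.where(off == 1, 1, 0) + np.where(off == 1, 1, 0)
        rdf, ldf = self._matrices(offspring, types)
        thr = binning_thresholds(240, 0.0)
        bins, _ = bin_markers(rdf, ldf, thr, types,
                              n_missing={"dup": 0, "clean_sxn": 0, "missing_sxn": 4})
        big = max(bins, key=lambda b: len(b.members))
        assert big.representative == "clean_sxn"

    def test_no_qualifying_pairs_all_singletons(self):
        g1, g2 = random_marker_layout(6, 10.0, (FundamentalType.SxN,), seed=51)
        pop = simulate_cross(g1, g2, MeiosisModel(), 150, seed=52)
        rdf, ldf = self._matrices(pop.offspring_dict(), pop.types_dict())
        thr = binning_thresholds(150, 0.0)
        bins, reduced = bin_markers(rdf, ldf, thr, pop.types_dict())
        assert all(len(b.members) == 1 for b in bins)
        assert len(reduced) == 6


def _chain_matrices(n, r_adj):
    """Analytic pairwise matrices for a marker chain with adjacent r = r_adj."""
    ids = [f"m{i}" for i in range(n)]
    d_adj = haldane_cM(r_adj)
    r = np.zeros((n, n))
    lod = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = d_adj * (j - i)
        r[i, j] = r[j, i] = haldane_inverse(d)
        lod[i, j] = lod[j, i] = 10.0 / (j - i)
    rdf = pd.DataFrame(r, index=ids, columns=ids)
    ldf = pd.DataFrame(lod, index=ids, columns=ids)
    return rdf, ldf


class TestOrdering:
    def test_exact_chain_recovered(self):
        """5-marker chain with exact r: true order and Haldane spacing."""
        rdf, ldf = _chain_matrices(5, 0.01)
        hmap = order_homologue(rdf, ldf)
        names = hmap.marker_ids
        assert names in (["m0", "m1", "m2", "m3", "m4"],
                         ["m4", "m3", "m2", "m1", "m0"])
        steps = np.diff(hmap.positions)
        np.testing.assert_allclose(steps, haldane_cM(0.01), atol=1e-6)

    def test_two_markers_trivial(self):
        rdf, ldf = _chain_matrices(2, 0.1)
        hmap = order_homologue(rdf, ldf)
        assert hmap.length == pytest.approx(float(haldane_cM(0.1)), abs=1e-9)

    def test_permuted_input_same_map_up_to_reversal(self):
        rdf, ldf = _chain_matrices(6, 0.05)
        perm = ["m3", "m0", "m5", "m1", "m4", "m2"]
        hmap = order_homologue(rdf.loc[perm, perm], ldf.loc[perm, perm])
        assert hmap.marker_ids in ([f"m{i}" for i in range(6)],
                                   [f"m{i}" for i in range(5, -1, -1)])

    def test_heuristic_matches_exhaustive_oracle_on_simulation(self):
        """Greedy+ripple order equals the exhaustive WLS optimum (<= 8 markers)."""
        g1, g2 = random_marker_layout(6, 5.0, (FundamentalType.SxN,), seed=61)
        g1.homologues[:, :] = 0
        g1.homologues[0, :] = 1  # one homologue: coupling chain
        pop = simulate_cross(g1, g2, MeiosisModel(), 300, seed=62)
        res = pairwise_matrix(pop.offspring_dict(), pop.types_dict())
        rdf, ldf, _ = res.to_frames()
        hmap = order_homologue(rdf, ldf)
        oracle, _ = order_exhaustive(rdf, ldf)
        assert hmap.marker_ids in (oracle, oracle[::-1])

    def test_disconnected_components_reported(self):
        rdf1, ldf1 = _chain_matrices(3, 0.05)
        n = 6
        ids = [f"m{i}" for i in range(n)]
        r = np.full((n, n), np.nan)
        lod = np.zeros((n, n))
        r[:3, :3] = rdf1.to_numpy()
        lod[:3, :3] = ldf1.to_numpy()
        r[3:, 3:] = rdf1.to_numpy()
        lod[3:, 3:] = ldf1.to_numpy()
        hmap = order_homologue(pd.DataFrame(r, index=ids, columns=ids),
                               pd.DataFrame(lod, index=ids, columns=ids))
        assert len(hmap.marker_ids) == 3
        assert len(hmap.fragments) == 1
        assert len(hmap.fragments[0].marker_ids) == 3

    def test_simulated_homologue_length_within_15_percent(self):
        """A 100 cM homologue at n = 235 maps to within 15% of its true length."""
        g1, g2 = random_marker_layout(21, 5.0, (FundamentalType.SxN,), seed=63)
        g1.homologues[:, :] = 0
        g1.homologues[0, :] = 1
        pop = simulate_cross(g1, g2, MeiosisModel(), 235, seed=64)
        res = pairwise_matrix(pop.offspring_dict(), pop.types_dict())
        rdf, ldf, _ = res.to_frames()
        hmap = order_homologue(rdf, ldf)
        assert not hmap.fragments
        assert abs(hmap.length - 100.0) / 100.0 < 0.15


class TestReinsertBinned:
    def test_members_at_representative_position(self):
        from tetramap.mapbuild import MarkerBin
        hmap = HomologueMap(["a", "b"], np.array([0.0, 10.0]))
        bins = [MarkerBin("a", ["a", "a2", "a3"], 0.001)]
        out = reinsert_binned(hmap, bins)
        assert out.marker_ids == ["a", "a2", "a3", "b"]
        np.testing.assert_allclose(out.positions, [0.0, 0.0, 0.0, 10.0])

    def test_no_bins_identity(self):
        hmap = HomologueMap(["a", "b"], np.array([0.0, 5.0]))
        out = reinsert_binned(hmap, [])
        assert out.marker_ids == ["a", "b"]

    def test_missing_representative_errors(self):
        from tetramap.mapbuild import MarkerBin
        hmap = HomologueMap(["a"], np.array([0.0]))
        with pytest.raises(KeyError):
            reinsert_binned(hmap, [MarkerBin("zz", ["zz", "a"], 0.0)])
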