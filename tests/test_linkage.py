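"""Two-point estimation against exhaustive-grid oracles, clustering
behaviour, ordering optimality on small instances, map functions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salmap.genotypes import GenotypeMatrix, make_individual_table
from salmap.linkage import (
    _family_pairs,
    _loglik,
    build_genetic_map,
    cluster_groups,
    haldane_cM,
    inverse_haldane,
    join_singles,
    kosambi_cM,
    order_markers,
    pairwise_lod,
    plateau_threshold,
    sweep_thresholds,
    two_point_estimate,
    PairwiseLOD,
)

LN10 = np.log(10.0)


def _two_marker_gm(sire, dam, offspring):
    rows = [("S1", "0", "0", "M"), ("D1", "0", "0", "F")] + [
        (f"O{k}", "S1", "D1", "M") for k in range(len(offspring))
    ]
    ind = make_individual_table(rows)
    mk = pd.DataFrame(
        {"chrom": ["c", "c"], "pos": [0, 1], "ref": ["A", "A"], "alt": ["C", "C"]},
        index=pd.Index(["m1", "m2"], name="marker_id"),
    )
    calls = np.array([sire, dam] + list(offspring), dtype=np.int8)
    return GenotypeMatrix(mk, ind, calls)


class TestMapFunctions:
    def test_haldane_values(self):
        assert haldane_cM(0.0) == pytest.approx(0.0)
        assert float(haldane_cM(0.2)) == pytest.approx(25.541281, abs=1e-4)
        assert np.isinf(haldane_cM(0.5))

    @given(st.floats(0.0, 0.49))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_haldane_inverse_roundtrip(self, theta):
        assert float(inverse_haldane(haldane_cM(theta))) == pytest.approx(theta, abs=1e-9)

    def test_kosambi_below_haldane(self):
        t = np.array([0.05, 0.1, 0.2, 0.3])
        assert (kosambi_cM(t) < haldane_cM(t)).all()


class TestTwoPoint:
    def test_duplicated_marker_gives_theta_zero(self):
        off = [[0, 0]] * 4 + [[1, 1]] * 4 + [[2, 2]] * 2
        gm = _two_marker_gm([1, 1], [1, 1], off)
        est = two_point_estimate(gm, "m1", "m2")
        assert est.theta_pooled == pytest.approx(0.0, abs=1e-6)
        assert est.lod > 1.0

    def test_two_recombinants_in_ten(self):
        # sire doubly het, dam hom-ref: paternal transmission fully observed
        off = [[0, 0]] * 4 + [[1, 1]] * 4 + [[0, 1], [1, 0]]
        gm = _two_marker_gm([1, 1], [0, 0], off)
        est = two_point_estimate(gm, "m1", "m2")
        assert est.theta_male == pytest.approx(0.2, abs=1e-3)
        assert est.n_informative_male == 10
        assert np.isnan(est.theta_female)  # dam not doubly het

    def test_lod_matches_exhaustive_grid(self):
        off = [[0, 0]] * 4 + [[1, 1]] * 4 + [[0, 1], [1, 0]]
        gm = _two_marker_gm([1, 1], [0, 0], off)
        est = two_point_estimate(gm, "m1", "m2")
        fams = _family_pairs(gm, 0, 1)
        grid = np.linspace(0.0, 0.5, 51)
        ll = _loglik(fams, grid, grid, 0.0)
        lod_grid = (ll.max() - ll[-1]) / LN10
        assert est.lod == pytest.approx(lod_grid, abs=1e-4)
        assert grid[ll.argmax()] == pytest.approx(est.theta_pooled, abs=0.01)

    def test_half_theta_means_zero_lod(self):
        off = [[0, 0], [0, 2], [2, 0], [2, 2]] * 3
        gm = _two_marker_gm([1, 1], [1, 1], off)
        est = two_point_estimate(gm, "m1", "m2")
        # perfectly balanced transmissions: theta-hat near 0.5, LOD ~ 0
        assert est.lod < 0.5

    def test_no_informative_family_flagged(self):
        gm = _two_marker_gm([0, 0], [2, 2], [[1, 1]] * 6)
        est = two_point_estimate(gm, "m1", "m2")
        assert np.isnan(est.theta_pooled)
        assert est.lod == 0.0
        assert "no_informative_meioses" in est.flags

    def test_cross_chromosome_markers_unlinked(self, clean_fixture):
        truth = clean_fixture.truth.markers
        a = truth[truth["chrom"] == "chr1"].index[0]
        b = truth[truth["chrom"] == "chr2"].index[0]
        est = two_point_estimate(clean_fixture.gm, a, b)
        if not np.isnan(est.theta_pooled):
            assert est.theta_pooled > 0.3
            assert est.lod < 3.0

    def test_batch_lod_agrees_with_scalar_at_grid_resolution(self, clean_fixture):
        gm = clean_fixture.gm
        pl = pairwise_lod(gm, error_rate=0.0)
        ids = list(gm.markers.index)
        rng = np.random.default_rng(5)
        for _ in range(5):
            i, j = sorted(rng.choice(len(ids), 2, replace=False))
            est = two_point_estimate(gm, ids[i], ids[j])
            if np.isnan(est.theta_pooled):
                continue
            assert pl.lod[i, j] <= est.lod + 1e-3  # grid max is a lower bound
            assert pl.lod[i, j] >= est.lod - max(0.05 * est.lod, 0.2)


class TestClustering:
    @pytest.fixture(scope="class")
    def pl(self, clean_fixture):
        return pairwise_lod(clean_fixture.gm, error_rate=0.0)

    def test_zero_threshold_merges_linked_universe(self, pl):
        groups = cluster_groups(pl, 0.0)
        assert len(groups[0]) > 0.9 * len(pl.marker_ids)

    def test_infinite_threshold_isolates_everything(self, pl):
        groups = cluster_groups(pl, np.inf)
        assert all(len(g) == 1 for g in groups)

    def test_group_count_monotone_in_threshold(self, pl):
        sw = sweep_thresholds(pl, np.arange(0.5, 20.5, 1.0), min_size=1)
        assert (np.diff(sw["n_groups"]) >= 0).all()

    def test_plateau_recovers_true_chromosome_partition(self, clean_fixture, pl):
        thr, n = plateau_threshold(pl)
        assert n == 3
        truth = clean_fixture.truth.markers["chrom"]
        for g in cluster_groups(pl, thr):
            if len(g) < 2:
                continue
            assert truth.loc[g].nunique() == 1

    def test_join_singles_rules(self):
        ids = ["a", "b", "c", "d", "x"]
        lod = np.zeros((5, 5), dtype=np.float32)
        lod[0, 1] = lod[1, 0] = 50.0
        lod[2, 3] = lod[3, 2] = 50.0
        lod[4, 0] = lod[0, 4] = 40.0
        lod[4, 2] = lod[2, 4] = 2.0
        pl = PairwiseLOD(ids, lod, np.full((5, 5), 0.5, dtype=np.float32))
        groups, left = join_singles(pl, [["a", "b"], ["c", "d"]], ["x"], lod_limit=20.0)
        assert "x" in groups[0] and left == []
        # below the limit: stays out
        lod[4, 0] = lod[0, 4] = 10.0
        groups, left = join_singles(pl, [["a", "b"], ["c", "d"]], ["x"], lod_limit=20.0)
        assert left == ["x"]
        # ambiguous margin: stays out
        lod[4, 0] = lod[0, 4] = 25.0
        lod[4, 2] = lod[2, 4] = 24.5
        groups, left = join_singles(pl, [["a", "b"], ["c", "d"]], ["x"], lod_limit=20.0)
        assert left == ["x"]


class TestOrdering:
    def _collinear_dist(self, pos):
        theta = inverse_haldane(np.abs(np.subtract.outer(pos, pos)))
        return np.asarray(haldane_cM(theta))

    def test_noise_free_order_recovered(self):
        pos = np.array([0, 3, 7, 11, 18, 26, 30, 41, 55, 60], dtype=float)
        ids = [f"m{k}" for k in range(10)]
        order, _ = order_markers(ids, self._collinear_dist(pos), seed=0)
        idx = [ids.index(m) for m in order]
        assert idx == sorted(idx) or idx == sorted(idx, reverse=True)

    def test_small_groups_match_exhaustive_minimum(self, rng):
        for n in (6, 7, 8):
            d = rng.uniform(1, 30, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            ids = [f"m{k}" for k in range(n)]
            order, lengths = order_markers(ids, d, n_restarts=10, seed=1)
            best = min(
                sum(d[p[k], p[k + 1]] for k in range(n - 1))
                for p in itertools.permutations(range(n))
            )
            got = min(lengths)
            assert got == pytest.approx(best, rel=1e-9)

    def test_returned_order_never_beats_identity(self, rng):
        n = 12
        d = rng.uniform(1, 30, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"m{k}" for k in range(n)]
        order, lengths = order_markers(ids, d, seed=3)
        identity = sum(d[k, k + 1] for k in range(n - 1))
        assert min(lengths) <= identity + 1e-9

    def test_length_invariant_under_reversal(self, rng):
        n = 9
        d = rng.uniform(1, 20, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        order = np.arange(n)
        fwd = d[order[:-1], order[1:]].sum()
        rev = d[order[::-1][:-1], order[::-1][1:]].sum()
        assert fwd == pytest.approx(rev)

    def test_single_marker_group(self):
        order, lengths = order_markers(["solo"], np.zeros((1, 1)), seed=0)
        assert order == ["solo"] and lengths == [0.0]


class TestFullMap:
    def test_map_recovers_structure_on_clean_fixture(self, clean_fixture):
        res = build_genetic_map(clean_fixture.gm, error_rate=0.0, seed=2)
        assert res.n_groups == 3
        gmap = res.genetic_map
        truth = clean_fixture.truth.markers
        # groups are chromosome-pure
        for lg, sub in gmap.groupby("linkage_group"):
            assert truth.loc[sub.index, "chrom"].nunique() == 1
        # positions start at 0 and are non-decreasing along the order
        for lg, sub in gmap.groupby("linkage_group"):
            sub = sub.sort_values("order_index")
            for col in ("male_cM", "female_cM"):
                assert sub[col].iloc[0] == 0.0
                assert (np.diff(sub[col]) >= 0).all()

    def test_error_free_female_total_near_truth(self):
        # one chromosome, wide marker spacing, many meioses: the adjacent
        # re-estimation on the fixed (true) order must recover the female
        # span between the terminal markers
        from salmap.linkage import sex_specific_distances
        from salmap.simulate import PedigreeSpec, StudyConfig, simulate_study

        cfg = StudyConfig(
            n_chrom=1, length_range=(4_000_000, 4_000_000), unplaced_fraction=0.0,
            n_markers=8, n_genes=0, maf_distribution=(0.3, 0.5),
            genotyping_error_rate=0.0, missing_rate=0.0,
            pedigree=PedigreeSpec(25, 50, 40),
        )
        fx = simulate_study(cfg, seed=17)
        truth = fx.truth.markers
        ids = list(truth.sort_values("chrom_pos").index)
        tr = sex_specific_distances(fx.gm, ids, error_rate=0.0)
        true_span = truth.loc[ids, "cM_female"].max() - truth.loc[ids, "cM_female"].min()
        assert tr["female_cM"].max() == pytest.approx(true_span, rel=0.2)
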