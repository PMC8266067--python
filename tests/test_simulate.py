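"""Structural and statistical properties of the synthetic-bundle generator."""

import json

import numpy as np
import pandas as pd
import pytest

from paleopcs.grid import CLIMATE_VARIABLES, grid_sites, occurrence_matrix
from paleopcs.pcs import ses_pcs
from paleopcs.simulate import (
    Scenario,
    assemble_communities,
    generate_fixture_bundle,
    simulate_climate_history,
    simulate_ice_retreat,
    simulate_trait_bm,
    simulate_tree,
    withhold_node_ages,
)
from paleopcs.spatial import DistanceBandWeights, morans_i
from paleopcs.tree import cophenetic_distances, read_tree


class TestTree:
    def test_tip_count_and_labels(self):
        tree = simulate_tree(15, seed=0)
        tips = [n.label for n in tree.leaves()]
        assert len(tips) == 15
        assert set(tips) == {f"t{i}" for i in range(1, 16)}

    def test_ultrametric(self):
        tree = simulate_tree(25, seed=1)
        ages = [n.age for n in tree.leaves()]
        np.testing.assert_allclose(ages, 0.0, atol=1e-9)
        for node in tree.preorder():
            if node.parent is not None:
                assert node.parent.age >= node.age - 1e-12

    def test_deterministic(self):
        a = simulate_tree(12, seed=7)
        b = simulate_tree(12, seed=7)
        Da = cophenetic_distances(a)
        Db = cophenetic_distances(b)
        pd.testing.assert_frame_equal(Da, Db)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            simulate_tree(5, birth=0.5, death=0.8)


class TestWithholdAges:
    def test_root_always_present(self):
        tree = simulate_tree(20, seed=3)
        ages = withhold_node_ages(tree, 0.0, seed=0)
        assert list(ages["clade_name"]) == [tree.root.label]

    def test_fraction_respected(self):
        tree = simulate_tree(30, seed=4)
        internals = sum(1 for n in tree.preorder()
                        if not n.is_leaf and n is not tree.root)
        ages = withhold_node_ages(tree, 0.5, seed=1)
        assert len(ages) == 1 + round(0.5 * internals)

    def test_listed_ages_are_true_ages(self):
        tree = simulate_tree(18, seed=5)
        by_label = {n.label: n.age for n in tree.preorder() if not n.is_leaf}
        ages = withhold_node_ages(tree, 0.6, seed=2)
        for _, row in ages.iterrows():
            assert row["age_ma"] == pytest.approx(by_label[row["clade_name"]])


class TestTraits:
    def test_sister_tips_more_similar(self):
        # BM variance of the tip difference is 2*sigma2*t_mrca: sisters on a
        # deep tree covary more than distant pairs, on average
        rng = np.random.default_rng(0)
        close, far = [], []
        tree = read_tree("(((A:0.1,B:0.1):9.9,C:10):10,D:20);")
        for rep in range(400):
            tr = simulate_trait_bm(tree, 1.0, seed=rep)
            close.append((tr["A"] - tr["B"]) ** 2)
            far.append((tr["A"] - tr["D"]) ** 2)
        assert np.mean(close) < np.mean(far) / 10

    def test_variance_scales_with_depth(self):
        tree = read_tree("(A:4,B:4);")
        vals = [simulate_trait_bm(tree, 2.0, seed=s)["A"] for s in range(800)]
        # Var = sigma2 * depth = 8
        assert np.var(vals, ddof=1) == pytest.approx(8.0, rel=0.2)

    def test_zero_sigma_constant(self):
        tree = simulate_tree(10, seed=6)
        tr = simulate_trait_bm(tree, 0.0, seed=0)
        np.testing.assert_allclose(tr.to_numpy(), tr.iloc[0])


class TestClimate:
    def test_columns_and_coverage(self):
        sc = Scenario(seed=2)
        clim = simulate_climate_history(sc, seed=0)
        assert set(CLIMATE_VARIABLES) <= set(clim.columns)
        assert len(clim) == sc.n_lon * sc.n_lat * sc.n_slices
        assert sorted(clim["time_ka"].unique()) == sorted(sc.slices())

    def test_latitudinal_gradient_recovered(self):
        sc = Scenario(seed=3, climate_noise_sd=0.05)
        clim = simulate_climate_history(sc, seed=1)
        one = clim.loc[clim["time_ka"] == 0]
        slope = np.polyfit(one["cell_lat"], one["tmin"], 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.3)

    def test_temporal_trend_recovered(self):
        sc = Scenario(seed=4, climate_noise_sd=0.05)
        clim = simulate_climate_history(sc, seed=2)
        cell = clim.loc[(clim["cell_lon"] == clim["cell_lon"].min())
                        & (clim["cell_lat"] == clim["cell_lat"].min())]
        slope = np.polyfit(cell["time_ka"], cell["tmin"], 1)[0]
        # tmin decreases with age (colder in the past): d tmin / d ka = -0.5
        assert slope == pytest.approx(-0.5, abs=0.15)

    def test_noise_spatially_autocorrelated(self):
        sc = Scenario(seed=5)
        clim = simulate_climate_history(sc, seed=3)
        one = clim.loc[clim["time_ka"] == 0].copy()
        # detrend latitude, then test the residual field with Moran's I
        resid = one["tmin"] - np.polyval(
            np.polyfit(one["cell_lat"], one["tmin"], 1), one["cell_lat"])
        pts = one[["cell_lon", "cell_lat"]].to_numpy()
        w = DistanceBandWeights(pts, 120.0)
        r = morans_i(resid.to_numpy(), w, n_perm=999, seed=0)
        assert r.I > r.expected_I
        assert r.p_perm < 0.05

    def test_etr_bounded(self):
        clim = simulate_climate_history(Scenario(seed=6), seed=4)
        assert clim["etr"].between(0.0, 1.0).all()


class TestIce:
    def test_monotone_poleward_retreat(self):
        sc = Scenario(seed=0)
        ice = simulate_ice_retreat(sc)
        frac = ice.groupby("time_ka")["glaciated"].mean().sort_index()
        # glaciated fraction never increases toward the present
        # (ascending time_ka = increasing age, so the fraction is
        # non-decreasing along the sorted index)
        assert (np.diff(frac.to_numpy()) >= -1e-12).all()
        assert frac.iloc[-1] > 0  # ice present at start of mask record
        assert frac.iloc[0] == 0.0  # ice-free present

    def test_premask_slices_present(self):
        sc = Scenario(seed=0)
        ice = simulate_ice_retreat(sc)
        assert ice["time_ka"].max() == sc.n_slices - 1 + sc.n_ice_preslices

    def test_margin_rule(self):
        sc = Scenario(seed=0)
        ice = simulate_ice_retreat(sc)
        for t in (sc.n_slices - 1, 0):
            m = sc.margin_lat(t)
            sub = ice.loc[ice["time_ka"] == t]
            assert ((sub["cell_lat"] >= m) == (sub["glaciated"] == 1)).all()


class TestCommunities:
    def test_schema_and_constraints(self, small_bundle):
        sites = small_bundle["sites"]
        assert list(sites.columns) == ["site_id", "lon", "lat", "time_ka",
                                       "quality", "taxon", "rel_abund"]
        assert (sites["quality"] == 1.0).all()
        sums = sites.groupby(["site_id", "time_ka"])["rel_abund"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_no_sites_on_ice(self, small_bundle):
        sites, ice = small_bundle["sites"], small_bundle["ice"]
        res = small_bundle["scenario"].resolution
        cells = sites.assign(
            cell_lon=(np.floor(sites["lon"] / res) * res),
            cell_lat=(np.floor(sites["lat"] / res) * res),
        )
        joined = cells.merge(ice, on=["cell_lon", "cell_lat", "time_ka"])
        assert (joined["glaciated"] == 0).all()

    def test_richness_equals_target(self, small_bundle):
        sc = small_bundle["scenario"]
        counts = small_bundle["sites"].groupby(["site_id", "time_ka"])[
            "taxon"].nunique()
        assert (counts == sc.richness_target).all()

    def _mean_nri(self, sc, seed_offset=0):
        bundle_rng = np.random.SeedSequence(sc.seed + seed_offset)
        s_tree, s_trait, s_clim, s_comm = bundle_rng.spawn(4)
        tree = simulate_tree(sc.n_taxa, seed=s_tree)
        traits = simulate_trait_bm(tree, sc.sigma2_bm, seed=s_trait)
        climate = simulate_climate_history(sc, seed=s_clim)
        ice = simulate_ice_retreat(sc)
        sites = assemble_communities(sc, tree, traits, climate, ice,
                                     seed=s_comm)
        D = cophenetic_distances(tree)
        g = grid_sites(sites, resolution=sc.resolution)
        vals = []
        for t in (0,):
            M = occurrence_matrix(g, t, taxa=list(D.index))
            res = ses_pcs(M, D, n_runs=199, seed=13)
            vals.append(res["nri"].dropna().mean())
        return float(np.mean(vals))

    def test_filtering_clusters_neutral_does_not(self):
        """Environmental filtering on a BM trait produces NRI above the
        neutral mechanism's, which itself sits near zero."""
        base = dict(n_taxa=24, n_lon=6, n_lat=6, n_slices=4, seed=42,
                    richness_target=6, tau=0.3)
        nri_f = self._mean_nri(Scenario(mechanism="filtering", **base))
        nri_n = self._mean_nri(Scenario(mechanism="neutral", **base))
        assert nri_f > nri_n + 0.2
        assert abs(nri_n) < 0.6

    def test_limiting_similarity_overdisperses_vs_neutral(self):
        base = dict(n_taxa=24, n_lon=6, n_lat=6, n_slices=4, seed=43,
                    richness_target=6, delta=0.8)
        nri_l = self._mean_nri(Scenario(mechanism="limiting_similarity",
                                        **base))
        nri_n = self._mean_nri(Scenario(mechanism="neutral", **base))
        assert nri_l < nri_n

    def test_unknown_mechanism_rejected(self):
        sc = Scenario(mechanism="magic", richness_target=2)
        tree = simulate_tree(5, seed=0)
        traits = simulate_trait_bm(tree, seed=0)
        with pytest.raises(ValueError, match="mechanism"):
            assemble_communities(sc, tree, traits,
                                 simulate_climate_history(sc, seed=0),
                                 simulate_ice_retreat(sc), seed=0)


class TestBundle:
    def test_files_written(self, small_bundle):
        d = small_bundle["dir"]
        for name in ("tree.nwk", "node_ages.csv", "sites.csv", "climate.csv",
                     "ice.csv", "truth.json"):
            assert (d / name).exists()

    def test_byte_deterministic(self, tmp_path):
        sc = Scenario(n_taxa=10, n_lon=4, n_lat=4, n_slices=3, seed=5,
                      richness_target=4)
        generate_fixture_bundle(sc, tmp_path / "a")
        generate_fixture_bundle(sc, tmp_path / "b")
        for name in ("tree.nwk", "node_ages.csv", "sites.csv", "climate.csv",
                     "ice.csv", "truth.json"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_truth_records_scenario(self, small_bundle):
        truth = json.loads((small_bundle["dir"] / "truth.json").read_text())
        sc = small_bundle["scenario"]
        assert truth["mechanism"] == sc.mechanism
        assert truth["b_schedule"] == sc.b_at(0)
        assert len(truth["traits"]) == sc.n_taxa

    def test_round_trip_through_readers(self, small_bundle):
        d = small_bundle["dir"]
        tree = read_tree(d / "tree.nwk")
        D = cophenetic_distances(tree)
        D0 = cophenetic_distances(small_bundle["tree"])
        np.testing.assert_allclose(D.loc[D0.index, D0.columns].values,
                                   D0.values, atol=1e-6)
        sites = pd.read_csv(d / "sites.csv")
        assert len(sites) == len(small_bundle["sites"])
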