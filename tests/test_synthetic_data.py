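"""Synthetic-world generator: trees, trait evolution, surfaces, filtering."""

import numpy as np
import pandas as pd
import pytest

from phyloflora.metrics import mpd
from phyloflora.phylo_core import Phylogeny
from phyloflora.spatial_stats import morans_i
from phyloflora.synthetic_data import (
    SyntheticConfig,
    assemble,
    early_burst_rescale,
    evolve_bm,
    generate_environment,
    generate_world,
    grid_rook_weights,
    make_grid_regions,
    sar_surface,
    simulate_tree,
    write_world,
)


class TestSimulateTree:
    def test_two_tips_form_a_cherry(self):
        t = simulate_tree(2, birth=0.5, death=0.0, seed=1)
        assert t.n_tips == 2
        D, labels = t.distance_matrix()
        # equal depths: patristic distance is twice the shared tip depth
        assert t.is_ultrametric(rel_tol=1e-9)

    def test_conditioned_tip_count_and_ultrametricity(self):
        t = simulate_tree(64, birth=0.4, death=0.0, seed=7)
        assert t.n_tips == 64
        assert t.is_ultrametric(rel_tol=1e-9)

    def test_seed_determinism(self):
        a = simulate_tree(32, birth=0.4, death=0.1, seed=9)
        b = simulate_tree(32, birth=0.4, death=0.1, seed=9)
        assert a.to_newick() == b.to_newick()

    def test_supercritical_death_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(10, birth=0.2, death=0.3, seed=1)


class TestEvolveBM:
    def test_zero_rate_fixes_root_state(self):
        tree = simulate_tree(16, 0.5, 0.0, seed=3)
        states = evolve_bm(tree, sigma2=0.0, root_state=12.5, seed=4)
        assert set(states) == set(tree.tip_labels)
        assert all(v == 12.5 for v in states.values())

    def test_tip_covariance_tracks_shared_path_lengths(self):
        """Across 500 replicates the empirical tip-state covariance matches
        sigma2 times the shared root-path length matrix."""
        tree = Phylogeny.from_newick(
            "(((a:1,b:1):2,(c:2,d:2):1):2,((e:1,f:1):3,(g:3,h:3):1):1);")
        sigma2 = 2.0
        draws = np.array([
            [evolve_bm(tree, sigma2, 0.0, seed=s)[lab] for lab in tree.tip_labels]
            for s in range(500)
        ])
        emp = np.cov(draws.T)
        D, _ = tree.distance_matrix()
        idx = tree._index()
        depths = idx.tip_depths
        shared = (depths[:, None] + depths[None, :] - D) / 2.0
        expected = sigma2 * shared
        # entrywise sampling error of a covariance over n replicates
        n = len(draws)
        var = np.diag(expected)
        se = np.sqrt((np.outer(var, var) + expected**2) / n)
        assert np.all(np.abs(emp - expected) <=
                      np.maximum(0.15 * np.abs(expected), 4.0 * se))
        # variances (diagonal) are the tightest check: sigma2 x tip depth
        assert np.allclose(np.diag(emp), sigma2 * depths, rtol=0.15)

    def test_close_relatives_stay_more_similar(self):
        tree = Phylogeny.from_newick(
            "(((a:1,b:1):2,(c:2,d:2):1):2,((e:1,f:1):3,(g:3,h:3):1):1);")
        cherry_gap, distant_gap = [], []
        for s in range(300):
            st = evolve_bm(tree, 1.0, 0.0, seed=1000 + s)
            cherry_gap.append(abs(st["a"] - st["b"]))
            distant_gap.append(abs(st["a"] - st["g"]))
        assert np.mean(cherry_gap) < np.mean(distant_gap)


class TestEarlyBurst:
    def test_zero_rate_is_identity(self):
        tree = simulate_tree(10, 0.5, 0.0, seed=5)
        assert early_burst_rescale(tree, 0.0) is tree

    def test_branch_rescaling_formula(self):
        tree = Phylogeny.from_newick("((a:1,b:1):1,c:2);")
        r = 0.5
        scaled = early_burst_rescale(tree, r)
        # pendant branch of c spans ages 0..2 from the root
        expected_c = (1 - np.exp(-r * 2.0)) / r
        assert scaled.patristic_distance("a", "c") == pytest.approx(
            (1 - np.exp(-r * 1.0)) / r                     # internal 0..1
            + (np.exp(-r * 1.0) - np.exp(-r * 2.0)) / r    # pendant a 1..2
            + expected_c)

    def test_rescaling_concentrates_divergence_deep(self):
        tree = simulate_tree(40, 0.5, 0.0, seed=6)
        scaled = early_burst_rescale(tree, 0.4)
        # deep structure dominates: total length shrinks toward the
        # integral of the decaying rate
        assert scaled.total_length < tree.total_length
        assert scaled.n_tips == tree.n_tips


class TestEnvironment:
    def _setup(self, shape=(7, 7), seed=0):
        regions = make_grid_regions(shape, seed=seed)
        return regions, grid_rook_weights(regions)

    def test_latent_surface_white_when_rho_zero(self):
        regions, W = self._setup()
        n = len(regions)
        rng = np.random.default_rng(1)
        vals = [morans_i(sar_surface(W, 0.0, rng), W) for _ in range(200)]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - (-1 / (n - 1))) <= 3 * se

    def test_autocorrelation_increases_with_rho(self):
        regions, W = self._setup()
        mean_i = {}
        for rho in (0.0, 0.8):
            rng = np.random.default_rng(2)
            mean_i[rho] = np.mean([morans_i(sar_surface(W, rho, rng), W)
                                   for _ in range(200)])
        assert mean_i[0.8] > mean_i[0.0]

    def test_environment_table_schema_and_invariants(self):
        regions, W = self._setup()
        env, subcells = generate_environment(
            regions, W, rho=0.7,
            epoch_shift={"temperature": 5.0, "precipitation": 250.0},
            n_subcells=20, seed=3)
        expected = ["T_mean", "T_min", "T_seas", "P_mean", "P_min", "P_seas",
                    "T_anom", "T_vel", "P_anom", "P_vel", "E_sd", "T_sd", "P_sd"]
        assert list(env.columns) == ["region_id"] + expected
        assert np.isfinite(env[expected].to_numpy()).all()
        assert (env["P_mean"] >= env["P_min"]).all()
        assert (env["P_min"] >= 0).all()
        for col in ("T_seas", "P_seas", "E_sd", "T_sd", "P_sd",
                    "T_vel", "P_vel"):
            assert (env[col] >= 0).all()
        assert (env["T_min"] <= env["T_mean"]).all()

    def test_heterogeneity_columns_are_subcell_sds(self):
        regions, W = self._setup()
        env, subcells = generate_environment(
            regions, W, rho=0.5,
            epoch_shift={"temperature": 5.0, "precipitation": 250.0},
            n_subcells=15, seed=4)
        np.testing.assert_allclose(
            env["E_sd"], subcells["elevation"].std(axis=1, ddof=1))
        np.testing.assert_allclose(
            env["T_sd"], subcells["temperature"].std(axis=1, ddof=1))

    def test_singular_system_rejected(self):
        regions, W = self._setup()
        with pytest.raises(ValueError, match="singular"):
            sar_surface(W, 1.0, np.random.default_rng(0))


class TestAssemble:
    def _world_pieces(self, seed=0):
        regions = make_grid_regions((5, 5), seed=seed)
        W = grid_rook_weights(regions)
        env, _ = generate_environment(
            regions, W, 0.6, {"temperature": 5.0, "precipitation": 250.0},
            10, seed)
        rng = np.random.default_rng(seed)
        niches = {
            "temperature": {f"s{i}": rng.uniform(-5, 30) for i in range(40)},
            "precipitation": {f"s{i}": rng.uniform(100, 4000) for i in range(40)},
        }
        return env, niches

    def test_infinite_tolerance_admits_everything(self):
        env, niches = self._world_pieces()
        asm = assemble(niches, env, {"temperature": np.inf, "precipitation": np.inf})
        assert len(asm) == len(env) * 40

    def test_zero_tolerance_excludes_everything(self):
        env, niches = self._world_pieces()
        asm = assemble(niches, env, {"temperature": 1e-12, "precipitation": 1e-12})
        assert len(asm) == 0

    def test_matches_brute_force_double_loop(self):
        env, niches = self._world_pieces(seed=2)
        tol = {"temperature": 6.0, "precipitation": 700.0}
        asm = assemble(niches, env, tol)
        got = set(map(tuple, asm.to_numpy()))
        expected = set()
        for _, row in env.iterrows():
            for sp in niches["temperature"]:
                if (abs(niches["temperature"][sp] - row["T_mean"]) <= tol["temperature"]
                        and abs(niches["precipitation"][sp] - row["P_mean"])
                        <= tol["precipitation"]):
                    expected.add((row["region_id"], sp))
        assert got == expected


class TestWorld:
    SMALL = dict(n_tips=40, grid_shape=(6, 6), n_subcells=8)

    def test_bit_reproducible_given_master_seed(self, tmp_path):
        a = generate_world(SyntheticConfig(seed=42, **self.SMALL))
        b = generate_world(SyntheticConfig(seed=42, **self.SMALL))
        assert a.tree.to_newick() == b.tree.to_newick()
        pd.testing.assert_frame_equal(a.env, b.env)
        pd.testing.assert_frame_equal(a.assemblages, b.assemblages)
        pd.testing.assert_frame_equal(a.regions, b.regions)
        pa = write_world(a, tmp_path / "a")
        pb = write_world(b, tmp_path / "b")
        for key in pa:
            assert open(pa[key], "rb").read() == open(pb[key], "rb").read()

    def test_different_seeds_differ(self):
        a = generate_world(SyntheticConfig(seed=1, **self.SMALL))
        b = generate_world(SyntheticConfig(seed=2, **self.SMALL))
        assert a.tree.to_newick() != b.to_newick() if hasattr(b, "to_newick") \
            else a.tree.to_newick() != b.tree.to_newick()

    def test_richness_increases_with_temperature(self):
        """The conserved warm ancestral niche makes warm regions richer."""
        from scipy.stats import spearmanr

        hits = 0
        for seed in range(5):
            w = generate_world(SyntheticConfig(seed=seed))
            rich = w.assemblages.groupby("region_id").size()
            tmean = w.env.set_index("region_id").loc[rich.index, "T_mean"]
            hits += spearmanr(rich, tmean).statistic > 0
        assert hits == 5

    def test_cold_floras_are_clade_concentrated(self):
        """Cold-adapted species are closer relatives than a same-sized
        random pool sample, reflecting niche conservatism."""
        w = generate_world(SyntheticConfig(seed=3))
        opt = w.niches["temperature"]
        tips = sorted(opt, key=opt.get)
        cold = tips[:30]
        assert mpd(w.tree, cold) < mpd(w.tree, tips)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, rho=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, birth=0.1, death=0.2)
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, tolerance={"temperature": -1.0,
                                               "precipitation": 100.0})
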