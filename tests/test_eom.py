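"""Ensemble selection: refinement, GA, fraction extraction."""

import numpy as np
import pytest

import oligosas as og
from oligosas.eom import _merged, _state_chi2


@pytest.fixture(scope="module")
def mini_data(mini_pool):
    truth = og.MixtureTruth(fractions=(0.6, 0.4, 0, 0, 0), seed=42)
    profile, _ = og.make_mixture_profile(mini_pool, truth)
    return profile


class TestRefine:
    def test_keep_larger_than_state_is_noop(self, mini_pool, mini_data):
        refined = og.refine_pool(mini_pool, mini_data, keep=10_000)
        assert refined.n_per_state() == mini_pool.n_per_state()

    def test_keep_one_retains_global_state_minimum(self, mini_pool, mini_data):
        refined = og.refine_pool(mini_pool, mini_data, keep=1)
        for o in mini_pool.orders:
            # brute-force oracle over the whole state
            all_chi2 = [og.chi2_fit(mini_data, mini_pool.curves[o][i]).chi2
                        for i in range(mini_pool.curves[o].shape[0])]
            kept = og.chi2_fit(mini_data, refined.curves[o][0]).chi2
            assert kept == pytest.approx(min(all_chi2))

    def test_bad_keep(self, mini_pool, mini_data):
        with pytest.raises(ValueError):
            og.refine_pool(mini_pool, mini_data, keep=0)


class TestBestSingle:
    def test_returned_chi2_is_state_minimum(self, mini_pool, mini_data):
        singles = og.best_single(mini_pool, mini_data)
        for o in mini_pool.orders:
            chi2s = _state_chi2(mini_pool, mini_data, o)
            assert singles[o][1].chi2 == pytest.approx(chi2s.min())
            assert singles[o][0] == int(np.argmin(chi2s))

    def test_monomer_data_prefers_monomer_state(self, mini_pool):
        truth = og.MixtureTruth(fractions=(1.0, 0, 0, 0, 0), seed=9)
        profile, _ = og.make_mixture_profile(mini_pool, truth)
        singles = og.best_single(mini_pool, profile)
        assert singles[1][1].chi2 < singles[2][1].chi2


class TestGASelect:
    def test_determinism(self, mini_pool, mini_data):
        cfg = og.GAConfig(ensemble_size=20, seed=5, generations=40)
        a = og.eom_select(mini_pool, mini_data, cfg)
        b = og.eom_select(mini_pool, mini_data, cfg)
        np.testing.assert_array_equal(a.selected, b.selected)
        assert a.fit.chi2 == b.fit.chi2

    def test_degenerate_pool_of_identical_curves(self, mini_data, mini_pool):
        base = mini_pool.curves[1][0]
        pool = og.ConformerPool(
            q_grid=mini_pool.q_grid,
            curves={1: np.tile(base, (8, 1))},
            rg={1: np.full(8, 30.0)}, seed=0)
        cfg = og.GAConfig(ensemble_size=10, seed=1, generations=10)
        sol = og.eom_select(pool, mini_data, cfg)
        assert sol.fit.chi2 == pytest.approx(
            og.chi2_fit(mini_data, base).chi2, rel=1e-9)

    def test_never_worse_than_best_single(self, mini_pool, mini_data):
        cfg = og.GAConfig(ensemble_size=20, seed=3, generations=30)
        sol = og.eom_select(mini_pool, mini_data, cfg)
        singles = og.best_single(mini_pool, mini_data)
        best = min(s.chi2 for _, s in singles.values())
        assert sol.fit.chi2 <= best + 1e-9

    def test_solution_invariants(self, mini_pool, mini_data):
        cfg = og.GAConfig(ensemble_size=20, seed=3, generations=30)
        sol = og.eom_select(mini_pool, mini_data, cfg)
        assert sol.ensemble_size == 20
        assert sum(sol.state_counts.values()) == 20
        assert sum(sol.intensity_share.values()) == pytest.approx(1.0)


class TestFractions:
    def test_single_all_monomer_run(self):
        sol = og.EnsembleSolution(
            selected=np.zeros(10, dtype=int), curve=np.ones(5),
            fit=og.FitStat(chi2=1.0, scale=1.0, n_points=5),
            state_counts={1: 10, 2: 0}, run_seed=0)
        dist = og.extract_fractions([sol])
        assert dist.fraction[1] == 1.0 and dist.fraction[2] == 0.0
        assert all(v == 0.0 for v in dist.sd.values())

    def test_identical_runs_zero_sd(self):
        sol = og.EnsembleSolution(
            selected=np.zeros(10, dtype=int), curve=np.ones(5),
            fit=og.FitStat(chi2=2.0, scale=1.0, n_points=5),
            state_counts={1: 6, 2: 4}, run_seed=0)
        dist = og.extract_fractions([sol, sol, sol])
        assert dist.sd[1] == 0.0 and dist.sd[2] == 0.0
        assert dist.n_runs == 3

    def test_hand_arithmetic(self):
        counts = [(30, 20), (26, 24), (28, 22)]
        sols = []
        for c1, c2 in counts:
            sols.append(og.EnsembleSolution(
                selected=np.zeros(50, dtype=int), curve=np.ones(5),
                fit=og.FitStat(chi2=1.0, scale=1.0, n_points=5),
                state_counts={1: c1, 2: c2}, run_seed=0))
        dist = og.extract_fractions(sols)
        assert dist.fraction[1] == pytest.approx(0.56)
        assert dist.fraction[2] == pytest.approx(0.44)
        expected_sd = np.std([0.60, 0.52, 0.56])
        assert dist.sd[1] == pytest.approx(expected_sd)

    def test_inconsistent_sizes_rejected(self):
        a = og.EnsembleSolution(selected=np.zeros(10, dtype=int),
                                curve=np.ones(5),
                                fit=og.FitStat(chi2=1, scale=1, n_points=5),
                                state_counts={1: 10}, run_seed=0)
        b = og.EnsembleSolution(selected=np.zeros(20, dtype=int),
                                curve=np.ones(5),
                                fit=og.FitStat(chi2=1, scale=1, n_points=5),
                                state_counts={1: 20}, run_seed=0)
        with pytest.raises(ValueError, match="inconsistent"):
            og.extract_fractions([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            og.extract_fractions([])


class TestRgHistogram:
    def test_single_model_single_bin(self):
        table = og.rg_histogram({1: np.array([30.0])}, bin_width=2.0)
        row = table[(table.state == "1") & (table["count"] > 0)]
        assert len(row) == 1
        assert row.iloc[0].bin_left == 30.0 and row.iloc[0].bin_right == 32.0

    def test_counts_conserved(self, mini_pool):
        table = og.rg_histogram(mini_pool.rg, bin_width=2.0)
        for o in mini_pool.orders:
            total = table[table.state == str(o)]["count"].sum()
            assert total == mini_pool.rg[o].size

    def test_state_means_ordered(self, mini_pool):
        table = og.rg_histogram(mini_pool.rg, bin_width=2.0)

        def mean_rg(state):
            t = table[table.state == str(state)]
            mid = (t.bin_left + t.bin_right) / 2
            return np.average(mid, weights=t["count"])

        assert mean_rg(1) < mean_rg(2)

    def test_empty(self):
        assert og.rg_histogram({}).empty


class TestFitReport:
    @pytest.fixture(scope="class")
    def report(self, mini_pool, mini_data):
        cfg = og.GAConfig(ensemble_size=20, n_runs=2, seed=8, generations=60)
        return og.fit_report(mini_data, mini_pool, cfg, keep=10)

    def test_schema(self, report):
        for key in ("best_single_chi2", "ensemble_chi2_per_run", "distribution",
                    "intensity_share", "rg_histogram", "chi2_vs_rg", "config"):
            assert key in report
        frac = report["distribution"]["fraction"]
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_ensemble_not_worse_than_best_single(self, report):
        best = min(float(v) for v in report["best_single_chi2"].values())
        assert max(report["ensemble_chi2_per_run"]) <= best + 1e-9

    def test_determinism(self, mini_pool, mini_data, report):
        cfg = og.GAConfig(ensemble_size=20, n_runs=2, seed=8, generations=60)
        again = og.fit_report(mini_data, mini_pool, cfg, keep=10)
        assert again == report
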