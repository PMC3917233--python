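"""Morphodynamics: dip test (with LP oracle), lowess, profiles, densities."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog
from scipy.stats import kstest

from quanthisto.morphodynamics import (count_within_radius, dip_statistic,
                                       dip_test, incline_density,
                                       lowess_trend, radial_class_profile)


def dip_by_linear_program(values):
    """Independent oracle: dip as the smallest sup-norm distance from the
    empirical CDF to a piecewise-linear unimodal CDF, minimized over every
    candidate modal knot by linear programming."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    dx = np.diff(x)
    best = np.inf
    for m in range(1, n + 1):
        c = np.zeros(n + 1)
        c[-1] = 1.0
        A, b = [], []
        for i in range(n):
            row = np.zeros(n + 1); row[i] = 1; row[-1] = -1
            A.append(row); b.append(i / n)
            row = np.zeros(n + 1); row[i] = -1; row[-1] = -1
            A.append(row); b.append(-(i + 1) / n)
        for i in range(n - 1):
            row = np.zeros(n + 1); row[i] = 1; row[i + 1] = -1
            A.append(row); b.append(0.0)
        for i in range(0, m - 2):       # convex left of the modal knot
            row = np.zeros(n + 1)
            row[i] += -1 / dx[i]; row[i + 1] += 1 / dx[i]
            row[i + 1] += 1 / dx[i + 1]; row[i + 2] += -1 / dx[i + 1]
            A.append(row); b.append(0.0)
        for i in range(m - 1, n - 2):   # concave right of it
            row = np.zeros(n + 1)
            row[i] += 1 / dx[i]; row[i + 1] += -1 / dx[i]
            row[i + 1] += -1 / dx[i + 1]; row[i + 2] += 1 / dx[i + 1]
            A.append(row); b.append(0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * n + [(0, 1)], method="highs")
        if res.success:
            best = min(best, res.fun)
    return best


class TestDipStatistic:
    def test_six_point_sample_matches_brute_force(self):
        x = np.array([0.1, 0.2, 0.25, 0.7, 0.75, 0.9])
        assert dip_statistic(x) == pytest.approx(dip_by_linear_program(x),
                                                 abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_samples_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        x = rng.normal(0, 1, n) if seed % 2 else np.concatenate(
            [rng.normal(0, 0.2, n // 2), rng.normal(4, 0.2, n - n // 2)])
        assert dip_statistic(x) == pytest.approx(dip_by_linear_program(x),
                                                 abs=1e-9)

    def test_known_values(self):
        assert dip_statistic([0.0, 1.0]) == 0.25
        assert dip_statistic(np.arange(10)) == pytest.approx(0.05)

    def test_far_separated_modes_approach_quarter(self):
        x = np.concatenate([np.linspace(0, 0.01, 500), np.linspace(6, 6.01, 500)])
        assert dip_statistic(x) == pytest.approx(0.25, abs=1e-3)


class TestDipTest:
    def test_uniform_sample_not_rejected(self):
        rng = np.random.default_rng(0)
        _, p = dip_test(rng.random(1000), n_boot=500, seed=1)
        assert p > 0.001

    def test_bimodal_mixture_rejected(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(6, 1, 500)])
        _, p = dip_test(x, n_boot=2000, seed=1)
        assert p < 0.001

    def test_constant_sample(self):
        d, p = dip_test(np.ones(50), n_boot=100, seed=0)
        assert d == 0.0 and p == 1.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            dip_test([1, 2, 3])

    def test_null_pvalues_approximately_uniform(self):
        """Desk-scale calibration: 200 uniform-null replicates give
        near-uniform bootstrap p-values (KS test not rejecting)."""
        rng = np.random.default_rng(7)
        ps = []
        for i in range(200):
            x = rng.random(60)
            _, p = dip_test(x, n_boot=200, seed=1000 + i)
            ps.append(p)
        stat, p_ks = kstest(ps, "uniform")
        assert p_ks > 0.01

    def test_synthetic_bimodality_recovery(self, small_table):
        """Pooled inclines of a structured section (radial xylem +
        orthoradial phloem) are bimodal; a single-orientation section is
        not."""
        inc = small_table["incline"].dropna().to_numpy()
        _, p_structured = dip_test(inc, n_boot=1000, seed=2)
        assert p_structured < 0.01
        rng = np.random.default_rng(3)
        single = np.clip(np.abs(rng.normal(0.3, 0.25, len(inc))), 0, np.pi / 2)
        _, p_single = dip_test(single, n_boot=1000, seed=2)
        assert p_single > 0.05


class TestLowess:
    def test_constant_signal_flat(self):
        r = np.linspace(0, 1, 50)
        out = lowess_trend(r, np.full(50, 0.7), frac=0.4)
        assert np.allclose(out["incline"], 0.7, atol=1e-9)

    def test_linear_relation_recovered(self):
        r = np.linspace(0, 1, 80)
        y = 1.2 - 0.9 * r
        out = lowess_trend(r, y, frac=0.3)
        interior = out[(out["radius_norm"] > 0.05) & (out["radius_norm"] < 0.95)]
        assert np.allclose(interior["incline"],
                           1.2 - 0.9 * interior["radius_norm"], atol=1e-6)

    def test_plateau_then_drop_monotone(self):
        """Constructed profile: radial plateau near pi/2 in the xylem,
        dropping at the cambium — fitted curve decreases across it."""
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 1, 400)
        y = np.where(r < 0.4, 1.5, 0.15) + rng.normal(0, 0.05, 400)
        out = lowess_trend(r, y, frac=0.25)
        mid = out[(out["radius_norm"] > 0.3) & (out["radius_norm"] < 0.55)]
        assert (np.diff(mid["incline"]) <= 1e-9).all()

    def test_bad_frac(self):
        with pytest.raises(ValueError):
            lowess_trend(np.linspace(0, 1, 30), np.zeros(30), frac=0.0)


class TestRadialClassProfile:
    def test_hand_built_quartiles(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9.0]) / 10
        t = pd.DataFrame({"class": "c", "incline": vals,
                          "polar_radius_norm": 0.5})
        prof = radial_class_profile(t)
        assert prof.loc[0, "incline_q1"] == pytest.approx(0.3)
        assert prof.loc[0, "incline_median"] == pytest.approx(0.5)
        assert prof.loc[0, "incline_q3"] == pytest.approx(0.7)

    def test_zone_ordering(self, small_table):
        prof = radial_class_profile(small_table).set_index("class")
        assert (prof.loc["xylem_vessel_parenchyma", "mean_radius_norm"]
                < prof.loc["cambium", "mean_radius_norm"]
                < prof.loc["phloem_parenchyma", "mean_radius_norm"])

    def test_absent_class_omitted(self):
        t = pd.DataFrame({"class": ["a"] * 5, "incline": np.linspace(0, 1, 5),
                          "polar_radius_norm": 0.5})
        prof = radial_class_profile(t)
        assert prof["class"].tolist() == ["a"]


class TestCountWithinRadius:
    def test_planted_counts(self):
        t = pd.DataFrame({
            "centroid_x": [10, 20, 30, 50, 100, 150, 180,
                           250, 260, 270, 280, 290],
            "centroid_y": [0] * 12})
        counts = count_within_radius(t, [200, 300, 400, 500], center=(0, 0))
        assert counts[200] == 7
        assert counts.is_monotonic_increasing

    def test_zero_radius(self):
        t = pd.DataFrame({"centroid_x": [5.0], "centroid_y": [5.0]})
        assert count_within_radius(t, [0], center=(0, 0))[0] == 0

    def test_negative_radius_rejected(self):
        t = pd.DataFrame({"centroid_x": [1.0], "centroid_y": [1.0]})
        with pytest.raises(ValueError):
            count_within_radius(t, [-1], center=(0, 0))


class TestInclineDensity:
    def test_integrates_to_one(self, rng):
        vals = rng.uniform(0, np.pi / 2, 200)
        out = incline_density(vals)
        assert np.trapezoid(out["density"], out["incline"]) == pytest.approx(
            1.0, abs=1e-6)

    def test_two_cluster_bimodality(self, rng):
        vals = np.concatenate([rng.normal(0.15, 0.04, 300),
                               rng.normal(1.35, 0.04, 300)])
        out = incline_density(np.clip(vals, 0, np.pi / 2), bandwidth=0.1)
        d = out["density"].to_numpy()
        peaks = [i for i in range(1, len(d) - 1)
                 if d[i] > d[i - 1] and d[i] >= d[i + 1] and d[i] > 0.1 * d.max()]
        assert len(peaks) == 2

    def test_point_mass_mode(self):
        out = incline_density(np.full(20, np.pi / 4))
        mode = out.loc[out["density"].idxmax(), "incline"]
        assert mode == pytest.approx(np.pi / 4, abs=0.01)
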