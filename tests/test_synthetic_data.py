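import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atlas_smooth.spatial_structure import adjacency_from_edges, repair_islands
from atlas_smooth.synthetic_data import (
    StrataDesign,
    SyntheticConfig,
    generate_exclusion_fixture,
    generate_lattice_geography,
    simulate_incidence_counts,
    simulate_leroux_draws,
    simulate_leroux_field,
    simulate_survival_cohort,
    write_synthetic_inputs,
)


class TestLatticeGeography:
    def test_2x2_grid(self):
        g = generate_lattice_geography(SyntheticConfig(grid_rows=2, grid_cols=2, n_islands=0))
        assert g.n_areas == 4
        assert np.array_equal(g.neighbour_counts, np.full(4, 2))

    def test_1x1_plus_island(self):
        g = generate_lattice_geography(SyntheticConfig(grid_rows=1, grid_cols=1, n_islands=1))
        assert g.n_areas == 2
        assert np.array_equal(g.neighbour_counts, np.zeros(2))

    def test_3x3_degrees(self):
        g = generate_lattice_geography(SyntheticConfig(grid_rows=3, grid_cols=3, n_islands=0))
        deg = g.neighbour_counts.reshape(3, 3)
        assert deg[1, 1] == 4
        assert deg[0, 0] == deg[0, 2] == deg[2, 0] == deg[2, 2] == 2

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(grid_rows=0, grid_cols=3)

    def test_pop_floor_enforced(self):
        with pytest.raises(ValueError, match="residents"):
            SyntheticConfig(pop_range=(2, 100))


class TestLerouxField:
    def test_rho_zero_is_iid_normal(self, lattice_4x5):
        draws = simulate_leroux_draws(lattice_4x5, rho=0.0, sigma2=1.0, n_draws=10_000, seed=4)
        corr = np.corrcoef(draws.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.max(np.abs(off)) < 0.05
        # KS against N(0, 1) at alpha = 0.01
        p = stats.kstest(draws[:, 0], "norm").pvalue
        assert p > 0.01

    def test_two_area_analytic_covariance(self):
        g = adjacency_from_edges([("A", "B")], ["A", "B"])
        draws = simulate_leroux_draws(g, rho=0.5, sigma2=1.0, n_draws=50_000, seed=5)
        emp = np.cov(draws.T)
        expect = np.array([[4 / 3, 2 / 3], [2 / 3, 4 / 3]])
        assert np.max(np.abs(emp - expect)) < 0.02
        assert abs(np.corrcoef(draws.T)[0, 1] - 0.5) < 0.02

    def test_seeded_reproducibility(self, lattice_4x5):
        a = simulate_leroux_field(lattice_4x5, 0.7, 0.3, seed=9)
        b = simulate_leroux_field(lattice_4x5, 0.7, 0.3, seed=9)
        assert np.array_equal(a, b)

    def test_rho_one_refused(self, lattice_4x5):
        with pytest.raises(ValueError, match="rank-deficient"):
            simulate_leroux_field(lattice_4x5, 1.0, 0.3, seed=0)

    def test_empirical_covariance_converges(self, chain3):
        rho, sigma2 = 0.6, 0.4
        D = np.diag(chain3.neighbour_counts)
        Q = (rho * (D - chain3.W) + (1 - rho) * np.eye(3)) / sigma2
        target = np.linalg.inv(Q)
        small = np.cov(simulate_leroux_draws(chain3, rho, sigma2, 2_000, seed=1).T)
        large = np.cov(simulate_leroux_draws(chain3, rho, sigma2, 50_000, seed=1).T)
        assert np.max(np.abs(large - target)) < np.max(np.abs(small - target)) + 1e-6
        assert np.max(np.abs(large - target)) < 0.02


class TestIncidenceCounts:
    def test_unit_sir_mean(self):
        E = np.full(200, 1000.0)
        y = simulate_incidence_counts(E, beta0=0.0, S=np.zeros(200), seed=2)
        assert abs(np.mean(y / E) - 1.0) < 0.02

    def test_doubled_rate(self):
        E = np.full(400, 500.0)
        y = simulate_incidence_counts(E, beta0=np.log(2.0), S=np.zeros(400), seed=3)
        assert abs(y.mean() - 1000.0) < 10.0

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_incidence_counts([0.0, 1.0], 0.0, [0.0, 0.0], seed=0)


class TestSurvivalCohort:
    def test_realised_excess_matches_hazard(self, repaired_10x10):
        h = 0.05
        design = StrataDesign(alpha_true=tuple(np.log(h) for _ in range(5)),
                              patients_per_area=30)
        table, truth = simulate_survival_cohort(
            repaired_10x10, design, np.zeros(repaired_10x10.n_areas),
            background_rates=0.02, seed=3,
        )
        cells = table.cells
        live = cells["person_time"] > 0
        excess = cells.loc[live, "deaths"] - cells.loc[live, "expected_deaths"]
        expected_excess = cells.loc[live, "person_time"] * h
        # aggregate Poisson error shrinks with the number of cells
        assert abs(excess.sum() / expected_excess.sum() - 1.0) < 0.05

    def test_background_only_death_rate(self, repaired_10x10):
        design = StrataDesign(alpha_true=tuple([-30.0] * 5), patients_per_area=30)
        table, _ = simulate_survival_cohort(
            repaired_10x10, design, np.zeros(repaired_10x10.n_areas),
            background_rates=0.02, seed=4,
        )
        cells = table.cells[table.cells["person_time"] > 0]
        ratio = cells["deaths"].sum() / cells["expected_deaths"].sum()
        assert abs(ratio - 1.0) < 0.05

    def test_person_time_matches_interval_oracle(self, chain3):
        design = StrataDesign(patients_per_area=7)
        w0, w1 = 2006.0, 2015.0
        table, _ = simulate_survival_cohort(chain3, design, np.zeros(3), 0.02, (w0, w1), seed=8)
        # independent per-patient interval-intersection oracle on the same seed
        rng = np.random.default_rng(8)
        total = 0.0
        for _ in chain3.area_ids:
            for _ in design.labels:
                diag = rng.uniform(w0 - 5.0, w1, size=design.patients_per_area)
                for dgt in diag:
                    for t in range(1, 6):
                        lo = max(dgt + t - 1, w0)
                        hi = min(dgt + t, w1)
                        total += max(0.0, hi - lo)
        assert table.cells["person_time"].sum() == pytest.approx(total, rel=1e-9)

    def test_empty_window_rejected(self, chain3):
        with pytest.raises(ValueError, match="window"):
            simulate_survival_cohort(chain3, StrataDesign(), np.zeros(3), 0.02,
                                     (2010.0, 2010.0), seed=0)


class TestExclusionFixture:
    def test_reference_counts(self):
        fixture = generate_exclusion_fixture(
            2214, {"no_population": 28, "no_location": 18,
                   "under_5_residents": 17, "remote_island": 3},
        )
        assert fixture.total == 2214
        assert sum(fixture.flag_counts().values()) == 66

    def test_zero_flags(self):
        fixture = generate_exclusion_fixture(10, {})
        assert fixture.total == 10 and fixture.flag_counts() == {}

    def test_overflow_rejected(self):
        with pytest.raises(ValueError, match="total"):
            generate_exclusion_fixture(10, {"no_population": 11})


def test_write_synthetic_inputs_round_trip(tmp_path):
    cfg = SyntheticConfig(grid_rows=3, grid_cols=3, n_islands=1, seed=1)
    paths = write_synthetic_inputs(cfg, tmp_path)
    for p in paths.values():
        assert (tmp_path / p.split("/")[-1]).stat().st_size > 0
    areas = pd.read_csv(paths["areas"])
    assert len(areas) == cfg.n_areas
    surv = pd.read_csv(paths["survival"])
    assert {"area", "stratum", "followup_year", "deaths", "person_time",
            "expected_deaths"} <= set(surv.columns)
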