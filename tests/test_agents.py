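"""Cellular agents: probability laws, event lottery, occupancy, migration."""

import numpy as np
import pytest

from callusim.agents import (
    CellAgent,
    CellPopulation,
    Occupancy,
    PhenotypeParams,
    PolarizationParams,
    RecruitmentParams,
    apoptosis_probability,
    event_lottery,
    expected_recruits,
    migrate,
    polarization_probabilities,
    recruit,
)
from callusim.geometry import build_domain


@pytest.fixture()
def pheno_params():
    return PhenotypeParams(
        k_v={"M0": 2.0, "M1": 2.0, "M2": 2.0, "PMN": 5.0},
        k_p={"M0": 6e-4, "M1": 8.33e-4, "M2": 4e-4, "PMN": 0.0},
        k_a0={"M0": 3e-4, "M1": 5e-4, "M2": 3e-4, "PMN": 5e-4},
        k_e={"M0": 5e-3, "M1": 5e-3, "M2": 5e-3, "PMN": 3.33e-3},
    )


@pytest.fixture()
def pol_params():
    return PolarizationParams(k01=1.5e-3, k02=7e-4, k12=5e-4, k21=5e-5,
                              a01=0.3, a02=0.3, a12=0.3, a21=0.3)


class TestPolarizationProbabilities:
    def test_zero_tnfa_blocks_m1_transitions(self, pol_params):
        p = polarization_probabilities(0.0, 5.0, pol_params, dt=1.0)
        assert p["M0->M1"] == 0.0
        assert p["M2->M1"] == 0.0
        assert p["M0->M2"] > 0.0

    def test_half_saturation(self, pol_params):
        p = polarization_probabilities(pol_params.a01, 0.0, pol_params, dt=1.0)
        assert p["M0->M1"] == pytest.approx(pol_params.k01 / 2)

    def test_saturation_limit(self, pol_params):
        p = polarization_probabilities(1e9, 1e9, pol_params, dt=1.0)
        assert p["M0->M1"] == pytest.approx(pol_params.k01, rel=1e-6)
        assert p["M1->M2"] == pytest.approx(pol_params.k12, rel=1e-6)

    def test_probabilities_clamped(self, pol_params):
        p = polarization_probabilities(1e9, 1e9, pol_params, dt=1e9)
        assert all(0.0 <= v <= 1.0 for v in p.values())


class TestApoptosisProbability:
    def test_baseline(self, pheno_params):
        cell = CellAgent(0, "M0", (0, 0), debris_load=0.0)
        assert apoptosis_probability(cell, 0, pheno_params, 1.0) == \
            pytest.approx(pheno_params.k_a0["M0"])

    def test_monotone_in_load_and_crowding(self, pheno_params):
        base = apoptosis_probability(CellAgent(0, "M1", (0, 0), 10.0), 2,
                                     pheno_params, 1.0)
        more_load = apoptosis_probability(CellAgent(0, "M1", (0, 0), 20.0), 2,
                                          pheno_params, 1.0)
        more_nbrs = apoptosis_probability(CellAgent(0, "M1", (0, 0), 10.0), 5,
                                          pheno_params, 1.0)
        assert more_load >= base
        assert more_nbrs >= base

    def test_closed_form(self, pheno_params):
        cell = CellAgent(0, "M2", (0, 0), debris_load=2.0)
        expected = pheno_params.k_a0["M2"] * (
            1 + pheno_params.alpha_d * 2.0 + pheno_params.alpha_n * 5) * 1.0
        assert apoptosis_probability(cell, 5, pheno_params, 1.0) == \
            pytest.approx(expected, abs=1e-12)


class TestEventLottery:
    def test_all_zero_probabilities_never_trigger(self, rng):
        cell = CellAgent(0, "M0", (0, 0))
        probs = {"apoptosis": 0.0, "proliferation": 0.0,
                 "polarization": {"M1": 0.0, "M2": 0.0}}
        for _ in range(200):
            assert event_lottery(cell, probs, rng) == ("none",)

    def test_certain_apoptosis_preempts(self, rng):
        cell = CellAgent(0, "M0", (0, 0))
        probs = {"apoptosis": 1.0, "proliferation": 1.0, "polarization": {"M1": 1.0}}
        for _ in range(50):
            assert event_lottery(cell, probs, rng) == ("apoptosis",)

    def test_trigger_frequency_binomial(self, rng):
        """Empirical trigger rate at p=0.3 sits within 3 SE over 1e5 trials."""
        cell = CellAgent(0, "M0", (0, 0))
        p = 0.3
        n = 100_000
        hits = sum(event_lottery(cell, {"proliferation": p}, rng)[0] == "proliferation"
                   for _ in range(n))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) <= 3 * se


class TestOccupancy:
    def test_exclusion_detects_close_neighbor(self):
        occ = Occupancy(100.0, 100.0, (0.0, 0.0), r_ex=7.5)
        xs, ys = np.array([50.0]), np.array([50.0])
        occ.rebuild(xs, ys)
        assert not occ.is_free(52.0, 50.0, xs, ys)        # 2 um away
        assert occ.is_free(58.0, 50.0, xs, ys)            # 8 um away
        assert occ.is_free(52.0, 50.0, xs, ys, exclude=0)

    def test_neighbor_count_radius(self):
        occ = Occupancy(100.0, 100.0, (0.0, 0.0), r_ex=7.5)
        xs = np.array([50.0, 60.0, 80.0])
        ys = np.array([50.0, 50.0, 50.0])
        occ.rebuild(xs, ys)
        assert occ.neighbors_within(50.0, 50.0, 15.0, xs, ys, exclude=0) == 1
        assert occ.neighbors_within(50.0, 50.0, 31.0, xs, ys, exclude=0) == 2


class TestRecruitment:
    def test_zero_debris_recruits_nothing(self):
        assert expected_recruits(2.1e-2, 100.0, 1000.0, 0.0, 1.0, 1.6) == 0.0

    def test_full_compartment_recruits_nothing(self):
        assert expected_recruits(2.1e-2, 1000.0, 1000.0, 500.0, 1.0, 1.6) == 0.0

    def test_over_full_clamped_to_zero(self):
        assert expected_recruits(2.1e-2, 1500.0, 1000.0, 500.0, 1.0, 1.6) == 0.0

    def test_monte_carlo_mean_matches_closed_form(self, quarter_spec, params):
        """Poisson-realized recruit counts agree with the analytic mean."""
        masks = build_domain(quarter_spec)
        rng = np.random.default_rng(7)
        rp = RecruitmentParams(k_R_M0=2.1e-2, k_R_PMN=0.0, MPhi_max=1e9,
                               PMN_0=0.0, Db_0=0.0)
        debris = np.where(masks.healing_region, 500.0, 0.0)
        from callusim.geometry import area_of

        area = area_of(masks.healing_region, masks.resolution)
        expected = expected_recruits(rp.k_R_M0, 0.0, rp.MPhi_max, 500.0, 1.0, area)
        n_trials = 400
        total = 0
        for _ in range(n_trials):
            pop = CellPopulation()
            occ = Occupancy(quarter_spec.extent, quarter_spec.extent,
                            masks.origin, 7.5)
            occ.rebuild(pop.x, pop.y)
            total += recruit(pop, masks, debris, rp, 1.0, rng, occ)
        mean = total / n_trials
        se = np.sqrt(expected / n_trials)  # Poisson SE of the mean
        assert abs(mean - expected) <= 3 * se

    def test_recruits_placed_on_recruitment_boundary(self, quarter_spec):
        masks = build_domain(quarter_spec)
        rng = np.random.default_rng(3)
        rp = RecruitmentParams(k_R_M0=50.0, k_R_PMN=0.0, MPhi_max=1e9,
                               PMN_0=0.0, Db_0=0.0)
        debris = np.where(masks.healing_region, 100.0, 0.0)
        pop = CellPopulation()
        occ = Occupancy(quarter_spec.extent, quarter_spec.extent, masks.origin, 7.5)
        occ.rebuild(pop.x, pop.y)
        added = recruit(pop, masks, debris, rp, 1.0, rng, occ)
        assert added > 0
        rows, cols = masks.voxel_of(pop.x, pop.y)
        assert masks.recruitment_boundary[rows, cols].all()


class TestMigration:
    def _setup(self, quarter_spec, n_cells=1, rng=None):
        masks = build_domain(quarter_spec)
        pop = CellPopulation()
        pop.add(500.0, 300.0, 0)
        occ = Occupancy(quarter_spec.extent, quarter_spec.extent, masks.origin, 7.5)
        occ.rebuild(pop.x, pop.y)
        return masks, pop, occ

    def test_zero_speed_static(self, quarter_spec, rng):
        masks, pop, occ = self._setup(quarter_spec)
        debris = np.zeros(masks.shape)
        x, y = migrate(0, pop, debris, masks, k_v=0.0, occupancy=occ, rng=rng)
        assert (x, y) == (500.0, 300.0)

    def test_jump_count_follows_speed(self, quarter_spec, rng):
        """k_v = 5 um/min on the 1 um lattice executes exactly five jumps."""
        masks, pop, occ = self._setup(quarter_spec)
        x, _ = masks.voxel_centers()
        ramp = np.tile(x, (masks.shape[0], 1))  # steep +x ramp, no ties
        x1, y1 = migrate(0, pop, ramp, masks, k_v=5.0, occupancy=occ, rng=rng,
                         chemotaxis=True)
        assert abs(x1 - 500.0) + abs(y1 - 300.0) == pytest.approx(5.0)
        assert x1 == pytest.approx(505.0)  # pure ascent along the ramp

    def test_ascent_on_linear_ramp(self, quarter_spec, rng):
        """Net displacement over 100 iterations climbs the debris ramp."""
        masks, pop, occ = self._setup(quarter_spec)
        x, _ = masks.voxel_centers()
        ramp = np.tile(x, (masks.shape[0], 1))
        start = ramp[masks.voxel_of(500.0, 300.0)]
        for _ in range(100):
            migrate(0, pop, ramp, masks, k_v=2.0, occupancy=occ, rng=rng,
                    chemotaxis=True)
        end = ramp[masks.voxel_of(float(pop.x[0]), float(pop.y[0]))]
        assert end > start
        assert pop.x[0] == pytest.approx(700.0)  # 100 it x 2 jumps, all +x

    def test_blocked_cell_stays(self, quarter_spec, rng):
        masks, pop, occ = self._setup(quarter_spec)
        # ring of blockers within r_ex of every 1 um neighbour of the cell
        for dx, dy in ((6.0, 0.0), (-6.0, 0.0), (0.0, 6.0), (0.0, -6.0)):
            pop.add(500.0 + dx, 300.0 + dy, 0)
        occ.rebuild(pop.x, pop.y)
        debris = np.zeros(masks.shape)
        x1, y1 = migrate(0, pop, debris, masks, k_v=3.0, occupancy=occ, rng=rng)
        assert (x1, y1) == (500.0, 300.0)

    def test_jumps_never_leave_healing_region(self, quarter_spec, rng):
        masks, pop, occ = self._setup(quarter_spec)
        debris = np.zeros(masks.shape)
        for _ in range(300):
            migrate(0, pop, debris, masks, k_v=5.0, occupancy=occ, rng=rng,
                    chemotaxis=False)
            r, c = masks.voxel_of(float(pop.x[0]), float(pop.y[0]))
            assert masks.healing_region[r, c]


class TestPhenotypeParams:
    def test_pmn_proliferation_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeParams(k_v={}, k_p={"PMN": 1e-3}, k_a0={}, k_e={})
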