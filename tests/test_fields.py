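"""Molecular level: diffusion-decay, secretion laws, engulfment, gradients."""

import math

import numpy as np
import pytest

from callusim.agents import CellAgent
from callusim.fields import (
    ConsistencyError,
    MolecularState,
    SecretionParams,
    TransportParams,
    apply_secretion,
    engulf_debris,
    local_gradient,
    secretion_rate,
    step_diffuse_decay,
)


def make_state(tiny_masks, db0=0.0):
    return MolecularState.zeros(tiny_masks, db0=db0)


class TestDiffuseDecay:
    def test_uniform_field_unchanged_without_decay(self, tiny_masks):
        state = make_state(tiny_masks)
        state.tnfa[tiny_masks.healing_region] = 3.7
        tp = TransportParams(d_tnfa=0.0, d_il10=0.0, d_tgfb=0.0, d_ifng=0.0)
        out = step_diffuse_decay(state, tp)
        np.testing.assert_allclose(out.tnfa[tiny_masks.healing_region], 3.7)

    def test_pulse_decay_closed_form(self, tiny_masks):
        state = make_state(tiny_masks)
        state.il10[5, 5] = 10.0
        d = 3.0e-4
        tp = TransportParams(D_tnfa=0, D_il10=0, D_tgfb=0, D_ifng=0, d_il10=d,
                             d_tnfa=0, d_tgfb=0, d_ifng=0)
        t = 500.0
        for _ in range(int(t)):
            state = step_diffuse_decay(state, tp)
        assert state.il10[5, 5] == pytest.approx(10.0 * math.exp(-d * t), rel=1e-12)

    def test_mass_conserved_without_decay(self, tiny_masks, rng):
        """No-flux diffusion conserves total mass to floating tolerance."""
        state = make_state(tiny_masks)
        m = tiny_masks.healing_region
        state.tnfa[m] = rng.random(m.sum()) * 10
        tp = TransportParams(d_tnfa=0, d_il10=0, d_tgfb=0, d_ifng=0)
        before = state.tnfa[m].sum()
        for _ in range(1000):
            state = step_diffuse_decay(state, tp)
        after = state.tnfa[m].sum()
        assert abs(after - before) / before <= 1e-9

    def test_nonnegativity_preserved(self, tiny_masks, rng):
        state = make_state(tiny_masks)
        m = tiny_masks.healing_region
        for cyt in ("tnfa", "il10", "tgfb", "ifng"):
            state.field(cyt)[m] = rng.random(m.sum())
        tp = TransportParams()
        for _ in range(50):
            state = step_diffuse_decay(state, tp)
            for cyt in ("tnfa", "il10", "tgfb", "ifng"):
                assert (state.field(cyt)[m] >= 0).all()

    def test_substepping_invariance(self, tiny_masks):
        """Halving the molecular step changes the result by < 1%."""
        def evolve(dt_mol, n_seconds=600):
            state = make_state(tiny_masks)
            state.tnfa[6, 6] = 100.0
            tp = TransportParams(dt_mol=dt_mol)
            for _ in range(int(n_seconds / dt_mol)):
                state = step_diffuse_decay(state, tp)
            return state.tnfa

        a = evolve(1.0)
        b = evolve(0.5)
        m = tiny_masks.healing_region
        assert np.abs(a[m] - b[m]).max() <= 0.01 * np.abs(a[m]).max()

    def test_debris_untouched(self, tiny_masks):
        state = make_state(tiny_masks, db0=42.0)
        out = step_diffuse_decay(state, TransportParams())
        np.testing.assert_array_equal(out.debris, state.debris)


class TestSecretionRate:
    sp = SecretionParams()

    def zero_local(self):
        return {"tnfa": 0.0, "il10": 0.0, "tgfb": 0.0, "ifng": 0.0}

    def test_m2_secretes_no_tnfa(self):
        local = {"tnfa": 1.0, "il10": 2.0, "tgfb": 0.5, "ifng": 3.0}
        assert secretion_rate("M2", "TNFα", local, self.sp) == 0.0

    def test_absent_pairs_are_zero(self):
        local = self.zero_local()
        assert secretion_rate("PMN", "IL10", local, self.sp) == 0.0
        assert secretion_rate("PMN", "TGFβ", local, self.sp) == 0.0
        assert secretion_rate("M1", "IL10", local, self.sp) == 0.0
        assert secretion_rate("M2", "IFNγ", local, self.sp) == 0.0

    def test_m0_tnfa_ifng_saturation(self):
        """At saturating IFNγ the amplification reaches 1 + k_TNI."""
        local = self.zero_local()
        local["ifng"] = 1e6
        assert secretion_rate("M0", "TNFα", local, self.sp) == \
            pytest.approx(self.sp.k_TNF * (1 + self.sp.k_TNI), rel=1e-9)

    def test_m1_tnfa_full_inhibition_limit(self):
        """Saturating IL10 and TGFβ leave only the b-floor factors."""
        local = {"tnfa": 0.0, "il10": 1e6, "tgfb": 1e6, "ifng": 0.0}
        expected = (self.sp.k_TNF * self.sp.b_TNIL * self.sp.b_TNTG
                    * (1 + self.sp.k_TNI / (1 + math.exp(self.sp.a_TNI))))
        assert secretion_rate("M1", "TNFα", local, self.sp) == \
            pytest.approx(expected, rel=1e-9)

    def test_m1_vs_m0_tnfa_ratio_at_zero(self):
        """At zero concentrations M1/M0 differ by the two inhibition sums."""
        local = self.zero_local()
        m0 = secretion_rate("M0", "TNFα", local, self.sp)
        m1 = secretion_rate("M1", "TNFα", local, self.sp)
        ratio = (self.sp.k_TNIL + self.sp.b_TNIL) * (self.sp.k_TNTG + self.sp.b_TNTG)
        assert m1 == pytest.approx(m0 * ratio, rel=1e-12)

    def test_ifng_secretion_suppressed_by_tnfa(self):
        lo = secretion_rate("M0", "IFNγ", {"tnfa": 0.0}, self.sp)
        hi = secretion_rate("M0", "IFNγ", {"tnfa": 5.0}, self.sp)
        assert lo == pytest.approx(self.sp.k_IFN)
        assert hi == pytest.approx(self.sp.k_IFN * math.exp(-5.0 * self.sp.a_ITN))

    def test_pmn_constant_rates(self):
        local = {"tnfa": 9.9, "il10": 9.9, "tgfb": 9.9, "ifng": 9.9}
        assert secretion_rate("PMN", "TNFα", local, self.sp) == self.sp.k_TNF
        assert secretion_rate("PMN", "IFNγ", local, self.sp) == self.sp.k_IFN

    def test_unknown_cytokine_raises(self):
        with pytest.raises(KeyError):
            secretion_rate("M0", "IL6", self.zero_local(), self.sp)


class TestApplySecretion:
    sp = SecretionParams()

    def test_no_cells_no_change(self, tiny_masks):
        state = make_state(tiny_masks)
        out = apply_secretion(state, [], self.sp, dt=60.0)
        np.testing.assert_array_equal(out.il10, state.il10)

    def test_two_m2_cells_one_voxel_additive(self, tiny_masks):
        state = make_state(tiny_masks)
        cells = [CellAgent(0, "M2", (32.0, 32.0)), CellAgent(1, "M2", (36.0, 37.0))]
        out = apply_secretion(state, cells, self.sp, dt=60.0)
        assert out.il10[3, 3] == pytest.approx(2 * self.sp.k_IL10 * 1.0)

    def test_mixed_population_matches_per_cell_loop(self, tiny_masks, rng):
        """Vectorized-path increments equal brute-force per-cell accumulation."""
        from callusim.fields import CYTOKINES

        state = make_state(tiny_masks)
        m = tiny_masks.healing_region
        for cyt in CYTOKINES:
            state.field(cyt)[m] = rng.random(m.sum())
        phens = ["M0", "M1", "M2", "PMN"]
        cells = [CellAgent(i, phens[i % 4],
                           (float(rng.uniform(12, 108)), float(rng.uniform(12, 108))))
                 for i in range(40)]
        out = apply_secretion(state, cells, self.sp, dt=60.0)

        expected = {c: state.field(c).copy() for c in CYTOKINES}
        for cell in cells:
            r, c = tiny_masks.voxel_of(*cell.position)
            local = {k: float(state.field(k)[r, c]) for k in CYTOKINES}
            for cyt in CYTOKINES:
                expected[cyt][r, c] += secretion_rate(cell.phenotype, cyt, local,
                                                      self.sp) * 1.0
        for cyt in CYTOKINES:
            np.testing.assert_allclose(out.field(cyt), expected[cyt], rtol=1e-12)

    def test_order_independence(self, tiny_masks, rng):
        state = make_state(tiny_masks)
        cells = [CellAgent(i, "M0", (float(rng.uniform(12, 108)),
                                     float(rng.uniform(12, 108))))
                 for i in range(20)]
        a = apply_secretion(state, cells, self.sp, dt=60.0)
        b = apply_secretion(state, cells[::-1], self.sp, dt=60.0)
        np.testing.assert_allclose(a.tnfa, b.tnfa, rtol=1e-12)

    def test_cell_outside_region_rejected(self, tiny_masks):
        state = make_state(tiny_masks)
        with pytest.raises(ConsistencyError):
            apply_secretion(state, [CellAgent(0, "M0", (1.0, 1.0))], self.sp, 60.0)


class TestEngulfDebris:
    k_e = {"M0": 5e-3, "M1": 5e-3, "M2": 5e-3, "PMN": 3.33e-3}

    def test_zero_debris_no_change(self, tiny_masks):
        state = make_state(tiny_masks, db0=0.0)
        cells = [CellAgent(0, "PMN", (55.0, 55.0))]
        out, gains = engulf_debris(state, cells, self.k_e, dt=60.0)
        assert gains[0] == 0.0
        assert out.debris.sum() == 0.0

    def test_equal_rates_equal_shares(self, tiny_masks):
        """Two phagocytes with one k_e on the same voxel split the removal."""
        state = make_state(tiny_masks, db0=100.0)
        k_e = {"PMN": 4e-3, "M0": 4e-3}
        cells = [CellAgent(0, "PMN", (55.0, 55.0)), CellAgent(1, "M0", (55.0, 55.0))]
        _, gains = engulf_debris(state, cells, k_e, dt=60.0)
        assert gains[0] == pytest.approx(gains[1], rel=1e-12)
        assert gains[0] > 0

    def test_debris_never_negative_and_mass_balance(self, tiny_masks, rng):
        state = make_state(tiny_masks, db0=50.0)
        cells = [CellAgent(i, "M1", (float(rng.uniform(12, 108)),
                                     float(rng.uniform(12, 108))))
                 for i in range(30)]
        before = state.debris.sum()
        out, gains = engulf_debris(state, cells, self.k_e, dt=600.0)
        assert (out.debris >= 0).all()
        assert before - out.debris.sum() == pytest.approx(gains.sum(), rel=1e-9)

    def test_order_independence(self, tiny_masks, rng):
        state = make_state(tiny_masks, db0=80.0)
        cells = [CellAgent(i, "M0", (float(rng.uniform(12, 108)),
                                     float(rng.uniform(12, 108))))
                 for i in range(25)]
        out1, g1 = engulf_debris(state, cells, self.k_e, dt=60.0)
        out2, g2 = engulf_debris(state, cells[::-1], self.k_e, dt=60.0)
        np.testing.assert_allclose(out1.debris, out2.debris, rtol=1e-12)
        np.testing.assert_allclose(g1, g2[::-1], rtol=1e-12)


class TestLocalGradient:
    def test_uniform_field_zero_gradient(self, tiny_masks):
        field = np.full(tiny_masks.shape, 5.0)
        g = local_gradient(field, (55.0, 55.0), tiny_masks)
        np.testing.assert_array_equal(g, [0.0, 0.0])

    def test_linear_ramp(self, tiny_masks):
        x, _ = tiny_masks.voxel_centers()
        field = np.tile(x, (tiny_masks.shape[0], 1))
        g = local_gradient(field, (55.0, 55.0), tiny_masks)
        np.testing.assert_allclose(g, [1.0, 0.0])

    def test_matches_brute_finite_difference(self, tiny_masks, rng):
        field = rng.random(tiny_masks.shape) * 10
        mask = tiny_masks.healing_region
        h = tiny_masks.resolution
        for _ in range(50):
            r = int(rng.integers(2, 9))
            c = int(rng.integers(2, 9))
            pos = (c * 10.0 + 5.0, r * 10.0 + 5.0)
            g = local_gradient(field, pos, tiny_masks)
            gx = (field[r, c + 1] - field[r, c - 1]) / (2 * h) if mask[r, c + 1] and mask[r, c - 1] else None
            if gx is not None:
                assert g[0] == pytest.approx(gx, rel=1e-12)
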