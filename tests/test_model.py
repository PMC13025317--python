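"""Unit and property tests for the electrodiffusion model core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from betadisp import (
    FieldState,
    ForcingSpec,
    GridSpec,
    ModelParams,
    euler_step,
    forcing_value,
    init_field,
    laplacian_neumann,
    make_weight_profile,
    normalize_charge,
    stability_limit,
)
from betadisp.errors import DimensionError, InvalidGridError, StabilityError
from betadisp.sweep import _run_window


class TestGridSpec:
    def test_rejects_too_small_grids(self):
        with pytest.raises(InvalidGridError):
            GridSpec(nx=2, ny=5)
        with pytest.raises(InvalidGridError):
            GridSpec(nx=5, ny=2)
        with pytest.raises(InvalidGridError):
            GridSpec(nx=5, ny=5, h=0.0)

    def test_stability_limit_scales_with_spacing(self):
        assert stability_limit(GridSpec(5, 5, h=1.0)) == 0.25
        assert stability_limit(GridSpec(5, 5, h=2.0)) == 1.0


class TestWeightProfile:
    @pytest.mark.parametrize("nx", [3, 10, 50, 200])
    def test_endpoints_and_monotonicity(self, nx):
        w = make_weight_profile(GridSpec(nx=nx, ny=3))
        assert w[0] == 1.0
        assert w[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(w) < 0)
        assert np.all((w >= 0) & (w <= 1))

    def test_logarithmic_decay_value(self):
        # w(9) on a 50-wide grid: 1 - ln(10)/ln(50)
        w = make_weight_profile(GridSpec(nx=50, ny=3))
        assert w[9] == pytest.approx(1 - np.log(10) / np.log(50), abs=1e-12)
        assert w[9] == pytest.approx(0.4114, abs=5e-5)


class TestForcingValue:
    def test_harmonic_drive(self):
        w = np.ones(5)
        spec = ForcingSpec(frequency=2.0, amplitude=0.7, weight=w)
        assert forcing_value(0.0, spec) == 0.0
        quarter = 1.0 / (4 * spec.frequency)
        assert forcing_value(quarter, spec) == pytest.approx(0.7, rel=1e-12)

    def test_zero_frequency_gives_zero_drive(self):
        spec = ForcingSpec(frequency=0.0, amplitude=1.0, weight=np.ones(5))
        for t in (0.0, 0.3, 17.0):
            assert forcing_value(t, spec) == 0.0

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            ForcingSpec(frequency=1.0, amplitude=1.0, weight=np.array([0.5, 1.0, 0.0]))
        with pytest.raises(ValueError):
            ForcingSpec(frequency=1.0, amplitude=1.0, weight=np.array([1.0, 2.0, 0.0]))


class TestLaplacian:
    def test_annihilates_constants(self, small_grid):
        psi = np.full(small_grid.shape, 3.7)
        assert np.all(laplacian_neumann(psi, small_grid) == 0)

    def test_interior_spike_stencil(self):
        grid = GridSpec(nx=7, ny=5)
        psi = np.zeros(grid.shape)
        psi[3, 2] = 1.0
        lap = laplacian_neumann(psi, grid)
        assert lap[3, 2] == -4.0
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            assert lap[3 + di, 2 + dj] == 1.0
        assert np.count_nonzero(lap) == 5

    @given(arrays(float, (10, 7), elements=st.floats(-5, 5)))
    def test_zero_flux_sum_is_zero(self, psi):
        # discrete divergence theorem under mirror ghosts
        grid = GridSpec(nx=10, ny=7)
        assert abs(laplacian_neumann(psi, grid).sum()) < 1e-10

    def test_shape_mismatch_raises(self, small_grid):
        with pytest.raises(DimensionError):
            laplacian_neumann(np.zeros((4, 4)), small_grid)


class TestNormalizeCharge:
    def test_none_is_identity(self, rng):
        state = FieldState(psi=rng.normal(size=(6, 4)), t=1.0)
        out = normalize_charge(state, "none")
        assert out is state

    def test_zero_mean_preserves_deviations(self, rng):
        psi = rng.normal(size=(6, 4)) + 0.3
        state = FieldState(psi=psi, t=0.0)
        out = normalize_charge(state, "zero-mean")
        assert out.psi.mean() == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(out.psi - out.psi.mean(), psi - psi.mean())

    def test_idempotent(self, rng):
        state = FieldState(psi=rng.normal(size=(5, 5)), t=0.0)
        once = normalize_charge(state, "zero-mean")
        twice = normalize_charge(once, "zero-mean")
        np.testing.assert_allclose(twice.psi, once.psi, atol=1e-15)


class TestInitField:
    def test_range_and_reproducibility(self, reference_grid):
        a = init_field(reference_grid, seed=123)
        b = init_field(reference_grid, seed=123)
        assert np.array_equal(a.psi, b.psi)
        assert a.t == 0.0
        assert np.all(np.abs(a.psi) <= 0.05)
        c = init_field(reference_grid, seed=124)
        assert not np.array_equal(a.psi, c.psi)

    def test_uniform_moments(self, reference_grid):
        # 100 seeds x 1000 cells = 1e5 draws; SE of the mean = 0.05/sqrt(3)/sqrt(n)
        vals = np.concatenate(
            [init_field(reference_grid, seed=s).psi.ravel() for s in range(100)]
        )
        se = 0.05 / np.sqrt(3) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se


class TestEulerStep:
    def test_zero_is_fixed_point(self, small_grid):
        params = ModelParams(kappa=0.1, amplitude=0.0, dt=0.05)
        forcing = ForcingSpec(
            frequency=1.0, amplitude=0.0, weight=make_weight_profile(small_grid)
        )
        state = FieldState(psi=np.zeros(small_grid.shape))
        for _ in range(20):
            state = euler_step(state, small_grid, params, forcing)
        assert np.all(state.psi == 0.0)
        assert state.t == pytest.approx(20 * 0.05)

    def test_uniform_field_unscreened_is_invariant(self, small_grid):
        params = ModelParams(kappa=0.0, amplitude=0.0, dt=0.05, normalization="none")
        forcing = ForcingSpec(
            frequency=1.0, amplitude=0.0, weight=make_weight_profile(small_grid)
        )
        state = FieldState(psi=np.full(small_grid.shape, 0.42))
        out = euler_step(state, small_grid, params, forcing)
        np.testing.assert_allclose(out.psi, 0.42, atol=1e-14)

    def test_uniform_screened_decay_one_step(self, small_grid):
        # sinh(x) ~ x for x = 0.01: psi * (1 - dt kappa^2) to 1e-9
        params = ModelParams(kappa=0.1, amplitude=0.0, dt=0.1, normalization="none")
        forcing = ForcingSpec(
            frequency=0.0, amplitude=0.0, weight=make_weight_profile(small_grid)
        )
        state = FieldState(psi=np.full(small_grid.shape, 0.01))
        out = euler_step(state, small_grid, params, forcing)
        np.testing.assert_allclose(out.psi, 0.01 * (1 - 0.1 * 0.01), atol=1e-9)

    def test_linear_regime_decay_closed_form(self, small_grid):
        # uniform psi0 <= 1e-3: after n steps psi = psi0 (1 - dt kappa^2)^n
        psi0, kappa, dt, n = 1e-3, 0.1, 0.1, 100
        params = ModelParams(kappa=kappa, amplitude=0.0, dt=dt, normalization="none")
        forcing = ForcingSpec(
            frequency=0.0, amplitude=0.0, weight=make_weight_profile(small_grid)
        )
        state = FieldState(psi=np.full(small_grid.shape, psi0))
        for _ in range(n):
            state = euler_step(state, small_grid, params, forcing)
        expected = psi0 * (1 - dt * kappa**2) ** n
        np.testing.assert_allclose(state.psi, expected, rtol=1e-6)

    def test_oversized_dt_rejected(self, small_grid):
        params = ModelParams(kappa=0.0, amplitude=0.0, dt=0.3)
        forcing = ForcingSpec(
            frequency=1.0, amplitude=0.0, weight=make_weight_profile(small_grid)
        )
        state = FieldState(psi=np.zeros(small_grid.shape))
        with pytest.raises(ValueError, match="stability bound"):
            euler_step(state, small_grid, params, forcing)

    def test_blowup_raises_stability_error(self, small_grid):
        # a field beyond the sinh guard must abort, naming dt and max|psi|
        params = ModelParams(kappa=1.0, amplitude=0.0, dt=0.25, normalization="none")
        forcing = ForcingSpec(
            frequency=0.0, amplitude=0.0, weight=make_weight_profile(small_grid)
        )
        psi = np.zeros(small_grid.shape)
        psi[5, 3] = 29.0  # sinh(29) ~ 2e12: one step is enough
        state = FieldState(psi=psi)
        with pytest.raises(StabilityError) as exc:
            euler_step(state, small_grid, params, forcing)
        assert exc.value.dt == 0.25
        assert exc.value.max_abs_psi > 30


class TestConservationAndRelaxation:
    def test_unforced_mean_is_conserved(self, small_grid, quiet_params, rng):
        forcing = ForcingSpec(
            frequency=1.0, amplitude=0.0, weight=make_weight_profile(small_grid)
        )
        state = init_field(small_grid, seed=5)
        mean0 = state.psi.mean()
        for _ in range(200):
            state = euler_step(state, small_grid, quiet_params, forcing)
        assert abs(state.psi.mean() - mean0) < 1e-10

    @pytest.mark.parametrize("kappa", [0.0, 0.1, 1.0])
    def test_max_abs_nonincreasing_without_forcing(self, small_grid, kappa):
        params = ModelParams(kappa=kappa, amplitude=0.0, dt=0.05, normalization="none")
        forcing = ForcingSpec(
            frequency=1.0, amplitude=0.0, weight=make_weight_profile(small_grid)
        )
        state = init_field(small_grid, seed=11)
        prev = np.abs(state.psi).max()
        for _ in range(100):
            state = euler_step(state, small_grid, params, forcing)
            cur = np.abs(state.psi).max()
            assert cur <= prev + 1e-14
            prev = cur

    def test_decay_to_uniform(self, reference_grid):
        # unforced, unscreened, zero-mean: std drops below 1e-6 in bounded steps
        params = ModelParams(kappa=0.0, amplitude=0.0, dt=0.2)
        state = init_field(reference_grid, seed=3)
        padded = np.zeros((reference_grid.nx + 2, reference_grid.ny + 2))
        padded[1:-1, 1:-1] = state.psi
        w_col = make_weight_profile(reference_grid)[:, None]
        psi = padded[1:-1, 1:-1]
        t = 0.0
        for _ in range(40):  # at most 40k steps
            t = _run_window(padded, w_col, params, reference_grid, 0.0, t, 1000, None)
            if psi.std() < 1e-6:
                break
        assert psi.std() < 1e-6
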