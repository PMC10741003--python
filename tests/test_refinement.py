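import numpy as np
import pytest

from mcgss.forward import measurement_matrix, predict_measurements
from mcgss.propagation import realized_delay
from mcgss.refinement import (
    RefinementConfig,
    GradientSet,
    constraint_loss,
    gradient_gain_entry,
    measurement_loss,
    refine_epoch,
    refinement_forward,
    update_parameters,
    wrap_allpass,
)


class TestLosses:
    def test_measurement_loss_examples(self):
        assert measurement_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0
        assert measurement_loss(np.array([1.0, 0.0]), np.array([0.0, 0.0])) == pytest.approx(0.5)

    def test_measurement_loss_quadratic_homogeneity(self):
        z = np.array([0.4, -0.2, 0.1])
        zh = np.zeros(3)
        base = measurement_loss(z, zh)
        assert measurement_loss(3 * z, zh * 3) == pytest.approx(9 * base)

    def test_constraint_loss_hinge(self):
        assert constraint_loss(np.array([0.3, 0.3, 0.3])) == 0.0
        one = np.array([1.51, 0.0, 0.0])
        assert constraint_loss(one) == pytest.approx(0.25)
        assert constraint_loss(np.concatenate([one, one])) == pytest.approx(0.5)

    def test_constraint_uses_l1_norm(self):
        j = np.array([0.6, -0.6, 0.31])  # L1 = 1.51
        assert constraint_loss(j) == pytest.approx(0.25)


class TestGradientEntries:
    def test_zero_residual_zero_gradient(self):
        g = gradient_gain_entry(2.0, np.array([0.5]), np.array([0.0]), 0.2, 0.5, gamma=1.0)
        assert g == 0.0

    def test_direct_formula(self):
        g = gradient_gain_entry(2.0, np.array([0.5]), np.array([0.1]), 0.2, 0.5, gamma=1.0)
        assert g == pytest.approx(0.2)

    def test_constraint_term(self):
        g = gradient_gain_entry(
            1.0, np.array([0.0]), np.array([0.0]), j_component=0.4, l1_voxel=1.21, gamma=2.0
        )
        assert g == pytest.approx(2.0 * 2.0 * 1.0 * 1.0 * 0.2)


def perturbed_setup(chain3, chain3_sensors, rng, gamma):
    H = measurement_matrix(chain3.grid, chain3_sensors, scale=70.0, current_scale=1.0)
    model = chain3.model.copy()
    model.conn_gain = model.conn_gain + 0.2 * rng.standard_normal(model.conn_gain.shape)
    J_in = chain3.J + 0.05 * rng.standard_normal(chain3.J.shape)
    Z = predict_measurements(H, chain3.J, chain3.fs)
    config = RefinementConfig(eta=1.0, gamma=gamma)
    return H, model, J_in, Z, config


class TestGradientsAgainstFiniteDifferences:
    def total_loss(self, model, H, Z, J_in, config):
        loss, _ = refinement_forward(model, H, Z, J_in, config)
        return float(np.sum(loss.Lm_series + config.gamma * loss.Lv_series))

    def test_gain_gradients_match_fd(self, chain3, chain3_sensors, rng):
        H, model, J_in, Z, config = perturbed_setup(chain3, chain3_sensors, rng, gamma=0.7)
        _, grads = refinement_forward(model, H, Z, J_in, config)
        eps = 1e-6
        for _ in range(10):
            c = rng.integers(model.n_connections)
            j, k = rng.integers(3), rng.integers(3)
            mp, mm = model.copy(), model.copy()
            mp.conn_gain[c, j, k] += eps
            mm.conn_gain[c, j, k] -= eps
            fd = (
                self.total_loss(mp, H, Z, J_in, config)
                - self.total_loss(mm, H, Z, J_in, config)
            ) / (2 * eps)
            assert grads.d_gains[c, j, k] == pytest.approx(fd, rel=1e-4, abs=1e-12)

    def test_allpass_gradients_match_fd(self, chain3, chain3_sensors, rng):
        # the constraint term deliberately contributes nothing to dL/da, so
        # the finite-difference oracle runs at gamma = 0
        H, model, J_in, Z, config = perturbed_setup(chain3, chain3_sensors, rng, gamma=0.0)
        _, grads = refinement_forward(model, H, Z, J_in, config)
        eps = 1e-6
        for c in range(model.n_connections):
            if model.conn_a[c] >= 1.0 - eps:
                continue
            mp, mm = model.copy(), model.copy()
            mp.conn_a[c] += eps
            mm.conn_a[c] -= eps
            fd = (
                self.total_loss(mp, H, Z, J_in, config)
                - self.total_loss(mm, H, Z, J_in, config)
            ) / (2 * eps)
            assert grads.d_allpass[c] == pytest.approx(fd, rel=1e-4, abs=1e-12)

    def test_gradient_at_integer_delay_boundary_is_finite(self, chain3, chain3_sensors, rng):
        H, model, J_in, Z, config = perturbed_setup(chain3, chain3_sensors, rng, gamma=0.0)
        model.conn_a[:] = 1.0  # pure integer delays
        _, grads = refinement_forward(model, H, Z, J_in, config)
        assert np.all(np.isfinite(grads.d_allpass))


class TestParameterUpdates:
    @pytest.mark.parametrize(
        "a,k,expected",
        [(-0.2, 3, (0.8, 4)), (1.3, 2, (0.3, 1)), (1.3, 0, (1.0, 0)), (0.5, 2, (0.5, 2))],
    )
    def test_wrap_rules(self, a, k, expected):
        aw, kw = wrap_allpass(a, k)
        assert (pytest.approx(expected[0]), expected[1]) == (aw, kw)

    def test_wrap_preserves_realized_delay_at_lower_boundary(self):
        # crossing a -> 0 from above: delay k + (1-a)/(1+a) -> k + 1, and the
        # wrapped representation (a+1, k+1) continues continuously from it
        eps = 1e-6
        before = realized_delay(3, eps)
        a_w, k_w = wrap_allpass(-eps, 3)
        after = realized_delay(k_w, a_w)
        assert after == pytest.approx(before, abs=1e-5)

    def test_update_applies_scaled_gradient(self, chain3):
        model = chain3.model.copy()
        grads = GradientSet(
            d_gains=np.ones_like(model.conn_gain), d_allpass=np.zeros(model.n_connections)
        )
        new = update_parameters(model, grads, eta=10.0, Nm=100)
        np.testing.assert_allclose(new.conn_gain, model.conn_gain - 0.1)

    def test_non_finite_gradient_rejected(self, chain3):
        model = chain3.model.copy()
        bad = GradientSet(
            d_gains=np.zeros_like(model.conn_gain), d_allpass=np.zeros(model.n_connections)
        )
        bad.d_allpass[1] = np.nan
        with pytest.raises(FloatingPointError, match="connection"):
            update_parameters(model, bad, eta=1.0, Nm=10)


class TestRefineEpoch:
    def test_fixed_point_on_self_consistent_data(self, chain3, chain3_sensors):
        H = measurement_matrix(chain3.grid, chain3_sensors, scale=70.0)
        Z = predict_measurements(H, chain3.J, chain3.fs)

        class Est:
            filtered = chain3.J

        config = RefinementConfig(eta=200.0, gamma=0.0)
        new_model, loss = refine_epoch(chain3.model, H, Z, Est(), config)
        assert loss.Lm == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(new_model.conn_gain, chain3.model.conn_gain, atol=1e-10)
        np.testing.assert_allclose(new_model.conn_a, chain3.model.conn_a, atol=1e-10)

    def test_constraint_pushes_overshooting_gains_down(self, chain3, chain3_sensors):
        # the fractional-delay ripple overshoots the L1 ceiling slightly, so
        # with gamma > 0 the constraint term must reduce the feeding gains
        H = measurement_matrix(chain3.grid, chain3_sensors, scale=70.0)
        Z = predict_measurements(H, chain3.J, chain3.fs)

        class Est:
            filtered = chain3.J

        config = RefinementConfig(eta=200.0, gamma=1.0)
        new_model, loss = refine_epoch(chain3.model, H, Z, Est(), config)
        assert loss.Lv > 0
        active = np.abs(chain3.model.conn_gain).sum(axis=(1, 2)) > 0
        before = np.abs(chain3.model.conn_gain[active]).sum()
        after = np.abs(new_model.conn_gain[active]).sum()
        assert after < before

    def test_gamma_zero_total_is_measurement_loss(self, chain3, chain3_sensors, rng):
        H, model, J_in, Z, config = perturbed_setup(chain3, chain3_sensors, rng, gamma=0.0)
        loss, _ = refinement_forward(model, H, Z, J_in, config)
        assert loss.total == loss.Lm

    def test_loss_decreases_on_perturbed_toy(self, chain3, chain3_sensors):
        H = measurement_matrix(chain3.grid, chain3_sensors, scale=70.0)
        Z = predict_measurements(H, chain3.J, chain3.fs)
        model = chain3.model.copy()
        # perturb one established gain
        active = np.flatnonzero(np.abs(model.conn_gain).sum(axis=(1, 2)) > 0)
        model.conn_gain[active[0]] *= 1.5
        config = RefinementConfig(eta=50.0, gamma=1.0, input="open_loop")
        losses = []
        for _ in range(50):
            model, loss = refine_epoch(model, H, Z, None, config)
            losses.append(loss.total)
        assert losses[-1] < 0.2 * losses[0]
        assert losses[-1] == min(losses)

    def test_gradient_accumulation_adds_over_time_chunks(self, chain3, chain3_sensors, rng):
        """Gradients accumulated over the full run equal the sum over two
        halves: per-step contributions are additive and (at gamma = 0) linear
        in the residual, so zeroing the residual outside each half and adding
        the two gradient sets must reproduce the one-pass result."""
        from mcgss.forward import MeasurementSeries

        H, model, J_in, Z, config = perturbed_setup(chain3, chain3_sensors, rng, gamma=0.0)
        loss_full, grads_full = refinement_forward(model, H, Z, J_in, config)
        z_hat_T = loss_full.predicted_measurements / config.measurement_unit_scale
        half = Z.n_samples // 2
        za = Z.values.copy()
        za[half:] = z_hat_T[half:]  # residual zero on second half
        zb = Z.values.copy()
        zb[:half] = z_hat_T[:half]
        _, ga = refinement_forward(model, H, MeasurementSeries(za, Z.sampling_rate), J_in, config)
        _, gb = refinement_forward(model, H, MeasurementSeries(zb, Z.sampling_rate), J_in, config)
        np.testing.assert_allclose(ga.d_gains + gb.d_gains, grads_full.d_gains, rtol=1e-9, atol=1e-15)
        np.testing.assert_allclose(
            ga.d_allpass + gb.d_allpass, grads_full.d_allpass, rtol=1e-9, atol=1e-15
        )
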