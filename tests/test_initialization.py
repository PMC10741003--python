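import numpy as np
import pytest

from mcgss.geometry import (
    DEFAULT_CONNECTIVITY,
    DEFAULT_VELOCITIES,
    InvalidConfigurationError,
    VoxelType,
    assign_default_types,
    build_grid,
    default_layout,
    neighbors,
)
from mcgss.initialization import (
    build_model,
    connection_slots,
    control_vector,
    initial_delays,
    initialize_gains,
)


class TestInitialDelays:
    @pytest.mark.parametrize(
        "dist_mm,phi,expected",
        [
            (2.5, 1.1, 4.545454545),
            (2.5 * np.sqrt(2), 1.1, 6.428243465),
            (2.5, 0.012, 416.6666667),
        ],
    )
    def test_delay_formula(self, dist_mm, phi, expected):
        # tau = dist / phi * fs with the receiver's conduction velocity
        assert dist_mm * 1e-3 / phi * 2000.0 == pytest.approx(expected, rel=1e-6)

    def test_receiver_type_sets_velocity(self):
        # atrium -> AV hop must use the AV node's (slow) velocity
        grid = build_grid((1, 2, 1), 2.5)
        types = np.array([int(VoxelType.ATRIUM), int(VoxelType.AV_NODE)], dtype=np.int64)
        pairs = connection_slots(grid, types)
        tau = initial_delays(grid, types, DEFAULT_VELOCITIES, 2000.0, pairs)
        into_av = (pairs[0] == 1) & (pairs[1] == 0)
        assert tau[into_av][0] == pytest.approx(416.6666667, rel=1e-6)

    def test_sub_sample_delays_clamped(self, caplog):
        grid = build_grid((1, 2, 1), 2.5)
        types = np.array([int(VoxelType.HIS_PURKINJE)] * 2, dtype=np.int64)
        pairs = connection_slots(grid, types)
        tau = initial_delays(grid, types, DEFAULT_VELOCITIES, 500.0, pairs)
        assert np.all(tau >= 1.0)

    def test_zero_velocity_rejected(self):
        grid = build_grid((1, 2, 1), 2.5)
        types = np.array([int(VoxelType.ATRIUM)] * 2, dtype=np.int64)
        pairs = connection_slots(grid, types)
        with pytest.raises(InvalidConfigurationError):
            initial_delays(grid, types, {VoxelType.ATRIUM: 0.0}, 2000.0, pairs)


class TestWavefront:
    def test_chain3_activation_cascade(self, chain3):
        np.testing.assert_allclose(
            chain3.activation.activation_times, [0.0, 2.272727, 4.545454], rtol=1e-6
        )

    def test_sinoatrial_seed(self, chain3):
        assert chain3.activation.activation_times[0] == 0.0
        np.testing.assert_array_equal(chain3.activation.directions[0], [1.0, 0.0, 0.0])

    def test_direction_unit_l1_norm(self, sheet5x5):
        act = sheet5x5.activation
        connected = act.connected
        l1 = np.abs(act.directions[connected]).sum(axis=1)
        np.testing.assert_allclose(l1, 1.0)

    def test_diagonal_step_direction_and_gain(self):
        # one diagonal SA -> atrium hop: delta = (0.5, 0.5, 0), gain column 0
        grid = build_grid((2, 2, 1), 2.5)
        types = np.array(
            [int(VoxelType.SINOATRIAL_NODE), int(VoxelType.ATRIUM), int(VoxelType.ATRIUM), int(VoxelType.ATRIUM)],
            dtype=np.int64,
        )
        pairs = connection_slots(grid, types)
        tau = initial_delays(grid, types, DEFAULT_VELOCITIES, 2000.0, pairs)
        gains, act = initialize_gains(grid, types, pairs, tau, 2000.0)
        diag = grid.index_of(1, 1, 0)
        np.testing.assert_allclose(act.directions[diag], [0.5, 0.5, 0.0])
        c = (pairs[0] == diag) & (pairs[1] == 0)
        expected = np.zeros((3, 3))
        expected[:, 0] = [0.5, 0.5, 0.0]  # sign(delta_o) = (1, 0, 0)
        np.testing.assert_allclose(gains[c][0], expected)

    def test_each_voxel_single_parent_and_monotone_times(self, sheet5x5):
        m = sheet5x5.model
        act = sheet5x5.activation
        incoming = {}
        for c in range(m.n_connections):
            if m.conn_target[c] != m.conn_source[c] and np.any(m.conn_gain[c] != 0):
                t, s = int(m.conn_target[c]), int(m.conn_source[c])
                assert t not in incoming, "voxel activated twice"
                incoming[t] = s
                assert act.activation_times[t] >= act.activation_times[s]

    def test_pathological_never_connected(self, sheet5x5):
        patho = np.flatnonzero(sheet5x5.types == int(VoxelType.PATHOLOGICAL))
        act = sheet5x5.activation
        assert np.all(~act.connected[patho])
        assert np.all(np.isinf(act.activation_times[patho]))
        m = sheet5x5.model
        for c in range(m.n_connections):
            if m.conn_target[c] in patho or (
                m.conn_source[c] in patho and m.conn_target[c] != m.conn_source[c]
            ):
                assert np.all(m.conn_gain[c] == 0)

    def test_matches_naive_wavefront_oracle(self):
        """Independent re-implementation of the printed batch procedure."""
        grid = build_grid((4, 4, 1), 2.5)
        types = assign_default_types(
            grid,
            default_layout(
                atria_min_row=3,
                sa_site=(0, 3),
                av_site=(1, 2),
                his_column_x=1,
                his_rows=(1, 1),
                his_branch_row=1,
                his_branch_cols=(1, 2),
                patch_enabled=True,
                patch_cols=(3, 3),
                patch_rows=(0, 0),
            ),
        )
        pairs = connection_slots(grid, types)
        tau = initial_delays(grid, types, DEFAULT_VELOCITIES, 2000.0, pairs)
        gains, act = initialize_gains(grid, types, pairs, tau, 2000.0)

        # naive O(n^2) batch scan following the printed schedule literally
        allowed = {(int(a), int(b)) for a, b in DEFAULT_CONNECTIVITY}
        nv = grid.n_voxels
        sigma = np.full(nv, np.inf)
        connected = np.zeros(nv, dtype=bool)
        origin = int(np.flatnonzero(types == int(VoxelType.SINOATRIAL_NODE))[0])
        sigma[origin] = 0.0
        connected[origin] = True
        parents = {}
        ti = 0.0
        ts_ms = 1e3 / 2000.0
        taumap = {(int(t), int(s)): tau[c] for c, (t, s) in enumerate(zip(*pairs))}
        while True:
            for o in np.flatnonzero(np.abs(sigma - ti) < 1e-9):
                for i in neighbors(grid, int(o)):
                    i = int(i)
                    if connected[i]:
                        continue
                    if (int(types[o]), int(types[i])) not in allowed:
                        continue
                    sigma[i] = sigma[o] + taumap[(i, int(o))] * ts_ms
                    connected[i] = True
                    parents[i] = int(o)
            future = sigma[sigma > ti + 1e-9]
            if future.size == 0 or not np.isfinite(future.min()):
                break
            ti = future.min()

        np.testing.assert_allclose(act.activation_times, sigma, rtol=1e-9)
        model_parents = {}
        for c, (t, s) in enumerate(zip(*pairs)):
            if t != s and np.any(gains[c] != 0):
                model_parents[int(t)] = int(s)
        assert model_parents == parents


class TestControlVector:
    def test_single_unit_entry(self, sheet5x5):
        b = sheet5x5.model.control_vector
        assert b.sum() == 1.0
        assert np.count_nonzero(b) == 1
        origin = int(np.flatnonzero(sheet5x5.types == int(VoxelType.SINOATRIAL_NODE))[0])
        assert b[3 * origin] == 1.0

    def test_no_sinoatrial_voxel_rejected(self):
        grid = build_grid((2, 2, 1), 2.5)
        types = np.full(4, int(VoxelType.VENTRICLE), dtype=np.int64)
        with pytest.raises(InvalidConfigurationError):
            control_vector(grid, types)


class TestBuildModel:
    def test_reference_initial_layout_fully_connected(self):
        grid = build_grid((26, 37, 1), 2.5)
        types = assign_default_types(grid, default_layout(patch_enabled=False))
        model, act = build_model(grid, types, fs=2000.0, Nm=2000)
        assert model.n_states == 2886
        assert np.all(np.isfinite(act.activation_times))

    def test_reference_truth_layout_patch_isolated(self):
        grid = build_grid((26, 37, 1), 2.5)
        types = assign_default_types(grid, default_layout(patch_enabled=True))
        model, act = build_model(grid, types, fs=2000.0, Nm=2000)
        patho = np.flatnonzero(types == int(VoxelType.PATHOLOGICAL))
        assert patho.size == 42
        for c in range(model.n_connections):
            if model.conn_target[c] in patho:
                assert np.all(model.conn_gain[c] == 0)

    def test_single_voxel_model_is_drive_only(self):
        grid = build_grid((1, 1, 1), 2.5)
        types = np.array([int(VoxelType.SINOATRIAL_NODE)], dtype=np.int64)
        from mcgss.propagation import APTemplateParams

        ap = APTemplateParams(onset_ms=2, rise_ms=2, plateau_ms=20, repol_ms=10)
        model, act = build_model(grid, types, control_params=ap, fs=2000.0, Nm=100)
        assert model.n_connections == 1  # the self slot
        assert np.all(model.conn_gain == 0)
        assert model.control_vector[0] == 1.0

    def test_rebuild_is_bit_identical(self, sheet5x5):
        model2, act2 = build_model(
            sheet5x5.grid, sheet5x5.types, fs=sheet5x5.fs, Nm=sheet5x5.Nm,
            control_params=sheet5x5.model.control.params,
        )
        assert np.array_equal(model2.conn_gain, sheet5x5.model.conn_gain)
        assert np.array_equal(model2.conn_a, sheet5x5.model.conn_a)
        assert np.array_equal(model2.conn_delay, sheet5x5.model.conn_delay)
        np.testing.assert_array_equal(
            act2.activation_times, sheet5x5.activation.activation_times
        )
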