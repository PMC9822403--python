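"""T1-T2 map simulation, regularized inversion, and peak classification."""

import numpy as np
import pytest

from relaxochain import (
    T1T2Map,
    Peak,
    classify_map,
    gel_shift_diagnostic,
    invert_t1t2,
    simulate_ir_cpmg,
)
from relaxochain.t1t2 import (
    LABEL_AGGREGATE,
    LABEL_FREE,
    LABEL_VISCOUS,
    ClassificationError,
    IRCPMGSeries,
    default_grid,
)

TINV = np.logspace(0, np.log10(5000.0), 16)


def grid_neighbourhood(grid, value):
    """Grid values within one cell of the cell nearest to `value`."""
    i = int(np.argmin(np.abs(np.log(grid) - np.log(value))))
    return grid[max(i - 1, 0): i + 2]


def make_map(t1_ms, t2_ms, mass=1.0):
    """Minimal map with a single hand-placed peak (for classifier tests)."""
    g = default_grid(32)
    return T1T2Map(g, g, np.zeros((32, 32)), 1e-2, (Peak(t1_ms, t2_ms, mass),))


class TestSimulate:
    def test_full_recovery_short_time_amplitude_approaches_weight(self):
        s = simulate_ir_cpmg([(200.0, 150.0, 3.0)], TINV, n_echoes=64)
        assert s.data[-1, 0] == pytest.approx(3.0, rel=0.05)

    def test_zero_crossing_near_t1_ln2(self):
        t1 = 200.0
        tinv = np.linspace(1.0, 1000.0, 2000)
        s = simulate_ir_cpmg([(t1, 150.0, 1.0)], tinv, n_echoes=16)
        first_echo = s.data[:, 0]
        crossing = tinv[np.argmin(np.abs(first_echo))]
        assert crossing == pytest.approx(t1 * np.log(2), rel=0.01)

    def test_mixture_is_sum_of_components(self):
        a = simulate_ir_cpmg([(200.0, 150.0, 1.0)], TINV, n_echoes=64)
        b = simulate_ir_cpmg([(50.0, 20.0, 2.0)], TINV, n_echoes=64)
        both = simulate_ir_cpmg(
            [(200.0, 150.0, 1.0), (50.0, 20.0, 2.0)], TINV, n_echoes=64
        )
        assert np.allclose(both.data, a.data + b.data)

    def test_t1_below_t2_rejected(self):
        with pytest.raises(ValueError, match="unphysical"):
            simulate_ir_cpmg([(100.0, 200.0, 1.0)], TINV)

    def test_empty_components_rejected(self):
        with pytest.raises(ValueError):
            simulate_ir_cpmg([], TINV)

    def test_seed_reproducibility(self):
        kw = dict(noise_sigma=0.01, seed=42, n_echoes=64)
        a = simulate_ir_cpmg([(200.0, 150.0, 1.0)], TINV, **kw)
        b = simulate_ir_cpmg([(200.0, 150.0, 1.0)], TINV, **kw)
        assert np.array_equal(a.data, b.data)

    def test_series_validation(self):
        s = simulate_ir_cpmg([(200.0, 150.0, 1.0)], TINV, n_echoes=64)
        with pytest.raises(ValueError, match="increasing"):
            IRCPMGSeries(TINV[::-1], s.trains)
        with pytest.raises(ValueError, match="at least"):
            IRCPMGSeries(TINV[:4], s.trains[:4])


class TestInvert:
    def test_zero_data_gives_zero_map(self):
        s = simulate_ir_cpmg([(200.0, 150.0, 1.0)], TINV, n_echoes=64)
        zero_trains = tuple(tr.scaled(0.0) for tr in s.trains)
        zs = IRCPMGSeries(s.inversion_times_ms, zero_trains)
        m = invert_t1t2(zs)
        assert m.total_mass == 0.0
        assert m.peaks == ()

    def test_nonpositive_lambda_rejected(self):
        s = simulate_ir_cpmg([(200.0, 150.0, 1.0)], TINV, n_echoes=64)
        with pytest.raises(ValueError, match="lambda"):
            invert_t1t2(s, lambda_reg=0.0)

    def test_coarse_grid_rejected(self):
        s = simulate_ir_cpmg([(200.0, 150.0, 1.0)], TINV, n_echoes=64)
        with pytest.raises(ValueError, match="points"):
            invert_t1t2(s, default_grid(16), default_grid(64))

    def test_noiseless_single_component_round_trip(self):
        s = simulate_ir_cpmg([(200.0, 150.0, 1.0)], TINV, n_echoes=500)
        m = invert_t1t2(s, lambda_reg=1e-4)
        assert len(m.peaks) >= 1
        top = m.peaks[0]
        assert top.t1_ms in grid_neighbourhood(m.t1_grid_ms, 200.0)
        assert top.t2_ms in grid_neighbourhood(m.t2_grid_ms, 150.0)
        assert top.mass == pytest.approx(1.0, rel=0.1)

    def test_objective_decreases_monotonically(self):
        s = simulate_ir_cpmg(
            [(200.0, 150.0, 1.0)], TINV, n_echoes=200, noise_sigma=0.005, seed=3
        )
        m = invert_t1t2(s, lambda_reg=1e-2)
        hist = np.array(m.objective_history)
        assert np.all(np.diff(hist) <= 1e-9 * hist[0])

    def test_two_separated_components_masses(self):
        # SNR 500 on the stronger component
        s = simulate_ir_cpmg(
            [(15.0, 10.0, 1.0), (600.0, 500.0, 2.0)],
            TINV,
            n_echoes=1000,
            noise_sigma=2.0 / 500,
            seed=11,
        )
        m = invert_t1t2(s, lambda_reg=1e-2)
        assert len(m.peaks) >= 2
        heavy, light = m.peaks[0], m.peaks[1]
        assert heavy.t2_ms in grid_neighbourhood(m.t2_grid_ms, 500.0)
        assert light.t2_ms in grid_neighbourhood(m.t2_grid_ms, 10.0)
        assert heavy.mass / light.mass == pytest.approx(2.0, rel=0.2)

    def test_physical_components_leave_little_mass_above_diagonal(self):
        s = simulate_ir_cpmg([(400.0, 100.0, 1.0)], TINV, n_echoes=500)
        m = invert_t1t2(s, lambda_reg=1e-3)
        assert m.mass_above_diagonal() < 0.05

    def test_solver_matches_lawson_hanson_nnls(self):
        # independent route: solve the same Tikhonov-NNLS problem with
        # scipy's active-set solver on the explicit Kronecker system
        from scipy.optimize import nnls

        from relaxochain.t1t2 import _truncated_svd

        series = simulate_ir_cpmg(
            [(200.0, 150.0, 1.0)], np.logspace(0, np.log10(5000.0), 12), n_echoes=64
        )
        g = default_grid(32)
        lam = 1e-2
        k1 = 1 - 2 * np.exp(-series.inversion_times_ms[:, None] / g[None, :])
        k2 = np.exp(-series.echo_times_ms[:, None] / g[None, :])
        u1, k1c = _truncated_svd(k1, 1e-8)
        u2, k2c = _truncated_svd(k2, 1e-8)
        dc = u1.T @ series.data @ u2
        a = np.kron(k1c, k2c)
        a_aug = np.vstack([a, np.sqrt(lam) * np.eye(a.shape[1])])
        b_aug = np.concatenate([dc.ravel(), np.zeros(a.shape[1])])
        _, rnorm = nnls(a_aug, b_aug)

        m = invert_t1t2(series, g, g, lambda_reg=lam)
        assert m.objective_history[-1] == pytest.approx(rnorm**2, rel=1e-4)

    def test_negative_amplitude_map_rejected(self):
        g = default_grid(32)
        with pytest.raises(ValueError, match="nonnegative"):
            T1T2Map(g, g, -np.ones((32, 32)), 1e-2)


class TestClassify:
    @pytest.mark.parametrize(
        "t1,t2,label",
        [
            (5.0, 5.0, LABEL_VISCOUS),       # glycerol-like: short T2
            (800.0, 100.0, LABEL_AGGREGATE),  # resin-like: T1 >> T2
            (500.0, 500.0, LABEL_FREE),       # on the T1 = T2 diagonal
        ],
    )
    def test_peak_classes(self, t1, t2, label):
        result = classify_map(make_map(t1, t2))
        assert result["labels"] == {label}

    def test_peaks_sorted_by_mass_and_union_of_labels(self):
        g = default_grid(32)
        m = T1T2Map(
            g, g, np.zeros((32, 32)), 1e-2,
            (Peak(5.0, 5.0, 1.0), Peak(900.0, 90.0, 3.0)),
        )
        assert m.peaks[0].mass == 3.0
        assert classify_map(m)["labels"] == {LABEL_VISCOUS, LABEL_AGGREGATE}

    def test_empty_map_rejected(self):
        g = default_grid(32)
        empty = T1T2Map(g, g, np.zeros((32, 32)), 1e-2)
        with pytest.raises(ClassificationError):
            classify_map(empty)


class TestGelShift:
    def test_t1_up_t2_flat_flags_rigid_network(self):
        rep = gel_shift_diagnostic(make_map(200.0, 150.0), make_map(600.0, 150.0))
        assert rep.rigid_network_formation
        assert rep.delta_t1_rel == pytest.approx(2.0)
        assert rep.delta_t2_rel == 0.0

    def test_identical_maps_not_flagged(self):
        rep = gel_shift_diagnostic(make_map(200.0, 150.0), make_map(200.0, 150.0))
        assert not rep.rigid_network_formation

    def test_t2_collapse_not_flagged(self):
        rep = gel_shift_diagnostic(make_map(200.0, 150.0), make_map(210.0, 40.0))
        assert not rep.rigid_network_formation

    def test_missing_dominant_peak_rejected(self):
        g = default_grid(32)
        empty = T1T2Map(g, g, np.zeros((32, 32)), 1e-2)
        with pytest.raises(ClassificationError):
            gel_shift_diagnostic(make_map(200.0, 150.0), empty)
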