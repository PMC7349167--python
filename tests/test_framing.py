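import logging

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

from eegstream.framing import (
    FrameMaker,
    IllConditionedError,
    evaluate_rbf,
    fit_rbf,
    make_frame,
    normalize_subject,
)
from eegstream.montage import (
    ElectrodeMontage,
    Placement,
    default_deap_montage,
    place_vector,
)


@pytest.fixture(scope="module")
def deap():
    return default_deap_montage()


def single_node_montage(row=4, col=4, d=9):
    return ElectrodeMontage((Placement(1, row, col),), grid_side=d)


class TestNormalizeSubject:
    def test_zero_mean_unit_std_per_channel(self):
        rng = np.random.default_rng(0)
        trials = [rng.normal(3.0, 2.0, (4, 500)) for _ in range(3)]
        out = normalize_subject(trials)
        pooled = np.concatenate(out, axis=1)
        assert np.abs(pooled.mean(axis=1)).max() < 1e-6
        assert np.abs(pooled.std(axis=1) - 1).max() < 1e-6

    def test_single_channel_example(self):
        out = normalize_subject([np.array([[1.0, 2.0, 3.0]])])[0]
        assert np.isclose(out.mean(), 0)
        assert np.isclose(out.std(), 1)

    def test_constant_channel_zeroed_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="eegstream.framing"):
            out = normalize_subject([np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])])[0]
        assert np.all(out[0] == 0.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_subject([])


class TestFitRbf:
    def test_single_node_weight_equals_value(self):
        m = single_node_montage()
        interp = fit_rbf(place_vector([3.0], m), m, shape_param=1.0)
        assert np.allclose(interp.weights, [3.0])

    def test_exactness_at_nodes_random_inputs(self, deap):
        rng = np.random.default_rng(42)
        coords = deap.grid_coords()
        for _ in range(100):
            v = rng.normal(size=32)
            interp = fit_rbf(place_vector(v, deap), deap, 1.0)
            assert np.abs(interp(coords) - v).max() < 1e-8

    def test_two_equal_nodes_equal_weights(self):
        m = ElectrodeMontage((Placement(1, 0, 0), Placement(2, 0, 2)), grid_side=3)
        interp = fit_rbf(place_vector([2.0, 2.0], m), m, 0.7)
        assert np.isclose(interp.weights[0], interp.weights[1])

    def test_matches_hand_written_solve_small(self):
        """Oracle: brute-force linear solve of the collocation system, <=5 nodes."""
        rng = np.random.default_rng(3)
        m = ElectrodeMontage(
            tuple(Placement(i + 1, r, c) for i, (r, c) in
                  enumerate([(0, 0), (0, 3), (2, 1), (3, 3), (1, 2)])),
            grid_side=4,
        )
        v = rng.normal(size=5)
        eps = 0.8
        coords = m.grid_coords()
        phi = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                r2 = (coords[i, 0] - coords[j, 0]) ** 2 + (coords[i, 1] - coords[j, 1]) ** 2
                phi[i, j] = np.exp(-(eps**2) * r2)
        expected = np.linalg.solve(phi, v)
        interp = fit_rbf(place_vector(v, m), m, eps)
        assert np.abs(interp.weights - expected).max() < 1e-10

    def test_matches_scipy_rbf_interpolator(self, deap):
        """Independent cross-check against scipy's Gaussian RBF machinery."""
        rng = np.random.default_rng(5)
        v = rng.normal(size=32)
        eps = 1.0
        interp = fit_rbf(place_vector(v, deap), deap, eps)
        ref = RBFInterpolator(
            deap.grid_coords(), v, kernel="gaussian", epsilon=eps, degree=-1
        )
        pts = np.column_stack([np.repeat(np.linspace(0, 8, 7), 7),
                               np.tile(np.linspace(0, 8, 7), 7)])
        assert np.abs(interp(pts) - ref(pts)).max() < 1e-6

    def test_ill_conditioned_raises_with_advice(self, deap):
        with pytest.raises(IllConditionedError, match="smaller shape_param or a ridge"):
            fit_rbf(place_vector(np.ones(32), deap), deap, shape_param=1e-4)

    def test_nonpositive_epsilon_rejected(self, deap):
        with pytest.raises(ValueError):
            fit_rbf(place_vector(np.ones(32), deap), deap, shape_param=0.0)


class TestEvaluateRbf:
    def test_single_node_closed_form(self):
        m = single_node_montage(4, 4)
        interp = fit_rbf(place_vector([1.0], m), m, shape_param=1.0)
        # query at distance 1 from the node: phi(1) = e^{-1}
        val = interp(np.array([[4.0, 5.0]]))[0]
        assert np.isclose(val, np.exp(-1.0), atol=1e-12)

    def test_zero_node_gives_zero_field(self):
        m = single_node_montage()
        interp = fit_rbf(place_vector([0.0], m), m, 1.0)
        frame = evaluate_rbf(interp, 16, 16)
        assert np.all(frame == 0)

    def test_query_grid_hits_nodes_on_native_resolution(self, deap):
        rng = np.random.default_rng(7)
        v = rng.normal(size=32)
        interp = fit_rbf(place_vector(v, deap), deap, 1.0)
        native = evaluate_rbf(interp, 9, 9)
        for p in deap.by_channel():
            assert abs(native[p.row, p.col] - v[p.channel - 1]) < 1e-8


class TestMakeFrame:
    def test_output_size_64(self, deap):
        frame = make_frame(np.random.default_rng(0).normal(size=32), deap, out_size=64)
        assert frame.shape == (64, 64)
        assert np.all(np.isfinite(frame))

    def test_two_stage_identity_at_native_size(self, deap):
        v = np.random.default_rng(1).normal(size=32)
        direct = make_frame(v, deap, out_size=9, mode="direct")
        two_stage = make_frame(v, deap, out_size=9, mode="two_stage")
        assert np.allclose(direct, two_stage)

    def test_constant_input_exact_at_electrode_pixels(self, deap):
        # 65 grid points over [0,8] put every integer cell on a query pixel
        frame = make_frame(np.full(32, 1.7), deap, out_size=65, mode="direct")
        for p in deap.by_channel():
            assert abs(frame[p.row * 8, p.col * 8] - 1.7) < 1e-8

    def test_deterministic(self, deap):
        v = np.random.default_rng(2).normal(size=32)
        a = make_frame(v, deap)
        b = make_frame(v, deap)
        assert np.array_equal(a, b)

    def test_out_size_below_grid_rejected(self, deap):
        with pytest.raises(ValueError):
            make_frame(np.zeros(32), deap, out_size=8)


class TestLocality:
    def test_single_node_field_decays_monotonically(self):
        """With one electrode the field is a pure Gaussian: magnitude is
        non-increasing with distance from the node."""
        m = single_node_montage(4, 4)
        interp = fit_rbf(place_vector([1.0], m), m, 1.0)
        dists = np.linspace(0, 5, 50)
        vals = interp(np.column_stack([np.full(50, 4.0), 4.0 + dists]))
        assert np.all(np.diff(np.abs(vals)) <= 1e-12)

    def test_single_active_electrode_peak_is_local(self, deap):
        """With one active electrode among 32 (others zero), the frame's
        global magnitude peak lies within one inter-electrode spacing of that
        electrode's cell.  (Strict monotone decay cannot hold: the surface is
        pinned to zero at the 31 other electrodes, which creates side lobes.)"""
        rr, cc = np.meshgrid(np.linspace(0, 8, 64), np.linspace(0, 8, 64),
                             indexing="ij")
        for ch in (1, 7, 16, 32):
            v = np.zeros(32)
            v[ch - 1] = 1.0
            frame = make_frame(v, deap, out_size=64)
            p = next(q for q in deap.by_channel() if q.channel == ch)
            i, j = np.unravel_index(np.abs(frame).argmax(), frame.shape)
            dist = np.hypot(rr[i, j] - p.row, cc[i, j] - p.col)
            assert dist <= 1.0, (ch, dist)


class TestFrameMaker:
    def test_matches_make_frame_both_modes(self, deap):
        rng = np.random.default_rng(9)
        seg = rng.normal(size=(32, 5))
        for mode in ("direct", "two_stage"):
            fm = FrameMaker(deap, 1.0, 16, mode)
            batch = fm.frames(seg)
            assert batch.shape == (5, 16, 16)
            for k in range(5):
                ref = make_frame(seg[:, k], deap, 1.0, 16, mode)
                assert np.abs(batch[k] - ref).max() < 1e-9

    def test_wrong_channel_count_rejected(self, deap):
        fm = FrameMaker(deap, 1.0, 16)
        with pytest.raises(ValueError):
            fm.frames(np.zeros((31, 4)))
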