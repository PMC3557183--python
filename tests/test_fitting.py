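import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import lsq_linear

import actipet as ap
from actipet.decay_model import frame_basis
from actipet.fitting import (
    FitConstraints,
    FixedHalfLifeFitter,
    FreeHalfLifeFitter,
    grid_search_oracle,
)


def _tac(schedule, values):
    return ap.TimeActivityCurve(schedule.frame_bounds, tuple(values))


class TestFixedFit:
    def test_recovers_voi1_fractions_exactly(self, voi1_tac):
        res = ap.fit_fixed(voi1_tac)
        assert res.normalized_fractions == pytest.approx(
            (0.32, 0.65, 0.03), abs=1e-9
        )
        assert res.constant == pytest.approx(0.0, abs=1e-12)
        assert res.sse == pytest.approx(0.0, abs=1e-20)
        assert res.labels == ("C11", "O15", "N13")

    def test_all_zero_tac_gives_zero_solution(self, schedule):
        res = ap.fit_fixed(_tac(schedule, np.zeros(15)))
        assert np.all(res.amplitudes == 0)
        assert res.constant == 0
        assert res.sse == 0
        assert res.normalized_fractions is None

    def test_pure_constant_tac_recovered_by_constant_term(self, schedule):
        res = ap.fit_fixed(_tac(schedule, np.full(15, 0.42)))
        assert res.constant == pytest.approx(0.42, abs=1e-10)
        assert np.all(res.amplitudes < 1e-10)

    def test_too_few_frames_rejected(self):
        sched = ap.default_schedule(n_frames=4)
        with pytest.raises(ValueError, match="at least"):
            ap.fit_fixed(_tac(sched, np.ones(4)))

    def test_matches_independent_bounded_linear_solver(self, schedule, voi1_tac):
        """NNLS route agrees with scipy's bounded linear LS to 1e-10."""
        rng = np.random.default_rng(11)
        noisy = np.clip(
            voi1_tac.values_array + rng.normal(0, 0.01, 15), 0, None
        )
        res = ap.fit_fixed(_tac(schedule, noisy))
        A = np.column_stack(
            [frame_basis((20.39, 2.04, 9.97), schedule.bounds_array), np.ones(15)]
        )
        ref = lsq_linear(A, noisy, bounds=(0, np.inf), tol=1e-14)
        assert np.concatenate([res.amplitudes, [res.constant]]) == pytest.approx(
            ref.x, abs=1e-10
        )

    @given(scale=st.floats(1e-3, 1e3))
    def test_scaling_invariance(self, schedule, voi1_tac, scale):
        """Rescaling the TAC scales amplitudes, not normalized fractions."""
        base = ap.fit_fixed(voi1_tac)
        scaled = ap.fit_fixed(_tac(schedule, voi1_tac.values_array * scale))
        assert scaled.amplitudes == pytest.approx(
            base.amplitudes * scale, rel=1e-8
        )
        assert scaled.normalized_fractions == pytest.approx(
            base.normalized_fractions, abs=1e-10
        )

    def test_optimum_dominates_random_feasible_points(self, schedule):
        rng = np.random.default_rng(4)
        y = np.clip(
            ap.predicted_tac(
                ap.MultiExpModel(
                    (ap.DecayComponent(0.5, 20.39), ap.DecayComponent(0.5, 2.04))
                ),
                schedule,
            ).values_array
            + rng.normal(0, 0.02, 15),
            0,
            None,
        )
        res = ap.fit_fixed(_tac(schedule, y))
        A = np.column_stack(
            [frame_basis((20.39, 2.04, 9.97), schedule.bounds_array), np.ones(15)]
        )
        for _ in range(50):
            theta = rng.uniform(0, 1, size=4)
            sse = float(np.sum((y - A @ theta) ** 2))
            assert res.sse <= sse + 1e-12


class TestFreeFit:
    def test_recovers_two_component_half_lives(self, voi2_tac):
        res = ap.fit_free(voi2_tac)
        ident = np.array(res.identified)
        assert ident.sum() == 2
        hls = res.half_lives[ident]
        assert sorted(hls) == pytest.approx([2.04, 20.39], rel=1e-5)
        assert res.amplitudes[ident] == pytest.approx([0.08, 0.92], rel=1e-5)
        # components sorted by descending half-life
        assert np.all(np.diff(res.half_lives) <= 0)

    def test_recovers_single_exponential(self, schedule):
        m = ap.MultiExpModel((ap.DecayComponent(1.0, 5.0),))
        res = ap.fit_free(ap.predicted_tac(m, schedule))
        ident = np.array(res.identified)
        assert ident.sum() == 1
        assert res.half_lives[ident][0] == pytest.approx(5.0, rel=1e-5)
        assert res.amplitudes[ident][0] == pytest.approx(1.0, rel=1e-5)

    def test_all_zero_tac(self, schedule):
        res = ap.fit_free(_tac(schedule, np.zeros(15)))
        assert np.all(res.amplitudes == 0)
        assert res.constant == 0

    @pytest.mark.parametrize(
        "amps, hls",
        [((0.4, 0.4, 0.2), (18.0, 2.5, 8.0)), ((1.0, 2.0, 0.5), (25.0, 1.5, 6.0))],
    )
    def test_noiseless_identifiability(self, schedule, amps, hls):
        """Distinct half-lives and positive amplitudes are recovered from
        noiseless 15-frame data."""
        m = ap.MultiExpModel(
            tuple(ap.DecayComponent(a, t) for a, t in zip(amps, hls))
        )
        tac = ap.predicted_tac(m, schedule)
        res = ap.fit_free(tac)
        scale = float(np.sum(np.square(tac.values_array)))
        assert res.sse / scale < 1e-12
        order = np.argsort(-np.asarray(hls))
        assert res.half_lives == pytest.approx(
            np.asarray(hls)[order], rel=1e-4
        )
        assert res.amplitudes == pytest.approx(np.asarray(amps)[order], rel=1e-4)

    def test_too_few_frames_rejected(self):
        sched = ap.default_schedule(n_frames=6)
        with pytest.raises(ValueError, match="at least"):
            ap.fit_free(_tac(sched, np.ones(6)))

    def test_deterministic_across_runs(self, voi2_tac):
        a = ap.fit_free(voi2_tac)
        b = ap.fit_free(voi2_tac)
        assert np.array_equal(a.half_lives, b.half_lives)
        assert np.array_equal(a.amplitudes, b.amplitudes)


class TestNormalizeAmplitudes:
    def test_simple_normalization(self, voi1_tac):
        res = ap.fit_fixed(voi1_tac)
        res.amplitudes = np.array([2.0, 2.0, 0.0])
        res = ap.normalize_amplitudes(res)
        assert res.normalized_fractions == pytest.approx((0.5, 0.5, 0.0))

    def test_already_normalized_unchanged(self, voi1_tac):
        res = ap.fit_fixed(voi1_tac)
        res.amplitudes = np.array([0.08, 0.92, 0.0])
        res = ap.normalize_amplitudes(res)
        assert res.normalized_fractions == pytest.approx((0.08, 0.92, 0.0))

    def test_zero_sum_flagged_undefined(self, voi1_tac):
        res = ap.fit_fixed(voi1_tac)
        res.amplitudes = np.zeros(3)
        res = ap.normalize_amplitudes(res)
        assert res.normalized_fractions is None
        assert not res.fractions_defined


class TestConfidenceIntervals:
    def test_noiseless_linearized_ci_collapses(self, voi1_tac):
        res = ap.confidence_intervals(ap.fit_fixed(voi1_tac), voi1_tac)
        widths = res.ci95["amplitudes"][:, 1] - res.ci95["amplitudes"][:, 0]
        assert np.all(widths < 1e-8)

    def test_bootstrap_is_seed_reproducible(self, schedule):
        spec = ap.SimulationSpec(
            tissue="adipose_adult2", noise="poisson", seed=3, amplitude_scale=1e4
        )
        tac = ap.simulate_tac(spec)
        kw = dict(method="bootstrap", n_boot=40, seed=17)
        a = ap.confidence_intervals(ap.fit_fixed(tac), tac, **kw)
        b = ap.confidence_intervals(ap.fit_fixed(tac), tac, **kw)
        for key in a.ci95:
            assert np.allclose(a.ci95[key], b.ci95[key], equal_nan=True)

    def test_bootstrap_requires_seed(self, voi1_tac):
        with pytest.raises(ValueError, match="seed"):
            ap.confidence_intervals(
                ap.fit_fixed(voi1_tac), voi1_tac, method="bootstrap"
            )

    def test_free_mode_ci_covers_half_lives(self, voi2_tac, schedule):
        """Half-life CIs of an identified noisy free fit bracket the truth."""
        rng = np.random.default_rng(8)
        y = np.clip(
            voi2_tac.values_array * (1 + rng.normal(0, 0.005, 15)), 0, None
        )
        tac = ap.TimeActivityCurve(schedule.frame_bounds, tuple(y))
        res = ap.confidence_intervals(ap.fit_free(tac), tac, method="linearized")
        hl_ci = res.ci95["half_lives"]
        ident = np.array(res.identified)
        slow = np.flatnonzero(ident)[0]
        fast = np.flatnonzero(ident)[-1]
        assert hl_ci[slow][0] <= 20.39 <= hl_ci[slow][1]
        assert hl_ci[fast][0] <= 2.04 <= hl_ci[fast][1]


class TestGridSearchOracle:
    def test_oracle_finds_truth_on_grid(self, schedule):
        m = ap.MultiExpModel((ap.DecayComponent(1.0, 4.0),))
        tac = ap.predicted_tac(m, schedule)
        best = grid_search_oracle(
            tac, half_life_grid=(1.0, 2.0, 4.0, 8.0, 16.0), n_components=1
        )
        assert best["sse"] == pytest.approx(0.0, abs=1e-20)
        assert best["half_lives"][0] == 4.0

    def test_fit_free_dominates_oracle(self, voi2_tac):
        res = ap.fit_free(voi2_tac)
        best = grid_search_oracle(
            voi2_tac, half_life_grid=np.geomspace(0.5, 30, 10), n_components=3
        )
        assert res.sse <= best["sse"] + 1e-9

    def test_oversized_grid_refused_with_estimate(self, voi2_tac):
        with pytest.raises(ValueError, match="combinations"):
            grid_search_oracle(
                voi2_tac,
                half_life_grid=np.linspace(0.5, 30, 400),
                n_components=3,
                max_evaluations=1000,
            )


class TestSklearnInterface:
    def test_get_set_params_roundtrip(self):
        est = FreeHalfLifeFitter(n_components=2)
        params = est.get_params()
        assert params["n_components"] == 2
        est.set_params(half_life_min=0.2)
        assert est.half_life_min == 0.2

    def test_predict_reproduces_noiseless_input(self, voi1_tac):
        X = voi1_tac.bounds_array
        est = FixedHalfLifeFitter().fit(X, voi1_tac.values_array)
        assert np.allclose(est.predict(X), voi1_tac.values_array, atol=1e-12)
        assert est.score(X, voi1_tac.values_array) == pytest.approx(1.0)

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            FixedHalfLifeFitter().predict([[0.0, 2.0]])


def test_constraints_validation():
    with pytest.raises(ValueError, match="mode"):
        FitConstraints(mode="wild")
    with pytest.raises(ValueError, match="half-lives"):
        FitConstraints(mode="fixed", fixed_half_lives=(1.0, 2.0))
    with pytest.raises(ValueError, match="positive"):
        FitConstraints(mode="free", half_life_lower_bound=0.0)
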