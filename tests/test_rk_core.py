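"""Embedded Runge-Kutta engine: tableau validation, stepping, adaptivity."""

import json
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinetrial.errors import IntegrationError, NonConvergenceError, TableauStructureError
from kinetrial.rk_core import (
    ButcherTableau,
    IntegratorConfig,
    dormand_prince_54,
    integrate_adaptive,
    integrate_fixed,
    load_tableau,
    rk_step,
    validate_tableau,
)


class TestTableauValidation:
    def test_default_tableau_exact_rational_pass(self):
        """The shipped pair satisfies every invariant under exact arithmetic."""
        tb = dormand_prince_54()
        assert validate_tableau(tb) == []
        # independent rational-arithmetic oracle for the order-5 weight sum
        assert sum(
            [Fraction(35, 384), Fraction(0), Fraction(500, 1113), Fraction(125, 192),
             Fraction(-2187, 6784), Fraction(11, 84), Fraction(0)]
        ) == 1

    def test_scaled_weights_flagged_with_residual(self):
        tb = dormand_prince_54()
        bad = ButcherTableau(
            "bad", tb.stages, tb.c, tb.a,
            tuple(b / 2 for b in tb.b_high), tb.b_low, tb.p, tb.p_hat,
        )
        violations = validate_tableau(bad)
        codes = {v.code for v in violations}
        assert "sum_b_high" in codes
        (v,) = [v for v in violations if v.code == "sum_b_high"]
        assert math.isclose(v.residual, 0.5)

    def test_identical_weight_rows_degenerate(self):
        """A pair printed with b == b* has a zero error estimate: flagged."""
        tb = dormand_prince_54()
        degenerate = ButcherTableau(
            "printed", tb.stages, tb.c, tb.a, tb.b_high, tb.b_high, 6, 5
        )
        codes = {v.code for v in validate_tableau(degenerate)}
        assert "degenerate_embedded" in codes

    def test_equal_orders_rejected(self):
        tb = dormand_prince_54()
        same_order = ButcherTableau("p=p", tb.stages, tb.c, tb.a, tb.b_high, tb.b_low, 5, 5)
        assert "orders" in {v.code for v in validate_tableau(same_order)}

    def test_non_explicit_entry_located(self):
        tb = dormand_prince_54()
        a = [list(row) for row in tb.a]
        a[2][4] = Fraction(1, 10)
        bad = ButcherTableau("implicit", tb.stages, tb.c,
                             tuple(tuple(r) for r in a), tb.b_high, tb.b_low, 5, 4)
        (v,) = [v for v in validate_tableau(bad) if v.code == "not_explicit"]
        assert v.stage == 2

    def test_malformed_shape_is_structural_error(self):
        tb = dormand_prince_54()
        with pytest.raises(TableauStructureError):
            ButcherTableau("short", tb.stages, tb.c[:-1], tb.a, tb.b_high, tb.b_low, 5, 4)

    def test_json_round_trip_with_rational_strings(self, tmp_path):
        obj = {
            "name": "midpoint-euler 2(1)", "stages": 2,
            "c": ["0", "1/2"], "a": [[], ["1/2"]],
            "b_high": ["0", "1"], "b_low": ["1", "0"],
            "order_high": 2, "order_low": 1,
        }
        path = tmp_path / "tb.json"
        path.write_text(json.dumps(obj))
        tb = load_tableau(path)
        assert validate_tableau(tb) == []
        assert tb.b_high[1] == Fraction(1)

    def test_malformed_file_raises(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"stages": 2, "c": [0, 0.5]}))
        with pytest.raises(TableauStructureError):
            load_tableau(path)


class TestRkStep:
    def test_zero_dynamics(self):
        yh, yl, err = rk_step(lambda t, y: 0 * y, 0.0, np.array([3.0, -1.0]), 0.7,
                              dormand_prince_54())
        assert np.allclose(yh, [3.0, -1.0]) and np.allclose(yl, yh) and err == 0.0

    def test_constant_derivative_exact(self):
        yh, _, _ = rk_step(lambda t, y: np.ones_like(y), 0.0, np.array([0.0]), 0.5,
                           dormand_prince_54())
        assert yh[0] == pytest.approx(0.5, abs=1e-15)

    def test_exponential_decay_accuracy(self):
        yh, _, _ = rk_step(lambda t, y: -y, 0.0, np.array([1.0]), 0.1, dormand_prince_54())
        assert abs(yh[0] - math.exp(-0.1)) <= 1e-8

    def test_non_finite_stage_reported(self):
        def f(t, y):
            with np.errstate(divide="ignore", invalid="ignore"):
                return y / t  # 1/0 at the first stage

        with pytest.raises(IntegrationError) as exc:
            rk_step(f, 0.0, np.array([1.0]), 0.1, dormand_prince_54())
        assert exc.value.stage == 0


class TestAdaptiveIntegration:
    def test_exponential_oracle(self):
        cfg = IntegratorConfig(rtol=1e-8, atol=1e-12)
        path = integrate_adaptive(lambda t, y: -y, 0.0, 1.0, [1.0], config=cfg)
        assert abs(path.states[-1, 0] - math.exp(-1)) <= 1e-7
        assert path.times[0] == 0.0 and path.times[-1] == 1.0

    def test_constant_solution_no_rejections(self):
        path = integrate_adaptive(lambda t, y: 0 * y, 0.0, 5.0, [7.0])
        assert np.all(path.states == 7.0)
        assert path.rejected_steps == 0

    def test_forced_linear_ode_closed_form(self):
        """dV/dt = k1*I - k2*V with I=1: V(10) = 2.5 * (1 - e^(-0.2))."""
        cfg = IntegratorConfig(rtol=1e-10, atol=1e-12)
        path = integrate_adaptive(lambda t, y: 0.05 - 0.02 * y, 0.0, 10.0, [0.0], config=cfg)
        assert path.states[-1, 0] == pytest.approx(2.5 * (1 - math.exp(-0.2)), abs=1e-6)

    @given(alpha=st.floats(-1.0, -0.01), beta=st.floats(-1.0, 1.0), y0=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_ode_matches_closed_form(self, alpha, beta, y0):
        """y' = a*y + b agrees with the analytic solution to 1e-6 relative."""
        cfg = IntegratorConfig(rtol=1e-8, atol=1e-12)
        path = integrate_adaptive(lambda t, y: alpha * y + beta, 0.0, 12.0, [y0], config=cfg)
        y_star = -beta / alpha
        exact = y_star + (y0 - y_star) * math.exp(alpha * 12.0)
        assert abs(path.states[-1, 0] - exact) <= 1e-6 * max(1.0, abs(exact))

    def test_tighter_rtol_never_worse(self):
        errs = []
        for rtol in (1e-4, 1e-5, 1e-6, 1e-7, 1e-8):
            cfg = IntegratorConfig(rtol=rtol, atol=1e-14)
            path = integrate_adaptive(lambda t, y: -y, 0.0, 1.0, [1.0], config=cfg)
            errs.append(abs(path.states[-1, 0] - math.exp(-1)))
            assert np.isfinite(path.accepted_steps + path.rejected_steps)
        assert all(e2 <= e1 * 1.001 for e1, e2 in zip(errs, errs[1:]))

    def test_dense_output_hits_requested_times(self):
        weeks = [1.0, 2.0, 3.0, 4.0]
        path = integrate_adaptive(lambda t, y: -0.5 * y, 0.0, 4.0, [1.0], t_eval=weeks)
        for w in weeks:
            assert abs(path.state_at(w)[0] - math.exp(-0.5 * w)) < 1e-5

    def test_max_steps_reported(self):
        cfg = IntegratorConfig(max_steps=3, h_init=1e-4, h_max=1e-4, h_min=1e-5)
        with pytest.raises(NonConvergenceError) as exc:
            integrate_adaptive(lambda t, y: -y, 0.0, 10.0, [1.0], config=cfg)
        assert exc.value.t_reached is not None


class TestFixedStepIntegration:
    def test_order_five_convergence(self):
        """Global error on y' = -y halves as h^5: log2 ratio within 5 +/- 0.2."""
        def err(n):
            path = integrate_fixed(lambda t, y: -y, 0.0, 1.0, [1.0], n_steps=n)
            return abs(path.states[-1, 0] - math.exp(-1))

        ratios = [err(n) / err(2 * n) for n in (16, 32)]
        for r in ratios:
            assert 5 - 0.2 <= math.log2(r) <= 5 + 0.2

    def test_single_step_equals_rk_step(self):
        f = lambda t, y: -2.0 * y + 1.0
        path = integrate_fixed(f, 0.0, 0.3, [1.5], n_steps=1)
        yh, _, _ = rk_step(f, 0.0, np.array([1.5]), 0.3, dormand_prince_54())
        assert np.array_equal(path.states[-1], yh)

    def test_fixed_matches_adaptive(self):
        f = lambda t, y: -0.3 * y + 0.1
        fixed = integrate_fixed(f, 0.0, 12.0, [2.0], n_steps=1000)
        adaptive = integrate_adaptive(
            f, 0.0, 12.0, [2.0], config=IntegratorConfig(rtol=1e-10, atol=1e-12)
        )
        assert fixed.states[-1, 0] == pytest.approx(adaptive.states[-1, 0], abs=1e-8)
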