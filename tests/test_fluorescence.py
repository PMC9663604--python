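import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoresponse.curve_core import DomainError
from photoresponse.fitting import FitConfig
from photoresponse.fluorescence import (
    EPParameters,
    FluorTrace,
    TraceStep,
    ep_cardinals,
    ep_predict,
    etr_from_yield,
    fit_ep,
    fvfm_scaled,
    partition_from_trace,
)

R1 = EPParameters(a=-0.000006637, b=0.06827, c=11.5297)


def rlc_pairs(rlc_table, repeat):
    sub = rlc_table[rlc_table["repeat"] == repeat]
    return list(zip(sub["par"].astype(float), sub["etr"].astype(float)))


class TestEtrFromYield:
    def test_slow_kinetics_repeat1(self):
        assert etr_from_yield(198, 0.124) == pytest.approx(10.3, abs=0.05)

    def test_rlc_repeat1_par31(self):
        assert etr_from_yield(31, 0.184) == pytest.approx(2.4, abs=0.05)

    def test_zero_yield(self):
        assert etr_from_yield(500.0, 0.0) == 0.0

    def test_factors_exposed(self):
        assert etr_from_yield(100, 0.5, absorptance=1.0, psii_fraction=1.0) == 50.0

    @given(
        par=st.floats(0, 5000),
        y=st.floats(0, 1),
        k=st.floats(0.1, 5.0),
    )
    def test_linear_in_par_and_yield(self, par, y, k):
        base = etr_from_yield(par, y)
        assert etr_from_yield(par * k, y) == pytest.approx(base * k, rel=1e-12, abs=1e-12)
        if y * k <= 1:
            assert etr_from_yield(par, y * k) == pytest.approx(
                base * k, rel=1e-12, abs=1e-12
            )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            etr_from_yield(-1.0, 0.5)
        with pytest.raises(ValueError):
            etr_from_yield(10.0, 1.5)


class TestEpPredict:
    def test_repeat1_par31(self):
        assert ep_predict(R1, 31) == pytest.approx(2.273, abs=5e-4)

    def test_repeat1_par4292(self):
        # exact evaluation of the printed parameters gives 23.5459; the
        # printed fitted value 23.547 carries the table's own rounding
        assert ep_predict(R1, 4292) == pytest.approx(23.547, abs=2e-3)

    def test_zero_at_zero_par(self):
        assert ep_predict(R1, 0.0) == 0.0

    def test_vectorized(self):
        out = ep_predict(R1, [0.0, 31.0, 4292.0])
        assert out.shape == (3,)

    def test_nonpositive_denominator(self):
        p = EPParameters(a=-1e-4, b=0.0, c=1.0)
        with pytest.raises(DomainError, match="PAR"):
            ep_predict(p, 200.0)

    def test_initial_slope_is_inverse_c(self):
        h = 1e-6
        slope = ep_predict(R1, h) / h
        assert slope == pytest.approx(1.0 / R1.c, rel=1e-5)


class TestFitEP:
    def test_repeat1_r_squared(self, rlc_table, fit_config):
        fit = fit_ep(rlc_pairs(rlc_table, 1), fit_config)
        assert fit.r_squared >= 0.99

    def test_repeat3_r_squared(self, rlc_table, fit_config):
        fit = fit_ep(rlc_pairs(rlc_table, 3), fit_config)
        assert fit.r_squared >= 0.95

    def test_zero_noise_recovery(self):
        par = [0, 6, 31, 101, 198, 363, 619, 981, 1386, 2015, 2970, 3588, 4292]
        pts = [(p, ep_predict(R1, float(p))) for p in par]
        fit = fit_ep(pts)
        assert fit.params.a == pytest.approx(R1.a, rel=5e-4)
        assert fit.params.b == pytest.approx(R1.b, rel=5e-4)
        assert fit.params.c == pytest.approx(R1.c, rel=5e-4)

    def test_refit_dominates_printed_parameters(self, rlc_table, table6):
        for ref in table6["repeats"]:
            pairs = rlc_pairs(rlc_table, ref["repeat"])
            par = np.array([p for p, _ in pairs])
            etr = np.array([v for _, v in pairs])
            printed = EPParameters(a=ref["a"], b=ref["b"], c=ref["c"])
            printed_sse = float(np.sum((np.asarray(ep_predict(printed, par)) - etr) ** 2))
            fit = fit_ep(pairs)
            assert fit.residual_sum_of_squares <= printed_sse + 1e-9

    def test_deterministic(self, rlc_table):
        cfg = FitConfig(seed=7)
        a = fit_ep(rlc_pairs(rlc_table, 2), cfg)
        b = fit_ep(rlc_pairs(rlc_table, 2), cfg)
        assert (a.params.a, a.params.b, a.params.c) == (b.params.a, b.params.b, b.params.c)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="4 points"):
            fit_ep([(0, 0), (10, 1), (20, 2)])


class TestEpCardinals:
    def test_symmetric_closed_form(self):
        d = ep_cardinals(EPParameters(a=1.0, b=2.0, c=1.0), (0.0, 10.0))
        assert d.alpha == 1.0
        assert d.etr_max == pytest.approx(0.25)
        assert d.i_k == pytest.approx(0.25)
        assert d.saturating_fit

    def test_identity_ik_alpha_etrmax(self):
        d = ep_cardinals(EPParameters(a=2e-6, b=0.05, c=12.0), (0.0, 5000.0))
        assert d.i_k * d.alpha == pytest.approx(d.etr_max, rel=1e-12)

    def test_closed_form_matches_grid_argmax(self):
        p = EPParameters(a=2e-6, b=0.05, c=12.0)
        d = ep_cardinals(p, (0.0, 20000.0))
        grid = np.linspace(0.0, 20000.0, 200001)
        grid_max = float(np.max(ep_predict(p, grid)))
        assert d.etr_max == pytest.approx(grid_max, rel=1e-3)

    def test_nonsaturating_falls_back_to_domain_max(self):
        # frozen grid-argmax oracle: the repeat-1 curve is monotone on
        # [0, 4292], so its maximum sits at the right edge, 23.5459
        with pytest.warns(UserWarning, match="no interior"):
            d = ep_cardinals(R1, (0.0, 4292.0))
        assert not d.saturating_fit
        assert d.etr_max == pytest.approx(23.545855418736043, rel=1e-6)
        assert d.i_k * d.alpha == pytest.approx(d.etr_max, rel=1e-12)

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ep_cardinals(R1, (10.0, 10.0))

    def test_fvfm_passthrough(self):
        with pytest.warns(UserWarning):
            d = ep_cardinals(R1, (0.0, 100.0), fvfm=0.5383)
        assert d.fvfm_etr_half == pytest.approx(0.226, abs=5e-4)


def build_trace(dark_fvfm, ladder):
    """ladder: list of (par, y_ii, npq)."""
    fm = 1.0
    fo = fm * (1.0 - dark_fvfm)
    steps = []
    for par, y_ii, npq in ladder:
        fm_prime = fm / (1.0 + npq)
        f_s = fm_prime * (1.0 - y_ii)
        fo_prime = fo / ((1.0 - fo / fm) + fo / fm_prime)
        steps.append(TraceStep(par=par, f_s=f_s, fm_prime=fm_prime, fo_prime=fo_prime))
    return FluorTrace(fo=fo, fm=fm, steps=steps)


class TestPartitionFromTrace:
    def test_dark_reference_step(self):
        trace = FluorTrace(
            fo=0.4, fm=1.0, steps=[TraceStep(par=0.0, f_s=0.4, fm_prime=1.0, fo_prime=0.4)]
        )
        (pt,) = partition_from_trace(trace)
        assert pt.y_ii == pytest.approx(0.6)
        assert pt.npq == 0.0
        assert pt.q_p == pytest.approx(1.0)
        assert pt.q_l == pytest.approx(1.0)
        assert pt.q_n == pytest.approx(0.0)
        assert pt.etr == 0.0

    def test_exact_yield_closure(self):
        trace = build_trace(0.573, [(6.0, 0.36, 0.701), (198.0, 0.098, 2.027)])
        for pt in partition_from_trace(trace):
            assert pt.yield_closure == pytest.approx(1.0, abs=1e-12)

    def test_forward_construct_invert_oracle(self):
        """Trace built to hit Y(II)=0.36, NPQ=0.701 at PAR=6; the partition
        must recover the construction and the independent hand computation
        of the five quenching formulas."""
        trace = build_trace(0.573, [(6.0, 0.36, 0.701)])
        (pt,) = partition_from_trace(trace)
        assert pt.y_ii == pytest.approx(0.36, abs=1e-12)
        assert pt.npq == pytest.approx(0.701, abs=1e-12)
        # independent recomputation from the raw levels
        s = trace.steps[0]
        fm, fo = trace.fm, trace.fo
        q_p = (s.fm_prime - s.f_s) / (s.fm_prime - s.fo_prime)
        q_l = q_p * s.fo_prime / s.f_s
        y_no = 1.0 / (0.701 + 1.0 + q_l * (fm / fo - 1.0))
        assert pt.q_p == pytest.approx(q_p, rel=1e-12)
        assert pt.q_l == pytest.approx(q_l, rel=1e-12)
        assert pt.y_no == pytest.approx(y_no, rel=1e-12)
        assert pt.y_npq == pytest.approx(1.0 - 0.36 - y_no, rel=1e-12)
        assert pt.etr == pytest.approx(6.0 * 0.36 * 0.42, rel=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        dark=st.floats(0.3, 0.8),
        y=st.floats(0.01, 0.5),
        npq=st.floats(0.0, 3.0),
    )
    def test_closure_and_ql_le_qp_property(self, dark, y, npq):
        trace = build_trace(dark, [(100.0, y, npq)])
        (pt,) = partition_from_trace(trace)
        assert pt.yield_closure == pytest.approx(1.0, abs=1e-12)
        s = trace.steps[0]
        if s.f_s >= s.fo_prime:
            assert pt.q_l <= pt.q_p + 1e-12

    def test_step_level_domain_error(self):
        trace = FluorTrace(
            fo=0.4, fm=1.0,
            steps=[TraceStep(par=10.0, f_s=0.3, fm_prime=0.35, fo_prime=0.38)],
        )
        with pytest.raises(DomainError, match="step 0"):
            partition_from_trace(trace)

    def test_trace_invariants(self):
        with pytest.raises(ValueError):
            FluorTrace(fo=1.0, fm=0.5, steps=[])
        with pytest.raises(ValueError, match="Fm >= Fm'"):
            FluorTrace(
                fo=0.4, fm=1.0,
                steps=[TraceStep(par=0, f_s=0.5, fm_prime=1.2, fo_prime=0.3)],
            )


class TestFvFmScaled:
    def test_repeat3(self):
        fm = 1.0
        fo = fm * (1.0 - 0.5383)
        assert fvfm_scaled(fo, fm) == pytest.approx(0.226, abs=5e-4)

    def test_repeat2(self):
        fm = 2.0
        fo = fm * (1.0 - 0.5616)
        assert fvfm_scaled(fo, fm) == pytest.approx(0.236, abs=5e-4)

    def test_fo_equal_fm_rejected(self):
        with pytest.raises(DomainError):
            fvfm_scaled(1.0, 1.0)

    def test_fo_to_zero_limit(self):
        assert fvfm_scaled(1e-12, 1.0) == pytest.approx(0.42, rel=1e-9)
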