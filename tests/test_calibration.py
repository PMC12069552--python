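import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from scncomplex.calibration import (
    COMPLEX_LABELS,
    RateCalibrator,
    RateConstants,
    RateSet,
    WT_AFFINITIES,
    calibrate_all,
    closed_form_bound_fraction,
    dimer_rhs,
    scan_rates,
    scan_rates_exhaustive,
    select_rate,
    steady_state_bound_fraction,
)

GOLDEN = (3.0 - math.sqrt(5.0)) / 2.0  # bound fraction at a = d, D0 = A0 = 1


@pytest.mark.parametrize(
    "state, rates, expected_ddA",
    [
        ((1.0, 1.0, 0.0), (0.1, 0.1), 0.1),
        ((0.5, 0.5, 0.25), (0.2, 0.2), 0.2 * 0.25 - 0.2 * 0.25),  # equilibrium
        ((1.0, 1.0, 0.3), (0.0, 0.2), -0.06),  # a = 0: pure dissociation
    ],
)
def test_dimer_rhs_direct_substitution(state, rates, expected_ddA):
    dD, dA, dDA = dimer_rhs(0.0, state, *rates)
    assert dDA == pytest.approx(expected_ddA, abs=1e-15)
    # donor and acceptor lose exactly what the complex gains
    assert dD == pytest.approx(-dDA, abs=1e-15)
    assert dA == pytest.approx(-dDA, abs=1e-15)


def test_closed_form_equal_rates_golden_ratio():
    assert closed_form_bound_fraction(0.1, 0.1) == pytest.approx(GOLDEN, abs=1e-12)
    assert closed_form_bound_fraction(0.4, 0.4) == pytest.approx(GOLDEN, abs=1e-12)


def test_closed_form_limits():
    assert closed_form_bound_fraction(0.0, 0.3) == 0.0
    assert closed_form_bound_fraction(0.3, 0.0) == pytest.approx(1.0)


def test_integrated_steady_state_matches_quadratic_root():
    rng = np.random.default_rng(7)
    for _ in range(10):
        a, d = rng.uniform(1e-3, 0.5, size=2)
        ode = steady_state_bound_fraction(RateConstants(a, d))
        exact = closed_form_bound_fraction(a, d)
        assert abs(ode - exact) < 1e-7


def test_steady_state_degenerate_rates():
    assert steady_state_bound_fraction(RateConstants(0.0, 0.2)) == 0.0
    assert steady_state_bound_fraction(RateConstants(0.2, 0.0)) == pytest.approx(
        1.0, abs=1e-6
    )


def test_dimer_conservation_along_trajectory():
    a, d = 0.3, 0.1
    sol = solve_ivp(
        dimer_rhs,
        (0.0, 200.0),
        [1.0, 1.0, 0.0],
        args=(a, d),
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
    )
    t = np.linspace(0, 200, 50)
    y = sol.sol(t)
    d_total = y[0] + y[2]
    a_total = y[1] + y[2]
    assert np.max(np.abs(d_total - 1.0)) < 1e-9
    assert np.max(np.abs(a_total - 1.0)) < 1e-9


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    a=st.floats(1e-3, 0.5),
    d=st.floats(1e-3, 0.5),
    bump=st.floats(1e-3, 0.2),
)
def test_bound_fraction_monotone_in_rates(a, d, bump):
    base = closed_form_bound_fraction(a, d)
    assert closed_form_bound_fraction(a + bump, d) > base
    assert closed_form_bound_fraction(a, d + bump) < base


class TestScan:
    def test_accepted_pairs_lie_on_ratio_line(self):
        b = 0.28
        scan = scan_rates(b, "BRAVOPLT3")
        assert scan.n_accepted > 0
        ratio = (1 - b) ** 2 / b  # d/a for target 0.28 -> about 1.8514
        for p in scan.pairs:
            assert p.d / p.a == pytest.approx(ratio, abs=2e-3)
        assert ratio == pytest.approx(1.8514, abs=1e-3)

    def test_accepted_fractions_within_tolerance(self):
        scan = scan_rates(0.306, "WOX5PLT3")
        for frac in scan.bound_fractions:
            assert abs(frac - 0.306) <= 1e-5

    def test_scan_matches_exhaustive_subrange(self):
        # brute-force a small block around a known accepted pair
        b = 0.28
        scan = scan_rates(b)
        p = scan.pairs[0]
        a_vals = p.a + 0.0002 * np.arange(-2, 3)
        d_vals = p.d + 0.0002 * np.arange(-2, 3)
        brute = scan_rates_exhaustive(b, a_vals, d_vals)
        in_block = {
            (round(q.a, 6), round(q.d, 6))
            for q in scan.pairs
            if a_vals.min() - 1e-9 <= q.a <= a_vals.max() + 1e-9
            and d_vals.min() - 1e-9 <= q.d <= d_vals.max() + 1e-9
        }
        brute_set = {(round(q.a, 6), round(q.d, 6)) for q in brute.pairs}
        assert brute_set == in_block

    def test_zero_affinity_accepts_only_zero_association(self):
        scan = scan_rates(0.0)
        assert scan.n_accepted > 0
        assert all(p.a == 0.0 and p.d > 0.0 for p in scan.pairs)

    def test_higher_affinity_has_larger_association_ratio(self):
        lo = scan_rates(0.224)
        hi = scan_rates(0.306)
        ratio_lo = np.median([p.a / p.d for p in lo.pairs])
        ratio_hi = np.median([p.a / p.d for p in hi.pairs])
        assert ratio_hi > ratio_lo


class TestSelection:
    def test_fastest_is_argmax_association(self):
        scan = scan_rates(0.28)
        fastest = select_rate(scan, "fastest")
        assert fastest.a == max(p.a for p in scan.pairs)

    def test_random_policy_deterministic_under_seed(self):
        scan = scan_rates(0.28)
        assert select_rate(scan, "random", seed=5) == select_rate(scan, "random", seed=5)

    def test_empty_set_raises(self):
        empty = scan_rates(0.28)
        empty.pairs = []
        with pytest.raises(ValueError):
            select_rate(empty)


class TestCalibrateAll:
    def test_full_rate_set_from_wt_table(self, wt_rates):
        rates, scans = wt_rates
        assert set(rates.rates) == set(COMPLEX_LABELS)
        for lab in COMPLEX_LABELS:
            assert scans[lab].n_accepted > 0
            assert rates[lab].a > 0

    def test_missing_label_raises(self):
        with pytest.raises(KeyError):
            calibrate_all({"BRAVOWOX5": 0.224})

    def test_rate_set_dict_round_trip(self, wt_rates):
        rates, _ = wt_rates
        again = RateSet.from_dict(rates.to_dict())
        assert again.to_dict() == rates.to_dict()

    def test_estimator_wrapper_matches_function(self):
        cal = RateCalibrator(policy="fastest").fit(WT_AFFINITIES)
        direct, _ = calibrate_all(WT_AFFINITIES, policy="fastest")
        assert cal.rates_.to_dict() == direct.to_dict()
        assert cal.get_params()["policy"] == "fastest"
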