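import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import root

from scncomplex.calibration import RateSet
from scncomplex.niche import (
    CELL_TYPES,
    NicheSimulator,
    SPECIES,
    conservation_totals,
    heatmap_matrix,
    scn_rhs,
    simulate_cell,
    simulate_niche,
)
from scncomplex.synthetic import DEFAULT_ABUNDANCE_MEANS


def _random_rates(rng):
    return RateSet.from_dict(
        {
            k: float(v)
            for k, v in zip(
                [f"{p}_{lab}" for lab in RateSet.uniform(1, 1).rates for p in "ad"],
                rng.uniform(0.01, 0.5, 10),
            )
        }
    )


def test_zero_rates_give_zero_derivatives():
    rates = RateSet.uniform(0.0, 0.0)
    y = [0.2, 0.3, 0.4, 0.05, 0.06, 0.07, 0.08]
    assert np.all(scn_rhs(0.0, y, rates) == 0.0)


def test_trimer_needs_dimers_to_form():
    # only free proteins present: no trimer production on either path
    rates = RateSet.uniform(0.3, 0.0)
    y = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0]
    deriv = scn_rhs(0.0, y, rates)
    assert deriv[6] == 0.0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(data=st.data())
def test_conservation_groups_cancel_algebraically(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    rates = _random_rates(rng)
    y = rng.uniform(0.0, 1.0, 7)
    d = scn_rhs(0.0, y, rates)
    # dWOX5 + dWP + dBW + dT = 0, and likewise for BRAVO and PLT3 groups
    assert d[0] + d[3] + d[5] + d[6] == pytest.approx(0.0, abs=1e-15)
    assert d[1] + d[4] + d[5] + d[6] == pytest.approx(0.0, abs=1e-15)
    assert d[2] + d[3] + d[4] + d[6] == pytest.approx(0.0, abs=1e-15)


def test_cell_with_only_plt3_stays_free():
    rates = RateSet.uniform(0.3, 0.1)
    profile = simulate_cell({"WOX5": 0.0, "BRAVO": 0.0, "PLT3": 0.7}, rates)
    assert profile["PLT3"] == pytest.approx(0.7, abs=1e-9)
    for c in SPECIES[3:]:
        assert profile[c] == pytest.approx(0.0, abs=1e-12)


def test_steady_state_matches_algebraic_fixed_point():
    rates = RateSet.uniform(0.1, 0.05)
    totals = {"WOX5": 1.0, "BRAVO": 1.0, "PLT3": 1.0}
    profile = simulate_cell(totals, rates)
    y_ode = np.array([profile[s] for s in SPECIES])

    def residual(y):
        d = scn_rhs(0.0, y, rates)
        cons = conservation_totals(y)
        return [
            d[3], d[4], d[5], d[6],
            cons["WOX5"] - 1.0,
            cons["BRAVO"] - 1.0,
            cons["PLT3"] - 1.0,
        ]

    sol = root(residual, np.full(7, 0.2), tol=1e-12)
    assert sol.success
    assert np.max(np.abs(y_ode - sol.x)) < 1e-6


def test_denser_pools_bind_larger_fraction():
    rates = RateSet.uniform(0.2, 0.1)
    small = simulate_cell({"WOX5": 0.3, "BRAVO": 0.3, "PLT3": 0.3}, rates)
    large = simulate_cell({"WOX5": 0.6, "BRAVO": 0.6, "PLT3": 0.6}, rates)
    bound_small = sum(small[c] for c in SPECIES[3:]) / 0.9
    bound_large = sum(large[c] for c in SPECIES[3:]) / 1.8
    assert bound_large > bound_small


def test_trajectory_conserves_protein_totals():
    rng = np.random.default_rng(3)
    for _ in range(5):
        rates = _random_rates(rng)
        totals = rng.uniform(0.1, 1.0, 3)
        y0 = np.zeros(7)
        y0[:3] = totals
        sol = solve_ivp(
            scn_rhs, (0.0, 500.0), y0, args=(rates,), method="LSODA",
            rtol=1e-10, atol=1e-12, dense_output=True,
        )
        y = sol.sol(np.linspace(0, 500, 40))
        for i, (protein, tot) in enumerate(zip(("WOX5", "BRAVO", "PLT3"), totals)):
            trace = np.array([conservation_totals(y[:, j])[protein] for j in range(y.shape[1])])
            assert np.max(np.abs(trace - tot)) / tot < 1e-9


def test_steady_state_independent_of_initial_partition(wt_rates):
    rates, _ = wt_rates
    totals = {"WOX5": 0.6, "BRAVO": 0.4, "PLT3": 0.55}
    base = simulate_cell(totals, rates)
    rng = np.random.default_rng(11)
    for _ in range(3):
        # random feasible pre-bound partition
        c = rng.uniform(0, 0.05, 4)
        alt = simulate_cell(totals, rates, initial_complexes=c)
        for s in SPECIES:
            assert alt[s] == pytest.approx(base[s], abs=1e-8)


def test_niche_requires_all_cell_types(wt_rates):
    rates, _ = wt_rates
    with pytest.raises(ValueError, match="missing cell types"):
        simulate_niche({"SI": {"WOX5": 1, "BRAVO": 1, "PLT3": 1}}, rates)


def test_signature_frame_shape_and_conservation(wt_signatures):
    sig = wt_signatures
    assert list(sig.columns) == list(CELL_TYPES)
    assert list(sig.index) == list(SPECIES)
    for ct in CELL_TYPES:
        y = sig[ct].to_numpy()
        cons = conservation_totals(y)
        for p in ("WOX5", "BRAVO", "PLT3"):
            assert cons[p] == pytest.approx(DEFAULT_ABUNDANCE_MEANS[ct][p], rel=1e-6)


def test_heatmap_row_normalisation(wt_signatures):
    heat = heatmap_matrix(wt_signatures)
    assert np.allclose(heat.max(axis=1), 1.0)


def test_transformer_wrapper_matches_function(wt_rates, wt_signatures):
    rates, _ = wt_rates
    sim = NicheSimulator(rates)
    out = sim.fit_transform(DEFAULT_ABUNDANCE_MEANS)
    pd.testing.assert_frame_equal(out, wt_signatures)
    assert sim.get_params()["rtol"] == 1e-10
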