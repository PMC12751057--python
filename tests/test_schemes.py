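"""Scheme construction, ODE simulation and closed-form steady-state constants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnphkin import (
    RateConstantSet,
    ReactionConditions,
    SchemeVariant,
    build_scheme,
    derived_constants,
    simulate_timecourse,
)


@pytest.mark.parametrize(
    "variant, n_species, n_reactions, labels",
    [
        ("binding_only", 3, 1, {"k1", "k2"}),
        ("two_step", 5, 2, {"k1", "k2", "k3"}),
        ("three_step", 6, 3, {"k1", "k2", "k3", "k5"}),
    ],
)
def test_build_scheme_variants(variant, n_species, n_reactions, labels):
    scheme = build_scheme(variant)
    assert len(scheme.species) == n_species
    assert len(scheme.reactions) == n_reactions
    assert set(scheme.rate_labels) == labels
    # first reaction is the reversible binding step
    assert scheme.reactions[0].reversible
    assert all(not r.reversible for r in scheme.reactions[1:])


def test_two_step_extends_binding_only():
    binding = build_scheme("binding_only")
    two = build_scheme("two_step")
    assert two.reactions[: len(binding.reactions)] == binding.reactions
    extra = two.reactions[len(binding.reactions):]
    assert len(extra) == 1 and not extra[0].reversible


def test_build_scheme_rejects_unknown_variant():
    with pytest.raises(ValueError, match="unknown scheme variant"):
        build_scheme("four_step")


def test_species_order_deterministic():
    assert build_scheme("three_step").species == ("E", "S", "ES", "EX", "P", "Q")


def test_rate_constant_validation():
    with pytest.raises(ValueError, match="k2"):
        RateConstantSet(k1=1.0, k2=-0.1)
    with pytest.raises(ValueError, match="k3"):
        RateConstantSet(k1=1.0, k2=1.0, k3=float("nan"))
    with pytest.raises(ValueError, match="requires k5"):
        RateConstantSet(k1=1.0, k2=1.0, k3=1.0).require(SchemeVariant.THREE_STEP)


def test_zero_rates_give_constant_concentrations():
    scheme = build_scheme("three_step")
    rates = RateConstantSet(k1=0.0, k2=0.0, k3=0.0, k5=0.0)
    cond = ReactionConditions(enzyme_total=20.0, substrate_total=10.0, dead_time=0.0)
    tc = simulate_timecourse(scheme, rates, cond, np.linspace(0, 10, 50))
    assert np.allclose(tc["E"], 20.0)
    assert np.allclose(tc["S"], 10.0)
    for sp in ("ES", "EX", "P", "Q"):
        assert np.allclose(tc[sp], 0.0)


def test_binding_equilibrium_matches_quadratic_root():
    """Long-time ES of the one-step binding ODE equals the closed-form root.

    Oracle: equilibrium satisfies k1*(E0-x)*(S0-x) = k2*x, the quadratic
    x^2 - (E0+S0+KD)x + E0*S0 = 0 with the physical (smaller) root.
    """
    e0, s0, k1, k2 = 88.0, 10.0, 1.0, 2.36
    kd = k2 / k1
    b = e0 + s0 + kd
    x_eq = (b - np.sqrt(b * b - 4 * e0 * s0)) / 2
    assert x_eq == pytest.approx(9.7074, abs=5e-4)  # frozen from the oracle

    scheme = build_scheme("binding_only")
    cond = ReactionConditions(enzyme_total=e0, substrate_total=s0, dead_time=0.0)
    tc = simulate_timecourse(
        scheme, RateConstantSet(k1=k1, k2=k2), cond, np.linspace(0, 5, 100)
    )
    assert tc["ES"][-1] == pytest.approx(x_eq, rel=1e-6)


def test_three_step_runs_to_completion():
    scheme = build_scheme("three_step")
    rates = RateConstantSet(k1=1.0, k2=2.4, k3=0.5, k5=0.2)
    cond = ReactionConditions(
        enzyme_total=20.0, substrate_total=10.0, active_fraction=0.5, dead_time=0.0
    )
    tc = simulate_timecourse(scheme, rates, cond, np.linspace(0, 200, 100))
    assert tc["S"][-1] == pytest.approx(0.0, abs=1e-6)
    assert tc["ES"][-1] == pytest.approx(0.0, abs=1e-6)
    assert tc["EX"][-1] == pytest.approx(0.0, abs=1e-6)
    assert tc["P"][-1] == pytest.approx(10.0, rel=1e-6)
    assert tc["Q"][-1] == pytest.approx(10.0, rel=1e-6)
    assert tc["E"][-1] == pytest.approx(10.0, rel=1e-6)  # active enzyme only


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    k1=st.floats(0.01, 10.0),
    k2=st.floats(0.01, 100.0),
    k3=st.floats(1e-3, 10.0),
    k5=st.floats(1e-4, 10.0),
    e0=st.floats(0.5, 200.0),
    s0=st.floats(0.5, 200.0),
    active=st.floats(0.3, 1.0),
)
def test_mass_conservation_holds_everywhere(k1, k2, k3, k5, e0, s0, active):
    """Enzyme and substrate conservation to 1e-9 relative at every time point."""
    scheme = build_scheme("three_step")
    rates = RateConstantSet(k1=k1, k2=k2, k3=k3, k5=k5)
    cond = ReactionConditions(
        enzyme_total=e0, substrate_total=s0, active_fraction=active, dead_time=0.0
    )
    tc = simulate_timecourse(scheme, rates, cond, np.geomspace(1e-4, 20.0, 60))
    scale = max(e0, s0)
    for name, resid in tc.conservation_residuals().items():
        assert np.max(np.abs(resid)) <= 1e-9 * scale, name
    assert tc.data.min() >= -1e-12


def test_pseudo_first_order_relaxation_rate():
    """With enzyme in large excess, ES relaxes mono-exponentially at k1*E0 + k2."""
    from scipy.optimize import curve_fit

    k1, k2, e0, s0 = 1.0, 2.36, 1000.0, 1.0
    scheme = build_scheme("binding_only")
    cond = ReactionConditions(enzyme_total=e0, substrate_total=s0, dead_time=0.0)
    t = np.linspace(0, 0.01, 400)
    tc = simulate_timecourse(scheme, RateConstantSet(k1=k1, k2=k2), cond, t)
    es = tc["ES"]
    popt, _ = curve_fit(
        lambda t, a, k: a * (1 - np.exp(-k * t)), t, es, p0=[es[-1], 2 * (k1 * e0)]
    )
    kobs = popt[1]
    assert kobs == pytest.approx(k1 * e0 + k2, rel=5e-3)


def test_quasi_steady_state_rate_matches_closed_form():
    """At S >> KM and catalytic enzyme, d[P]/dt follows the saturation rate law
    with kcat = k3*k5/(k3+k5) and KM = (k2+k3)*k5/(k1*(k3+k5))."""
    k1, k2, k3, k5 = 1.0, 2.36, 0.27, 0.1
    kcat = k3 * k5 / (k3 + k5)
    km = (k2 + k3) * k5 / (k1 * (k3 + k5))
    e_act, s0 = 0.5, 100.0
    scheme = build_scheme("three_step")
    cond = ReactionConditions(enzyme_total=e_act, substrate_total=s0, dead_time=0.0)
    t = np.linspace(0, 60, 600)
    tc = simulate_timecourse(scheme, RateConstantSet(k1, k2, k3, k5), cond, t)
    window = (t >= 20) & (t <= 40)
    slope = np.polyfit(t[window], tc["P"][window], 1)[0]
    s_mid = tc["S"][window][window.sum() // 2]
    v_expected = kcat * s_mid / (km + s_mid) * e_act
    assert slope == pytest.approx(v_expected, rel=5e-3)

    derived = derived_constants(RateConstantSet(k1, k2, k3, k5))
    assert derived["km"] == pytest.approx(km, rel=1e-12)
    assert derived["kcat"] == pytest.approx(kcat, rel=1e-12)


def test_dead_time_grid_supported():
    """Grids that start after t=0 (instrument dead time) integrate from mixing."""
    scheme = build_scheme("binding_only")
    cond = ReactionConditions(enzyme_total=88.0, substrate_total=10.0)
    grid = np.geomspace(cond.dead_time, 5.0, 50)
    tc = simulate_timecourse(scheme, RateConstantSet(1.0, 2.36), cond, grid)
    # some complex has already formed during the dead time
    assert tc["ES"][0] > 0


def test_derived_constants_closed_forms():
    # equal half-reaction rates halve kcat
    rates = RateConstantSet(k1=1.0, k2=1.0, k3=0.4, k5=0.4)
    assert derived_constants(rates)["kcat"] == pytest.approx(0.2, rel=1e-12)

    # slow second half-reaction dominates turnover
    slow = RateConstantSet(k1=1.0, k2=2.4, k3=0.270, k5=1.589e-3)
    assert derived_constants(slow)["kcat"] == pytest.approx(1.580e-3, rel=1e-3)

    # first-half flux sets the specificity constant
    wt = RateConstantSet(k1=1.0, k2=2.36, k3=0.219)
    out = derived_constants(wt)
    assert out["kcat_over_km"] == pytest.approx(8.49e4, rel=1e-3)
    assert out["kd_app"] == pytest.approx(2.36, rel=1e-12)
    assert "kcat" not in out  # k5 absent

    with pytest.raises(ValueError, match="k5"):
        derived_constants(wt, quantities=["kcat"])


def test_specificity_constant_limits():
    """kcat/KM -> k1 when chemistry outruns dissociation, k1*k3/k2 otherwise."""
    fast_chem = RateConstantSet(k1=2.0, k2=1.0, k3=1e7)
    assert derived_constants(fast_chem)["kcat_over_km"] == pytest.approx(2.0e6, rel=1e-6)
    slow_chem = RateConstantSet(k1=2.0, k2=1e5, k3=1e-2)
    assert derived_constants(slow_chem)["kcat_over_km"] == pytest.approx(
        2.0 * 1e-2 / 1e5 * 1e6, rel=1e-6
    )


def test_nonmonotonic_grid_rejected(wt_rates):
    scheme = build_scheme("two_step")
    cond = ReactionConditions(enzyme_total=10, substrate_total=10, dead_time=0.0)
    with pytest.raises(ValueError, match="strictly increasing"):
        simulate_timecourse(scheme, wt_rates, cond, np.array([0.0, 1.0, 1.0, 2.0]))
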