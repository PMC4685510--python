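"""Biochemical Ki workflow: fits, tight-binding conversion, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aurprof.enzymology import (
    DoseResponseDataset,
    KiConversion,
    TightBindingContext,
    VelocityDataset,
    aggregate_ki,
    compute_selectivity_ratios,
    estimate_active_enzyme,
    fit_four_parameter_logistic,
    fit_fourpl,
    fit_michaelis_menten,
    format_ratio,
    ic50_to_ki,
    morrison_fractional_activity,
)
from aurprof.synthdata import BiochemSpec, MMTitrationSpec, simulate_biochem_plate, simulate_mm_titration

from conftest import grid_fit_fourpl, grid_fit_michaelis


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------


def test_michaelis_menten_recovers_noiseless_parameters():
    S = np.logspace(0, 3, 8)
    v = 1.0 * S / (35.0 + S)
    kc = fit_michaelis_menten(VelocityDataset(S, v))
    assert kc.Km == pytest.approx(35.0, rel=1e-6)
    assert kc.Vmax == pytest.approx(1.0, rel=1e-6)
    # definition of Km: half-maximal velocity at [S] = Km
    assert kc.predict(kc.Km) == pytest.approx(kc.Vmax / 2.0, rel=1e-12)


def test_michaelis_menten_noisy_recovery_and_grid_oracle():
    """3% multiplicative noise, 8 points: median relative Km error < 5%;
    the fitted optimum agrees with an independent grid search on the same
    loss to < 0.1%."""
    spec = MMTitrationSpec(Km=10.0, Vmax=1.0, cv=0.03)
    errs = []
    for seed in range(300):
        ds, _ = simulate_mm_titration(spec, seed)
        kc = fit_michaelis_menten(ds)
        errs.append(abs(kc.Km - 10.0) / 10.0)
        if seed < 5:
            km_g, vmax_g, _ = grid_fit_michaelis(ds.substrate_conc, ds.velocity)
            assert kc.Km == pytest.approx(km_g, rel=1e-3)
            assert kc.Vmax == pytest.approx(vmax_g, rel=1e-3)
    assert np.median(errs) < 0.05


def test_michaelis_menten_flags_km_outside_sampled_range():
    S = np.logspace(2, 4, 8)  # all far above Km=1
    v = 1.0 * S / (1.0 + S)
    with pytest.warns(UserWarning, match="outside the sampled"):
        kc = fit_michaelis_menten(VelocityDataset(S, v))
    assert kc.km_outside_sampled_range


def test_velocity_dataset_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        VelocityDataset([1, 2, 3, 4], [1, 1, 1, 1])  # < 5 distinct conc
    with pytest.raises(ValueError):
        VelocityDataset([1, 2, 3, 4, -5], [1, 1, 1, 1, 1])


# ---------------------------------------------------------------------------
# 4PL fitting
# ---------------------------------------------------------------------------


def _curve(conc, top, bottom, ic50, hill):
    out = np.where(conc > 0,
                   bottom + (top - bottom) / (1.0 + (np.where(conc > 0, conc, 1.0) / ic50) ** hill),
                   top)
    return out


def _dataset(top=1.0, bottom=0.0, ic50=5.0, hill=1.0, n=24, reps=3, cv=0.0, seed=0):
    rng = np.random.default_rng(seed)
    doses = np.logspace(np.log10(ic50) - 2, np.log10(ic50) + 2, n)
    conc = np.concatenate([np.zeros(reps), np.repeat(doses, reps)])
    y = _curve(conc, top, bottom, ic50, hill)
    y = y * (1.0 + cv * rng.standard_normal(y.shape))
    return DoseResponseDataset(conc, y)


def test_fourpl_recovers_noiseless_parameters_exactly():
    # recovery is exact up to the zero-dose pseudo-concentration anchor,
    # which sits 3 decades below the lowest dose (model value there differs
    # from the plateau by ~1e-5 of the span)
    fit = fit_four_parameter_logistic(_dataset(), normalize=False)
    assert fit.top == pytest.approx(1.0, abs=1e-4)
    assert fit.bottom == pytest.approx(0.0, abs=1e-4)
    assert fit.ic50 == pytest.approx(5.0, rel=1e-4)
    assert fit.hill_slope == pytest.approx(1.0, rel=1e-3)
    # midpoint identity of the 4PL
    assert fit.predict(fit.ic50) == pytest.approx((fit.top + fit.bottom) / 2)


def test_fourpl_constant_response_flags_no_effect():
    conc = np.concatenate([[0, 0], np.repeat(np.logspace(0, 3, 10), 2)])
    fit = fit_fourpl(conc, np.full_like(conc, 0.7))
    assert fit.no_effect and not np.isfinite(fit.ic50)


def test_fourpl_invariant_under_dose_reordering():
    ds = _dataset(cv=0.02, seed=3)
    fit1 = fit_four_parameter_logistic(ds)
    rev = DoseResponseDataset(ds.inhibitor_conc[::-1], ds.response[::-1])
    fit2 = fit_four_parameter_logistic(rev)
    assert fit1.ic50 == pytest.approx(fit2.ic50, rel=1e-9)
    assert fit1.hill_slope == pytest.approx(fit2.hill_slope, rel=1e-9)


def test_fourpl_noisy_recovery_with_grid_oracle():
    """Triplicate 24-point curves at 2% CV, true IC50 = 0.5 nM: the IC50 is
    recovered within 10% in >= 95% of seeded simulations, and matches an
    independent coarse-to-fine grid fit."""
    hits = 0
    n_sim = 200
    for seed in range(n_sim):
        ds = _dataset(ic50=0.5, cv=0.02, seed=seed)
        fit = fit_four_parameter_logistic(ds, normalize=True)
        hits += abs(fit.ic50 - 0.5) / 0.5 < 0.10
        if seed < 3:
            g = grid_fit_fourpl(ds.inhibitor_conc,
                                ds.response / ds.control_mean())
            assert fit.ic50 == pytest.approx(g["ic50"], rel=0.02)
    assert hits / n_sim >= 0.95


def test_fourpl_rising_curve_midpoint():
    conc = np.concatenate([[0.0], np.logspace(0, 3, 12)])
    y = 100.0 + 400.0 * np.where(conc > 0, 1.0 / (1.0 + (30.0 / np.where(conc > 0, conc, 1)) ** 1.2), 0.0)
    fit = fit_fourpl(conc, y, normalize=False)
    assert not fit.no_effect
    assert fit.ic50 == pytest.approx(30.0, rel=0.01)
    assert fit.top > fit.bottom and fit.hill_slope < 0


def test_dose_response_dataset_invariants():
    with pytest.raises(ValueError, match="zero-dose"):
        DoseResponseDataset(np.logspace(0, 2, 10), np.ones(10))
    with pytest.raises(ValueError, match="8 distinct"):
        conc = np.array([0.0, 1, 2, 3, 4, 5, 6, 7])
        DoseResponseDataset(conc, np.ones_like(conc))


# ---------------------------------------------------------------------------
# Morrison closed form and active-enzyme titration
# ---------------------------------------------------------------------------


def test_morrison_limits():
    assert morrison_fractional_activity(0.0, 0.4, 2.0) == 1.0
    # stoichiometric endpoint: infinitely tight inhibitor consumes the enzyme
    assert morrison_fractional_activity(0.4, 0.4, 0.0) == pytest.approx(0.0, abs=1e-12)


def test_morrison_matches_hyperbolic_when_binding_is_weak():
    """For Ki_app >> Et the Morrison curve collapses onto the classical
    1/(1 + I/IC50) binding isotherm with IC50 = Ki_app + Et/2."""
    Et, ki_app = 0.4, 400.0
    I = np.logspace(-1, 5, 200)
    morrison = morrison_fractional_activity(I, Et, ki_app)
    hyperbolic = 1.0 / (1.0 + I / (ki_app + Et / 2.0))
    assert np.max(np.abs(morrison - hyperbolic)) < 0.01


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.01, 100), st.floats(0.0, 1000),
       st.lists(st.floats(0.0, 1e4), min_size=2, max_size=20))
def test_morrison_monotone_non_increasing(Et, ki_app, doses):
    frac = morrison_fractional_activity(np.sort(np.asarray(doses)), Et, ki_app)
    assert np.all(np.diff(frac) <= 1e-12)
    assert np.all((np.asarray(frac) >= 0) & (np.asarray(frac) <= 1))


def _titration_dataset(Et, ki_app, cv=0.0, seed=0, n=24, reps=3):
    rng = np.random.default_rng(seed)
    ic50 = ki_app + Et / 2.0
    doses = np.logspace(np.log10(ic50) - 1.25, np.log10(ic50) + 1.25, n)
    conc = np.concatenate([np.zeros(reps), np.repeat(doses, reps)])
    y = morrison_fractional_activity(conc, Et, ki_app)
    y = y * (1.0 + cv * rng.standard_normal(conc.shape))
    return DoseResponseDataset(conc, np.clip(y, 0, None))


def test_estimate_active_enzyme_stoichiometric_limit():
    ds = _titration_dataset(Et=0.8, ki_app=0.0)
    est = estimate_active_enzyme(ds, reference_ki=1e-4)
    # the symmetric 4PL has a small shape bias on the sharp-cornered
    # stoichiometric titration curve; the half-point itself is exactly Et/2
    assert est.ic50 == pytest.approx(0.4, rel=0.04)
    assert est.Et == pytest.approx(0.8, rel=0.04)
    assert est.in_stoichiometric_regime


def test_estimate_active_enzyme_flags_non_stoichiometric_regime():
    ds = _titration_dataset(Et=0.8, ki_app=0.0)
    with pytest.warns(UserWarning, match="stoichiometric"):
        est = estimate_active_enzyme(ds, reference_ki=0.4)
    assert not est.in_stoichiometric_regime


def test_estimate_active_enzyme_noisy_recovery():
    errs = []
    for seed in range(20):
        ds = _titration_dataset(Et=0.5, ki_app=0.002, cv=0.01, seed=seed)
        est = estimate_active_enzyme(ds, reference_ki=0.001)
        errs.append(abs(est.Et - 0.5) / 0.5)
    assert np.median(errs) < 0.05


# ---------------------------------------------------------------------------
# IC50 -> Ki conversion
# ---------------------------------------------------------------------------


def test_cheng_prusoff_reduction_at_zero_enzyme():
    ctx = TightBindingContext(Et=0.0, S=35.0, Km=35.0)
    assert ic50_to_ki(2.0, ctx).ki == pytest.approx(1.0)


def test_conversion_denominator_is_exactly_two_at_s_equals_km():
    ctx = TightBindingContext(Et=0.4, S=35.0, Km=35.0)
    for ic50 in (0.5, 3.7, 120.0):
        assert ic50_to_ki(ic50, ctx).ki == (ic50 - 0.2) / 2.0


def test_conversion_at_titration_limit_returns_floor_bound():
    ctx = TightBindingContext(Et=0.4, S=35.0, Km=35.0)
    res = ic50_to_ki(0.2, ctx)  # ic50 == Et/2
    assert res.is_upper_bound
    assert res.bound_value == pytest.approx(0.01)  # resolution floor, nM
    assert not np.isfinite(res.ki)


def test_conversion_never_negative():
    ctx = TightBindingContext(Et=1.0, S=35.0, Km=35.0)
    res = ic50_to_ki(0.3, ctx)  # ic50 < Et/2
    assert res.is_upper_bound and res.bound_value > 0


def test_cheng_prusoff_limit_agreement_within_one_percent():
    """For Et/Ki <= 0.01 the tight-binding conversion and the Et=0
    approximation agree within 1%."""
    for ki in (50.0, 500.0, 5000.0):
        Et = 0.01 * ki
        ic50 = 2.0 * ki + Et / 2.0  # exact Morrison half-point at S=Km
        full = ic50_to_ki(ic50, TightBindingContext(Et=Et, S=35, Km=35)).ki
        approx = ic50_to_ki(ic50, TightBindingContext(Et=0.0, S=35, Km=35)).ki
        assert abs(full - approx) / full < 0.01


def test_fourpl_on_noiseless_morrison_matches_half_point():
    """With Ki_app >= 10*Et the fitted IC50 is within 2% of Ki_app + Et/2."""
    Et = 0.4
    for ki_app in (4.0, 40.0, 400.0):
        ds = _titration_dataset(Et=Et, ki_app=ki_app)
        fit = fit_four_parameter_logistic(ds)
        assert fit.ic50 == pytest.approx(ki_app + Et / 2.0, rel=0.02)


def test_simulated_tight_binding_ki_recovery():
    """Morrison-simulated curve (Ki = 1 nM, Et = 0.5 nM, S = Km), 4PL fit
    plus conversion recovers Ki within 5%."""
    ctx = TightBindingContext(Et=0.5, S=35.0, Km=35.0)
    spec = BiochemSpec(Ki=1.0, Et=0.5, cv=0.01)
    ds, _ = simulate_biochem_plate(spec, seed=11)
    fit = fit_four_parameter_logistic(ds)
    res = ic50_to_ki(fit.ic50, ctx, ic50_se=fit.ic50_se)
    assert not res.is_upper_bound
    assert res.ki == pytest.approx(1.0, rel=0.05)


# ---------------------------------------------------------------------------
# Aggregation and selectivity
# ---------------------------------------------------------------------------


def test_aggregate_ki_trivial():
    est = aggregate_ki([1.0, 1.0, 1.0])
    assert (est.mean, est.sd, est.n) == (1.0, 0.0, 3)


def test_aggregate_ki_reproduces_reference_moments():
    """Eleven values constructed with mean 1.03 and sample SD 0.18 aggregate
    to exactly those summary statistics (the reference-compound row)."""
    rng = np.random.default_rng(5)
    z = rng.standard_normal(11)
    z = (z - z.mean()) / z.std(ddof=1)
    values = 1.03 + 0.18 * z
    est = aggregate_ki(values.tolist())
    assert est.mean == pytest.approx(1.03, abs=1e-12)
    assert est.sd == pytest.approx(0.18, abs=1e-12)
    assert est.n == 11


def test_aggregate_ki_rejects_nonpositive():
    with pytest.raises(ValueError):
        aggregate_ki([1.0, -0.5])


def test_aggregate_ki_propagates_upper_bounds():
    est = aggregate_ki([KiConversion(ki=float("nan"), is_upper_bound=True,
                                     bound_value=0.01),
                        KiConversion(ki=0.02)])
    assert est.is_upper_bound
    assert "mixed" in est.note


def _estimate(mean, n=3, sd=0.0, bound=None):
    from aurprof.enzymology import KiEstimate
    if bound is not None:
        return KiEstimate(ki_values=(bound,) * n, mean=float("nan"), sd=sd,
                          n=n, is_upper_bound=True, bound_value=bound)
    return KiEstimate(ki_values=(mean,) * n, mean=mean, sd=sd, n=n)


PAIRS = (("AurA", "AurA-TPX2"), ("AurA", "AurB-INCENP"),
         ("AurA-TPX2", "AurB-INCENP"), ("AurB-INCENP", "AurA"),
         ("AurB-INCENP", "AurA-TPX2"))


def test_selectivity_ratios_reference_panel():
    """Published mean Ki values reproduce the printed fold-selectivity
    entries after display rounding."""
    table = {
        "VX-680": {"AurA": _estimate(1.03), "AurA-TPX2": _estimate(4.55),
                   "AurB-INCENP": _estimate(1.11)},
        "GSK1070916": {"AurA": _estimate(16.1), "AurA-TPX2": _estimate(130.2),
                       "AurB-INCENP": _estimate(0.38)},
        "Genentech Aurora Inhibitor 1": {"AurA": _estimate(0.57),
                                         "AurB-INCENP": _estimate(156.2)},
        "ZM447439": {"AurA-TPX2": _estimate(336.8),
                     "AurB-INCENP": _estimate(1.83)},
    }
    with pytest.warns(UserWarning):  # some pairs intentionally missing
        ratios = compute_selectivity_ratios(table, PAIRS)
    disp = {(r.compound_id, r.preferred_enzyme, r.comparator_enzyme):
            format_ratio(r) for r in ratios}
    assert disp[("VX-680", "AurA", "AurA-TPX2")] == "4.4"
    assert disp[("VX-680", "AurA", "AurB-INCENP")] == "1.1"
    assert disp[("VX-680", "AurA-TPX2", "AurB-INCENP")] == "0.2"
    assert disp[("VX-680", "AurB-INCENP", "AurA")] == "0.9"
    assert disp[("VX-680", "AurB-INCENP", "AurA-TPX2")] == "4.1"
    assert disp[("GSK1070916", "AurA", "AurA-TPX2")] == "8.1"
    assert disp[("GSK1070916", "AurB-INCENP", "AurA-TPX2")] == "343"
    assert disp[("Genentech Aurora Inhibitor 1", "AurA", "AurB-INCENP")] == "274"
    assert disp[("ZM447439", "AurB-INCENP", "AurA-TPX2")] == "184"


def test_selectivity_upper_bound_gives_lower_bound_ratio():
    table = {"MK-5108": {"AurA": _estimate(None, bound=0.01),
                         "AurA-TPX2": _estimate(0.04),
                         "AurB-INCENP": _estimate(1.49)}}
    ratios = compute_selectivity_ratios(table, PAIRS[:2])
    disp = {r.comparator_enzyme: format_ratio(r) for r in ratios}
    assert disp["AurA-TPX2"] == ">4"
    assert disp["AurB-INCENP"] == ">149"


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.01, 1000), st.floats(0.01, 1000))
def test_selectivity_ratio_antisymmetry(ka, kb):
    table = {"c": {"X": _estimate(ka), "Y": _estimate(kb)}}
    r = compute_selectivity_ratios(table, (("X", "Y"), ("Y", "X")))
    assert r[0].ratio * r[1].ratio == pytest.approx(1.0, rel=1e-12)


def test_selectivity_equal_ki_gives_unity():
    table = {"c": {"X": _estimate(7.7), "Y": _estimate(7.7)}}
    (r,) = compute_selectivity_ratios(table, (("X", "Y"),))
    assert r.ratio == pytest.approx(1.0)
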