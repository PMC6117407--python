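"""The overall-conversion LP: reproduction of published designs, scans,
ferric limits, carbon ceilings and co-product designs."""

import math

import pytest

from gasferm.design import (
    DesignError,
    DesignProblem,
    design_conversion,
    design_coproduct,
    design_from_composition,
    ferric_limits,
    max_carbon_fraction,
    scan_ternary,
    table2_conditions,
)

#: balance-determined published rows (printed dG <= -9): gas objective
#: coefficients must reproduce to +/- 0.01 mol
BALANCE_ROWS = [
    ("pyr", "ch4", 6.66, 4.999),
    ("pyr", "co", 0.0, 7.777),
    ("oxa", "ch4", 5.0, 3.75),
    ("oxa", "co", 0.0, 9.17),
    ("2kg", "co", 0.0, 8.0),
    ("gap", "ch4", 10.0, 6.249),
    ("e4p", "ch4", 10.0, 6.25),
    ("sca", "co", 0.0, 7.066),
]


@pytest.mark.parametrize("target,objective,ferric,expected", BALANCE_ROWS)
def test_published_balance_rows_reproduce(registry, thermo_table, target,
                                          objective, ferric, expected):
    d = design_conversion(
        DesignProblem(target=target, objective=objective, ferric=ferric),
        registry, thermo_table,
    )
    assert d.optimal
    assert d.objective_value == pytest.approx(expected, abs=0.01)


def test_pyruvate_max_ch4_full_stoichiometry(registry, thermo_table):
    """The complete printed pyruvate row, coefficient by coefficient."""
    d = design_conversion(
        DesignProblem(target="pyr", objective="ch4", ferric=6.66),
        registry, thermo_table,
    )
    c = d.coefficients
    assert c["ch4"] == pytest.approx(-4.999, abs=0.01)
    assert c["co2"] == pytest.approx(-5.000, abs=0.01)
    assert c["co"] == pytest.approx(0.0, abs=0.01)
    assert c["pyr"] == pytest.approx(10 / 3)
    assert c["h"] == pytest.approx(9.993, abs=0.01)
    assert c["fe3"] == -6.66 and c["fe2"] == 6.66


def test_all_published_conditions_are_exergonic_or_thermo_bound(registry,
                                                                thermo_table):
    """Every re-created published design has dG <= 0; the only conditions
    infeasible at the printed ferric level are the thermo-bound max-CO rows
    of phosphorylated sugars, whose minimum ferric is table-dependent."""
    for p in table2_conditions():
        d = design_conversion(p, registry, thermo_table)
        if d.optimal:
            assert d.delta_g <= 1e-6
        else:
            assert d.infeasibility == "thermo"
            assert p.objective == "co"
            assert registry[p.target].n("P") > 0


def test_co_alone_cannot_support_pyruvate(registry, thermo_table):
    """10 mol CO supplies fewer electrons than 10 C-mol pyruvate requires."""
    d = design_conversion(
        DesignProblem(target="pyr", objective="co", ferric=0.0,
                      allowed_gases=("co",)),
        registry, thermo_table,
    )
    assert not d.optimal
    assert d.infeasibility == "balance"


def test_conservation_invariants(registry, thermo_table):
    """Gas carbon equals product carbon; acceptor coefficients mirror."""
    d = design_conversion(
        DesignProblem(target="2kg", objective="ch4", ferric=6.0),
        registry, thermo_table,
    )
    gas_c = sum(d.coefficients[g] * registry[g].n("C") for g in ("ch4", "co", "co2"))
    assert gas_c == pytest.approx(-10.0, abs=1e-6)
    assert d.coefficients["fe3"] == pytest.approx(-d.coefficients["fe2"])


def test_max_ch4_objective_monotone_in_ferric(registry, thermo_table):
    vals = []
    for F in (0.0, 2.0, 4.0, 6.0):
        d = design_conversion(
            DesignProblem(target="pyr", objective="ch4", ferric=F),
            registry, thermo_table,
        )
        assert d.optimal
        vals.append(d.objective_value)
    assert vals == sorted(vals)


def test_relaxing_dg_threshold_never_hurts(registry, thermo_table):
    tight = design_conversion(
        DesignProblem(target="gap", objective="co", ferric=4.0),
        registry, thermo_table,
    )
    loose = design_conversion(
        DesignProblem(target="gap", objective="co", ferric=4.0,
                      dg_threshold=math.inf),
        registry, thermo_table,
    )
    assert loose.objective_value >= tight.objective_value - 1e-9


def test_deterministic_reporting(registry, thermo_table):
    p = DesignProblem(target="aca", objective="co2", ferric=5.0)
    d1 = design_conversion(p, registry, thermo_table)
    d2 = design_conversion(p, registry, thermo_table)
    assert d1.coefficients == d2.coefficients


def test_helper_gating(registry, thermo_table):
    """Phosphate/ammonium/sulfide only appear for P/N/S-containing targets."""
    d = design_conversion(
        DesignProblem(target="pyr", objective="ch4", ferric=5.0),
        registry, thermo_table,
    )
    assert "hpo4" not in d.coefficients and "nh4" not in d.coefficients
    d = design_conversion(
        DesignProblem(target="sca", objective="ch4", ferric=8.0),
        registry, thermo_table,
    )
    assert d.coefficients["hpo4"] == pytest.approx(-1.2, abs=0.01)
    assert d.coefficients["nh4"] == pytest.approx(-2.8, abs=0.01)
    assert d.coefficients["h2s"] == pytest.approx(-0.4, abs=0.01)


# ---------------------------------------------------------------------------
# problem validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(target="pyr", objective="ch4", ferric=-1.0),
        dict(target="pyr", objective="ch4", bound=0.0),
        dict(target="pyr", objective="etoh"),
        dict(target="btoh", objective="btoh", coproduct="btoh"),
        dict(target="pyr", objective="ch4", allowed_gases=()),
    ],
)
def test_invalid_problems_rejected(kwargs):
    with pytest.raises(DesignError):
        DesignProblem(**kwargs)


def test_unknown_target_raises(registry, thermo_table):
    with pytest.raises(KeyError):
        design_conversion(
            DesignProblem(target="nope", objective="ch4"), registry, thermo_table
        )


# ---------------------------------------------------------------------------
# ternary scan
# ---------------------------------------------------------------------------


def test_scan_pure_compositions_infeasible(registry, thermo_table):
    fmap = scan_ternary("pyr", [0.0], 0.25, registry, thermo_table)
    flags = {(p.f_ch4, p.f_co, p.f_co2): p.feasible for p in fmap}
    assert flags[(1.0, 0.0, 0.0)] is False  # no acceptor: CH4 over-reduced
    assert flags[(0.0, 0.0, 1.0)] is False  # no electron source
    assert any(flags.values())  # the CH4/CO co-utilization line exists


def test_scan_finds_published_oxa_point(registry, thermo_table):
    """The published OXA max-CH4 design (3.75, 0, 6.25) at ferric 5 lights
    up the nearest grid points."""
    fmap = scan_ternary("oxa", [5.0], 0.05, registry, thermo_table)
    flags = {(p.f_ch4, p.f_co, p.f_co2): p.feasible for p in fmap}
    assert flags[(0.35, 0.0, 0.65)] or flags[(0.4, 0.0, 0.6)]


def test_scan_points_are_normalized_and_ordered(registry, thermo_table):
    fmap = scan_ternary("pyr", [1.0, 0.0], 0.5, registry, thermo_table)
    for p in fmap:
        assert p.f_ch4 + p.f_co + p.f_co2 == pytest.approx(1.0, abs=1e-9)
    ferrics = [p.ferric for p in fmap]
    assert ferrics == sorted(ferrics)


def test_scan_rejects_bad_grid(registry, thermo_table):
    with pytest.raises(DesignError):
        scan_ternary("pyr", [], 0.05, registry, thermo_table)
    with pytest.raises(DesignError):
        scan_ternary("pyr", [0.0], 0.03, registry, thermo_table)


# ---------------------------------------------------------------------------
# ferric limits / carbon ceilings
# ---------------------------------------------------------------------------


def test_pyruvate_ferric_ceiling(registry, thermo_table):
    """Charge balance forces s_H+ = F + 3.333, so the proton bound of 10
    caps the ferric level at 6.66."""
    fmin, fmax = ferric_limits("pyr", registry, thermo_table)
    assert fmin == pytest.approx(0.0, abs=0.01)
    assert fmax == pytest.approx(6.667, abs=0.02)


def test_zero_acceptor_bound_degenerates(registry, thermo_table):
    fmin, fmax = ferric_limits("pyr", registry, thermo_table, acceptor_bound=0.0)
    assert (fmin, fmax) == (0.0, 0.0)


def test_impossible_threshold_gives_empty_interval(registry, thermo_table):
    fmin, fmax = ferric_limits("pyr", registry, thermo_table,
                               dg_threshold=-10000.0)
    assert fmin is None and fmax is None


def test_max_carbon_fraction_examples(registry, thermo_table):
    """Methane can never supply more than half of pyruvate's carbon; CO can
    supply 91.7% of oxaloacetate's."""
    assert max_carbon_fraction("pyr", "ch4", registry, thermo_table) <= 0.5 + 1e-6
    assert max_carbon_fraction("oxa", "co", registry, thermo_table) == pytest.approx(
        0.917, abs=0.005
    )


def test_max_carbon_fraction_rejects_disallowed_gas(registry, thermo_table):
    with pytest.raises(DesignError):
        max_carbon_fraction("pyr", "co", registry, thermo_table,
                            allowed_gases=("ch4", "co2"))


# ---------------------------------------------------------------------------
# co-product and fixed-composition designs
# ---------------------------------------------------------------------------


def test_butanol_ethanol_coproduction(registry, thermo_table):
    """Ethanol alongside 1 mol butanol at 1 mol ferric: the CO:CH4 uptake
    ratio lands near the published 0.47."""
    res = design_coproduct("btoh", "etoh", 1.0, registry, thermo_table)
    assert res.design.optimal
    assert res.coproduct_amount > 1.0
    assert 0.0 < res.coproduct_fraction < 1.0
    assert res.co_to_ch4_ratio == pytest.approx(0.47, abs=0.05)


def test_coproduct_identity_rejected(registry, thermo_table):
    with pytest.raises(DesignError):
        design_coproduct("btoh", "btoh", 1.0, registry, thermo_table)


def test_fixed_composition_oxa(registry, thermo_table):
    """Published OXA composition (1.833, 7.166, 1) at ferric 4 gives the
    stoichiometric optimum of 2.5 mol per 10 C-mol of gas."""
    d = design_from_composition(
        "oxa", {"ch4": 1.833, "co": 7.166, "co2": 1.0}, 4.0, registry, thermo_table
    )
    assert d.optimal
    assert d.objective_value == pytest.approx(2.5, abs=0.01)


def test_fixed_composition_gap_balance_only(registry, thermo_table):
    """The GAP composition closes carbon and electron balance at 3.333 mol;
    its thermodynamic feasibility is formation-energy-table dependent."""
    d = design_from_composition(
        "gap", {"ch4": 4.333, "co": 4.666, "co2": 1.0}, 4.0, registry,
        thermo_table, dg_threshold=math.inf,
    )
    assert d.optimal
    assert d.objective_value == pytest.approx(10 / 3, abs=0.01)


def test_zero_composition_is_infeasible(registry, thermo_table):
    d = design_from_composition("oxa", {"ch4": 0.0, "co": 0.0, "co2": 0.0},
                                4.0, registry, thermo_table)
    assert not d.optimal
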