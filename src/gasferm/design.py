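"""Design of thermodynamically feasible overall gas-to-product conversions.

A design is one net conversion equation with signed molar coefficients:
substrates negative, products positive.  The designer solves a linear
program over those coefficients for a fixed target amount (default 10 C-mol
of product) and a fixed ferric uptake F:

* per-element balance for C, H, O, N, S, P, Fe;
* charge balance;
* gases (CH4, CO, CO2) are substrate-only; water and protons are free in
  sign; hydrogenphosphate, ammonium and hydrogen sulfide are substrate-only
  and enabled only when the product actually contains P, N or S;
* the acceptor couple is pinned at (-F, +F);
* every coefficient magnitude is capped by a bound B (default 10);
* the overall standard transformed Gibbs energy of the conversion must not
  exceed a threshold (default 0 kcal).

The objective maximizes the coefficient magnitude of one named species
(a gas, the target, or a co-product).  Among alternate optima a secondary
solve minimizes |s_H2O| + |s_H+| so reported designs are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from gasferm.compounds import Compound, Registry, load_registry
from gasferm.thermo import ThermoTable, delta_g_of_coefficients, load_thermo_table

#: Elements balanced in every design.
BALANCED_ELEMENTS = ("C", "H", "O", "N", "S", "P", "Fe")

GASES = ("ch4", "co", "co2")

#: helper id -> element that gates it on.
GATED_HELPERS = {"hpo4": "P", "nh4": "N", "h2s": "S"}
FREE_HELPERS = ("h2o", "h")

BALANCE_TOL = 1e-6


class DesignError(ValueError):
    """Invalid design problem specification."""


@dataclass(frozen=True)
class DesignProblem:
    """Specification of one overall-conversion LP instance.

    ``target_amount`` defaults to 10/nC so the product carries 10 C-mol.
    ``objective`` names the species whose coefficient magnitude is
    maximized.  ``dg_threshold=math.inf`` disables the thermodynamic
    constraint (balance-only design).
    """

    target: str
    objective: str
    ferric: float = 0.0
    target_amount: float | None = None  # None -> 10 / nC(target)
    acceptor_pair: tuple[str, str] = ("fe3", "fe2")
    allowed_gases: tuple[str, ...] = GASES
    bound: float = 10.0
    dg_threshold: float = 0.0
    coproduct: str | None = None
    coproduct_amount_free: bool = True
    #: gas id -> fixed signed coefficient (design_from_composition)
    fixed_gases: Mapping[str, float] | None = None
    #: slack around fixed gas uptakes; published compositions are rounded to
    #: three decimals, so exact equality would be unsatisfiable
    composition_tol: float = 5e-3
    #: gas id -> (lo, hi) signed-coefficient box (ternary scan)
    gas_boxes: Mapping[str, tuple[float, float]] | None = None
    #: if True the target amount is a variable in [0, bound] (and usually
    #: the objective); ``target_amount`` is then ignored.
    target_free: bool = False
    #: if True the ferric level is a variable in [0, acceptor_bound].
    ferric_free: bool = False
    acceptor_bound: float | None = None  # None -> bound

    def __post_init__(self):
        if self.bound <= 0:
            raise DesignError("coefficient bound must be positive")
        if self.ferric < 0:
            raise DesignError("ferric level must be non-negative")
        if not self.allowed_gases:
            raise DesignError("at least one gas substrate must be allowed")
        objective_pool = set(self.allowed_gases) | {self.target}
        if self.coproduct:
            objective_pool.add(self.coproduct)
        if self.fixed_gases:
            objective_pool |= set(self.fixed_gases)
        if self.objective not in objective_pool:
            raise DesignError(
                f"objective species {self.objective!r} is not part of the design"
            )
        if self.coproduct is not None and self.coproduct == self.target:
            raise DesignError("co-product must differ from the main product")

    def resolved_amount(self, registry: Registry) -> float:
        if self.target_amount is not None:
            if self.target_amount <= 0:
                raise DesignError("target amount must be positive")
            return self.target_amount
        n_c = registry[self.target].n("C")
        if n_c < 1:
            raise DesignError(f"target {self.target!r} contains no carbon")
        return 10.0 / n_c


@dataclass(frozen=True)
class OverallDesign:
    """Solved overall conversion: signed coefficients plus diagnostics.

    ``status`` is ``"optimal"`` or ``"infeasible"``; for infeasible problems
    ``infeasibility`` distinguishes ``"balance"`` (no elementally/charge
    balanced design exists at all) from ``"thermo"`` (balanced designs exist
    but none meets the Gibbs-energy threshold).
    """

    coefficients: Mapping[str, float]
    objective_value: float
    delta_g: float | None
    status: str
    infeasibility: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        """Coefficients rounded for reporting (3 decimals by convention)."""
        return {
            cid: round(s, ndigits)
            for cid, s in self.coefficients.items()
            if abs(round(s, ndigits)) > 0
        }


@dataclass(frozen=True)
class FeasibilityPoint:
    f_ch4: float
    f_co: float
    f_co2: float
    ferric: float
    feasible: bool


@dataclass(frozen=True)
class FeasibilityMap:
    """Normalized gas-composition feasibility flags over a ferric grid."""

    points: Sequence[FeasibilityPoint]
    target: str
    step: float

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)

    def feasible_points(self) -> list[FeasibilityPoint]:
        return [p for p in self.points if p.feasible]


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------


@dataclass
class _Column:
    cid: str
    lo: float
    hi: float


def _helper_ids(target: Compound, coproduct: Compound | None) -> list[str]:
    """Gated helpers enabled for this product set, plus the free helpers."""
    need = dict(target.formula)
    if coproduct is not None:
        for el, n in coproduct.formula.items():
            need[el] = need.get(el, 0) + n
    enabled = [hid for hid, el in GATED_HELPERS.items() if need.get(el, 0) > 0]
    return list(FREE_HELPERS) + enabled


def _build_lp(problem: DesignProblem, registry: Registry, table: ThermoTable | None):
    """Assemble columns, fixed contributions and constraint matrices.

    Returns (columns, A_eq, b_eq, thermo_row, thermo_rhs, fixed) where
    ``fixed`` maps species id -> pinned signed coefficient.
    """
    target = registry[problem.target]
    coproduct = registry[problem.coproduct] if problem.coproduct else None
    ox_id, red_id = problem.acceptor_pair
    ox, red = registry[ox_id], registry[red_id]
    if ox.formula != red.formula or ox.charge == red.charge:
        raise DesignError("acceptor couple must share a formula and differ in charge")
    B = problem.bound
    acceptor_bound = problem.acceptor_bound if problem.acceptor_bound is not None else B

    fixed: dict[str, float] = {}
    columns: list[_Column] = []

    # target
    if problem.target_free:
        columns.append(_Column(target.id, 0.0, B))
    else:
        fixed[target.id] = problem.resolved_amount(registry)

    # gases
    fixed_gases = dict(problem.fixed_gases or {})
    boxes = dict(problem.gas_boxes or {})
    for gid in problem.allowed_gases:
        if gid not in registry:
            raise DesignError(f"unknown gas {gid!r}")
        if gid in fixed_gases:
            amt = fixed_gases.pop(gid)
            if amt < 0:
                raise DesignError("fixed gas amounts are uptakes, given as >= 0")
            tol = problem.composition_tol
            columns.append(
                _Column(gid, max(-amt - tol, -B), min(-amt + tol, 0.0))
            )
        elif gid in boxes:
            lo, hi = boxes.pop(gid)
            columns.append(_Column(gid, max(lo, -B), min(hi, 0.0)))
        else:
            columns.append(_Column(gid, -B, 0.0))
    if fixed_gases:
        raise DesignError(f"fixed amounts given for disallowed gases {sorted(fixed_gases)}")
    if boxes:
        raise DesignError(f"boxes given for disallowed gases {sorted(boxes)}")

    # helpers
    for hid in _helper_ids(target, coproduct):
        if hid in FREE_HELPERS:
            columns.append(_Column(hid, -B, B))
        else:
            columns.append(_Column(hid, -B, 0.0))

    # acceptor couple
    if problem.ferric_free:
        columns.append(_Column(ox.id, -acceptor_bound, 0.0))
        columns.append(_Column(red.id, 0.0, acceptor_bound))
    else:
        if problem.ferric > acceptor_bound + 1e-12:
            raise DesignError("ferric level exceeds the acceptor bound")
        fixed[ox.id] = -problem.ferric
        fixed[red.id] = +problem.ferric

    # coproduct
    if coproduct is not None:
        columns.append(_Column(coproduct.id, 0.0, B))

    col_index = {c.cid: i for i, c in enumerate(columns)}
    n = len(columns)

    rows = []
    rhs = []
    for el in BALANCED_ELEMENTS:
        row = np.array([registry[c.cid].n(el) for c in columns], dtype=float)
        const = sum(registry[cid].n(el) * s for cid, s in fixed.items())
        if np.any(row != 0.0) or abs(const) > 0:
            rows.append(row)
            rhs.append(-const)
    # charge
    row = np.array([registry[c.cid].charge for c in columns], dtype=float)
    const = sum(registry[cid].charge * s for cid, s in fixed.items())
    rows.append(row)
    rhs.append(-const)
    # acceptor coupling when ferric is free: s_ox + s_red = 0
    if problem.ferric_free:
        row = np.zeros(n)
        row[col_index[ox.id]] = 1.0
        row[col_index[red.id]] = 1.0
        rows.append(row)
        rhs.append(0.0)

    A_eq = np.vstack(rows) if rows else np.zeros((0, n))
    b_eq = np.array(rhs)

    thermo_row = thermo_rhs = None
    if table is not None and math.isfinite(problem.dg_threshold):
        thermo_row = np.array(
            [0.0 if c.cid == table.proton_id else table[c.cid] for c in columns]
        )
        fixed_dg = delta_g_of_coefficients(fixed, table)
        thermo_rhs = problem.dg_threshold - fixed_dg

    return columns, A_eq, b_eq, thermo_row, thermo_rhs, fixed


def _run_linprog(c, A_ub, b_ub, A_eq, b_eq, bounds):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )


def _solve(problem: DesignProblem, registry: Registry, table: ThermoTable | None,
           feasibility_only: bool = False) -> OverallDesign:
    columns, A_eq, b_eq, thermo_row, thermo_rhs, fixed = _build_lp(
        problem, registry, table
    )
    n = len(columns)
    col_index = {c.cid: i for i, c in enumerate(columns)}
    bounds = [(c.lo, c.hi) for c in columns]

    c_obj = np.zeros(n)
    if not feasibility_only:
        j = col_index.get(problem.objective)
        if j is None:
            # objective species is pinned; any feasible point is optimal
            pass
        else:
            # maximize magnitude: gases/substrates head negative, products positive
            sense = 1.0 if columns[j].hi <= 0 else -1.0
            c_obj[j] = sense

    A_ub = b_ub = None
    if thermo_row is not None:
        A_ub = thermo_row.reshape(1, -1)
        b_ub = np.array([thermo_rhs])

    res = _run_linprog(c_obj, A_ub, b_ub, A_eq, b_eq, bounds)
    if res.status != 0:
        if res.status == 3:
            raise RuntimeError(
                "unbounded design LP: the coefficient bound failed to bind"
            )
        kind = "balance"
        if thermo_row is not None:
            relaxed = _run_linprog(np.zeros(n), None, None, A_eq, b_eq, bounds)
            if relaxed.status == 0:
                kind = "thermo"
        return OverallDesign({}, 0.0, None, "infeasible", kind)

    x = res.x
    # deterministic reporting: re-solve minimizing |s_H2O| + |s_H+| with the
    # primary objective pinned at its optimum
    tie_ids = [h for h in FREE_HELPERS if h in col_index]
    j = col_index.get(problem.objective)
    if tie_ids and j is not None and not feasibility_only:
        m = len(tie_ids)
        c2 = np.concatenate([np.zeros(n), np.ones(m)])
        A_eq2 = np.hstack([A_eq, np.zeros((A_eq.shape[0], m))])
        pin = np.zeros(n + m)
        pin[j] = 1.0
        A_eq2 = np.vstack([A_eq2, pin])
        b_eq2 = np.concatenate([b_eq, [x[j]]])
        ub_rows, ub_rhs = [], []
        if thermo_row is not None:
            ub_rows.append(np.concatenate([thermo_row, np.zeros(m)]))
            ub_rhs.append(thermo_rhs)
        for k, hid in enumerate(tie_ids):
            r1 = np.zeros(n + m)
            r1[col_index[hid]] = 1.0
            r1[n + k] = -1.0
            ub_rows.append(r1)  # x - t <= 0
            r2 = np.zeros(n + m)
            r2[col_index[hid]] = -1.0
            r2[n + k] = -1.0
            ub_rows.append(r2)  # -x - t <= 0
            ub_rhs.append(0.0)
            ub_rhs.append(0.0)
        bounds2 = bounds + [(0.0, None)] * m
        res2 = _run_linprog(
            c2, np.vstack(ub_rows), np.array(ub_rhs), A_eq2, b_eq2, bounds2
        )
        if res2.status == 0:
            x = res2.x[:n]

    coeffs = dict(fixed)
    for col, v in zip(columns, x):
        coeffs[col.cid] = float(v)
    _validate_balances(coeffs, registry)

    dg = delta_g_of_coefficients(coeffs, table) if table is not None else None
    obj_val = abs(coeffs.get(problem.objective, 0.0))
    return OverallDesign(coeffs, obj_val, dg, "optimal")


def _validate_balances(coeffs: Mapping[str, float], registry: Registry) -> None:
    """Assert element and charge balances close to < 1e-6 on every solve."""
    for el in BALANCED_ELEMENTS:
        resid = sum(registry[cid].n(el) * s for cid, s in coeffs.items())
        if abs(resid) > BALANCE_TOL:
            raise RuntimeError(f"{el} balance residual {resid:.2e} exceeds tolerance")
    resid = sum(registry[cid].charge * s for cid, s in coeffs.items())
    if abs(resid) > BALANCE_TOL:
        raise RuntimeError(f"charge balance residual {resid:.2e} exceeds tolerance")


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _defaults(registry, table):
    if registry is None:
        registry = load_registry()
    if table is None:
        table = load_thermo_table(registry=registry)
    return registry, table


def design_conversion(problem: DesignProblem, registry: Registry | None = None,
                      table: ThermoTable | None = None) -> OverallDesign:
    """Solve one overall-conversion LP and return the signed coefficients."""
    registry, table = _defaults(registry, table)
    return _solve(problem, registry, table)


def _feasible(problem: DesignProblem, registry, table) -> bool:
    return _solve(problem, registry, table, feasibility_only=True).optimal


def scan_ternary(target: str, ferric_grid: Sequence[float], step: float = 0.05,
                 registry: Registry | None = None, table: ThermoTable | None = None,
                 bound: float = 10.0, dg_threshold: float = 0.0) -> FeasibilityMap:
    """Feasibility of gas compositions on a simplex grid, per ferric level.

    Compositions are fractions of total gas moles (all three gases carry one
    carbon, so these equal carbon fractions).  A grid point is flagged
    feasible when a fully balanced, thermodynamically feasible design exists
    whose gas coefficients lie within half a grid step of the nominal
    composition; exact on-grid ratios are measure-zero because water,
    protons and helpers close the remaining balances.
    """
    if len(ferric_grid) == 0:
        raise DesignError("empty ferric grid")
    if any(f < 0 for f in ferric_grid):
        raise DesignError("ferric grid values must be >= 0")
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise DesignError(f"step {step} does not divide 1 evenly")
    registry, table = _defaults(registry, table)

    half = 10.0 * step / 2.0  # half grid step, on the 10 C-mol basis
    points: list[FeasibilityPoint] = []
    for F in sorted(ferric_grid):
        for i in range(n + 1):
            for jj in range(n + 1 - i):
                k = n - i - jj
                fracs = (i / n, jj / n, k / n)
                boxes = {}
                for gid, f in zip(GASES, fracs):
                    nominal = -10.0 * f
                    boxes[gid] = (nominal - half, min(nominal + half, 0.0))
                problem = DesignProblem(
                    target=target,
                    objective=GASES[0],
                    ferric=F,
                    bound=bound,
                    dg_threshold=dg_threshold,
                    gas_boxes=boxes,
                )
                ok = _feasible(problem, registry, table)
                points.append(FeasibilityPoint(*fracs, float(F), ok))
    return FeasibilityMap(tuple(points), target, step)


def ferric_limits(target: str, registry: Registry | None = None,
                  table: ThermoTable | None = None, bound: float = 10.0,
                  acceptor_bound: float | None = None, dg_threshold: float = 0.0,
                  tol: float = 0.01) -> tuple[float | None, float | None]:
    """Minimum and maximum ferric level admitting any feasible design.

    Bisection to ``tol`` (default 0.01 mol) on the existence of a feasible
    coefficient vector; the maximum respects the coefficient bound.  Returns
    ``(None, None)`` when no ferric level in [0, acceptor_bound] is feasible.
    """
    registry, table = _defaults(registry, table)
    hi_cap = acceptor_bound if acceptor_bound is not None else bound

    def feas(F: float) -> bool:
        problem = DesignProblem(
            target=target, objective=GASES[0], ferric=F, bound=bound,
            dg_threshold=dg_threshold, acceptor_bound=hi_cap,
        )
        return _feasible(problem, registry, table)

    if hi_cap == 0:
        return (0.0, 0.0) if feas(0.0) else (None, None)

    n_grid = max(int(round(hi_cap / 0.5)), 1)
    grid = [hi_cap * i / n_grid for i in range(n_grid + 1)]
    flags = [feas(F) for F in grid]
    if not any(flags):
        return (None, None)

    first = next(i for i, ok in enumerate(flags) if ok)
    if first == 0:
        fmin = 0.0
    else:
        lo, hi = grid[first - 1], grid[first]
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if feas(mid):
                hi = mid
            else:
                lo = mid
        fmin = hi

    last = max(i for i, ok in enumerate(flags) if ok)
    if last == len(grid) - 1:
        fmax = grid[-1]
    else:
        lo, hi = grid[last], grid[last + 1]
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if feas(mid):
                lo = mid
            else:
                hi = mid
        fmax = lo
    return (fmin, fmax)


def max_carbon_fraction(target: str, gas: str, registry: Registry | None = None,
                        table: ThermoTable | None = None, bound: float = 10.0,
                        dg_threshold: float = 0.0,
                        allowed_gases: tuple[str, ...] = GASES) -> float:
    """Maximum fraction of product carbon suppliable by one named gas.

    The ferric level is left free in [0, bound] (one LP over the whole
    acceptor range), the named gas coefficient magnitude is maximized, and
    the result is carbon moles from that gas divided by the 10 C-mol basis.
    """
    if gas not in allowed_gases:
        raise DesignError(f"gas {gas!r} is not in the allowed set {allowed_gases}")
    registry, table = _defaults(registry, table)
    problem = DesignProblem(
        target=target, objective=gas, bound=bound, dg_threshold=dg_threshold,
        allowed_gases=allowed_gases, ferric_free=True,
    )
    design = _solve(problem, registry, table)
    if not design.optimal:
        return 0.0
    return design.objective_value * registry[gas].n("C") / 10.0


@dataclass(frozen=True)
class CoproductDesign:
    """A co-production design: main product fixed, co-product maximized."""

    design: OverallDesign
    main: str
    coproduct: str
    coproduct_amount: float
    coproduct_fraction: float  # co-product share of total product moles
    co_to_ch4_ratio: float | None  # CO:CH4 uptake ratio, None if no CH4 uptake


def design_coproduct(main: str, coproduct: str, ferric: float,
                     registry: Registry | None = None,
                     table: ThermoTable | None = None,
                     main_amount: float = 1.0, bound: float = 10.0,
                     dg_threshold: float = 0.0,
                     allowed_gases: tuple[str, ...] = ("ch4", "co")) -> CoproductDesign:
    """Fix the main product (default 1 mol) and maximize a co-product.

    Follows the alcohol co-production analysis: CH4 and CO are the carbon
    sources by default and the CO:CH4 uptake ratio is reported alongside the
    co-product share of total product.
    """
    registry, table = _defaults(registry, table)
    if coproduct == main:
        raise DesignError("co-product must differ from the main product")
    problem = DesignProblem(
        target=main, objective=coproduct, ferric=ferric,
        target_amount=main_amount, coproduct=coproduct, bound=bound,
        dg_threshold=dg_threshold, allowed_gases=allowed_gases,
    )
    design = _solve(problem, registry, table)
    if not design.optimal:
        return CoproductDesign(design, main, coproduct, 0.0, 0.0, None)
    x = design.coefficients.get(coproduct, 0.0)
    frac = x / (x + main_amount) if x + main_amount > 0 else 0.0
    ch4_up = -design.coefficients.get("ch4", 0.0)
    co_up = -design.coefficients.get("co", 0.0)
    ratio = co_up / ch4_up if ch4_up > 1e-9 else None
    return CoproductDesign(design, main, coproduct, x, frac, ratio)


def design_from_composition(target: str, gas_amounts: Mapping[str, float],
                            ferric: float, registry: Registry | None = None,
                            table: ThermoTable | None = None, bound: float = 10.0,
                            dg_threshold: float = 0.0) -> OverallDesign:
    """Fix the gas uptakes and maximize the target amount.

    ``gas_amounts`` maps gas id -> uptake in mol (>= 0); by convention the
    amounts carry 10 C-mol of gas in total.  A composition that cannot
    support any product (optimum 0) is reported as infeasible.
    """
    registry, table = _defaults(registry, table)
    if any(v < 0 for v in gas_amounts.values()):
        raise DesignError("gas amounts must be >= 0")
    unknown = set(gas_amounts) - set(GASES)
    if unknown:
        raise DesignError(f"unknown gases {sorted(unknown)}")
    problem = DesignProblem(
        target=target, objective=target, ferric=ferric, bound=bound,
        dg_threshold=dg_threshold, fixed_gases=dict(gas_amounts),
        allowed_gases=tuple(g for g in GASES if g in gas_amounts),
        target_free=True,
    )
    design = _solve(problem, registry, table)
    if design.optimal and design.objective_value < 1e-9:
        return OverallDesign({}, 0.0, None, "infeasible", "balance")
    return design


def table2_conditions() -> list[DesignProblem]:
    """The thirty published optimization conditions (target, objective, F).

    Ferric levels are the printed ones; each problem re-creates one row of
    the published design table under the packaged registry.
    """
    rows = {
        "pyr": (6.66, 3.5, 0.0),
        "pep": (10.0, 5.0, 0.14),
        "gap": (10.0, 7.0, 3.04),
        "oxa": (5.0, 3.0, 0.0),
        "e4p": (10.0, 7.0, 2.85),
        "r5p": (10.0, 6.5, 2.55),
        "2kg": (6.0, 3.0, 0.0),
        "g6p": (10.0, 6.5, 2.474),
        "aca": (8.26, 5.0, 0.117),
        "sca": (8.0, 4.5, 0.0),
    }
    problems = []
    for target, (f_ch4, f_co2, f_co) in rows.items():
        for objective, F in (("ch4", f_ch4), ("co2", f_co2), ("co", f_co)):
            problems.append(DesignProblem(target=target, objective=objective, ferric=F))
    return problems
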