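"""Synthetic fixtures: random compound sets, brute-force design oracle,
planted metabolic networks.

Everything is driven by one explicit seed; no global random state is
touched.  The brute-force oracle enumerates the free directions of the
balance system on a grid and closes the remaining coefficients by exact
linear solve, giving an LP-independent check of the conversion designer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iter_product

import numpy as np

from gasferm.compounds import Compound, Registry
from gasferm.design import (
    BALANCED_ELEMENTS,
    DesignProblem,
    OverallDesign,
    _build_lp,
)
from gasferm.thermo import ThermoTable, delta_g_of_coefficients

#: dGf' sampling interval (kcal/mol) for random compounds: wide enough that
#: random design problems land on both sides of the feasibility threshold.
DG_SAMPLING_RANGE = (-400.0, 50.0)

GRID_GUARD = 10_000_000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generators; the seed fixes all outputs."""

    seed: int = 0
    n_compounds: int = 20
    #: element -> (lo, hi) inclusive count range for random formulas
    element_ranges: tuple = (
        ("C", (1, 6)),
        ("H", (1, 12)),
        ("O", (0, 8)),
        ("N", (0, 2)),
        ("P", (0, 1)),
        ("S", (0, 1)),
    )
    charge_range: tuple[int, int] = (-3, 1)
    dg_range: tuple[float, float] = DG_SAMPLING_RANGE
    #: planted-network shape
    n_chain: int = 4
    bottleneck: float = 3.0
    parallel_branch: bool = False

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_compounds(spec: SyntheticSpec) -> Registry:
    """Reproducible random compounds with parseable formulas and dGf' values."""
    ranges = dict(spec.element_ranges)
    if "C" in ranges and ranges["C"][1] < 1:
        raise ValueError("element ranges must allow at least one carbon")
    for el, (lo, hi) in ranges.items():
        if lo > hi or lo < 0:
            raise ValueError(f"impossible range for {el}: ({lo}, {hi})")
    rng = spec.rng()
    reg = Registry()
    lo_dg, hi_dg = spec.dg_range
    for i in range(spec.n_compounds):
        formula = {}
        for el, (lo, hi) in ranges.items():
            n = int(rng.integers(lo, hi + 1))
            if n > 0:
                formula[el] = n
        if formula.get("C", 0) == 0:
            formula["C"] = 1
        if formula.get("H", 0) == 0:
            formula["H"] = 1
        reg.add(
            Compound(
                id=f"syn{i:03d}",
                name=f"synthetic compound {i}",
                formula=formula,
                charge=int(rng.integers(spec.charge_range[0], spec.charge_range[1] + 1)),
                roles=frozenset({"target_product"}),
                dg_f_prime=float(rng.uniform(lo_dg, hi_dg)),
            )
        )
    return reg


# ---------------------------------------------------------------------------
# brute-force design oracle
# ---------------------------------------------------------------------------


def brute_force_design(problem: DesignProblem, registry: Registry,
                       table: ThermoTable | None, resolution: float = 0.01
                       ) -> OverallDesign:
    """Grid-enumeration oracle for :func:`gasferm.design.design_conversion`.

    The balance system (elements + charge) over the variable coefficients
    has a small null space; the oracle enumerates the gas/co-product
    coordinates spanning that null space on a grid of the given resolution
    and solves the remaining coefficients exactly, keeping the best point
    that satisfies sign restrictions, bounds and the Gibbs threshold.
    Guarded at 1e7 grid points.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    import math

    columns, A_eq, b_eq, thermo_row, thermo_rhs, fixed = _build_lp(
        problem, registry, table if math.isfinite(problem.dg_threshold) else None
    )
    n = len(columns)
    ids = [c.cid for c in columns]
    col_index = {cid: i for i, cid in enumerate(ids)}

    rank = np.linalg.matrix_rank(A_eq)
    dof = n - rank
    if dof < 0:
        raise RuntimeError("over-determined balance system")

    # enumerate gas / co-product columns; putting the objective first keeps
    # the objective granularity at exactly one grid step
    enum_candidates = [c.cid for c in columns
                       if c.cid in problem.allowed_gases or c.cid == problem.coproduct]
    enum_candidates.sort(key=lambda cid: cid != problem.objective)
    enum_ids: list[str] = []
    base_cols = list(range(n))
    for cid in enum_candidates:
        if len(enum_ids) == dof:
            break
        trial = [i for i in base_cols if ids[i] not in enum_ids + [cid]]
        if np.linalg.matrix_rank(A_eq[:, trial]) == rank:
            enum_ids.append(cid)
    if len(enum_ids) < dof:
        raise RuntimeError("could not isolate free directions for enumeration")

    enum_idx = [col_index[cid] for cid in enum_ids]
    solve_idx = [i for i in range(n) if i not in enum_idx]
    A_enum = A_eq[:, enum_idx]
    A_solve = A_eq[:, solve_idx]

    grids = []
    for cid in enum_ids:
        col = columns[col_index[cid]]
        lo, hi = col.lo, col.hi
        steps = int(np.floor((hi - lo) / resolution + 1e-9)) + 1
        grids.append(np.linspace(lo, lo + (steps - 1) * resolution, steps))
    total = int(np.prod([len(g) for g in grids])) if grids else 1
    if total > GRID_GUARD:
        raise ValueError(f"grid of {total} points exceeds the {GRID_GUARD} guard")

    j_obj = col_index.get(problem.objective)
    best_val = -np.inf
    best_x = None
    lo_b = np.array([columns[i].lo for i in solve_idx])
    hi_b = np.array([columns[i].hi for i in solve_idx])
    tol = 1e-6

    for point in iter_product(*grids) if grids else [()]:
        rhs = b_eq - (A_enum @ np.array(point) if grids else 0.0)
        sol, residuals, _, _ = np.linalg.lstsq(A_solve, rhs, rcond=None)
        if np.linalg.norm(A_solve @ sol - rhs) > tol:
            continue
        if np.any(sol < lo_b - tol) or np.any(sol > hi_b + tol):
            continue
        x = np.zeros(n)
        x[enum_idx] = point
        x[solve_idx] = sol
        if thermo_row is not None and thermo_row @ x > thermo_rhs + 1e-9:
            continue
        if j_obj is not None:
            val = abs(x[j_obj])
        else:
            val = 0.0
        if val > best_val:
            best_val = val
            best_x = x

    if best_x is None:
        return OverallDesign({}, 0.0, None, "infeasible", None)
    coeffs = dict(fixed)
    for cid, v in zip(ids, best_x):
        coeffs[cid] = float(v)
    dg = delta_g_of_coefficients(coeffs, table) if table is not None else None
    return OverallDesign(coeffs, float(best_val), dg, "optimal")


# ---------------------------------------------------------------------------
# planted metabolic networks
# ---------------------------------------------------------------------------


def generate_planted_network(spec: SyntheticSpec):
    """A linear-chain model with a planted bottleneck (known FBA optimum).

    ``A_in -> m0 -> m1 -> ... -> B_out``; the first exchange is capped at
    ``spec.bottleneck`` so the optimal objective flux equals it exactly.
    With ``parallel_branch`` a duplicate of one interior step is added, so
    each duplicate spans [0, optimum] under FVA at fraction 1.
    """
    from gasferm.fba import MetabolicModel, Reaction

    if spec.n_chain < 2:
        raise ValueError("chain needs at least two metabolites")
    mets = [f"m{i}" for i in range(spec.n_chain)]
    rxns = [
        Reaction("R_in", {mets[0]: 1.0}, 0.0, spec.bottleneck),
    ]
    for i in range(spec.n_chain - 1):
        rxns.append(Reaction(f"R{i}", {mets[i]: -1.0, mets[i + 1]: 1.0}, 0.0, 1000.0))
    if spec.parallel_branch:
        rxns.append(Reaction("R0_dup", {mets[0]: -1.0, mets[1]: 1.0}, 0.0, 1000.0))
    rxns.append(Reaction("R_out", {mets[-1]: -1.0}, 0.0, 1000.0))
    return MetabolicModel(
        id=f"planted-{spec.seed}",
        metabolites={m: "c" for m in mets},
        reactions=rxns,
        objective="R_out",
    )
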