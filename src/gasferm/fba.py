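"""Minimal constraint-based modeling engine: FBA, FVA, gas-design bounds.

Models are stoichiometric networks with flux bounds, read either from a
plain JSON schema (documented below) or from SBML Level 3 (fbc flux
bounds).  Exchange reactions follow the usual sign convention: uptake is
negative flux, secretion positive.  Fluxes are mol per 10 C-mol of gas fed,
the same basis the conversion designer uses.

JSON schema::

    {
      "id": str,
      "objective": reaction id,
      "metabolites": {met id: compartment tag, ...},
      "reactions": [
        {"id": str, "metabolites": {met id: signed coeff, ...},
         "lower_bound": float, "upper_bound": float, "annotation": str},
        ...
      ]
    }

An optional overall-thermodynamic-feasibility constraint can be imposed on
both FBA and FVA: one linear row over the exchange fluxes,
``sum_ex v_ex * dGf'(species) <= threshold`` (kcal), using a
:class:`~gasferm.thermo.ThermoTable`; exchange reactions are mapped to
species by the ``EX_<id>`` naming convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from gasferm.thermo import ThermoTable

STEADY_STATE_TOL = 1e-6


class ModelError(ValueError):
    """Malformed model file or inconsistent model."""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    annotation: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(f"reaction {self.id!r}: lower bound exceeds upper bound")


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[str, str]  # id -> compartment tag
    reactions: list[Reaction]
    objective: str
    description: str = ""

    def __post_init__(self):
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelError("duplicate reaction ids")
        referenced: set[str] = set()
        for r in self.reactions:
            unknown = set(r.stoichiometry) - set(self.metabolites)
            if unknown:
                raise ModelError(f"reaction {r.id!r} references unknown {sorted(unknown)}")
            referenced |= set(r.stoichiometry)
        orphan = set(self.metabolites) - referenced
        if orphan:
            raise ModelError(f"metabolites referenced by no reaction: {sorted(orphan)}")
        if self.objective not in set(rids):
            raise ModelError(f"objective reaction {self.objective!r} not in model")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions=[
                Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                         r.annotation)
                for r in self.reactions
            ],
            objective=self.objective,
            description=self.description,
        )

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        mids = list(self.metabolites)
        rids = [r.id for r in self.reactions]
        S = np.zeros((len(mids), len(rids)))
        mindex = {m: i for i, m in enumerate(mids)}
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[mindex[m], j] = c
        return S, mids, rids


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective_value: float

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


FluxRange = dict  # reaction id -> (min flux, max flux)


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------


def _model_from_dict(doc: dict) -> MetabolicModel:
    try:
        reactions = [
            Reaction(
                id=r["id"],
                stoichiometry={m: float(c) for m, c in r["metabolites"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                annotation=r.get("annotation", ""),
            )
            for r in doc["reactions"]
        ]
        return MetabolicModel(
            id=doc.get("id", "model"),
            metabolites=dict(doc["metabolites"]),
            reactions=reactions,
            objective=doc["objective"],
            description=doc.get("description", ""),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ModelError):
            raise
        raise ModelError(f"malformed model document: {exc}") from exc


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from JSON or SBML; the format defaults to the suffix."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ModelError(f"{path}: invalid JSON: {exc}") from exc
        return _model_from_dict(doc)
    if format == "sbml":
        return _read_sbml(path)
    raise ModelError(f"unsupported model format {format!r}")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        doc = {
            "id": model.id,
            "description": model.description,
            "objective": model.objective,
            "metabolites": model.metabolites,
            "reactions": [
                {
                    "id": r.id,
                    "metabolites": r.stoichiometry,
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "annotation": r.annotation,
                }
                for r in model.reactions
            ],
        }
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ModelError(f"unsupported model format {format!r}")


def _sanitize(sid: str) -> str:
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in sid)
    return out if out[:1].isalpha() or out[:1] == "_" else "_" + out


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text(encoding="utf-8"))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0 or doc.getModel() is None:
        raise ModelError(f"{path}: not a parseable SBML document")
    sbml_model = doc.getModel()
    mets = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        mets[sp.getId().removeprefix("M_")] = sp.getCompartment() or "c"
    fbc = sbml_model.getPlugin("fbc")
    objective = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        fo = fbc.getObjective(0)
        if fo.getNumFluxObjectives() > 0:
            objective = fo.getFluxObjective(0).getReaction().removeprefix("R_")
    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            sr = rx.getReactant(k)
            mid = sr.getSpecies().removeprefix("M_")
            stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for k in range(rx.getNumProducts()):
            sr = rx.getProduct(k)
            mid = sr.getSpecies().removeprefix("M_")
            stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        lb, ub = -1000.0, 1000.0
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None:
            plb = sbml_model.getParameter(rfbc.getLowerFluxBound() or "")
            pub = sbml_model.getParameter(rfbc.getUpperFluxBound() or "")
            if plb is not None:
                lb = plb.getValue()
            if pub is not None:
                ub = pub.getValue()
        elif rx.isSetReversible() and not rx.getReversible():
            lb = 0.0
        reactions.append(
            Reaction(rx.getId().removeprefix("R_"), stoich, lb, ub,
                     rx.getName() or "")
        )
    if objective is None:
        objective = reactions[-1].id
    return MetabolicModel(
        id=sbml_model.getId() or "sbml_model",
        metabolites=mets,
        reactions=reactions,
        objective=objective,
    )


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    m = doc.createModel()
    m.setId(_sanitize(model.id))
    mfbc = m.getPlugin("fbc")
    mfbc.setStrict(True)
    for comp in sorted(set(model.metabolites.values())):
        c = m.createCompartment()
        c.setId(_sanitize(comp))
        c.setConstant(True)
    for mid, comp in model.metabolites.items():
        sp = m.createSpecies()
        sp.setId("M_" + _sanitize(mid))
        sp.setCompartment(_sanitize(comp))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
    bounds: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds:
            pid = f"bnd_{len(bounds)}"
            p = m.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bounds[value] = pid
        return bounds[value]

    for r in model.reactions:
        rx = m.createReaction()
        rx.setId("R_" + _sanitize(r.id))
        rx.setName(r.annotation)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for mid, coeff in r.stoichiometry.items():
            sr = rx.createReactant() if coeff < 0 else rx.createProduct()
            sr.setSpecies("M_" + _sanitize(mid))
            sr.setStoichiometry(abs(coeff))
            sr.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(r.lower_bound))
        rfbc.setUpperFluxBound(bound_param(r.upper_bound))
    obj = mfbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction("R_" + _sanitize(model.objective))
    fo.setCoefficient(1.0)
    mfbc.setActiveObjectiveId("obj")
    libsbml.writeSBMLToFile(doc, str(path))


def toy_core_model() -> MetabolicModel:
    """The packaged toy reverse-methanogenesis core network."""
    ref = resources.files("gasferm.data").joinpath("toy_core_model.json")
    return _model_from_dict(json.loads(ref.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------


def _exchange_species(model: MetabolicModel) -> dict[str, str]:
    """Map exchange reaction id -> exchanged species id (EX_<id> convention)."""
    out = {}
    for r in model.reactions:
        if r.id.startswith("EX_") and len(r.stoichiometry) == 1:
            out[r.id] = next(iter(r.stoichiometry))
    return out


def _thermo_row(model: MetabolicModel, rids: Sequence[str], table: ThermoTable
                ) -> np.ndarray:
    """One row over fluxes: sum over exchanges of v * dGf'(species).

    Secretion (positive flux) counts the species as product, uptake as
    substrate, matching the signed-coefficient convention of the designer.
    """
    row = np.zeros(len(rids))
    ex = _exchange_species(model)
    for j, rid in enumerate(rids):
        if rid in ex:
            sid = ex[rid]
            if sid == table.proton_id:
                continue
            row[j] = table[sid]
    return row


def _solve_lp(model: MetabolicModel, c: np.ndarray,
              extra_ub: tuple[np.ndarray, float] | None,
              bounds_override: Mapping[str, tuple[float, float]] | None = None):
    S, _, rids = model.stoichiometric_matrix()
    bounds = []
    for r in model.reactions:
        if bounds_override and r.id in bounds_override:
            bounds.append(bounds_override[r.id])
        else:
            bounds.append((r.lower_bound, r.upper_bound))
    A_ub = b_ub = None
    if extra_ub is not None:
        A_ub = extra_ub[0].reshape(1, -1)
        b_ub = np.array([extra_ub[1]])
    return (
        linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(S.shape[0]),
                bounds=bounds, method="highs"),
        rids,
    )


def fba(model: MetabolicModel, objective: str | None = None,
        thermo_table: ThermoTable | None = None,
        dg_threshold: float = 0.0) -> FluxDistribution:
    """Maximize the objective flux subject to S v = 0 and bounds.

    With ``thermo_table`` the overall-conversion Gibbs energy implied by the
    exchange fluxes is constrained to ``<= dg_threshold`` kcal.
    """
    objective = objective or model.objective
    rids_all = [r.id for r in model.reactions]
    if objective not in rids_all:
        raise ModelError(f"objective reaction {objective!r} not in model")
    c = np.zeros(len(rids_all))
    c[rids_all.index(objective)] = -1.0  # linprog minimizes
    extra = None
    if thermo_table is not None:
        extra = (_thermo_row(model, rids_all, thermo_table), dg_threshold)
    res, rids = _solve_lp(model, c, extra)
    if res.status == 3:
        raise ModelError(f"objective {objective!r} is unbounded")
    if res.status != 0:
        raise ModelError("FBA infeasible under the given bounds")
    fluxes = {rid: float(v) for rid, v in zip(rids, res.x)}
    _assert_steady_state(model, fluxes)
    return FluxDistribution(fluxes, float(-res.fun))


def _assert_steady_state(model: MetabolicModel, fluxes: Mapping[str, float]) -> None:
    S, mids, rids = model.stoichiometric_matrix()
    v = np.array([fluxes[rid] for rid in rids])
    resid = S @ v
    worst = float(np.max(np.abs(resid))) if resid.size else 0.0
    if worst > STEADY_STATE_TOL:
        raise RuntimeError(f"steady-state residual {worst:.2e} exceeds tolerance")


def fva(model: MetabolicModel, fraction: float = 1.0,
        objective: str | None = None,
        thermo_table: ThermoTable | None = None,
        dg_threshold: float = 0.0,
        reactions: Sequence[str] | None = None) -> FluxRange:
    """Per-reaction flux ranges at >= ``fraction`` of the FBA optimum."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    objective = objective or model.objective
    sol = fba(model, objective, thermo_table, dg_threshold)
    floor = fraction * sol.objective_value
    rids_all = [r.id for r in model.reactions]
    extra = None
    if thermo_table is not None:
        extra = (_thermo_row(model, rids_all, thermo_table), dg_threshold)
    obj_rxn = model.reaction(objective)
    override = {objective: (max(obj_rxn.lower_bound, floor - 1e-9),
                            obj_rxn.upper_bound)}
    wanted = list(reactions) if reactions is not None else rids_all
    out: FluxRange = {}
    for rid in wanted:
        j = rids_all.index(rid)
        lohi = []
        for sense in (1.0, -1.0):
            c = np.zeros(len(rids_all))
            c[j] = sense
            res, _ = _solve_lp(model, c, extra, override)
            if res.status != 0:
                raise ModelError(f"FVA subproblem for {rid!r} failed")
            lohi.append(float(res.x[j]))
        out[rid] = (min(lohi), max(lohi))
    return out


def apply_gas_design(model: MetabolicModel, gas_amounts: Mapping[str, float],
                     ferric: float) -> MetabolicModel:
    """Fix gas-uptake exchange bounds to a designed composition (a copy).

    ``gas_amounts`` maps species id (e.g. ``ch4``) to uptake in mol; each
    corresponding ``EX_<id>`` reaction gets lower = upper = -amount.  The
    ferric exchange is fixed the same way.
    """
    if ferric < 0 or any(v < 0 for v in gas_amounts.values()):
        raise ValueError("uptake amounts must be >= 0")
    new = model.copy()
    ex = _exchange_species(new)
    by_species = {sid: rid for rid, sid in ex.items()}
    for sid, amount in {**gas_amounts, "fe3": ferric}.items():
        rid = by_species.get(sid)
        if rid is None:
            raise ModelError(f"no exchange reaction for species {sid!r}")
        r = new.reaction(rid)
        r.lower_bound = -float(amount)
        r.upper_bound = -float(amount)
    return new


def flux_split(model: MetabolicModel, solution: FluxDistribution,
               metabolite: str, consumers: Sequence[str]) -> dict[str, float]:
    """Fraction of a metabolite's total consumption through each consumer.

    Consumption by reaction r is ``max(0, -c_mr * v_r)``; fractions are
    normalized over the named consumers and sum to 1.
    """
    rates = {}
    for rid in consumers:
        r = model.reaction(rid)
        coeff = r.stoichiometry.get(metabolite, 0.0)
        rates[rid] = max(0.0, -coeff * solution.fluxes.get(rid, 0.0))
    total = sum(rates.values())
    if total <= STEADY_STATE_TOL:
        raise ValueError(f"no consumption of {metabolite!r} by {list(consumers)}")
    return {rid: rate / total for rid, rate in rates.items()}
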