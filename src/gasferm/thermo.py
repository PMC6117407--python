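"""Standard transformed Gibbs energies and the overall-dG feasibility test.

All energies are kcal/mol, standard transformed at the conditions carried by
the table (default pH 7.0, 298.15 K, ionic strength 0.25 M).  Under the
transformed convention the proton has a formation energy of exactly zero, so
the H+ coefficient of a design never moves the overall dG.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

from gasferm.compounds import Registry, load_registry

if TYPE_CHECKING:  # pragma: no cover
    from gasferm.design import OverallDesign

KJ_PER_KCAL = 4.184


class MissingEnergyError(KeyError):
    """A compound with a nonzero coefficient has no formation energy."""


@dataclass(frozen=True)
class ThermoTable:
    """Mapping compound id -> dGf' (kcal/mol) plus the condition metadata."""

    energies: Mapping[str, float]
    ph: float = 7.0
    temperature: float = 298.15  # K
    ionic_strength: float = 0.25  # M
    proton_id: str = "h"

    def __post_init__(self):
        e = dict(self.energies)
        e.setdefault(self.proton_id, 0.0)
        if abs(e[self.proton_id]) > 1e-12:
            raise ValueError("transformed convention requires dGf'(H+) = 0")
        object.__setattr__(self, "energies", e)

    def __contains__(self, cid: str) -> bool:
        return cid in self.energies

    def __getitem__(self, cid: str) -> float:
        try:
            return self.energies[cid]
        except KeyError:
            raise MissingEnergyError(f"no dGf' entry for compound {cid!r}") from None


def load_thermo_table(path: str | Path | None = None, registry: Registry | None = None,
                      **conditions) -> ThermoTable:
    """Build a :class:`ThermoTable`.

    Precedence: an explicit two-column TSV (``id``, ``dg_f_prime_kcal_mol``),
    else the ``dg_f_prime`` column of ``registry``, else the packaged
    registry.
    """
    if path is not None:
        energies: dict[str, float] = {}
        for i, ln in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
            if not ln.strip() or ln.startswith("#"):
                continue
            cells = ln.rstrip("\n").split("\t")
            if cells[0] == "id":
                continue
            if len(cells) != 2:
                raise ValueError(f"{path}:{i + 1}: expected 2 columns")
            energies[cells[0]] = float(cells[1])
        return ThermoTable(energies, **conditions)
    if registry is None:
        registry = load_registry()
    return ThermoTable(
        {c.id: c.dg_f_prime for c in registry if c.dg_f_prime is not None}, **conditions
    )


def delta_g_of_coefficients(coefficients: Mapping[str, float], table: ThermoTable,
                            tol: float = 1e-12) -> float:
    """Overall dG (kcal) of a signed coefficient vector.

    Products carry positive and substrates negative coefficients, so the sum
    ``sum_i s_i dGf'(i)`` is the reaction Gibbs energy of the written
    conversion.  The proton is exempt from the coverage check (its
    transformed energy is identically zero).
    """
    total = 0.0
    for cid, s in coefficients.items():
        if abs(s) <= tol:
            continue
        if cid == table.proton_id:
            continue
        total += s * table[cid]
    return total


def overall_delta_g(design: "OverallDesign | Mapping[str, float]", table: ThermoTable) -> float:
    """Overall dG (kcal) of a design (or bare coefficient mapping)."""
    coeffs = getattr(design, "coefficients", design)
    return delta_g_of_coefficients(coeffs, table)


def is_feasible(design: "OverallDesign | Mapping[str, float]", table: ThermoTable,
                threshold: float = 0.0) -> bool:
    """True iff the overall dG of the design is <= ``threshold`` (kcal)."""
    return overall_delta_g(design, table) <= threshold
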