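"""Registry of chemical species: formulas, charges, roles, degree of reduction.

Formulas are Hill-style strings over the supported elements
(C, H, O, N, S, P, Fe); the ionic charge is carried separately and is never
folded into the element counts.

Degree-of-reduction convention
------------------------------
The per-carbon degree of reduction gamma is computed with the weight set

    C = +4, H = +1, O = -2, N = -3, P = +5, S = +6,   charge ignored,

i.e. available electrons are counted against the reference states CO2, H2O,
NH3, H3PO4 and H2SO4.  This weight set reproduces every tabulated value for
the ten precursor targets shipped in the default registry (the printed
values truncate, not round, the exact ratio: GAP 11/3 -> 3.66).  Iron
carries weight 0; it only ever appears in the acceptor couple.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: Elements the formula parser accepts, in Hill-ish display order.
SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "P", "S", "Fe")

#: Electron-count weights behind the degree-of-reduction convention.
REDUCTION_WEIGHTS = {"C": 4, "H": 1, "O": -2, "N": -3, "P": 5, "S": 6, "Fe": 0}

#: Role tags a compound may carry in a registry.
ROLES = frozenset(
    {
        "gas_substrate",
        "target_product",
        "helper",
        "acceptor_oxidized",
        "acceptor_reduced",
        "coproduct",
    }
)

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported chemical formulas."""


ElementVector = dict  # mapping element symbol -> non-negative int count


def parse_formula(text: str, charge: int = 0) -> ElementVector:
    """Parse a Hill-style formula into an element-count mapping.

    ``charge`` is accepted for interface symmetry but is *not* folded into
    the counts; it is validated to be an int and otherwise ignored.

    >>> parse_formula("C3H3O3", -1)
    {'C': 3, 'H': 3, 'O': 3}
    """
    if not isinstance(charge, int):
        raise FormulaError(f"charge must be an integer, got {charge!r}")
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: ElementVector = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed token at {text[pos:]!r} in {text!r}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unsupported element {sym!r} in {text!r}")
        n = int(num) if num else 1
        if n <= 0:
            raise FormulaError(f"zero count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
    if pos != len(text):
        raise FormulaError(f"malformed token at {text[pos:]!r} in {text!r}")
    if not counts:
        raise FormulaError(f"no elements parsed from {text!r}")
    return counts


def format_formula(formula: Mapping[str, int]) -> str:
    """Render an element vector back to a Hill-style string."""
    parts = []
    for sym in SUPPORTED_ELEMENTS:
        n = formula.get(sym, 0)
        if n == 1:
            parts.append(sym)
        elif n > 1:
            parts.append(f"{sym}{n}")
    return "".join(parts)


@dataclass(frozen=True)
class Compound:
    """A chemical species with formula, charge, role tags and optional dGf'."""

    id: str
    name: str
    formula: ElementVector
    charge: int
    roles: frozenset = field(default_factory=frozenset)
    dg_f_prime: float | None = None  # kcal/mol, standard transformed

    def __post_init__(self):
        bad = set(self.roles) - ROLES
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)} for compound {self.id!r}")
        if "gas_substrate" in self.roles and self.formula.get("C", 0) < 1:
            raise ValueError(f"gas substrate {self.id!r} must contain carbon")

    def n(self, element: str) -> int:
        return self.formula.get(element, 0)


def degree_of_reduction(compound: Compound) -> float:
    """Per-carbon degree of reduction of a carbon-containing compound.

    gamma = (4 nC + nH - 2 nO - 3 nN + 5 nP + 6 nS) / nC, charge ignored.
    """
    n_c = compound.n("C")
    if n_c < 1:
        raise ValueError(f"degree of reduction undefined for carbon-free {compound.id!r}")
    total = sum(REDUCTION_WEIGHTS[el] * n for el, n in compound.formula.items())
    return total / n_c


def tabulated_degree_of_reduction(compound: Compound) -> float:
    """Degree of reduction truncated to 2 decimals, the printed convention."""
    return math.floor(degree_of_reduction(compound) * 100.0) / 100.0


class Registry:
    """An id-keyed collection of :class:`Compound` records."""

    def __init__(self, compounds: Iterable[Compound] = ()):
        self._by_id: dict[str, Compound] = {}
        for c in compounds:
            self.add(c)

    def add(self, compound: Compound) -> None:
        if compound.id in self._by_id:
            raise ValueError(f"duplicate compound id {compound.id!r}")
        self._by_id[compound.id] = compound

    def __getitem__(self, cid: str) -> Compound:
        try:
            return self._by_id[cid]
        except KeyError:
            raise KeyError(f"unknown compound id {cid!r}") from None

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def ids(self) -> list[str]:
        return list(self._by_id)

    def with_role(self, role: str) -> list[Compound]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [c for c in self if role in c.roles]

    def acceptor_pair(self) -> tuple[Compound, Compound]:
        """Default (oxidized, reduced) acceptor couple of the registry."""
        ox = self.with_role("acceptor_oxidized")
        red = self.with_role("acceptor_reduced")
        if len(ox) != 1 or len(red) != 1:
            raise ValueError("registry must define exactly one acceptor couple")
        if ox[0].formula != red[0].formula or ox[0].charge == red[0].charge:
            raise ValueError("acceptor couple must share a formula and differ in charge")
        return ox[0], red[0]


_HEADER = ["id", "name", "formula", "charge", "roles", "dg_f_prime_kcal_mol"]


def load_registry(path: str | Path | None = None) -> Registry:
    """Load a compound registry from a TSV file.

    With no argument the registry packaged with the distribution is loaded
    (the three gases, helper species, the Fe3+/Fe2+ couple, the ten
    precursor targets and a set of alcohol/acetate co-products).

    The file must carry the header ``id name formula charge roles
    dg_f_prime_kcal_mol``; roles are ``|``-separated.  Any malformed row
    aborts the whole load.
    """
    if path is None:
        ref = resources.files("gasferm.data").joinpath("compounds.tsv")
        text = ref.read_text(encoding="utf-8")
        source = "packaged registry"
    else:
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        source = str(path)
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        logger.warning("empty registry file %s", source)
        return Registry()
    header = lines[0].rstrip("\n").split("\t")
    if header != _HEADER:
        raise ValueError(f"{source}: expected header {_HEADER}, got {header}")
    reg = Registry()
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.rstrip("\n").split("\t")
        if len(cells) != len(_HEADER):
            raise ValueError(f"{source}:{i}: expected {len(_HEADER)} columns")
        cid, name, formula, charge, roles, dg = cells
        dgval = None if dg.strip() in ("", "NA", "nan") else float(dg)
        reg.add(
            Compound(
                id=cid.strip(),
                name=name.strip(),
                formula=parse_formula(formula, int(charge)),
                charge=int(charge),
                roles=frozenset(r for r in roles.split("|") if r),
                dg_f_prime=dgval,
            )
        )
    return reg
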