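"""Small stoichiometric reaction networks with food and waste species.

A network is a set of reactions over species tokens.  Each species plays
exactly one of three roles:

``internal``
    produced and consumed by the network; the candidates for replicator
    status live here.
``food``
    externally supplied input (the :math:`\\Sigma x_i` of a cycle turn);
    treated as an unlimited reservoir by every dynamic analysis.
``waste``
    discarded output (:math:`\\Sigma y_j`); a sink, never consumed.

Catalysis is a first-class reaction field rather than a duplicated
reactant/product pair, so "is this species required only catalytically?"
is a syntactic question.  Stoichiometric coefficients are positive
integers throughout.

The module also defines the line-based text format::

    # comment
    food: x1, x2
    waste: y1
    R1: 2 A + x1 -> A2 + B | cat: E

Coefficients default to 1, species tokens match ``[A-Za-z0-9_]+`` and the
``| cat:`` clause is optional.  ``write_network`` emits a deterministic
canonical form (reactions sorted by id, species alphabetically) so that
``parse_network(write_network(net))`` reproduces ``net`` exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

__all__ = [
    "NetworkError",
    "ParseError",
    "Species",
    "Reaction",
    "ReactionNetwork",
    "FiringVector",
    "parse_network",
    "write_network",
    "net_stoichiometry",
]

_TOKEN = re.compile(r"^[A-Za-z0-9_]+$")
_TERM = re.compile(r"^(?:(\d+)\s+)?([A-Za-z0-9_]+)$")

ROLE_INTERNAL = "internal"
ROLE_FOOD = "food"
ROLE_WASTE = "waste"
_ROLES = (ROLE_INTERNAL, ROLE_FOOD, ROLE_WASTE)


class NetworkError(ValueError):
    """Invalid network structure or reference."""


class ParseError(NetworkError):
    """Malformed network document; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Species:
    """A chemical (or abstract) species token."""

    id: str
    role: str = ROLE_INTERNAL
    name: str = ""

    def __post_init__(self) -> None:
        if not _TOKEN.match(self.id):
            raise NetworkError(f"invalid species id {self.id!r}")
        if self.role not in _ROLES:
            raise NetworkError(f"invalid role {self.role!r} for species {self.id!r}")


@dataclass
class Reaction:
    """An irreversible reaction with explicit catalysts.

    ``catalysts`` maps species id to the count that must be present for the
    reaction to proceed; catalysts are returned unchanged.  A species may
    not be both reactant and catalyst of the same reaction.
    """

    id: str
    reactants: Dict[str, int]
    products: Dict[str, int]
    catalysts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not _TOKEN.match(self.id):
            raise NetworkError(f"invalid reaction id {self.id!r}")
        for label, side in (
            ("reactant", self.reactants),
            ("product", self.products),
            ("catalyst", self.catalysts),
        ):
            for sid, count in side.items():
                if not isinstance(count, int) or count < 1:
                    raise NetworkError(
                        f"reaction {self.id}: {label} {sid!r} has "
                        f"non-positive count {count!r}"
                    )
        overlap = set(self.reactants) & set(self.catalysts)
        if overlap:
            raise NetworkError(
                f"reaction {self.id}: species {sorted(overlap)} cannot be "
                "both reactant and catalyst"
            )

    def species_ids(self) -> set:
        return set(self.reactants) | set(self.products) | set(self.catalysts)

    def _key(self) -> tuple:
        return (
            self.id,
            tuple(sorted(self.reactants.items())),
            tuple(sorted(self.products.items())),
            tuple(sorted(self.catalysts.items())),
        )


class ReactionNetwork:
    """A validated set of reactions plus species role declarations.

    Parameters
    ----------
    species
        All species of the network.  Every species must take part in at
        least one reaction.
    reactions
        The reactions; ids must be unique and may only reference declared
        species.

    Notes
    -----
    Waste species may never appear as reactants or catalysts.  Food
    species appearing as products do not raise (they are externally
    supplied either way) but a warning string is recorded in
    :attr:`warnings`.
    """

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction]):
        self.species: List[Species] = sorted(species, key=lambda s: s.id)
        self.reactions: List[Reaction] = sorted(reactions, key=lambda r: r.id)
        self.warnings: List[str] = []
        self._species_by_id = {s.id: s for s in self.species}
        self._reactions_by_id = {r.id: r for r in self.reactions}
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        if not self.reactions:
            raise NetworkError("empty network: no reactions")
        if len(self._species_by_id) != len(self.species):
            raise NetworkError("duplicate species ids")
        if len(self._reactions_by_id) != len(self.reactions):
            raise NetworkError("duplicate reaction ids")
        used: set = set()
        for r in self.reactions:
            unknown = r.species_ids() - set(self._species_by_id)
            if unknown:
                raise NetworkError(
                    f"reaction {r.id} references unknown species {sorted(unknown)}"
                )
            used |= r.species_ids()
            for sid in list(r.reactants) + list(r.catalysts):
                if self._species_by_id[sid].role == ROLE_WASTE:
                    raise NetworkError(
                        f"waste species {sid!r} used as reactant/catalyst "
                        f"in reaction {r.id}"
                    )
            for sid in r.products:
                if self._species_by_id[sid].role == ROLE_FOOD:
                    self.warnings.append(
                        f"food species {sid!r} produced by reaction {r.id}"
                    )
        unused = set(self._species_by_id) - used
        if unused:
            raise NetworkError(f"species never used in any reaction: {sorted(unused)}")

    # -- lookups --------------------------------------------------------

    def species_by_id(self, sid: str) -> Species:
        try:
            return self._species_by_id[sid]
        except KeyError:
            raise NetworkError(f"unknown species {sid!r}") from None

    def reaction_by_id(self, rid: str) -> Reaction:
        try:
            return self._reactions_by_id[rid]
        except KeyError:
            raise NetworkError(f"unknown reaction {rid!r}") from None

    @property
    def food_ids(self) -> Tuple[str, ...]:
        return tuple(s.id for s in self.species if s.role == ROLE_FOOD)

    @property
    def waste_ids(self) -> Tuple[str, ...]:
        return tuple(s.id for s in self.species if s.role == ROLE_WASTE)

    @property
    def internal_ids(self) -> Tuple[str, ...]:
        return tuple(s.id for s in self.species if s.role == ROLE_INTERNAL)

    # -- identity -------------------------------------------------------

    def canonical(self) -> tuple:
        """Order-independent structural key; basis of equality and hashing."""
        return (
            tuple((s.id, s.role) for s in self.species),
            tuple(r._key() for r in self.reactions),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork({len(self.species)} species, "
            f"{len(self.reactions)} reactions)"
        )


#: number of times each reaction fires; plain mapping reaction-id -> count >= 0
FiringVector = Mapping[str, int]


def net_stoichiometry(net: ReactionNetwork, firing: FiringVector) -> Dict[str, int]:
    """Net species change of a firing vector.

    Returns ``sum over reactions of count * (products - reactants)`` for
    every species of the network (zero entries included).  Catalysts are
    required-and-returned, so they contribute nothing.
    """
    result = {s.id: 0 for s in net.species}
    for rid, count in firing.items():
        if not isinstance(count, int) or count < 0:
            raise NetworkError(f"firing count for {rid!r} must be a non-negative int")
        reaction = net.reaction_by_id(rid)
        for sid, n in reaction.reactants.items():
            result[sid] -= count * n
        for sid, n in reaction.products.items():
            result[sid] += count * n
    return result


# ---------------------------------------------------------------------------
# text format


def _parse_side(text: str, lineno: int) -> Dict[str, int]:
    side: Dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ParseError("empty term in reaction", lineno)
        m = _TERM.match(term)
        if not m:
            raise ParseError(f"malformed term {term!r}", lineno)
        count = int(m.group(1)) if m.group(1) else 1
        if count < 1:
            raise ParseError(f"non-positive coefficient in {term!r}", lineno)
        sid = m.group(2)
        side[sid] = side.get(sid, 0) + count
    return side


def _parse_id_list(text: str, lineno: int) -> List[str]:
    ids = [tok.strip() for tok in text.split(",")]
    for tok in ids:
        if not _TOKEN.match(tok):
            raise ParseError(f"invalid species id {tok!r}", lineno)
    return ids


def parse_network(text: str) -> ReactionNetwork:
    """Parse a reaction-list document into a validated network."""
    food: List[str] = []
    waste: List[str] = []
    reactions: List[Reaction] = []
    seen_ids: set = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("food:"):
            food.extend(_parse_id_list(line[len("food:"):], lineno))
            continue
        if line.startswith("waste:"):
            waste.extend(_parse_id_list(line[len("waste:"):], lineno))
            continue
        if ":" not in line:
            raise ParseError(f"malformed line {line!r}", lineno)
        rid, body = line.split(":", 1)
        rid = rid.strip()
        if not _TOKEN.match(rid):
            raise ParseError(f"invalid reaction id {rid!r}", lineno)
        if rid in seen_ids:
            raise ParseError(f"duplicate reaction id {rid!r}", lineno)
        seen_ids.add(rid)
        catalysts: Dict[str, int] = {}
        if "|" in body:
            body, clause = body.split("|", 1)
            clause = clause.strip()
            if not clause.startswith("cat:"):
                raise ParseError(f"unknown clause {clause!r}", lineno)
            catalysts = _parse_side(clause[len("cat:"):], lineno)
        if "->" not in body:
            raise ParseError("reaction lacks '->'", lineno)
        lhs, rhs = body.split("->", 1)
        try:
            reactions.append(
                Reaction(
                    id=rid,
                    reactants=_parse_side(lhs, lineno),
                    products=_parse_side(rhs, lineno),
                    catalysts=catalysts,
                )
            )
        except NetworkError as exc:
            raise ParseError(str(exc), lineno) from None
    if not reactions:
        raise NetworkError("empty network: document declares no reactions")

    referenced: set = set()
    for r in reactions:
        referenced |= r.species_ids()
    for sid in food + waste:
        if sid not in referenced:
            raise NetworkError(
                f"food/waste declaration references unknown species {sid!r}"
            )
    both = set(food) & set(waste)
    if both:
        raise NetworkError(f"species declared both food and waste: {sorted(both)}")

    species = []
    for sid in sorted(referenced):
        role = ROLE_FOOD if sid in food else ROLE_WASTE if sid in waste else ROLE_INTERNAL
        species.append(Species(id=sid, role=role, name=sid))
    return ReactionNetwork(species, reactions)


def _format_side(side: Mapping[str, int]) -> str:
    terms = []
    for sid in sorted(side):
        n = side[sid]
        terms.append(sid if n == 1 else f"{n} {sid}")
    return " + ".join(terms)


def write_network(net: ReactionNetwork) -> str:
    """Serialize a network to the canonical text form (deterministic bytes)."""
    lines: List[str] = []
    if net.food_ids:
        lines.append("food: " + ", ".join(sorted(net.food_ids)))
    if net.waste_ids:
        lines.append("waste: " + ", ".join(sorted(net.waste_ids)))
    for r in sorted(net.reactions, key=lambda r: r.id):
        line = f"{r.id}: {_format_side(r.reactants)} -> {_format_side(r.products)}"
        if r.catalysts:
            line += " | cat: " + _format_side(r.catalysts)
        lines.append(line)
    return "\n".join(lines) + "\n"
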