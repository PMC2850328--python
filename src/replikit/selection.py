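"""Selection as a sorting / equivalence formalism.

A selective force cannot do more than sort: two entities it cannot sort
between better than random are *equivalent*.  The phenotype is the
function of an entity that selection discriminates on, so a phenotype
function induces an equivalence partition of any entity set — entities
share a block iff their phenotypes are equal.  Everything else here
(units of selection and of evolution, genotype–phenotype decoupling,
the four-way taxonomy of acquired changes) is built on that partition.

The standard genetic code is the worked fixture: 64 codon entities,
translation as phenotype, 20 sense classes plus the stop class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Hashable, Iterable, List, Optional, Sequence, Set, Tuple

from .heredity import VHParameters

__all__ = [
    "Entity",
    "PhenotypeFunction",
    "Partition",
    "GenotypePhenotypeMap",
    "partition_by_phenotype",
    "are_equivalent",
    "count_phenotype_classes",
    "is_unit_of_selection",
    "is_decoupled",
    "is_unit_of_evolution",
    "classify_change",
    "STANDARD_GENETIC_CODE",
    "codon_entities",
    "translation_phenotype",
    "read_entities_tsv",
    "write_entities_tsv",
]


@dataclass(frozen=True)
class Entity:
    """An entity described by an ordered feature vector of symbols."""

    id: str
    features: Tuple[str, ...]


@dataclass(frozen=True)
class PhenotypeFunction:
    """A named, total, deterministic mapping from entities to phenotype values.

    ``quantize`` optionally coarsens real-valued phenotypes before the
    exact-equality comparison the formalism requires.
    """

    func: Callable[[Entity], Hashable]
    name: str = "phenotype"
    quantize: Optional[Callable[[Hashable], Hashable]] = None

    def __call__(self, entity: Entity) -> Hashable:
        try:
            value = self.func(entity)
        except Exception as exc:
            raise ValueError(
                f"phenotype {self.name!r} undefined on entity {entity.id!r}"
            ) from exc
        if self.quantize is not None:
            value = self.quantize(value)
        return value


@dataclass
class Partition:
    """Disjoint blocks of entity ids covering an entity set."""

    blocks: List[List[str]]

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for block in self.blocks:
            if not block:
                raise ValueError("empty partition block")
            for eid in block:
                if eid in seen:
                    raise ValueError(f"entity {eid!r} appears in two blocks")
                seen.add(eid)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, entity_id: str) -> List[str]:
        for block in self.blocks:
            if entity_id in block:
                return block
        raise KeyError(entity_id)

    def same_block(self, a: str, b: str) -> bool:
        return self.block_of(a) is self.block_of(b)


def partition_by_phenotype(
    entities: Iterable[Entity], p: PhenotypeFunction
) -> Partition:
    """Partition an entity set into phenotype-equivalence classes.

    Blocks are ordered by their smallest member id and sorted within, so
    the result is deterministic regardless of input order.
    """
    groups: Dict[Hashable, List[str]] = {}
    for e in entities:
        groups.setdefault(p(e), []).append(e.id)
    blocks = [sorted(ids) for ids in groups.values()]
    blocks.sort(key=lambda b: b[0])
    return Partition(blocks)


def are_equivalent(e1: Entity, e2: Entity, p: PhenotypeFunction) -> bool:
    """True iff selection through ``p`` cannot sort between the two."""
    return p(e1) == p(e2)


def count_phenotype_classes(
    entities: Iterable[Entity],
    p: PhenotypeFunction,
    include: Optional[Callable[[Hashable], bool]] = None,
) -> int:
    """Number of phenotype classes, optionally filtered by class value."""
    values = {p(e) for e in entities}
    if include is not None:
        values = {v for v in values if include(v)}
    return len(values)


def is_unit_of_selection(entities: Sequence[Entity], p: PhenotypeFunction) -> bool:
    """A population is under (potential) selection iff phenotypes differ.

    True iff the phenotype partition has at least two blocks; a clonal
    (single-phenotype) population offers selection nothing to sort.
    """
    if not entities:
        raise ValueError("need at least one entity")
    return partition_by_phenotype(entities, p).n_blocks >= 2


@dataclass(frozen=True)
class GenotypePhenotypeMap:
    """Index-set view of which features carry genotype and phenotype.

    ``g_idx`` are the feature indices whose restriction (through ``h``)
    is the genotype; ``p_idx`` those determining the phenotype (through
    ``f``).  Overlap is what couples evolution to selection.
    """

    g_idx: FrozenSet[int]
    p_idx: FrozenSet[int]
    h: Optional[Callable[[Tuple[str, ...]], Hashable]] = None
    f: Optional[Callable[[Tuple[str, ...]], Hashable]] = None

    def genotype(self, e: Entity) -> Hashable:
        restricted = tuple(e.features[i] for i in sorted(self.g_idx))
        return self.h(restricted) if self.h else restricted

    def phenotype(self, e: Entity) -> Hashable:
        restricted = tuple(e.features[i] for i in sorted(self.p_idx))
        return self.f(restricted) if self.f else restricted


def is_decoupled(gp_map: GenotypePhenotypeMap) -> bool:
    """True iff genotype and phenotype share no feature index.

    A decoupled map makes every genotype change selectively neutral and
    blocks selection from reaching the genotype — evolution stalls.
    """
    return not (gp_map.g_idx & gp_map.p_idx)


def is_unit_of_evolution(
    entities: Sequence[Entity],
    p: PhenotypeFunction,
    gp_map: GenotypePhenotypeMap,
    heredity: VHParameters,
) -> bool:
    """Unit of selection + heritable genotype + genotype–phenotype link."""
    return (
        is_unit_of_selection(entities, p)
        and heredity.H_frac > 0
        and not is_decoupled(gp_map)
    )


def classify_change(
    delta: Set[int],
    gp_map: GenotypePhenotypeMap,
    heritable_idx: Set[int],
) -> int:
    """Quadrant (1–4) of an acquired change.

    Heritable iff the changed indices meet the heritable set; effective
    iff they meet the phenotype-determining set.  1: non-heritable
    neutral; 2: non-heritable effective; 3: heritable neutral (the
    trivial/non-trivial distinction within it is caller metadata, not
    computed); 4: heritable effective.
    """
    heritable = bool(delta & set(heritable_idx))
    effective = bool(delta & set(gp_map.p_idx))
    return 1 + (1 if effective else 0) + (2 if heritable else 0)


# ---------------------------------------------------------------------------
# the standard genetic code, frozen

_CODE_BY_AA = {
    "F": ("UUU", "UUC"),
    "L": ("UUA", "UUG", "CUU", "CUC", "CUA", "CUG"),
    "I": ("AUU", "AUC", "AUA"),
    "M": ("AUG",),
    "V": ("GUU", "GUC", "GUA", "GUG"),
    "S": ("UCU", "UCC", "UCA", "UCG", "AGU", "AGC"),
    "P": ("CCU", "CCC", "CCA", "CCG"),
    "T": ("ACU", "ACC", "ACA", "ACG"),
    "A": ("GCU", "GCC", "GCA", "GCG"),
    "Y": ("UAU", "UAC"),
    "H": ("CAU", "CAC"),
    "Q": ("CAA", "CAG"),
    "N": ("AAU", "AAC"),
    "K": ("AAA", "AAG"),
    "D": ("GAU", "GAC"),
    "E": ("GAA", "GAG"),
    "C": ("UGU", "UGC"),
    "W": ("UGG",),
    "R": ("CGU", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "G": ("GGU", "GGC", "GGA", "GGG"),
    "*": ("UAA", "UAG", "UGA"),
}

#: codon (RNA) -> one-letter amino acid, '*' for stop; 64 entries
STANDARD_GENETIC_CODE: Dict[str, str] = {
    codon: aa for aa, codons in _CODE_BY_AA.items() for codon in codons
}
assert len(STANDARD_GENETIC_CODE) == 64


def codon_entities() -> List[Entity]:
    """The 64 codons as entities with per-base feature vectors."""
    return [Entity(id=c, features=tuple(c)) for c in sorted(STANDARD_GENETIC_CODE)]


#: translation through the standard code as a phenotype function
translation_phenotype = PhenotypeFunction(
    func=lambda e: STANDARD_GENETIC_CODE["".join(e.features)],
    name="translation",
)


# ---------------------------------------------------------------------------
# tabular IO


def read_entities_tsv(path: str) -> Tuple[List[Entity], Dict[str, str]]:
    """Read entities from TSV (columns: id, features[, phenotype]).

    The feature string is split into single-symbol features.  Returns the
    entities and an id -> phenotype mapping (empty when the column is
    absent), usable as a table-backed :class:`PhenotypeFunction`.
    """
    entities: List[Entity] = []
    phenotypes: Dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a TSV with an 'id' column")
        for row in reader:
            entities.append(Entity(id=row["id"], features=tuple(row["features"])))
            if "phenotype" in row and row["phenotype"] not in (None, ""):
                phenotypes[row["id"]] = row["phenotype"]
    return entities, phenotypes


def write_entities_tsv(
    path: str,
    entities: Sequence[Entity],
    phenotypes: Optional[Dict[str, str]] = None,
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["id", "features"] + (["phenotype"] if phenotypes else [])
        writer.writerow(header)
        for e in entities:
            row = [e.id, "".join(e.features)]
            if phenotypes:
                row.append(phenotypes.get(e.id, ""))
            writer.writerow(row)
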