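"""Built-in reaction-network fixtures.

These are the worked autocatalytic systems of the replicator-theory
literature, encoded at the granularity needed for seed and ratio
analysis: the formose core, the Calvin cycle sugar-phosphate skeleton,
the reductive citric acid cycle, the RNA/protein systems, and the
bird-and-nest cycle in both its naive (bird as plain catalyst) and
formal (nesting-bird phase with an obligatory nest) versions.

Fixture documents are frozen strings; ``fixture(name)`` parses them on
demand.  The canonical serialization is byte-stable, which tests pin by
content hash.
"""

from __future__ import annotations

from .network import ReactionNetwork, parse_network

__all__ = ["FIXTURE_NAMES", "fixture", "fixture_text"]


_FORMOSE = """\
# Autocatalytic core of the formose reaction.
# One full turn: GA + 2 FORM -> 2 GA (glycolaldehyde doubles).
food: FORM
R1: GA + FORM -> GLY
R2: GLY -> DHA
R3: DHA + FORM -> TET
R4: TET -> 2 GA
"""

# Sugar-phosphate skeleton of the Calvin cycle.  ENZ is the obligate
# enzyme set, modelled as a single always-available (food-role) catalyst.
# Aldolase+phosphatase pairs and the epimerase/isomerase steps are merged;
# CO2 is the sole carbon input.
_CALVIN = """\
food: CO2, ENZ
R01: PGA -> GAP | cat: ENZ
R02: GAP -> DHAP | cat: ENZ
R03: DHAP -> GAP | cat: ENZ
R04: GAP + DHAP -> F6P | cat: ENZ
R05: F6P + GAP -> E4P + X5P | cat: ENZ
R06: E4P + DHAP -> Se7P | cat: ENZ
R07: Se7P + GAP -> R5P + X5P | cat: ENZ
R08: R5P -> Ru5P | cat: ENZ
R09: X5P -> Ru5P | cat: ENZ
R10: Ru5P -> RuBP | cat: ENZ
R11: RuBP + CO2 -> 2 PGA | cat: ENZ
"""

# Reductive citric acid cycle: one turn doubles every intermediate; the
# two oxaloacetate copies arise on asymmetric branches (one through the
# reductive arm, one through citrate cleavage and carboxylation).
_REDUCTIVE_TCA = """\
food: CO2
R01: OAA -> MAL
R02: MAL -> FUM
R03: FUM -> SUC
R04: SUC -> SUCCOA
R05: SUCCOA + CO2 -> AKG
R06: AKG + CO2 -> ISOCIT
R07: ISOCIT -> CIT
R08: CIT -> OAA + ACCOA
R09: ACCOA + CO2 -> PYR
R10: PYR -> PEP
R11: PEP + CO2 -> OAA
"""

# Formal bird/nest cycle: A1 the bird, A2 the nesting bird, B the nest
# (obligatory catalyst of the nesting phase).  Net of one turn:
# A1 + inputs -> 2 A1 + B + waste.
_BIRD_NEST = """\
food: x1, x2
waste: y1
R1: A1 + x1 -> A2 + B
R2: A2 + x2 -> 2 A1 + y1 | cat: B
"""

# Naive version: birds reproduce on their own and merely catalyse nest
# production; nests are unneeded side products.
_BIRD_CATALYST = """\
food: x1, x2
waste: y1
R1: A1 + x1 -> 2 A1 + y1
R2: x2 -> B | cat: A1
"""

_RNA_ONLY = """\
# RNA as a true self-replicator.
food: x
waste: y
R1: RNA + x -> 2 RNA + y
"""

# Proteins appear as side products of RNA replication and facultatively
# catalyse it (the catalysed route duplicates the spontaneous one).
_RNA_PROTEIN_FACULTATIVE = """\
food: x
waste: y
R1: RNA + x -> 2 RNA + P + y
R2: RNA + x -> 2 RNA + P + y | cat: P
"""

# Gene/enzyme system with fully obligatory coupling: DNA replication
# needs enzymes, enzyme production needs both the genes and pre-existing
# enzymes; neither species can ignite alone.
_RNA_PROTEIN_OBLIGATE = """\
food: x1, x2
waste: y1, z1
R1: DNA + x1 -> 2 DNA + y1 | cat: E
R2: x2 -> E + z1 | cat: DNA + E
"""


_FIXTURES = {
    "formose": _FORMOSE,
    "calvin": _CALVIN,
    "reductive_tca": _REDUCTIVE_TCA,
    "bird_nest": _BIRD_NEST,
    "bird_catalyst": _BIRD_CATALYST,
    "rna_only": _RNA_ONLY,
    "rna_protein_facultative": _RNA_PROTEIN_FACULTATIVE,
    "rna_protein_obligate": _RNA_PROTEIN_OBLIGATE,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture_text(name: str) -> str:
    """Frozen source document of a built-in network."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None


def fixture(name: str) -> ReactionNetwork:
    """Parse and return a built-in network by name."""
    return parse_network(fixture_text(name))
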