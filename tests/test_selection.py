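"""Phenotype partitions, equivalence, units of selection/evolution."""

import itertools
import random

import pytest

from replikit.heredity import VHParameters
from replikit.selection import (
    Entity,
    GenotypePhenotypeMap,
    Partition,
    PhenotypeFunction,
    STANDARD_GENETIC_CODE,
    are_equivalent,
    classify_change,
    codon_entities,
    count_phenotype_classes,
    is_decoupled,
    is_unit_of_evolution,
    is_unit_of_selection,
    partition_by_phenotype,
    read_entities_tsv,
    translation_phenotype,
    write_entities_tsv,
)


def _entity(codon: str) -> Entity:
    return Entity(id=codon, features=tuple(codon))


class TestGeneticCodeFixture:
    def test_code_agrees_with_biopython_reference(self):
        # independent cross-check of the frozen table
        from Bio.Data.CodonTable import standard_rna_table

        for codon, aa in STANDARD_GENETIC_CODE.items():
            if aa == "*":
                assert codon in standard_rna_table.stop_codons
            else:
                assert standard_rna_table.forward_table[codon] == aa

    def test_sixty_four_codons(self):
        assert len(codon_entities()) == 64

    def test_synonymous_codons_are_equivalent(self):
        # UCA and AGU differ in every base yet both encode serine
        assert are_equivalent(_entity("UCA"), _entity("AGU"), translation_phenotype)

    def test_sense_stop_codons_not_equivalent(self):
        assert not are_equivalent(
            _entity("UCA"), _entity("UGA"), translation_phenotype
        )

    def test_twenty_sense_classes_plus_stop(self):
        codons = codon_entities()
        sense = count_phenotype_classes(
            codons, translation_phenotype, include=lambda aa: aa != "*"
        )
        total = count_phenotype_classes(codons, translation_phenotype)
        assert (sense, total) == (20, 21)

    def test_partition_puts_synonymous_codons_together(self):
        part = partition_by_phenotype(codon_entities(), translation_phenotype)
        assert part.same_block("UCA", "AGU")
        assert not part.same_block("UCA", "UGA")
        assert part.n_blocks == 21


class TestPartition:
    def test_constant_phenotype_single_block(self):
        entities = [_entity(c) for c in ("AAA", "CCC", "GGG")]
        p = PhenotypeFunction(lambda e: "same", name="constant")
        assert partition_by_phenotype(entities, p).n_blocks == 1

    def test_identity_phenotype_singleton_blocks(self):
        entities = [_entity(c) for c in ("AAA", "CCC", "GGG")]
        p = PhenotypeFunction(lambda e: e.id, name="identity")
        part = partition_by_phenotype(entities, p)
        assert part.blocks == [["AAA"], ["CCC"], ["GGG"]]

    def test_empty_set_has_zero_classes(self):
        assert count_phenotype_classes([], translation_phenotype) == 0

    def test_partial_phenotype_raises(self):
        p = PhenotypeFunction(lambda e: {"a": 1}[e.id], name="partial")
        with pytest.raises(ValueError, match="undefined"):
            partition_by_phenotype([Entity("b", ("b",))], p)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="two blocks"):
            Partition([["a", "b"], ["b"]])

    def test_induced_relation_is_an_equivalence(self, rng: random.Random):
        # reflexive/symmetric/transitive on random entity sets
        for _ in range(20):
            entities = [
                Entity(f"e{i}", tuple(rng.choice("AB") for _ in range(3)))
                for i in range(rng.randint(1, 8))
            ]
            p = PhenotypeFunction(lambda e: e.features[0], name="first")
            part = partition_by_phenotype(entities, p)
            ids = [e.id for e in entities]
            assert sorted(itertools.chain(*part.blocks)) == sorted(ids)
            for a, b, c in itertools.product(ids, repeat=3):
                assert part.same_block(a, a)
                assert part.same_block(a, b) == part.same_block(b, a)
                if part.same_block(a, b) and part.same_block(b, c):
                    assert part.same_block(a, c)


class TestUnits:
    def test_strains_with_different_division_times_are_under_selection(self):
        strains = [Entity("fast", ("1",)), Entity("slow", ("2",))]
        p = PhenotypeFunction(lambda e: e.features[0], name="division_time")
        assert is_unit_of_selection(strains, p)

    def test_clonal_population_is_not(self):
        clones = [Entity(f"c{i}", ("1",)) for i in range(5)]
        p = PhenotypeFunction(lambda e: e.features[0], name="rate")
        assert not is_unit_of_selection(clones, p)

    def test_exact_replicators_with_two_rates_are_selectable(self):
        # no heredity needed for selection, only phenotype diversity
        pop = [Entity("a", ("fast",)), Entity("b", ("slow",))]
        p = PhenotypeFunction(lambda e: e.features[0], name="rate")
        assert is_unit_of_selection(pop, p)

    @pytest.mark.parametrize(
        "g,p,expected",
        [
            ({1, 2}, {3, 4}, True),
            ({1, 2}, {1, 2}, False),
            ({1, 2, 3}, {3, 4}, False),
        ],
    )
    def test_decoupling_is_index_disjointness(self, g, p, expected):
        gp = GenotypePhenotypeMap(g_idx=frozenset(g), p_idx=frozenset(p))
        assert is_decoupled(gp) is expected

    def test_unit_of_evolution_needs_heredity_and_coupling(self):
        pop = [Entity("a", ("x", "y")), Entity("b", ("z", "y"))]
        p = PhenotypeFunction(lambda e: e.features[0], name="p0")
        coupled = GenotypePhenotypeMap(g_idx=frozenset({0}), p_idx=frozenset({0}))
        decoupled = GenotypePhenotypeMap(g_idx=frozenset({1}), p_idx=frozenset({0}))
        heritable = VHParameters(I_size=2, V_frac=1.0, H_frac=0.5)
        sterile = VHParameters(I_size=2, V_frac=1.0, H_frac=0.0)
        assert is_unit_of_evolution(pop, p, coupled, heritable)
        assert not is_unit_of_evolution(pop, p, coupled, sterile)
        assert not is_unit_of_evolution(pop, p, decoupled, heritable)

    def test_unit_of_evolution_implies_unit_of_selection(self, rng: random.Random):
        for _ in range(50):
            pop = [
                Entity(f"e{i}", tuple(rng.choice("AB") for _ in range(4)))
                for i in range(rng.randint(1, 6))
            ]
            p = PhenotypeFunction(lambda e: e.features[0], name="p0")
            gp = GenotypePhenotypeMap(
                g_idx=frozenset(rng.sample(range(4), rng.randint(0, 4))),
                p_idx=frozenset({0}),
            )
            h = rng.choice([0.0, 0.5])
            vh = VHParameters(I_size=4, V_frac=1.0, H_frac=h)
            if is_unit_of_evolution(pop, p, gp, vh):
                assert is_unit_of_selection(pop, p)


class TestChangeTaxonomy:
    GP = GenotypePhenotypeMap(g_idx=frozenset({0, 1}), p_idx=frozenset({2, 3}))

    @pytest.mark.parametrize(
        "delta,heritable,quadrant",
        [
            ({5}, {0, 1}, 1),  # outside heredity, outside phenotype: neutral blip
            ({2}, {0, 1}, 2),  # phenotype hit but not inherited
            ({0}, {0, 1}, 3),  # inherited but selectively silent
            ({0, 2}, {0, 2}, 4),  # heritable and effective: raw material of evolution
        ],
    )
    def test_quadrants(self, delta, heritable, quadrant):
        assert classify_change(delta, self.GP, heritable) == quadrant

    def test_decoupled_map_never_yields_quadrant_four_for_genotype_deltas(
        self, rng: random.Random
    ):
        for _ in range(50):
            g = frozenset(rng.sample(range(6), rng.randint(1, 3)))
            p = frozenset(set(range(6)) - g)
            gp = GenotypePhenotypeMap(g_idx=g, p_idx=p)
            assert is_decoupled(gp)
            delta = set(rng.sample(sorted(g), rng.randint(1, len(g))))
            assert classify_change(delta, gp, set(g)) == 3


class TestTabularIO:
    def test_round_trip(self, tmp_path):
        entities = codon_entities()[:8]
        phenos = {e.id: STANDARD_GENETIC_CODE[e.id] for e in entities}
        path = tmp_path / "codons.tsv"
        write_entities_tsv(path, entities, phenos)
        back, table = read_entities_tsv(path)
        assert back == entities
        assert table == phenos
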