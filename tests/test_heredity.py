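"""S/N and V/H classifiers, the similarity closed form, the hierarchy."""

import itertools
import math
import random

import pytest

from replikit.heredity import (
    HIERARCHY_CHAIN,
    HeredityContext,
    HierarchyProfile,
    VHParameters,
    classify_hierarchy,
    classify_SN,
    classify_VH,
    default_epsilon,
    expected_similarity,
    sequence_state_count,
)


class TestSN:
    @pytest.mark.parametrize(
        "S,N,label",
        [
            (1, 1000, "no_variation_exact"),
            (1, 1, "no_variation_exact"),  # S=1 takes precedence
            (4, 1, "no_population"),
            (4, 100, "limited_hereditary"),
            (4 ** 30, 10 ** 6, "unlimited_hereditary"),
            (100, 100, "unlimited_hereditary"),  # boundary N = S
        ],
    )
    def test_domains(self, S, N, label):
        assert classify_SN(HeredityContext(S_states=S, N_pop=N)) == label

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            HeredityContext(S_states=0, N_pop=5)
        with pytest.raises(ValueError):
            HeredityContext(S_states=4, N_pop=0)

    def test_infinite_state_space_is_unlimited(self):
        ctx = HeredityContext(S_states=math.inf, N_pop=10 ** 9)
        assert classify_SN(ctx) == "unlimited_hereditary"

    def test_scaling_both_preserves_side_of_boundary(self):
        rng = random.Random(7)
        for _ in range(50):
            S, N, k = rng.randint(2, 50), rng.randint(2, 50), rng.randint(2, 5)
            before = classify_SN(HeredityContext(S_states=S, N_pop=N))
            after = classify_SN(HeredityContext(S_states=S * k, N_pop=N * k))
            if before in ("limited_hereditary", "unlimited_hereditary"):
                assert after == before  # N > S iff kN > kS


class TestStateCount:
    def test_triplets_over_four_bases(self):
        # direct enumeration as the oracle
        bases = "ACGU"
        enumerated = len({t for t in itertools.product(bases, repeat=3)})
        assert sequence_state_count(3, 4) == enumerated == 64

    @pytest.mark.parametrize("L,A,expected", [(0, 4, 1), (1, 1, 1), (10, 2, 1024)])
    def test_edge_cases(self, L, A, expected):
        assert sequence_state_count(L, A) == expected

    def test_shortening_the_template_limits_heredity(self):
        # a long template outruns the population; a short one cannot
        N = 10 ** 6
        long_ctx = HeredityContext(sequence_state_count(30, 4), N)
        short_ctx = HeredityContext(sequence_state_count(5, 4), N)
        assert classify_SN(long_ctx) == "unlimited_hereditary"
        assert classify_SN(short_ctx) == "limited_hereditary"


class TestExpectedSimilarity:
    def test_no_variability_means_full_identity(self):
        p = VHParameters(I_size=100, V_frac=0.0, H_frac=0.0, upsilon=0.7, mu=0.9)
        assert expected_similarity(p) == 100

    def test_no_change_no_miscopy_means_full_identity(self):
        p = VHParameters(I_size=100, V_frac=0.5, H_frac=0.2)
        assert expected_similarity(p) == 100

    def test_frozen_reference_value(self):
        # confirmed against the Monte-Carlo oracle before freezing
        p = VHParameters(
            I_size=100, V_frac=0.5, H_frac=0.2, upsilon=0.1, mu=0.01, epsilon=0.0
        )
        assert expected_similarity(p) == pytest.approx(94.82)

    def test_monotone_in_upsilon_and_mu_without_backmutation(self):
        grid = [0.0, 0.1, 0.3, 0.6, 1.0]
        for V, H in [(0.4, 0.2), (1.0, 1.0), (0.8, 0.0)]:
            for m in grid:
                values = [
                    expected_similarity(
                        VHParameters(100, V, H, upsilon=u, mu=m, epsilon=0.0)
                    )
                    for u in grid
                ]
                assert all(a >= b for a, b in zip(values, values[1:]))
            for u in grid:
                values = [
                    expected_similarity(
                        VHParameters(100, V, H, upsilon=u, mu=m, epsilon=0.0)
                    )
                    for m in grid
                ]
                assert all(a >= b for a, b in zip(values, values[1:]))

    def test_bounded_by_stable_part_and_total(self):
        rng = random.Random(3)
        for _ in range(100):
            V = rng.random()
            p = VHParameters(
                I_size=50,
                V_frac=V,
                H_frac=rng.uniform(0, V),
                upsilon=rng.random(),
                mu=rng.random(),
                epsilon=rng.random(),
            )
            s = expected_similarity(p)
            assert 50 * (1 - p.V_frac) - 1e-9 <= s <= 50 + 1e-9

    def test_h_above_v_rejected(self):
        with pytest.raises(ValueError, match="H_frac"):
            VHParameters(I_size=10, V_frac=0.2, H_frac=0.5)

    def test_module_count_rounding_keeps_containment(self):
        v, h = VHParameters(I_size=10, V_frac=0.26, H_frac=0.25).module_counts()
        assert h <= v


class TestDefaultEpsilon:
    def test_binary_inventory_backmutates_with_certainty(self):
        assert default_epsilon(2) == 1.0

    def test_uniform_choice_among_alternatives(self):
        assert default_epsilon(5) == 0.25

    def test_large_inventory_negligible(self):
        assert default_epsilon(10 ** 6) == pytest.approx(0.0, abs=1e-5)

    def test_degenerate_inventory_rejected(self):
        with pytest.raises(ValueError):
            default_epsilon(1)


class TestVHClassifier:
    def test_exact_replicator(self):
        cls = classify_VH(VHParameters(I_size=10, V_frac=0.0, H_frac=0.0))
        assert (cls.label, cls.informational, cls.ideal) == ("exact", False, False)

    def test_variable_non_informational(self):
        cls = classify_VH(VHParameters(I_size=10, V_frac=0.4, H_frac=0.0))
        assert (cls.label, cls.informational) == ("variable", False)

    def test_ideal_replicator(self):
        cls = classify_VH(VHParameters(I_size=10, V_frac=1.0, H_frac=1.0))
        assert cls.ideal and cls.informational

    def test_informational_refined_by_population_context(self):
        params = VHParameters(I_size=10, V_frac=0.5, H_frac=0.5)
        limited = classify_VH(params, HeredityContext(S_states=4, N_pop=100))
        unlimited = classify_VH(params, HeredityContext(S_states=4 ** 30, N_pop=100))
        assert limited.hereditary_potential == "limited_hereditary"
        assert unlimited.hereditary_potential == "unlimited_hereditary"


def _hierarchy_predicates(profile: HierarchyProfile):
    """Capability predicates, one per hierarchy level (cumulative)."""
    return [
        True,
        profile.regenerates,
        profile.regenerates and profile.order_n >= 2 and profile.g_exceeds_d,
        profile.V_frac > 0,
        profile.H_frac > 0,
        profile.has_development,
    ]


class TestHierarchy:
    def test_formose_intermediate_is_exact_replicator(self):
        profile = HierarchyProfile(
            regenerates=True, order_n=2, g_exceeds_d=True, V_frac=0.0, H_frac=0.0
        )
        assert classify_hierarchy(profile) == "exact_replicator"

    def test_asexual_organism_is_reproducer(self):
        profile = HierarchyProfile(
            regenerates=True, order_n=2, g_exceeds_d=True,
            V_frac=0.9, H_frac=0.1, has_development=True,
        )
        assert classify_hierarchy(profile) == "reproducer"

    def test_order_one_is_sequential_replacement(self):
        profile = HierarchyProfile(
            regenerates=True, order_n=1, g_exceeds_d=True, V_frac=0.0, H_frac=0.0
        )
        assert classify_hierarchy(profile) == "regenerator_sequential_replacement"

    def test_kinetic_failure_blocks_replication(self):
        profile = HierarchyProfile(
            regenerates=True, order_n=3, g_exceeds_d=False, V_frac=0.5, H_frac=0.5
        )
        assert classify_hierarchy(profile) == "regenerator_sequential_replacement"

    def test_inconsistent_profile_rejected(self):
        with pytest.raises(ValueError):
            HierarchyProfile(
                regenerates=True, order_n=2, g_exceeds_d=True,
                V_frac=0.0, H_frac=0.5,
            )

    def test_labels_satisfy_chain_subsumption(self):
        rng = random.Random(11)
        for _ in range(300):
            V = rng.choice([0.0, 0.3, 1.0])
            H = rng.choice([h for h in (0.0, 0.3, 1.0) if h <= V])
            profile = HierarchyProfile(
                regenerates=rng.random() < 0.8,
                order_n=rng.randint(0, 3),
                g_exceeds_d=rng.random() < 0.8,
                V_frac=V,
                H_frac=H,
                has_development=rng.random() < 0.5,
            )
            label = classify_hierarchy(profile)
            level = HIERARCHY_CHAIN.index(label)
            preds = _hierarchy_predicates(profile)
            # the assigned level's predicate and every shallower one hold;
            # the next deeper one fails (the label is maximal)
            assert all(preds[: level + 1])
            if level + 1 < len(preds):
                assert not preds[level + 1]
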