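"""Hereditary-potential models for replicators.

Two complementary classifiers live here.

The (S, N) model compares the number of possible stable states of an
entity, ``S``, against the population size ``N``: with ``N > S`` the
population must contain repeats and heredity is *limited*; with
``N <= S`` the state space outruns the population and heredity is
*unlimited* (the precondition for open-ended evolution).  ``S = 1``
admits no variation at all and ``N = 1`` is no population.

The (V, H) model splits the full information content ``I`` of an entity
into a stable part (fraction ``1 - V``), a variable but non-heritable
part (``V - H``) and a heritable part ``H`` (the genotype), with
``0 <= H <= V <= 1`` by definition.  Together with the per-module
lifetime change probability ``upsilon``, the per-module copy error
``mu`` and the backmutation probability ``epsilon`` it yields a closed
form for the expected parent–offspring similarity (the expected number
of identical features):

    S = I(1-V) + I(V-H)(1-upsilon) + I*H*(1-upsilon)(1-mu)
        + I*H*upsilon*mu*epsilon

Term by term: the stable part always matches; a non-heritable variable
module matches unless the parent changed it; a heritable module matches
when neither changed nor miscopied; and a changed heritable module can
be miscopied *back* to the original with probability ``epsilon``.

Naming note: the literature overloads the symbol S — here
``HeredityContext.S_states`` is the state count while
``expected_similarity`` returns the similarity; they never mix.

The hierarchy classifier (``classify_hierarchy``) strings the concepts
into a chain of increasingly capable multiplying entities:
not multiplying → sequential replacement → exact replicator → variable
replicator → informational replicator → reproducer (an informational
replicator whose non-heritable part is rebuilt by development).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf
from typing import Optional, Tuple

__all__ = [
    "HeredityContext",
    "VHParameters",
    "HierarchyProfile",
    "VHClassification",
    "classify_SN",
    "sequence_state_count",
    "expected_similarity",
    "default_epsilon",
    "classify_VH",
    "classify_hierarchy",
]


@dataclass(frozen=True)
class HeredityContext:
    """Context of the (S, N) model.

    ``S_states`` may be ``math.inf`` for practically unbounded state
    spaces (long templates); ``N_pop`` is the census population size.
    """

    S_states: float  # int >= 1 or math.inf
    N_pop: int

    def __post_init__(self) -> None:
        if self.S_states != inf and (
            not float(self.S_states).is_integer() or self.S_states < 1
        ):
            raise ValueError("S_states must be an integer >= 1 or inf")
        if not isinstance(self.N_pop, int) or self.N_pop < 1:
            raise ValueError("N_pop must be an integer >= 1")


def classify_SN(ctx: HeredityContext) -> str:
    """Place a replicator population in the (S, N) plane.

    Returns one of ``no_variation_exact`` (S = 1), ``no_population``
    (N = 1), ``limited_hereditary`` (N > S) or ``unlimited_hereditary``
    (N <= S; the boundary N = S counts as unlimited).
    """
    if ctx.S_states == 1:
        return "no_variation_exact"
    if ctx.N_pop == 1:
        return "no_population"
    if ctx.N_pop > ctx.S_states:
        return "limited_hereditary"
    return "unlimited_hereditary"


def sequence_state_count(length: int, alphabet_size: int) -> int:
    """Exact number of sequences of ``length`` over ``alphabet_size`` symbols."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be >= 1")
    return alphabet_size ** length


@dataclass(frozen=True)
class VHParameters:
    """Parameters of the variability–heredity similarity model.

    All fractions/probabilities in [0, 1]; ``H_frac <= V_frac`` is the
    defining constraint (heredity exists only where variability does).
    """

    I_size: int
    V_frac: float
    H_frac: float
    upsilon: float = 0.0
    mu: float = 0.0
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.I_size, int) or self.I_size < 1:
            raise ValueError("I_size must be a positive integer")
        for name in ("V_frac", "H_frac", "upsilon", "mu", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.H_frac > self.V_frac + 1e-12:
            raise ValueError("H_frac must not exceed V_frac (H ⊆ V)")

    def module_counts(self) -> Tuple[int, int]:
        """(variable module count, heritable module count) for simulation.

        Nearest-integer rounding, with the heritable count clamped to the
        variable count so the containment V ⊇ H survives rounding.
        """
        v = round(self.I_size * self.V_frac)
        h = min(round(self.I_size * self.H_frac), v)
        return int(v), int(h)


def expected_similarity(parent: VHParameters) -> float:
    """Closed-form expected parent–offspring similarity (feature count).

    The reference for the heritable part is the parent at its own birth;
    for everything else, the current parent.  See the module docstring
    for the term-by-term reading.
    """
    I, V, H = parent.I_size, parent.V_frac, parent.H_frac
    u, m, e = parent.upsilon, parent.mu, parent.epsilon
    return (
        I * (1 - V)
        + I * (V - H) * (1 - u)
        + I * H * (1 - u) * (1 - m)
        + I * H * u * m * e
    )


def default_epsilon(alphabet_size: int) -> float:
    """Backmutation probability under uniform miscopy to a different symbol.

    A miscopied module lands on any of the ``A - 1`` non-current symbols
    with equal probability, so it returns to the original state with
    probability ``1/(A-1)``: certainty for a binary inventory, negligible
    for large ones.
    """
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be >= 2")
    return 1.0 / (alphabet_size - 1)


@dataclass(frozen=True)
class VHClassification:
    """Replicator class in the (V, H) plane."""

    label: str  # exact | variable | informational
    informational: bool
    ideal: bool
    hereditary_potential: Optional[str] = None  # from classify_SN when ctx given

    def __str__(self) -> str:  # pragma: no cover - convenience
        parts = [self.label]
        if self.hereditary_potential:
            parts.append(self.hereditary_potential)
        if self.ideal:
            parts.append("ideal")
        return "/".join(parts)


def classify_VH(
    params: VHParameters, ctx: Optional[HeredityContext] = None
) -> VHClassification:
    """Classify a replicator by its variable and heritable fractions.

    ``V = 0``: exact (holistic, non-informational) replicator — no
    variation can arise at all.  ``V > 0, H = 0``: variable but unable to
    pass changes on (still non-informational).  ``H > 0``: informational;
    with an (S, N) context the hereditary potential is refined into
    limited vs unlimited.  ``V = H = 1`` flags the hypothetical ideal
    replicator that can change anywhere and pass every change on.
    """
    if params.V_frac == 0:
        label, informational = "exact", False
    elif params.H_frac == 0:
        label, informational = "variable", False
    else:
        label, informational = "informational", True
    potential = None
    if informational and ctx is not None:
        potential = classify_SN(ctx)
    ideal = params.V_frac == 1 and params.H_frac == 1
    return VHClassification(label, informational, ideal, potential)


@dataclass(frozen=True)
class HierarchyProfile:
    """Declared capabilities of a multiplying entity.

    ``regenerates``: can produce at least one equivalent entity.
    ``order_n`` / ``g_exceeds_d``: stoichiometric and kinetic halves of
    true multiplication.  ``has_development`` is declared, not inferred:
    whether the non-heritable part is rebuilt by interpreting previously
    copied information rather than by copying.
    """

    regenerates: bool
    order_n: int
    g_exceeds_d: bool
    V_frac: float
    H_frac: float
    has_development: bool = False

    def __post_init__(self) -> None:
        if self.order_n < 0:
            raise ValueError("order_n must be >= 0")
        if not 0 <= self.H_frac <= 1 or not 0 <= self.V_frac <= 1:
            raise ValueError("V_frac and H_frac must lie in [0, 1]")
        if self.H_frac > self.V_frac:
            raise ValueError("H_frac must not exceed V_frac")


#: hierarchy labels from shallowest to deepest capability
HIERARCHY_CHAIN = (
    "not_multiplying",
    "regenerator_sequential_replacement",
    "exact_replicator",
    "variable_replicator",
    "informational_replicator",
    "reproducer",
)


def classify_hierarchy(profile: HierarchyProfile) -> str:
    """Deepest label of the multiplying-entity hierarchy the profile earns.

    Each label presupposes all shallower ones: a reproducer is an
    informational replicator, which is a (variable, hence exact-capable)
    replicator, which regenerates.
    """
    if not profile.regenerates:
        return "not_multiplying"
    if profile.order_n < 2 or not profile.g_exceeds_d:
        return "regenerator_sequential_replacement"
    if profile.V_frac == 0:
        return "exact_replicator"
    if profile.H_frac == 0:
        return "variable_replicator"
    if profile.has_development:
        return "reproducer"
    return "informational_replicator"
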