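"""Stochastic population simulator of modular replicators.

Entities carry a feature vector of length ``I`` over an inventory of
``A`` symbols, split into a stable part, a variable but non-heritable
part and a heritable part (the genotype).  Per generation a module of
the variable part changes with probability ``upsilon``; during
replication a heritable module is miscopied with probability ``mu`` to a
uniformly chosen *different* symbol — which makes the realized
backmutation probability exactly ``1/(A-1)``, closing the loop with the
closed-form similarity of :mod:`replikit.heredity` with no free
parameter.

Offspring construction is the crux: the heritable part is copied from
the parent's *current* symbols (so lifetime changes there are
inherited), while the non-heritable variable part is rebuilt to the
parent's *birth* state — a minimal stand-in for development, since the
process recreating the non-heritable part cannot be copying.

Similarity between parent and offspring can be measured under two
conventions.  ``as_printed`` compares heritable modules against the
parent at its own birth and everything else against the current parent;
``current_parent`` compares everything against the current parent.  The
``as_printed`` Monte-Carlo mean reproduces the closed form exactly.

Population dynamics is discrete and non-overlapping in bookkeeping:
each generation every entity independently dies with probability ``d``
and leaves one offspring with probability ``g``; an optional carrying
capacity is enforced by uniform random culling (neutral with respect to
type, so selection can only arise from ``g``/``d`` differences).
Exact-replicator types (no variable modules) are advanced by per-type
binomial counts — distributionally identical to per-entity draws, since
such entities are exchangeable — which keeps unlimited-growth runs
cheap.  Everything is driven by one seeded generator per run, so a
(config, seed) pair reproduces a trajectory bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .heredity import VHParameters, default_epsilon, expected_similarity

__all__ = [
    "ModularEntity",
    "TypeConfig",
    "SimulationConfig",
    "Trajectory",
    "make_entity",
    "mutate_lifetime",
    "replicate",
    "measure_similarity",
    "similarity_trial",
    "eq4_oracle",
    "OracleResult",
    "run",
    "dilution_experiment",
    "DilutionSummary",
]

CONVENTIONS = ("as_printed", "current_parent")


@dataclass
class ModularEntity:
    """A modular entity with a birth-state snapshot.

    ``variable_idx`` and ``heritable_idx`` are index arrays with
    ``heritable_idx ⊆ variable_idx``; features may drift from
    ``birth_features`` only at variable indices.
    """

    id: int
    features: np.ndarray
    variable_idx: np.ndarray
    heritable_idx: np.ndarray
    birth_features: np.ndarray
    birth_time: int = 0
    type_name: str = "wt"

    def __post_init__(self) -> None:
        if len(self.features) != len(self.birth_features):
            raise ValueError("features and birth_features must have equal length")
        if not set(self.heritable_idx.tolist()) <= set(self.variable_idx.tolist()):
            raise ValueError("heritable_idx must be a subset of variable_idx")


def make_entity(
    params: VHParameters,
    entity_id: int = 0,
    birth_time: int = 0,
    type_name: str = "wt",
    features: Optional[np.ndarray] = None,
) -> ModularEntity:
    """Fresh entity with the first V (resp. H) modules variable (heritable)."""
    n_var, n_her = params.module_counts()
    feats = (
        np.zeros(params.I_size, dtype=np.int64)
        if features is None
        else np.asarray(features, dtype=np.int64).copy()
    )
    return ModularEntity(
        id=entity_id,
        features=feats,
        variable_idx=np.arange(n_var),
        heritable_idx=np.arange(n_her),
        birth_features=feats.copy(),
        birth_time=birth_time,
        type_name=type_name,
    )


def _different_symbols(
    current: np.ndarray, alphabet_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draws over the alphabet excluding each current symbol."""
    shift = rng.integers(1, alphabet_size, size=len(current))
    return (current + shift) % alphabet_size


def mutate_lifetime(
    entity: ModularEntity,
    upsilon: float,
    rng: np.random.Generator,
    alphabet_size: int,
) -> ModularEntity:
    """One inter-replication interval of within-lifetime change.

    Each variable module independently switches to a uniformly chosen
    different symbol with probability ``upsilon``; all other modules are
    untouched.  Returns a new entity (the input is not modified).
    """
    features = entity.features.copy()
    if len(entity.variable_idx) and upsilon > 0:
        hit = rng.random(len(entity.variable_idx)) < upsilon
        idx = entity.variable_idx[hit]
        if len(idx):
            features[idx] = _different_symbols(features[idx], alphabet_size, rng)
    return dc_replace(entity, features=features)


def replicate(
    parent: ModularEntity,
    mu: float,
    rng: np.random.Generator,
    alphabet_size: int,
    child_id: int = -1,
    birth_time: int = 0,
) -> ModularEntity:
    """Produce one offspring.

    Heritable modules are copied from the parent's current state
    (miscopied with probability ``mu`` each); the non-heritable variable
    part is regenerated to the parent's birth state; the stable part is
    copied exactly.  The offspring's birth snapshot is its own initial
    state.
    """
    features = parent.birth_features.copy()
    her = parent.heritable_idx
    if len(her):
        features[her] = parent.features[her]
        if mu > 0:
            miss = rng.random(len(her)) < mu
            idx = her[miss]
            if len(idx):
                features[idx] = _different_symbols(features[idx], alphabet_size, rng)
    return ModularEntity(
        id=child_id,
        features=features,
        variable_idx=parent.variable_idx.copy(),
        heritable_idx=her.copy(),
        birth_features=features.copy(),
        birth_time=birth_time,
        type_name=parent.type_name,
    )


def measure_similarity(
    parent: ModularEntity,
    offspring: ModularEntity,
    convention: str = "as_printed",
) -> int:
    """Count of identical features between parent and offspring.

    ``as_printed``: heritable indices are compared against the parent's
    birth snapshot, everything else against the current parent.
    ``current_parent``: all indices against the current parent.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if len(parent.features) != len(offspring.features):
        raise ValueError("parent and offspring have different feature lengths")
    reference = parent.features.copy()
    if convention == "as_printed" and len(parent.heritable_idx):
        reference[parent.heritable_idx] = parent.birth_features[parent.heritable_idx]
    return int(np.sum(reference == offspring.features))


def similarity_trial(
    params: VHParameters,
    alphabet_size: int,
    rng: np.random.Generator,
    convention: str = "as_printed",
) -> int:
    """One parent lifetime + replication, returning the similarity count."""
    parent = make_entity(params)
    parent = mutate_lifetime(parent, params.upsilon, rng, alphabet_size)
    child = replicate(parent, params.mu, rng, alphabet_size)
    return measure_similarity(parent, child, convention)


@dataclass(frozen=True)
class OracleResult:
    mean: float
    se: float
    expected: float
    reps: int

    @property
    def z(self) -> float:
        """Standardized deviation of the Monte-Carlo mean from the closed form."""
        if self.se == 0:
            return 0.0 if self.mean == self.expected else float("inf")
        return (self.mean - self.expected) / self.se


def eq4_oracle(
    params: VHParameters,
    alphabet_size: int,
    reps: int,
    seed: int,
    convention: str = "as_printed",
) -> OracleResult:
    """Monte-Carlo check of the closed-form similarity.

    Runs ``reps`` independent lifetime+replication trials through the
    simulator's own operators and compares the mean similarity with
    ``expected_similarity`` evaluated at the same parameters and the
    alphabet's own backmutation probability ``1/(A-1)``.
    """
    rng = np.random.default_rng(seed)
    draws = np.fromiter(
        (
            similarity_trial(params, alphabet_size, rng, convention)
            for _ in range(reps)
        ),
        dtype=np.int64,
        count=reps,
    )
    mean = float(draws.mean())
    se = float(draws.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    # the closed form at the fractions the entity actually realizes
    n_var, n_her = params.module_counts()
    effective = VHParameters(
        I_size=params.I_size,
        V_frac=n_var / params.I_size,
        H_frac=n_her / params.I_size,
        upsilon=params.upsilon,
        mu=params.mu,
        epsilon=default_epsilon(alphabet_size),
    )
    return OracleResult(mean, se, expected_similarity(effective), reps)


# ---------------------------------------------------------------------------
# population dynamics


@dataclass(frozen=True)
class TypeConfig:
    """One replicator type in a population run."""

    name: str
    n0: int
    g: float  # per-entity replication probability per generation
    d: float = 0.0  # per-entity death probability per generation

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")
        if not 0 <= self.g <= 1 or not 0 <= self.d <= 1:
            raise ValueError("g and d must be probabilities")


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of one population run."""

    params: VHParameters
    alphabet_size: int
    types: Tuple[TypeConfig, ...]
    generations: int
    rng_seed: int
    carrying_capacity: Optional[int] = None  # None = unlimited resources
    convention: str = "as_printed"

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.carrying_capacity is not None and self.carrying_capacity < 1:
            raise ValueError("carrying_capacity must be >= 1")
        if not self.types:
            raise ValueError("at least one type required")


@dataclass
class Trajectory:
    """Per-generation record of a run; reproducible bit for bit per seed."""

    config: SimulationConfig
    generations: List[int] = field(default_factory=list)
    counts: List[Dict[str, int]] = field(default_factory=list)
    mean_similarity: List[float] = field(default_factory=list)
    status: str = "completed"

    @property
    def sizes(self) -> List[int]:
        return [sum(c.values()) for c in self.counts]

    def frequency(self, type_name: str) -> List[float]:
        return [
            (c.get(type_name, 0) / n if n else 0.0)
            for c, n in zip(self.counts, self.sizes)
        ]

    def to_tsv(self) -> str:
        lines = ["generation\ttype\tcount\tmean_similarity"]
        for gen, cts, sim in zip(self.generations, self.counts, self.mean_similarity):
            for name in sorted(cts):
                lines.append(f"{gen}\t{name}\t{cts[name]}\t{sim:.6g}")
        return "\n".join(lines) + "\n"


def _run_exact(config: SimulationConfig, rng: np.random.Generator) -> Trajectory:
    """Count-based dynamics for exact-replicator (V = 0) populations."""
    names = [t.name for t in config.types]
    counts = np.array([t.n0 for t in config.types], dtype=np.int64)
    g = np.array([t.g for t in config.types])
    d = np.array([t.d for t in config.types])
    traj = Trajectory(config)
    I = config.params.I_size

    def record(gen: int) -> None:
        traj.generations.append(gen)
        traj.counts.append({n: int(c) for n, c in zip(names, counts)})
        # exact copies: similarity is the full feature count whenever births occur
        traj.mean_similarity.append(float(I))

    record(0)
    for gen in range(1, config.generations + 1):
        deaths = rng.binomial(counts, d)
        births = rng.binomial(counts, g)
        counts = counts - deaths + births
        if config.carrying_capacity is not None:
            total = int(counts.sum())
            excess = total - config.carrying_capacity
            if excess > 0:
                # uniform culling without replacement across all entities
                kept = rng.multivariate_hypergeometric(
                    counts, config.carrying_capacity
                )
                counts = np.asarray(kept, dtype=np.int64)
        record(gen)
        if counts.sum() == 0:
            traj.status = "extinct"
            break
    return traj


def _run_entities(config: SimulationConfig, rng: np.random.Generator) -> Trajectory:
    params = config.params
    A = config.alphabet_size
    population: List[ModularEntity] = []
    rates: Dict[str, Tuple[float, float]] = {t.name: (t.g, t.d) for t in config.types}
    next_id = 0
    for t in config.types:
        for _ in range(t.n0):
            population.append(
                make_entity(params, entity_id=next_id, type_name=t.name)
            )
            next_id += 1
    traj = Trajectory(config)

    def record(gen: int, sims: List[int]) -> None:
        counts: Dict[str, int] = {t.name: 0 for t in config.types}
        for e in population:
            counts[e.type_name] += 1
        traj.generations.append(gen)
        traj.counts.append(counts)
        traj.mean_similarity.append(
            float(np.mean(sims)) if sims else float("nan")
        )

    record(0, [])
    for gen in range(1, config.generations + 1):
        population = [
            mutate_lifetime(e, params.upsilon, rng, A) for e in population
        ]
        survivors: List[ModularEntity] = []
        offspring: List[ModularEntity] = []
        sims: List[int] = []
        for e in population:
            g, d = rates[e.type_name]
            dies = rng.random() < d
            breeds = rng.random() < g
            if breeds:
                child = replicate(e, params.mu, rng, A, next_id, gen)
                next_id += 1
                offspring.append(child)
                sims.append(measure_similarity(e, child, config.convention))
            if not dies:
                survivors.append(e)
        population = survivors + offspring
        if (
            config.carrying_capacity is not None
            and len(population) > config.carrying_capacity
        ):
            keep = rng.choice(
                len(population), size=config.carrying_capacity, replace=False
            )
            keep.sort()
            population = [population[i] for i in keep]
        record(gen, sims)
        if not population:
            traj.status = "extinct"
            break
    return traj


def run(config: SimulationConfig) -> Trajectory:
    """Simulate a population under the configured dynamics."""
    rng = np.random.default_rng(config.rng_seed)
    n_var, _ = config.params.module_counts()
    if n_var == 0:
        return _run_exact(config, rng)
    return _run_entities(config, rng)


@dataclass
class DilutionSummary:
    """Replicate-averaged dilution of the slower of two exact replicators."""

    generations: np.ndarray
    expected_freq_slow: np.ndarray  # closed-form growth expectation
    mean_freq_slow: np.ndarray
    se_freq_slow: np.ndarray
    reps: int

    @property
    def final_mean(self) -> float:
        return float(self.mean_freq_slow[-1])

    @property
    def final_se(self) -> float:
        return float(self.se_freq_slow[-1])


def dilution_experiment(
    g_fast: float,
    g_slow: float,
    generations: int,
    reps: int,
    seed: int,
    n0: int = 200,
) -> DilutionSummary:
    """Two exact-replicator types under unlimited resources.

    With no death and unlimited resources both types grow, yet the
    relative frequency of the slower shrinks toward extreme dilution.
    The deterministic expectation with equal initial numbers is
    ``(1+g_slow)^t / ((1+g_slow)^t + (1+g_fast)^t)``; replicate seeds are
    derived from ``seed`` by fixed increments.
    """
    if g_fast < g_slow:
        raise ValueError("g_fast must be >= g_slow")
    params = VHParameters(I_size=1, V_frac=0.0, H_frac=0.0)
    freqs = np.empty((reps, generations + 1))
    for r in range(reps):
        config = SimulationConfig(
            params=params,
            alphabet_size=2,
            types=(
                TypeConfig("fast", n0, g_fast),
                TypeConfig("slow", n0, g_slow),
            ),
            generations=generations,
            rng_seed=seed + r,
        )
        freqs[r] = run(config).frequency("slow")
    t = np.arange(generations + 1)
    slow_growth = (1 + g_slow) ** t
    fast_growth = (1 + g_fast) ** t
    expected = slow_growth / (slow_growth + fast_growth)
    mean = freqs.mean(axis=0)
    se = (
        freqs.std(axis=0, ddof=1) / np.sqrt(reps)
        if reps > 1
        else np.zeros(generations + 1)
    )
    return DilutionSummary(t, expected, mean, se, reps)
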