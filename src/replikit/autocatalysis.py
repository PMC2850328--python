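"""Autocatalysis detection on stoichiometric networks.

The dynamic model is a token game: the state is a multiset of internal
species, food species are an unlimited reservoir, waste is discarded.
A reaction may fire when its internal reactant *and* catalyst counts are
available; firing consumes reactants, emits products and leaves
catalysts untouched.

A seed multiset *ignites* when some firing sequence reaches a state that
dominates the seed (every seed species at least at its initial count)
with a strict surplus in at least one seed species — the operational
form of "one turn of the cycle returns the seed plus offspring".  It
*sustains* when some sequence returns exactly to the seed but none ever
exceeds it (sequential replacement), and *dies* when the whole reachable
set was exhausted without either.  Searches are bounded (steps and
visited states); a bound hit yields ``undecided`` rather than a claim.

Ignition is monotone: any multiset dominating an igniting seed ignites
via the same witness sequence.  The seed enumeration exploits this to
return only minimal seeds.

All searches are deterministic: seeds are enumerated size-ascending then
lexicographically, and reactions are tried in id order, so witnesses and
reports are bit-stable across runs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations_with_replacement
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .network import NetworkError, ReactionNetwork

__all__ = [
    "SeedMultiset",
    "IgnitionOutcome",
    "SeedSearchResult",
    "AutocatalysisReport",
    "BoundExhausted",
    "can_ignite",
    "replication_ratio",
    "mixed_seed_ratio",
    "classify_order",
    "minimal_seeds",
    "classify_role",
    "kinetic_viability",
    "analyze",
]

#: a seed is a plain mapping species-id -> positive count over internal species
SeedMultiset = Mapping[str, int]

DEFAULT_MAX_STEPS = 40
DEFAULT_MAX_SEED_SIZE = 6
DEFAULT_MAX_STATES = 400_000


class BoundExhausted(NetworkError):
    """Search bound hit before the question could be decided."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class IgnitionOutcome:
    """Result of one bounded ignition search.

    ``witness`` is the shortest igniting firing sequence (reaction ids)
    when ``status == "ignites"``, else ``None``.  ``final_state`` is the
    state reached by the witness.
    """

    status: str  # ignites | sustains | dies | undecided
    witness: Optional[Tuple[str, ...]]
    steps_used: int
    final_state: Optional[Dict[str, int]] = None

    @property
    def ignites(self) -> bool:
        return self.status == "ignites"


class _TokenGame:
    """Compiled token-game semantics for one network.

    ``equivalence`` (optional) is a partition of species ids; domination
    and surplus are then measured on equivalence-class counts, which lets
    "functionally identical" products count toward a seed species.
    """

    def __init__(self, net: ReactionNetwork, equivalence=None):
        self.net = net
        food = set(net.food_ids)
        waste = set(net.waste_ids)
        self.tracked: Tuple[str, ...] = tuple(
            s.id for s in net.species if s.id not in food and s.id not in waste
        )
        self.index = {sid: i for i, sid in enumerate(self.tracked)}
        # class id per tracked-species index (identity partition by default)
        if equivalence is None:
            self.class_of = list(range(len(self.tracked)))
            self.n_classes = len(self.tracked)
        else:
            block_of: Dict[str, int] = {}
            blocks = [sorted(b) for b in equivalence]
            blocks.sort()
            for bi, block in enumerate(blocks):
                for sid in block:
                    block_of[sid] = bi
            next_class = len(blocks)
            self.class_of = []
            for sid in self.tracked:
                if sid in block_of:
                    self.class_of.append(block_of[sid])
                else:
                    self.class_of.append(next_class)
                    next_class += 1
            self.n_classes = next_class

        self.rids: List[str] = []
        self.needs: List[Tuple[Tuple[int, int], ...]] = []
        self.deltas: List[Tuple[Tuple[int, int], ...]] = []
        for r in sorted(net.reactions, key=lambda r: r.id):
            need: Dict[int, int] = {}
            delta: Dict[int, int] = {}
            for sid, n in r.reactants.items():
                if sid in food:
                    continue
                i = self.index[sid]
                need[i] = need.get(i, 0) + n
                delta[i] = delta.get(i, 0) - n
            for sid, n in r.catalysts.items():
                if sid in food:
                    continue
                i = self.index[sid]
                need[i] = need.get(i, 0) + n
            for sid, n in r.products.items():
                if sid in food or sid in waste:
                    continue
                i = self.index[sid]
                delta[i] = delta.get(i, 0) + n
            self.rids.append(r.id)
            self.needs.append(tuple(sorted(need.items())))
            self.deltas.append(tuple(sorted(d for d in delta.items() if d[1] != 0)))

    # -- state helpers --------------------------------------------------

    def state_from_seed(self, seed: SeedMultiset) -> Tuple[int, ...]:
        state = [0] * len(self.tracked)
        for sid, count in seed.items():
            if sid not in self.index:
                raise NetworkError(
                    f"seed species {sid!r} is not an internal species of the network"
                )
            if not isinstance(count, int) or count < 1:
                raise NetworkError(f"seed count for {sid!r} must be a positive int")
            state[self.index[sid]] += count
        if not any(state):
            raise NetworkError("seed must be non-empty")
        return tuple(state)

    def project(self, state: Sequence[int]) -> Tuple[int, ...]:
        proj = [0] * self.n_classes
        for i, n in enumerate(state):
            proj[self.class_of[i]] += n
        return tuple(proj)

    def to_mapping(self, state: Sequence[int]) -> Dict[str, int]:
        return {sid: n for sid, n in zip(self.tracked, state) if n}

    def class_count(self, state: Sequence[int], sid: str) -> int:
        return self.project(state)[self.class_of[self.index[sid]]]

    def enabled_successors(self, state: Tuple[int, ...]):
        for ri in range(len(self.rids)):
            ok = True
            for i, n in self.needs[ri]:
                if state[i] < n:
                    ok = False
                    break
            if not ok:
                continue
            new = list(state)
            for i, d in self.deltas[ri]:
                new[i] += d
            yield ri, tuple(new)

    # -- bounded reachability -------------------------------------------

    def search(
        self,
        seed: SeedMultiset,
        max_steps: int = DEFAULT_MAX_STEPS,
        max_states: int = DEFAULT_MAX_STATES,
        focus: Optional[str] = None,
    ) -> IgnitionOutcome:
        """Breadth-first ignition search from ``seed``.

        When ``focus`` is given, the strict surplus must fall on the focus
        species' class; otherwise any seed class surplus suffices.
        """
        if max_steps < 1:
            raise NetworkError("max_steps must be >= 1")
        start = self.state_from_seed(seed)
        seed_proj = self.project(start)
        seed_classes = [c for c, n in enumerate(seed_proj) if n > 0]
        if focus is not None:
            if focus not in self.index:
                raise NetworkError(f"unknown focus species {focus!r}")
            focus_class = self.class_of[self.index[focus]]
        else:
            focus_class = None

        parents: Dict[Tuple[int, ...], Tuple[Tuple[int, ...], int]] = {}
        depth_of = {start: 0}
        queue = deque([start])
        bounded = False
        returned_exactly = False

        def dominates_with_surplus(proj: Tuple[int, ...]) -> bool:
            for c in seed_classes:
                if proj[c] < seed_proj[c]:
                    return False
            if focus_class is not None:
                return proj[focus_class] > seed_proj[focus_class]
            return any(proj[c] > seed_proj[c] for c in seed_classes)

        while queue:
            state = queue.popleft()
            depth = depth_of[state]
            if depth >= max_steps:
                # cut: any enabled reaction means the frontier was truncated
                for _ in self.enabled_successors(state):
                    bounded = True
                    break
                continue
            for ri, new in self.enabled_successors(state):
                if new == start:
                    # a sequence of >= 1 steps came back to the seed itself
                    returned_exactly = True
                if new in depth_of:
                    continue
                depth_of[new] = depth + 1
                parents[new] = (state, ri)
                proj = self.project(new)
                if dominates_with_surplus(proj):
                    witness = self._trace(parents, new)
                    return IgnitionOutcome(
                        "ignites", witness, depth + 1, self.to_mapping(new)
                    )
                if proj == seed_proj:
                    returned_exactly = True
                if len(depth_of) >= max_states:
                    bounded = True
                    queue.clear()
                    break
                queue.append(new)

        if bounded:
            return IgnitionOutcome("undecided", None, max_steps)
        status = "sustains" if returned_exactly else "dies"
        return IgnitionOutcome(status, None, max(depth_of.values()))

    def _trace(self, parents, state) -> Tuple[str, ...]:
        rids = []
        while state in parents:
            state, ri = parents[state]
            rids.append(self.rids[ri])
        return tuple(reversed(rids))


def can_ignite(
    net: ReactionNetwork,
    seed: SeedMultiset,
    max_steps: int = DEFAULT_MAX_STEPS,
    equivalence=None,
    max_states: int = DEFAULT_MAX_STATES,
) -> IgnitionOutcome:
    """Decide whether ``seed`` ignites the network (bounded search)."""
    return _TokenGame(net, equivalence).search(seed, max_steps, max_states)


def replication_ratio(
    net: ReactionNetwork,
    species: str,
    max_steps: int = DEFAULT_MAX_STEPS,
    max_seed_size: int = DEFAULT_MAX_SEED_SIZE,
    equivalence=None,
    max_states: int = DEFAULT_MAX_STATES,
) -> Fraction:
    """Per-turn replication ratio of a species from its smallest pure seed.

    Finds the smallest ``k`` for which the pure seed ``{species: k}``
    ignites; the ratio is the species count after the shortest igniting
    turn divided by ``k`` (exact rational).  Returns 1 when pure seeds
    only ever sustain (sequential replacement) and 0 when no pure seed of
    size <= ``max_seed_size`` works at all.

    Raises
    ------
    BoundExhausted
        when some pure seed search came back undecided and no smaller
        seed ignited — the answer would be a guess.
    """
    game = _TokenGame(net, equivalence)
    if species not in game.index:
        raise NetworkError(f"{species!r} is not an internal species")
    sustains = False
    undecided = None
    for k in range(1, max_seed_size + 1):
        outcome = game.search({species: k}, max_steps, max_states)
        if outcome.ignites:
            final = game.class_count(
                [outcome.final_state.get(sid, 0) for sid in game.tracked], species
            )
            return Fraction(final, k)
        if outcome.status == "sustains":
            sustains = True
        elif outcome.status == "undecided":
            undecided = k
    if sustains:
        return Fraction(1)
    if undecided is not None:
        raise BoundExhausted(
            f"pure-seed search for {species!r} undecided at k={undecided}",
            partial=Fraction(0),
        )
    return Fraction(0)


def _best_mixed_turn(
    game: "_TokenGame",
    species: str,
    seeds: Sequence[SeedMultiset],
    max_steps: int,
    max_states: int,
) -> Tuple[Fraction, int]:
    """(best per-turn ratio, focal count after that turn) over seed contexts."""
    best = Fraction(0)
    best_final = 0
    for seed in seeds:
        seed = dict(seed)
        if species not in seed:
            seed[species] = 1
        outcome = game.search(seed, max_steps, max_states, focus=species)
        if outcome.ignites:
            final = game.class_count(
                [outcome.final_state.get(sid, 0) for sid in game.tracked], species
            )
            ratio = Fraction(final, seed[species])
            if ratio > best:
                best, best_final = ratio, final
    return best, best_final


def mixed_seed_ratio(
    net: ReactionNetwork,
    species: str,
    seeds: Sequence[SeedMultiset],
    max_steps: int = DEFAULT_MAX_STEPS,
    max_states: int = DEFAULT_MAX_STATES,
    equivalence=None,
) -> Fraction:
    """Best per-turn ratio of ``species`` achievable from mixed seeds.

    For each seed (augmented with one copy of the species when absent) a
    focused search demands a strict surplus of the species while the
    whole seed is regenerated; the ratio is final/initial species count.
    Returns 0 when no seed context multiplies the species.
    """
    game = _TokenGame(net, equivalence)
    if species not in game.index:
        raise NetworkError(f"{species!r} is not an internal species")
    return _best_mixed_turn(game, species, seeds, max_steps, max_states)[0]


def classify_order(
    net: ReactionNetwork,
    species: str,
    equivalence=None,
    max_steps: int = DEFAULT_MAX_STEPS,
    max_seed_size: int = DEFAULT_MAX_SEED_SIZE,
) -> Tuple[int, str]:
    """Order ``n`` of the cycle around a species, with its label.

    ``n`` is the number of focal-equivalent entities present after one
    minimal full turn from the smallest igniting pure seed.  ``n = 0``
    means the species is never regenerated (``no_cycle``); ``n = 1``
    sequential replacement (the cycle returns exactly one equivalent
    entity, an SNCI); ``n >= 2`` autocatalysis of order ``n``.
    """
    game = _TokenGame(net, equivalence)
    if species not in game.index:
        raise NetworkError(f"{species!r} is not an internal species")
    for k in range(1, max_seed_size + 1):
        outcome = game.search({species: k}, max_steps)
        if outcome.ignites:
            n = game.class_count(
                [outcome.final_state.get(sid, 0) for sid in game.tracked], species
            )
            return n, "autocatalytic"
        if outcome.status == "sustains":
            return 1, "sequential_replacement"
    return 0, "no_cycle"


@dataclass
class SeedSearchResult:
    """Minimal igniting seeds, in deterministic order.

    Sequence-like over the seeds; ``incomplete`` is set when some
    candidate came back undecided under the search bounds (the listed
    seeds are still certain).
    """

    seeds: List[Dict[str, int]]
    incomplete: bool = False

    def __iter__(self):
        return iter(self.seeds)

    def __len__(self):
        return len(self.seeds)

    def __getitem__(self, i):
        return self.seeds[i]

    def __eq__(self, other):
        if isinstance(other, SeedSearchResult):
            return self.seeds == other.seeds and self.incomplete == other.incomplete
        return self.seeds == other


def _dominates(a: Mapping[str, int], b: Mapping[str, int]) -> bool:
    return all(a.get(sid, 0) >= n for sid, n in b.items())


def minimal_seeds(
    net: ReactionNetwork,
    max_seed_size: int = DEFAULT_MAX_SEED_SIZE,
    max_steps: int = DEFAULT_MAX_STEPS,
    equivalence=None,
    max_states: int = DEFAULT_MAX_STATES,
    allowed_species: Optional[Sequence[str]] = None,
) -> SeedSearchResult:
    """Exhaustively enumerate minimal igniting seed multisets.

    Seeds are enumerated by ascending total count, lexicographically by
    species id within a size; any candidate dominating an already-found
    igniting seed is non-minimal and skipped (ignition is monotone in
    the seed).  ``allowed_species`` restricts the enumeration alphabet,
    e.g. to a single species for pure-seed questions.
    """
    if max_seed_size < 1:
        raise NetworkError("max_seed_size must be >= 1")
    game = _TokenGame(net, equivalence)
    alphabet = list(game.tracked)
    if allowed_species is not None:
        unknown = set(allowed_species) - set(alphabet)
        if unknown:
            raise NetworkError(f"unknown seed species {sorted(unknown)}")
        alphabet = sorted(allowed_species)
    found: List[Dict[str, int]] = []
    incomplete = False
    for total in range(1, max_seed_size + 1):
        for combo in combinations_with_replacement(alphabet, total):
            seed: Dict[str, int] = {}
            for sid in combo:
                seed[sid] = seed.get(sid, 0) + 1
            if any(_dominates(seed, s) for s in found):
                continue
            outcome = game.search(seed, max_steps, max_states)
            if outcome.ignites:
                found.append(seed)
            elif outcome.status == "undecided":
                incomplete = True
    return SeedSearchResult(found, incomplete)


def _is_catalyst_only(net: ReactionNetwork, species: str) -> bool:
    """True when the species participates only catalytically (never as
    a stoichiometric reactant) yet is a catalyst somewhere."""
    catalyst = False
    for r in net.reactions:
        if species in r.reactants:
            return False
        if species in r.catalysts:
            catalyst = True
    return catalyst


def classify_role(
    net: ReactionNetwork,
    species: str,
    seeds: Optional[SeedSearchResult] = None,
    max_steps: int = DEFAULT_MAX_STEPS,
    max_seed_size: int = DEFAULT_MAX_SEED_SIZE,
    equivalence=None,
    max_states: int = DEFAULT_MAX_STATES,
) -> str:
    """Replicator role of one species.

    ``autonomous_obligate``
        some pure seed ``{species: k}`` ignites — the species can start
        the cycle on its own.
    ``autoinductive_facultative``
        the species takes part only catalytically yet is multiplied by
        the cycle it rides (a side product accelerating a sequence that
        indirectly makes more of it).
    ``dependent``
        multiplied by the cycle and needed in a minimal seed, but unable
        to ignite alone (obligatory partners required).
    ``sequential_replacement``
        regenerated exactly, never in surplus.
    ``non_autocatalytic``
        everything else.
    """
    game = _TokenGame(net, equivalence)
    if species not in game.index:
        raise NetworkError(f"{species!r} is not an internal species")
    if seeds is None:
        seeds = minimal_seeds(
            net, max_seed_size, max_steps, equivalence, max_states
        )

    sustains = False
    for k in range(1, max_seed_size + 1):
        outcome = game.search({species: k}, max_steps, max_states)
        if outcome.ignites:
            return "autonomous_obligate"
        if outcome.status == "sustains":
            sustains = True

    multiplied = (
        _best_mixed_turn(game, species, seeds.seeds, max_steps, max_states)[0] > 1
    )
    if _is_catalyst_only(net, species) and multiplied:
        return "autoinductive_facultative"
    if any(species in s for s in seeds) and multiplied:
        return "dependent"
    if sustains:
        return "sequential_replacement"
    return "non_autocatalytic"


def kinetic_viability(g: float, d: float) -> str:
    """Compare growth against decay: multiplying, replacing or depleting."""
    if g < 0 or d < 0:
        raise ValueError("rates must be non-negative")
    if g > d:
        return "multiplying"
    if g == d:
        return "replacing"
    return "depleting"


@dataclass
class AutocatalysisReport:
    """Per-species summary of an analyzed network."""

    species_id: str
    order_n: int
    order_label: str
    replication_ratio: Fraction
    ratio_basis: str  # pure | mixed | none
    is_autocatalytic: bool
    role: str
    minimal_seeds: List[Dict[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "species": self.species_id,
            "order_n": self.order_n,
            "order_label": self.order_label,
            "replication_ratio": str(self.replication_ratio),
            "replication_ratio_float": float(self.replication_ratio),
            "ratio_basis": self.ratio_basis,
            "is_autocatalytic": self.is_autocatalytic,
            "role": self.role,
            "minimal_seeds": [
                {k: v for k, v in sorted(s.items())} for s in self.minimal_seeds
            ],
        }


def analyze(
    net: ReactionNetwork,
    species: Optional[Sequence[str]] = None,
    max_steps: int = DEFAULT_MAX_STEPS,
    max_seed_size: int = DEFAULT_MAX_SEED_SIZE,
    equivalence=None,
    max_states: int = DEFAULT_MAX_STATES,
) -> Dict[str, AutocatalysisReport]:
    """Full autocatalysis report for every (or the given) internal species.

    The headline ratio is the pure-seed one when a pure seed exists,
    falling back to the best mixed-seed per-turn ratio for species (like
    an obligatory nest) multiplied only in company.
    """
    game = _TokenGame(net, equivalence)
    targets = list(species) if species is not None else list(game.tracked)
    seeds = minimal_seeds(net, max_seed_size, max_steps, equivalence, max_states)
    reports: Dict[str, AutocatalysisReport] = {}
    for sid in targets:
        try:
            pure = replication_ratio(
                net, sid, max_steps, max_seed_size, equivalence, max_states
            )
        except BoundExhausted as exc:
            pure = exc.partial
        if pure > 0:
            ratio, basis = pure, "pure"
            n, label = classify_order(net, sid, equivalence, max_steps, max_seed_size)
        else:
            mixed, final = _best_mixed_turn(
                game, sid, seeds.seeds, max_steps, max_states
            )
            ratio, basis = (mixed, "mixed") if mixed > 0 else (Fraction(0), "none")
            if mixed > 1:
                # cycle-level order: focal count after the best mixed turn
                n, label = final, "autocatalytic"
            else:
                n, label = classify_order(
                    net, sid, equivalence, max_steps, max_seed_size
                )
        role = classify_role(
            net, sid, seeds, max_steps, max_seed_size, equivalence, max_states
        )
        reports[sid] = AutocatalysisReport(
            species_id=sid,
            order_n=n,
            order_label=label,
            replication_ratio=ratio,
            ratio_basis=basis,
            is_autocatalytic=ratio > 1,
            role=role,
            minimal_seeds=[s for s in seeds if sid in s],
        )
    return reports
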