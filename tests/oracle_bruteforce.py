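"""Independent brute-force ignition oracle.

Enumerates *every* firing sequence up to a step bound by plain
depth-first recursion over dict states — no memoization, no compiled
reaction tables, no code shared with the package's search engine.  Only
feasible for tiny networks and bounds; that is its job.
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from typing import Dict, List

from replikit.network import ReactionNetwork


def brute_ignites(net: ReactionNetwork, seed: Dict[str, int], max_steps: int) -> bool:
    """True iff some firing sequence of <= max_steps reaches a state
    dominating the seed with a strict surplus in some seed species."""
    food = set(net.food_ids)
    waste = set(net.waste_ids)
    reactions = sorted(net.reactions, key=lambda r: r.id)

    def dominates_strictly(state: Dict[str, int]) -> bool:
        if any(state.get(s, 0) < n for s, n in seed.items()):
            return False
        return any(state.get(s, 0) > n for s, n in seed.items())

    def step(state: Dict[str, int], remaining: int) -> bool:
        if remaining == 0:
            return False
        for r in reactions:
            ok = all(
                state.get(s, 0) >= n
                for s, n in r.reactants.items()
                if s not in food
            ) and all(
                state.get(s, 0) >= n
                for s, n in r.catalysts.items()
                if s not in food
            )
            if not ok:
                continue
            new = dict(state)
            for s, n in r.reactants.items():
                if s not in food:
                    new[s] = new.get(s, 0) - n
            for s, n in r.products.items():
                if s not in food and s not in waste:
                    new[s] = new.get(s, 0) + n
            if dominates_strictly(new) or step(new, remaining - 1):
                return True
        return False

    return step(dict(seed), max_steps)


def brute_minimal_seeds(
    net: ReactionNetwork, max_seed_size: int, max_steps: int
) -> List[Dict[str, int]]:
    """All minimal igniting seeds, by exhaustive test of every multiset."""
    internal = sorted(net.internal_ids)
    igniting: List[Dict[str, int]] = []
    for total in range(1, max_seed_size + 1):
        for combo in combinations_with_replacement(internal, total):
            seed: Dict[str, int] = {}
            for sid in combo:
                seed[sid] = seed.get(sid, 0) + 1
            if brute_ignites(net, seed, max_steps):
                igniting.append(seed)

    def dominates(a: Dict[str, int], b: Dict[str, int]) -> bool:
        return a != b and all(a.get(s, 0) >= n for s, n in b.items())

    return [s for s in igniting if not any(dominates(s, o) for o in igniting)]
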