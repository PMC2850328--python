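"""Shared fixtures: seeded random reaction networks and entity sets."""

from __future__ import annotations

import random
from typing import List

import pytest

from replikit.network import NetworkError, Reaction, ReactionNetwork, Species


def random_network(rng: random.Random) -> ReactionNetwork:
    """A small random valid network (<= 6 species, <= 6 reactions).

    Food species only ever appear as reactants/catalysts, waste only as
    products, so all structural invariants hold by construction.  At
    least one internal species is guaranteed (seed candidates exist).
    """
    while True:
        n_internal = rng.randint(1, 4)
        n_food = rng.randint(0, 2)
        n_waste = rng.randint(0, 1)
        internal = [f"S{i}" for i in range(n_internal)]
        food = [f"F{i}" for i in range(n_food)]
        waste = [f"W{i}" for i in range(n_waste)]
        reactions: List[Reaction] = []
        for ri in range(rng.randint(1, 6)):
            lhs_pool = internal + food
            rhs_pool = internal + waste
            reactants = {}
            for sid in rng.sample(lhs_pool, min(len(lhs_pool), rng.randint(1, 2))):
                reactants[sid] = rng.randint(1, 2)
            products = {}
            for sid in rng.sample(rhs_pool, min(len(rhs_pool), rng.randint(1, 2))):
                products[sid] = rng.randint(1, 2)
            catalysts = {}
            pool = [s for s in internal if s not in reactants]
            if pool and rng.random() < 0.3:
                catalysts[rng.choice(pool)] = 1
            reactions.append(
                Reaction(
                    id=f"R{ri}",
                    reactants=reactants,
                    products=products,
                    catalysts=catalysts,
                )
            )
        used = set()
        for r in reactions:
            used |= r.species_ids()
        species = (
            [Species(s, "internal") for s in internal if s in used]
            + [Species(s, "food") for s in food if s in used]
            + [Species(s, "waste") for s in waste if s in used]
        )
        if not any(s.role == "internal" for s in species):
            continue
        try:
            return ReactionNetwork(species, reactions)
        except NetworkError:
            continue


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20_260_101)
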