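# replikit

Tools for deciding, exactly, what counts as a replicator.

Multiplication is autocatalysis: an entity A multiplies when one turn of
a reaction cycle, fed from an external food set, returns more than one
entity equivalent to A.  `replikit` makes that statement executable for
small stoichiometric reaction networks and layers the rest of replicator
theory on top of it — selection as an equivalence partition, heredity as
the ability to pass acquired changes on, and a hierarchy that places any
multiplying entity from a formose-cycle sugar to an asexual organism.

It is aimed at origin-of-life and theoretical-biology work where the
networks are small enough to be written by hand and the interesting
questions are structural: *can this species start the cycle alone?  What
is the smallest seed?  Is that side product a replicator too?*

## What it computes

**Autocatalysis** (`replikit.network`, `replikit.autocatalysis`).
Networks are token games: state is a multiset of internal species, food
(Σxᵢ) is unlimited, waste (Σyⱼ) is discarded, catalysts are required but
conserved.  A seed multiset *ignites* when some firing sequence
dominates the seed with a strict surplus — one cycle turn returned the
seed plus offspring.  On top of bounded, exhaustive, deterministic
search the package computes:

- per-species **replication ratios** as exact rationals (the formose
  core doubles glycolaldehyde, ratio 2; the Calvin cycle returns four
  3-phosphoglycerate for every three seeded, ratio 4/3);
- **minimal autocatalytic seeds** (the Calvin cycle ignites from two
  molecules, e.g. {Se7P, DHAP}, but needs three if only PGA is offered);
- **roles**: autonomous/obligate autocatalysts (a bird), dependent
  replicators (a nesting bird, which needs its nest), and
  autoinductive/facultative ones (the nest itself — required only
  catalytically, yet multiplied by the cycle it rides).

**Selection** (`replikit.selection`).  A selective force is a sorting;
entities it cannot sort between are equivalent.  A phenotype function p
partitions an entity set E into equivalence classes (e₁ ~ e₂ ⇔ p(e₁) =
p(e₂)); units of selection, genotype–phenotype decoupling (G ∩ P = ∅)
and the four-quadrant taxonomy of acquired changes follow.  The standard
genetic code ships as the worked fixture: 64 codons, 20 sense classes
plus stop, UCA ~ AGU.

**Heredity** (`replikit.heredity`).  Two classifiers: the (S, N) model
(possible states vs population size; N > S means limited heredity) and
the (V, H) model splitting an entity's information content I into a
stable part, a variable part V and its heritable subset H ≤ V.  With the
per-module lifetime-change probability υ, the copy-error probability μ
and the backmutation probability ε, the expected parent–offspring
similarity has the closed form

    S = I(1−V) + I(V−H)(1−υ) + I·H(1−υ)(1−μ) + I·H·υμε

**Simulation** (`replikit.simulate`).  A discrete-generation stochastic
simulator of modular entities (lifetime change, miscopy, birth/death
rates g and d, optional carrying capacity).  It doubles as the
Monte-Carlo oracle for the closed form above, demonstrates selection
among exact replicators with no death at all, and reproduces the
dilution of the slower of two types under unlimited growth.

## Worked example

Write the built-in networks to disk and analyze the bird–nest cycle
(R1: A1 + x1 → A2 + B; R2: A2 + x2 → 2 A1 + y1, catalysed by B):

```
$ replikit fixtures --emit nets
$ replikit analyze nets/bird_nest.net
```

The per-species section of the JSON report reads (manifest elided):

```json
{
  "A1": {"order_n": 2, "replication_ratio": "2", "ratio_basis": "pure",
         "is_autocatalytic": true, "role": "autonomous_obligate",
         "minimal_seeds": [{"A1": 1}]},
  "A2": {"order_n": 2, "replication_ratio": "2", "ratio_basis": "mixed",
         "is_autocatalytic": true, "role": "dependent",
         "minimal_seeds": [{"A2": 1, "B": 1}]},
  "B":  {"order_n": 2, "replication_ratio": "2", "ratio_basis": "mixed",
         "is_autocatalytic": true, "role": "autoinductive_facultative",
         "minimal_seeds": [{"A2": 1, "B": 1}]}
}
```

Reading it: the bird A1 ignites the cycle alone (pure seed {A1}) and is
doubled by one turn; the nesting bird A2 is equally doubled but only in
company ({A2, B} is the other minimal seed); the nest B is never a
reactant, only an obligatory catalyst, yet each turn leaves one more
nest than before — a dependent, autoinductive replicator with a
per-turn replication ratio of 2.  Classification one-liners work the
same way:

```
$ replikit classify --sn 4 100        # → "limited_hereditary"
$ replikit classify --vh 100 0.5 0.2 --upsilon 0.1 --mu 0.01
                                      # → expected_similarity: 94.82
```

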