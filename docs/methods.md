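# Methods

This note documents the models implemented by `replikit`, the choices
made where the underlying theory leaves the operational details open,
and what the shipped tests do and do not establish.

## Token-game semantics of autocatalysis

A reaction network is analysed as a token game over its internal
species.  Food species are an unlimited reservoir (they never gate a
firing and are not tracked in the state); waste species are a sink
(products to waste are discarded, and waste may never be consumed).
Catalysts are first-class: a reaction needs its catalyst counts present
and returns them unchanged, so "participates only catalytically" is a
syntactic property of the network, not an inference.  No rates are
attached — the game is purely stoichiometric; kinetic viability (g > d)
is a separate one-line predicate.

**Ignition.**  A seed multiset ignites if some firing sequence reaches a
state that dominates the seed (every seed species at or above its
initial count) with a strict surplus in at least one seed species.
This operationalizes "one turn of the cycle should return more
offspring than parents" without rate information.  Domination with
surplus, rather than mere growth of one species, guarantees the cycle
actually regenerated its starting material.  Ignition is monotone in
the seed: a witness sequence for s is enabled from any superset of s,
and the surplus carries over; the seed enumeration relies on this to
skip dominated candidates.

**Search.**  Breadth-first over multiset states with a visited set,
reactions tried in id order — so the witness returned is the shortest
igniting sequence and is bit-stable across runs.  Searches are bounded
by a step count (default 40) and a visited-state cap (default 4·10⁵).
`dies` is asserted only when the reachable set was exhausted within the
bounds; a truncated search returns `undecided`, and the seed report
carries an `incomplete` flag rather than a silent omission.  `sustains`
means some sequence of ≥ 1 steps returns exactly to the seed but none
ever exceeds it — sequential replacement, the order-1 case.

**Replication ratio.**  For a species with an igniting pure seed
{species: k*} (smallest such k*), the ratio is the species count after
the shortest igniting turn divided by k*, kept as an exact rational.
The value is per turn, not per unit time — the theory defines it only
through worked examples and a per-turn reading reproduces both (formose
glycolaldehyde 2, Calvin PGA 4/3).  A species with no pure seed (a
nest) gets ratio 0 from the pure-seed question; its per-turn ratio in
company is computed separately from minimal-seed contexts (a focused
search demanding strict surplus of that species while the whole seed is
regenerated), and the analysis report falls back to this mixed ratio so
that `is_autocatalytic ⇔ ratio > 1` holds for indirect replicators too.

**Roles.**  Precedence matters: a species with an igniting pure seed is
`autonomous_obligate`; otherwise a catalyst-only species multiplied by
the cycle is `autoinductive_facultative` (checked before seed
membership, because an obligatory nest satisfies both conditions);
otherwise a species in some minimal seed that the cycle multiplies is
`dependent`; a species only ever regenerated exactly is
`sequential_replacement`; the rest are `non_autocatalytic`.  A pure
side product that nothing catalytically requires (the naive bird/nest
variant) lands in the last class even though its count grows — it rides
the cycle without the autoinductive feedback loop.

**Equivalence-aware counting.**  All searches optionally take a species
partition; domination, surplus and counts are then measured on
equivalence classes, so functionally-identical products can close a
cycle (A + x → A′ + y with A ~ A′ sustains with order 1).

## Fixture networks

The fixtures encode the canonical worked systems at the coarsest
granularity that preserves their seed structure.  The Calvin skeleton
merges aldolase+phosphatase pairs and the pentose isomerase/epimerase
steps and uses a single always-available catalyst species `ENZ`
(food-role) for "all obligate enzymes present"; CO2 is the only carbon
input.  Hand-verified consequences: no single molecule ignites it, two
can ({Se7P, DHAP}, 24 steps), three PGA return as four (20 steps).  The
reductive citric acid cycle is a single asymmetric loop (the two
oxaloacetates arise on different branches); the thioanalogue-substituted
variant is not reconstructible from available detail and is not
encoded.  In the obligate gene–enzyme fixture the enzyme-production
step carries both DNA and E as catalysts, which is what makes the
coupling fully mutual (with DNA alone as catalyst, DNA would ignite
solo).  Fixtures are frozen; tests pin their canonical serialization by
SHA-256.

## Selection as partitioning

A phenotype function must be total and deterministic; the induced
partition is computed by exact value equality (a caller-supplied
quantizer can coarsen real-valued phenotypes first).  Blocks are
ordered by smallest member id, making partitions reproducible.
Genotype/phenotype structure is carried as index sets over the feature
vector; decoupling is their disjointness.  The taxonomy of acquired
changes is decided purely set-theoretically (change ∩ heritable,
change ∩ phenotype-determining); the trivial/non-trivial distinction
inside heritable-neutral changes has no operational criterion in the
theory and is accepted as caller metadata, never computed.  The
standard genetic code is a frozen in-repo table (cross-checked in the
test suite against biopython's codon table, which serves only as the
independent reference).

## The similarity closed form and its oracle

`expected_similarity` evaluates

    S = I(1−V) + I(V−H)(1−υ) + I·H(1−υ)(1−μ) + I·H·υμε

exactly as stated by the theory.  The formula mixes comparison
references: the non-heritable variable part is compared against the
*current* parent, the heritable part against the parent *at its own
birth* (a heritable module that changed during the parent's life and
was copied faithfully matches the current parent but is not counted).
The simulator therefore implements both conventions —
`as_printed` (heritable vs parent-at-birth, rest vs current) and
`current_parent` — and the Monte-Carlo oracle uses `as_printed`, under
which the simulated mean reproduces the closed form with no free
parameter.  Whether a pure current-parent reference (adding a term
I·H·υ(1−μ)) was intended is left open; both measurements are available.

Offspring construction fixes the remaining freedom: the heritable part
is copied from the parent's current symbols (so acquired genotype
changes are inherited — the heredity contract), the non-heritable
variable part is rebuilt to the parent's birth state (development is
modelled only as this reset; richer developmental operators are out of
scope), and miscopy targets are uniform over the A−1 non-current
symbols, which makes the realized backmutation probability exactly
1/(A−1) = `default_epsilon(A)`.

Parameter conventions: υ acts once per inter-replication interval (not
integrated as a rate); V and H are fractions of I, rounded to module
counts by nearest-integer with H-count clamped below V-count; the
boundary N = S of the (S, N) model counts as unlimited heredity.

## Population dynamics

Bookkeeping is discrete and per generation: every entity independently
dies with probability d and leaves one offspring with probability g
(both evaluated on the generation-start population); lifetime mutation
is applied each generation; an optional carrying capacity is enforced
by uniform random culling, which is neutral with respect to type so
that selection can only arise from g/d differences.  Populations of
exact replicators (no variable modules) are advanced by per-type
binomial counts — exchangeability makes this distributionally identical
to per-entity draws — so unlimited-growth experiments stay cheap.  One
seeded generator drives a run; replicate experiments derive seeds by
fixed increments.  Identical (config, seed) pairs give bit-identical
trajectories.

The dilution experiment compares the replicate-averaged frequency of
the slower of two exact-replicator types against the deterministic
expectation (1+g_s)ᵗ / ((1+g_s)ᵗ + (1+g_f)ᵗ).  The comparison carries a
small Jensen bias (the mean of a ratio is not the ratio of means),
which shrinks as 1/N; the default sizes (200 founders per type, 10
generations, 150 replicates) keep it an order of magnitude below the
Monte-Carlo standard error.

## Problem sizes used by tests and the acceptance script

Desk-scale stoichiometric results are recomputed exactly and
deterministically.  The similarity oracle uses a 20-point grid over
V ∈ {0, 0.3, 0.7, 1}, H ∈ {0, V/2, V}, (υ, μ) ∈ {(.05,.05), (.2,.05)}
at I = 60, A = 4, 10⁴ replications per point, asserting agreement
within 4 standard errors (deterministic points must match exactly).
The seed-search cross-validation runs 200 seeded random networks of at
most 6 species and 6 reactions against a brute-force oracle that
enumerates every firing sequence to depth 5 with no memoization and no
shared code.  These sizes were chosen as comfortably sufficient for the
statistical assertions they back.

## Known limitations

- Reachability in the token game is expensive in general; the bounded
  search is exhaustive only for the small networks the package targets.
  `undecided`/`incomplete` results are possible and are reported, never
  silently dropped.
- Reversible reactions are modelled as two directed reactions; there is
  no thermodynamics, no rate constants, no continuous-time kinetics.
- The order n reported for a species without a pure seed is the focal
  count after its best mixed-seed turn — a cycle-level reading, since a
  per-species order is not well defined there.
- Attractor-based (compositional) heredity, error-threshold theory and
  spatial or sexual population structure are outside the scope of the
  simulator.
- The synthetic random networks used for validation are structurally
  valid but chemically arbitrary; passing the oracle tests shows the
  search is correct, not that real metabolic networks are covered at
  scale.
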