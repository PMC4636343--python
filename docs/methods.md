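# Methods

## The model

`coevolang` simulates the origin of a simple compositional language in a
population of artificial agents, coupled to the biological evolution of the
agents' long-term memory (LTM) capacity for lexical knowledge. Two
transmission channels interact: *cultural* transmission (agents exchange
utterances and learn from them within and across generations) and
*biological* transmission (offspring inherit their parent's lexical-LTM
capacity, with occasional mutation). Selection — natural (who reproduces)
and cultural (who teaches offspring) — acts on *communicative success*
(CS), the fraction of the meaning space an agent decodes correctly from the
other agents' productions.

### Language

The world is a fixed semantic space of integrated meanings
`predicate<agent>` and `predicate<agent, patient>` over typed constituents:
E entities (one pool serves agent and patient roles; reflexive meanings are
excluded), P1 single-argument and P2 double-argument predicates, giving
`E·P1 + P2·E·(E−1)` meanings. The default space (4, 4, 4) holds 64 meanings
over 12 constituents. Utterances are strings of syllables from a 30-symbol
signalling alphabet (internally one character per syllable).

Linguistic knowledge comes in three kinds:

* **Lexical rules** — holistic (whole meaning ↔ whole utterance) or
  compositional (a set of one or two constituents ↔ a contiguous utterance
  fragment). Compositional rules are role-free: an entity constituent binds
  to the agent or patient slot at use time; printed example inventories
  show entity rules unbound, and full compositionality over the space with
  one rule per constituent requires entity rules to serve both S and O.
* **Categories** — S/V/O sets of lexical rules (agent→S, predicate→V,
  patient→O; nominative–accusative, no passive), each membership carrying
  an association weight.
* **Syntactic rules** — local orders (*before*/*after*) between two
  categories, written here as `S<<V` etc.

Rule strengths and association weights live in (0, 1]: +0.1 reward / −0.1
penalty in competition, −0.01 regular forgetting, capped at 1.0, removed
when ≤ 0.

### Memory

Each agent has a 40-slot short-term memory (STM) of meaning–utterance
mappings heard as a listener (FIFO eviction), and three bounded LTM stores:
lexical rules (capacity = the heritable trait), syntactic rules (40) and
categories (40). A full lexical store evicts the weakest rule (ties: the
oldest). Pruning removes rules and memberships at non-positive
strength/weight, then empty categories and order rules whose roles no
longer have a category.

### Communication

A communication is 20 utterance exchanges with fixed speaker/listener
roles. Per exchange: the speaker draws a meaning uniformly, builds
candidate sets (holistic matches plus exact covers of the meaning's role
slots by compositional rules), scores each as

    combined = mean(rule strengths)
             + mean(order-rule strength × mean member association weight)

and emits the utterance of the strongest set, ordering fragments by the
set's order rules and sequencing any remaining freedom randomly. Lacking a
cover, it occasionally (creation rate 0.25) invents a holistic rule with a
random utterance (length uniform on [2, 2+2·k] syllables for a
k-constituent meaning).

The listener receives the utterance plus an environmental cue: the intended
meaning with probability 0.6, otherwise a different uniformly random
meaning. Comprehension interprets the utterance by *segmentation*: rule
subsets whose fragments tile the whole utterance form interpretations;
complete ones become candidate sets, and the cue either joins an exactly
matching interpretation or forms one merged set with the strongest
cue-consistent rules present in the utterance (rules committed to a
conflicting complete interpretation abstain), the cue filling unspecified
slots. With no merge, the cue stands alone. Scoring adds the cue strength
(0.75) to cue-bearing sets.

The exchange succeeds when the winning set's combined strength *reaches*
the confidence threshold 0.75. The cue strength equals the threshold, so a
bare cue succeeds at exactly the margin: this is what lets a knowledge-free
learner store its first mappings, whose meanings come from the cues. There
is no intention check — a confidently wrong interpretation counts as
success. On success the listener stores the perceived mapping (triggering
learning) and both sides reward their chosen set and penalize items that
appear only in competing sets, each item once; on failure chosen-set items
are penalized. Every 10 communications, all strengths and weights decay by
0.01 population-wide.

### Learning

Before insertion, a new mapping is contrasted with every STM mapping
sharing at least one constituent (entities match across slots); the shared
constituents paired with the longest common contiguous substring become a
candidate compositional rule at strength 0.5 (identical repeated mappings
yield the holistic rule). Category and word-order acquisition runs over the
updated STM once per communication: local-order evidence is counted per
rule pair; a pair is *clean* when observed in one order only; two or more
same-role rules cleanly ordered on the same side of one other rule create
(or extend) the corresponding categories and the category-level order rule,
and a single rule cleanly ordered (≥2 mappings) against a member of an
ordered category joins its role's category. Pair-level bookkeeping is what
lets a word-order convention nucleate while global order is still random;
a population-wide consistency requirement would veto itself forever. Only
single-constituent rules are categorized (a two-constituent fragment spans
two roles, so a single membership role is undefined). Same-role categories
merge immediately, so an agent holds at most one S, one V and one O
category.

### Generations

Each generation: (1) 100 communications among the 10 adults (uniform random
ordered pairs); (2) CS evaluated for every agent — for each ordered pair
(speaker j, listener i) and every meaning, j encodes deterministically
(knowledge only: no cue, no creation, no updates) and i decodes by
segmentation; the count of meanings decoded back exactly, normalised by
64·9, is CS_i; the population mean is the understanding rate UR; (3) half
the adults become parents (CS-proportional roulette without replacement
under natural selection, else uniform; all-zero CS falls back to uniform),
each producing one knowledge-free offspring inheriting its capacity
(mutated ±1 with probability 0.05 when mutation is on, floored at 1); (4)
200 communications from an adult teacher (CS-proportional under cultural
selection, else uniform) to a uniformly random offspring; (5) offspring
replace their own parents — the only reading of one-offspring-per-parent
replacement that conserves population size; the non-parent half persists.

UR and mean capacity are sampled on an even generation grid; `Gen` is the
fraction of generations until sampled UR first exceeds 0.8 (1.0 if never);
`peak-UR` is the maximum sample.

## Parameters

| parameter | default | notes |
|---|---|---|
| space (E, P1, P2) | (4, 4, 4) | 64 meanings, 12 constituents |
| population | 10 | constant across generations |
| exchanges / communication | 20 | fixed roles within a communication |
| creation rate | 0.25 | speaker-side holistic invention |
| cue reliability (RC) | 0.6 | probability the cue is the intended meaning |
| cue strength = threshold | 0.75 | bare cue succeeds exactly at the margin |
| competition adjustment | ±0.1 | forgetting 0.01 every 10 communications |
| STM / syntactic / category capacity | 40 | fixed |
| initial lexical capacity | 30 (60) | the heritable trait; Gaussian sd 5 in selection conditions, identical in the baseline |
| intra / inter communications per generation | 100 / 200 | |
| mutation | rate 0.05, step ±1 | equal chances up/down |
| generations × sampling points | 2000 × 201 (full), 200 × 21 (desk) | |

Seeding: one master seed feeds four per-component streams (initialisation,
communication, selection, mutation); experiment replicates derive per-run
seeds by stable hashing of (condition, replicate) mixed with the master
seed, so conditions share comparable randomness and every trajectory is
bit-reproducible.

## What the initial state emulates

The first generation shares eight holistic seed rules (one meaning per
predicate, entities rotated through agent and patient positions so that all
12 constituents are covered) with distinct random utterances — a
preliminary holistic signalling system. This pins the initial UR at
8/64 = 0.125 exactly. Everything beyond those eight meanings must be
bootstrapped through cue-supported storage, pattern extraction and rule
competition; the generator does not emulate semantic innovation, population
growth, spatial structure, or any direct meaning-verification channel, so
high UR here demonstrates convergence of conventions under the stated
mechanisms, not robustness to richer ecologies.

## Numerical and design choices

* Success comparison is `combined strength ≥ threshold`. Under a strict
  `>` the model is provably dead: offspring own no rules, their only
  candidate set is the bare cue at exactly 0.75, nothing is ever stored and
  the language goes extinct within two generations (verified empirically).
  With `≥` the intended bootstrap — early meanings obtained from
  non-linguistic cues — operates, and the reference dynamics (UR rising
  from 0.125 to a high plateau with ample memory; extinction at low
  capacity) reproduce.
* Complete interpretations must segment the heard utterance exactly.
  Substring-only matching lets promiscuous single-syllable fragments join
  every exchange, and their indiscriminate rewards destroy conventions (the
  population converges on mutually unintelligible junk); segmentation makes
  comprehension the inverse of concatenative production.
* Candidate-set enumeration caps: top 3 alternatives per cover slot in
  production, top 10 compositional matches in comprehension, at most three
  fragments per interpretation. Inventories are strength-ranked so the caps
  trim dominated combinations only.
* Order rules accepted into a set strongest-first while acyclic; fragment
  permutation is drawn uniformly among those satisfying the accepted rules
  (first valid permutation in deterministic evaluation).
* Eviction ties break to the oldest rule; duplicate detection is exact
  equality of meaning/constituent pattern and utterance part.
* Occurrence caches for category learning are invalidated by a lexicon
  version counter and updated incrementally (rebuilt wholesale under heavy
  churn); they change nothing observable, only runtime.

## Emergent behaviour and known deviations

With ample memory (capacity ≥ ~20) and no selection at all, a communal
compositional language with a shared word order emerges within a few tens
of generations and UR plateaus near 1.0. At capacity 15 no communal
language ever forms (UR ≈ 0, Gen = 1.0): the lexical store churns too fast
for conventions to survive the transition, during which holistic seeds,
creations and extracted fragments must coexist.

The *location* of this sufficiency threshold is an emergent quantity. In
this implementation it sits near capacity ~18, lower than the ~30 reported
for the reference system; exhaustive cover/segmentation search and exact
duplicate detection make rule inventories more compact than a heuristic
matcher's, and the threshold moves accordingly. Two follow-on consequences
at initial capacity 30: UR converges to a high plateau even without
selection, and because capacity 30 is already sufficient, natural selection
has little to push against — the mean capacity drifts up only slowly
(mutation-supply limited, ~1 unit per 100–200 generations at desk scale)
rather than climbing to ~38. The coevolution machinery itself (capacity–CS
coupling, CS-proportional reproduction, heritable mutable capacity) is
exercised and visible from sub-threshold starting points. The forgetting
clock (every 10 communications population-wide, config-exposed) is a known
sensitivity: a faster clock raises memory pressure and would move the
threshold up.

## Problem sizes

Desk-scale experiments use 5 replicates × 200 generations × 21 sampling
points (baseline conditions) and 5 × 70 × 15 for selection conditions; the
full-scale values (50 × 2000 × 201) remain configurable. The acceptance
script's stochastic entries use exactly these desk sizes.

## Limitations

No semantic innovation, no passive voice, no intention detection, no
overlap of biological and cultural timescales (generations are punctuated),
no population growth or spatial structure. Statistical inference over the
2×2 factorial (ANCOVA / mixed models) is out of scope: the package exports
tidy per-run and marginal-mean tables for external analysis.
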