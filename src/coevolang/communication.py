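"""One utterance exchange: production, cues, comprehension, competition.

Candidate sets bundle the rules an agent brings to bear on one meaning or
utterance.  Their combined strength is

    production:     Avg(str(lexical)) + Avg(aso(categories) * str(syntactic))
    comprehension:  the same, plus the cue strength when a cue is in the set

where the syntactic term averages, over the order rules in the set, the rule
strength times the mean association weight of the lexical members it
regulates; the term is 0 when the set carries no syntax.  The set with the
highest combined strength wins; an exchange succeeds when the listener's
winning set reaches the confidence threshold.  The cue strength equals the
threshold, so a bare correct-or-not cue succeeds at exactly the margin --
this is what lets knowledge-free learners store their first mappings, whose
meanings come from the environmental cues.  There is no
check that the speaker's intended meaning matches the listener's
comprehension -- a confidently wrong interpretation still counts as success.

After each exchange both agents reward the rules of their chosen set and
penalize rules appearing only in competing sets (lateral inhibition), and
regular forgetting decays all strengths population-wide.
"""

from __future__ import annotations

import random
from itertools import combinations, permutations, product
from typing import Optional, Sequence

from .config import SimulationConfig
from .learning import acquire_categories_and_syntax, learn_from_mapping
from .memory import (
    Agent,
    Category,
    LexicalRule,
    ROLE_O,
    ROLE_S,
    ROLE_V,
    SyntacticRule,
    adjust_strength,
    apply_forgetting,
)
from .semantics import Meaning, NO_PATIENT, SemanticSpace, random_utterance

#: Candidate-set enumeration caps: alternatives kept per cover slot in
#: production, and compositional matches considered in comprehension.
#: Inventories are small (<= the lexical capacity) and rules are ranked by
#: strength, so the caps only trim clearly dominated combinations.
MAX_RULES_PER_PART = 2
MAX_COMP_MATCHES = 10


class CandidateSet:
    """A self-consistent bundle of rules (optionally plus a cue).

    ``lex_entries`` pairs each lexical rule with the role(s) it is bound to;
    ``syn_terms`` pairs each applicable order rule with the (category, rule,
    weight) memberships it regulates.  ``meaning`` is the encoded/decoded
    integrated meaning; ``utterance`` the built or heard syllable string.
    """

    __slots__ = (
        "lex_entries",
        "syn_terms",
        "cue_meaning",
        "meaning",
        "utterance",
        "lex_contribution",
        "syn_contribution",
        "strength",
    )

    def __init__(
        self,
        lex_entries: Sequence[tuple[LexicalRule, tuple[str, ...]]],
        syn_terms: Sequence[tuple[SyntacticRule, list[tuple[Category, LexicalRule]]]],
        meaning: Optional[Meaning],
        utterance: Optional[str],
        cue_meaning: Optional[Meaning] = None,
        cue_strength: float = 0.0,
    ):
        self.lex_entries = list(lex_entries)
        self.syn_terms = list(syn_terms)
        self.meaning = meaning
        self.utterance = utterance
        self.cue_meaning = cue_meaning
        if self.lex_entries:
            self.lex_contribution = sum(
                r.strength for r, _ in self.lex_entries
            ) / len(self.lex_entries)
        else:
            self.lex_contribution = 0.0
        if self.syn_terms:
            self.syn_contribution = sum(
                syn.strength
                * (sum(cat.members[r] for cat, r in pairs) / len(pairs))
                for syn, pairs in self.syn_terms
            ) / len(self.syn_terms)
        else:
            self.syn_contribution = 0.0
        self.strength = self.lex_contribution + self.syn_contribution
        if cue_meaning is not None:
            self.strength += cue_strength

    @property
    def has_cue(self) -> bool:
        return self.cue_meaning is not None

    def rules(self) -> list[LexicalRule]:
        return [r for r, _ in self.lex_entries]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CandidateSet({self.meaning}, /{self.utterance}/, "
            f"{self.strength:.3f})"
        )


def _choose_max(sets: Sequence[CandidateSet], rng: Optional[random.Random]):
    """Argmax over combined strength; ties broken randomly (or first)."""
    best = max(s.strength for s in sets)
    top = [s for s in sets if s.strength >= best - 1e-12]
    if rng is not None and len(top) > 1:
        return top[rng.randrange(len(top))]
    return top[0]


# ---------------------------------------------------------------------------
# Production
# ---------------------------------------------------------------------------


def _meaning_slots(meaning: Meaning) -> dict[str, int]:
    slots = {ROLE_V: meaning.pred, ROLE_S: meaning.agent}
    if meaning.has_patient:
        slots[ROLE_O] = meaning.patient
    return slots


def _set_partitions(roles: frozenset):
    """All partitions of a role set into disjoint blocks (precomputed)."""
    items = sorted(roles)
    if len(items) == 1:
        return [[roles]]
    if len(items) == 2:
        a, b = items
        return [
            [frozenset({a}), frozenset({b})],
            [roles],
        ]
    a, b, c = items
    return [
        [frozenset({a}), frozenset({b}), frozenset({c})],
        [frozenset({a, b}), frozenset({c})],
        [frozenset({a, c}), frozenset({b})],
        [frozenset({b, c}), frozenset({a})],
        [roles],
    ]


_PARTITIONS_BY_ROLESET: dict[frozenset, list[list[frozenset]]] = {}


def _partitions(roles: frozenset, parts: list[frozenset]):
    """Exact covers of ``roles`` by disjoint members of ``parts``.

    Role sets have at most three members, so the block structures are
    enumerated once and filtered against the available parts.
    """
    if roles not in _PARTITIONS_BY_ROLESET:
        _PARTITIONS_BY_ROLESET[roles] = _set_partitions(roles)
    available = set(parts)
    for blocks in _PARTITIONS_BY_ROLESET[roles]:
        if all(b in available for b in blocks):
            yield blocks


def _syn_machinery(
    agent: Agent, role_map: dict[str, LexicalRule]
) -> list[tuple[SyntacticRule, list[tuple[Category, LexicalRule]]]]:
    """Order rules applicable to single-role-bound rules with memberships."""
    applicable = []
    for syn in agent.syn_rules:
        ra = role_map.get(syn.first)
        rb = role_map.get(syn.second)
        if ra is None or rb is None or ra is rb:
            continue
        cat_a = agent.category(syn.first)
        cat_b = agent.category(syn.second)
        if cat_a is None or cat_b is None:
            continue
        if ra not in cat_a.members or rb not in cat_b.members:
            continue
        applicable.append((syn, [(cat_a, ra), (cat_b, rb)]))
    return applicable


def _select_syn_terms(agent, role_map):
    """Applicable order rules, accepted strongest-first while consistent.

    With at most three roles and reversed pairs filtered first, the only
    possible inconsistency left is a directed three-cycle, checked inline.
    """
    applicable = _syn_machinery(agent, role_map)
    if len(applicable) > 1:
        applicable.sort(key=lambda t: -t[0].strength)
    accepted = []
    edges: list[tuple[str, str]] = []
    for term in applicable:
        syn = term[0]
        a, b = syn.first, syn.second
        if (b, a) in edges:
            continue
        if len(edges) == 2:
            (p, q), (r, s) = edges
            # adding (a, b) closes a 3-cycle iff the three edges chain
            if (b == p and q == r and s == a) or (
                b == r and s == p and q == a
            ):
                continue
        edges.append((a, b))
        accepted.append(term)
    return accepted, set(edges)


def _production_covers(
    agent: Agent, meaning: Meaning, space: SemanticSpace
) -> list[CandidateSet]:
    """Candidate production sets; ordering (hence utterance) deferred.

    The combined strength of a set does not depend on the chosen fragment
    permutation, so utterances are materialised lazily for the set that wins
    (see :func:`materialize_utterance`).
    """
    sets: list[CandidateSet] = []
    slots = _meaning_slots(meaning)
    all_roles = tuple(slots)
    const_to_role = {c: r for r, c in slots.items()}
    const_set = frozenset(slots.values())

    options: dict[frozenset, list[LexicalRule]] = {}
    for rule in agent.lexicon:
        if rule.is_holistic:
            if rule.meaning == meaning:
                sets.append(
                    CandidateSet([(rule, all_roles)], [], meaning, rule.utterance)
                )
            continue
        if rule.constituents <= const_set:
            roles = frozenset(const_to_role[c] for c in rule.constituents)
            options.setdefault(roles, []).append(rule)
    for part in options:
        options[part].sort(key=lambda r: -r.strength)
        del options[part][MAX_RULES_PER_PART:]

    role_set = frozenset(all_roles)
    for parts in _partitions(role_set, list(options)):
        for combo in product(*(options[p] for p in parts)):
            entries = [
                (rule, tuple(sorted(p))) for rule, p in zip(combo, parts)
            ]
            role_map = {
                next(iter(p)): rule for rule, p in zip(combo, parts) if len(p) == 1
            }
            syn_terms, _edges = _select_syn_terms(agent, role_map)
            sets.append(CandidateSet(entries, syn_terms, meaning, None))
    return sets


def materialize_utterance(
    cset: CandidateSet, rng: Optional[random.Random]
) -> str:
    """Sequence a production set's fragments into its utterance.

    Fragments follow the set's accepted order rules; permutations they leave
    open are drawn seeded-randomly (first valid permutation when ``rng`` is
    None, for deterministic evaluation).
    """
    if cset.utterance is not None:
        return cset.utterance
    entries = cset.lex_entries
    constraints = [(syn.first, syn.second) for syn, _ in cset.syn_terms]
    valid = []
    for perm in permutations(entries):
        pos: dict[str, int] = {}
        for idx, (_rule, roles) in enumerate(perm):
            for ro in roles:
                pos[ro] = idx
        if all(pos[a] < pos[b] for a, b in constraints):
            valid.append(perm)
    if rng is not None and len(valid) > 1:
        perm = valid[rng.randrange(len(valid))]
    else:
        perm = valid[0]
    cset.utterance = "".join(rule.utterance for rule, _ in perm)
    return cset.utterance


def build_production_sets(
    agent: Agent,
    meaning: Meaning,
    space: SemanticSpace,
    rng: Optional[random.Random] = None,
) -> list[CandidateSet]:
    """Candidate sets covering each constituent of ``meaning`` exactly once.

    Holistic matches form singleton sets; compositional rules are combined by
    exact cover over the meaning's role slots.  Word order follows the
    applicable syntactic rules in the set's categories; parts they leave
    unordered are sequenced by a seeded-random permutation (first valid
    permutation when ``rng`` is None, for deterministic evaluation).
    """
    sets = _production_covers(agent, meaning, space)
    for cset in sets:
        materialize_utterance(cset, rng)
    return sets


def produce(
    agent: Agent,
    meaning: Meaning,
    space: SemanticSpace,
    cfg: SimulationConfig,
    rng: Optional[random.Random],
):
    """Speaker's side of an exchange.

    Emits the utterance of the strongest candidate set; lacking any cover,
    occasionally (creation rate) invents a holistic rule with a random
    utterance, stores it, and emits that.  Returns
    ``(utterance | None, chosen_set | None, all_sets, created_flag)``.
    """
    sets = _production_covers(agent, meaning, space)
    if sets:
        chosen = _choose_max(sets, rng)
        materialize_utterance(chosen, rng)
        return chosen.utterance, chosen, sets, False
    if rng is not None and rng.random() < cfg.creation_rate:
        utterance = random_utterance(rng, len(meaning.constituents()))
        rule = agent.insert_lex(LexicalRule(utterance, meaning=meaning))
        chosen = CandidateSet(
            [(rule, tuple(_meaning_slots(meaning)))], [], meaning, utterance
        )
        return utterance, chosen, [chosen], True
    return None, None, [], False


# ---------------------------------------------------------------------------
# Cue
# ---------------------------------------------------------------------------


def generate_cue(
    intended: Meaning,
    space: SemanticSpace,
    rng: random.Random,
    reliability: float,
) -> tuple[Meaning, bool]:
    """Environmental cue: the intended meaning with probability RC, else a
    uniformly random *different* meaning from the space."""
    if len(space) < 2:
        raise ValueError("cue generation needs at least two meanings")
    if rng.random() < reliability:
        return intended, True
    while True:
        m = space.random_meaning(rng)
        if m != intended:
            return m, False


# ---------------------------------------------------------------------------
# Comprehension
# ---------------------------------------------------------------------------


def _bindings(preds, ents, two_arg):
    """Slot assignments for the constituents of a rule subset.

    Yields ``(pred | None, agent | None, patient | None)`` with entity
    constituents assigned to distinct argument slots.
    """
    pred = preds[0] if preds else None
    slots = ("agent", "patient") if two_arg else ("agent",)
    if len(ents) > len(slots):
        return
    if not ents:
        yield (pred, None, None)
        return
    for assignment in permutations(slots, len(ents)):
        agent_c = None
        patient_c = None
        for ent, slot in zip(ents, assignment):
            if slot == "agent":
                agent_c = ent
            else:
                patient_c = ent
        yield (pred, agent_c, patient_c)


def _satisfied_syntax(agent, role_of_rule, spans):
    """Order rules whose member fragments occur in the recorded order."""
    terms = []
    role_map = {ro: rule for rule, ro in role_of_rule.items()}
    for syn in agent.syn_rules:
        ra = role_map.get(syn.first)
        rb = role_map.get(syn.second)
        if ra is None or rb is None or ra is rb:
            continue
        cat_a = agent.category(syn.first)
        cat_b = agent.category(syn.second)
        if cat_a is None or cat_b is None:
            continue
        if ra not in cat_a.members or rb not in cat_b.members:
            continue
        if spans[ra][1] <= spans[rb][0]:
            terms.append((syn, [(cat_a, ra), (cat_b, rb)]))
    return terms


def build_comprehension_sets(
    agent: Agent,
    utterance: str,
    cue_meaning: Optional[Meaning],
    space: SemanticSpace,
    cue_strength: float = 0.0,
) -> list[CandidateSet]:
    """Candidate sets interpreting ``utterance``, optionally under a cue.

    Rule combinations that segment the whole utterance into fragments
    specifying each constituent at most once form *interpretations*.
    Complete interpretations make their own candidate sets; the cue joins an
    interpretation whose meaning matches it exactly, or -- when the rules
    only interpret the utterance partially -- forms one merged set with the
    strongest cue-consistent rules found in the utterance, filling the
    unspecified slots from the cue.  Rules already committed to a complete
    interpretation that conflicts with the cue do not support it.  If the
    cue merges with nothing, it forms a cue-only set.  With
    ``cue_meaning=None`` (knowledge-only evaluation) only complete
    interpretations are returned.
    """
    sets: list[CandidateSet] = []
    merged = False
    seen: set = set()

    def add(entries, syn_terms, meaning, with_cue):
        nonlocal merged
        key = (frozenset(id(r) for r, _ in entries), meaning, with_cue)
        if key in seen:
            return
        seen.add(key)
        if with_cue:
            merged = True
            sets.append(
                CandidateSet(entries, syn_terms, meaning, utterance,
                             cue_meaning=cue_meaning, cue_strength=cue_strength)
            )
        else:
            sets.append(CandidateSet(entries, syn_terms, meaning, utterance))

    comp_matches: list[LexicalRule] = []
    committed: set[int] = set()  # rules inside complete interpretations
    for rule in agent.lexicon:
        if rule.is_holistic:
            if rule.utterance == utterance:
                roles = (
                    (ROLE_V, ROLE_S, ROLE_O)
                    if rule.meaning.has_patient
                    else (ROLE_V, ROLE_S)
                )
                add([(rule, roles)], [], rule.meaning,
                    cue_meaning is not None and cue_meaning == rule.meaning)
        elif rule.utterance in utterance:
            comp_matches.append(rule)
    comp_matches.sort(key=lambda r: -r.strength)
    del comp_matches[MAX_COMP_MATCHES:]

    for subset in _tilings(utterance, comp_matches):
        union: set[int] = set()
        for rule in subset:
            union |= rule.constituents
        preds = [c for c in union if space.is_pred(c)]
        if len(preds) > 1 or len(union) > 3:
            continue
        ents = sorted(c for c in union if space.is_entity(c))
        pos = 0
        spans = {}
        ok = True
        for rule in subset:
            i = utterance.find(rule.utterance, pos)
            spans[rule] = (i, i + len(rule.utterance))
            pos = i + len(rule.utterance)
        if preds and space.is_double_pred(preds[0]):
            templates = (True,)
        elif preds:
            templates = (False,)
        else:
            templates = (False, True)
        for two_arg in templates:
            for pred_c, agent_c, patient_c in _bindings(preds, ents, two_arg):
                interp = _interpretation(
                    agent, space, subset, spans, pred_c, agent_c,
                    patient_c, two_arg,
                )
                if interp is None:
                    continue
                entries, syn_terms, meaning, complete = interp
                if complete:
                    for rule in subset:
                        committed.add(id(rule))
                    add(entries, syn_terms, meaning,
                        cue_meaning is not None and cue_meaning == meaning)

    if cue_meaning is not None and not merged:
        merge = _greedy_cue_merge(
            agent, utterance, cue_meaning, space, comp_matches, committed,
        )
        if merge is not None:
            entries, syn_terms = merge
            add(entries, syn_terms, cue_meaning, True)
    if cue_meaning is not None and not merged:
        sets.append(
            CandidateSet([], [], cue_meaning, utterance,
                         cue_meaning=cue_meaning, cue_strength=cue_strength)
        )
    return sets


def _tilings(utterance: str, rules: list[LexicalRule]):
    """All ways (up to three fragments) to segment ``utterance`` exactly."""
    by_start: dict[int, list[LexicalRule]] = {}
    for rule in rules:
        start = 0
        while True:
            i = utterance.find(rule.utterance, start)
            if i < 0:
                break
            by_start.setdefault(i, []).append(rule)
            start = i + 1
    length = len(utterance)
    out: list[tuple[LexicalRule, ...]] = []
    seen: set = set()

    def walk(pos: int, chosen: list[LexicalRule], consts: frozenset) -> None:
        if pos == length:
            key = frozenset(id(r) for r in chosen)
            if chosen and key not in seen:
                seen.add(key)
                out.append(tuple(chosen))
            return
        if len(chosen) == 3:
            return
        for rule in by_start.get(pos, ()):
            if rule.constituents & consts:
                continue
            chosen.append(rule)
            walk(pos + len(rule.utterance), chosen, consts | rule.constituents)
            chosen.pop()

    walk(0, [], frozenset())
    return out


def _greedy_cue_merge(agent, utterance, cue, space, comp_matches, committed):
    """The cue-merged candidate set: strongest cue-consistent rules first.

    A rule supports the cue when its constituents all occur in the cue's
    meaning, it occurs in the utterance at a span disjoint from already
    accepted rules, and it is not committed to a complete interpretation
    conflicting with the cue.  Returns ``(entries, syn_terms)`` or None when
    no rule supports the cue.
    """
    cue_consts = set(cue.constituents())
    role_of_const = {cue.pred: ROLE_V, cue.agent: ROLE_S}
    if cue.has_patient:
        role_of_const[cue.patient] = ROLE_O
    covered: set[int] = set()
    spans: dict[LexicalRule, tuple[int, int]] = {}
    accepted: list[LexicalRule] = []
    taken: list[tuple[int, int]] = []
    for rule in comp_matches:  # already sorted by descending strength
        if id(rule) in committed:
            continue
        if not rule.constituents <= cue_consts or rule.constituents & covered:
            continue
        span = None
        start = 0
        while True:
            i = utterance.find(rule.utterance, start)
            if i < 0:
                break
            cand = (i, i + len(rule.utterance))
            if all(cand[1] <= s or e <= cand[0] for s, e in taken):
                span = cand
                break
            start = i + 1
        if span is None:
            continue
        accepted.append(rule)
        taken.append(span)
        spans[rule] = span
        covered |= rule.constituents
    if not accepted:
        return None
    role_of_rule = {}
    entries = []
    for rule in accepted:
        roles = tuple(sorted(role_of_const[c] for c in rule.constituents))
        entries.append((rule, roles))
        if len(roles) == 1:
            role_of_rule[rule] = roles[0]
    syn_terms = _satisfied_syntax(agent, role_of_rule, spans)
    return entries, syn_terms


def _interpretation(agent, space, subset, spans, pred_c, agent_c, patient_c,
                    two_arg):
    """Assemble one bound interpretation of a rule subset."""
    role_of_rule: dict[LexicalRule, str] = {}
    entries = []
    for rule in subset:
        roles = []
        for c in rule.constituents:
            if c == pred_c and pred_c is not None:
                roles.append(ROLE_V)
            elif c == agent_c and agent_c is not None:
                roles.append(ROLE_S)
            elif c == patient_c and patient_c is not None:
                roles.append(ROLE_O)
        entries.append((rule, tuple(sorted(roles))))
        if len(rule.constituents) == 1 and len(roles) == 1:
            role_of_rule[rule] = roles[0]
    syn_terms = _satisfied_syntax(agent, role_of_rule, spans)
    complete = (
        pred_c is not None
        and agent_c is not None
        and (patient_c is not None or not two_arg)
    )
    meaning = None
    if complete:
        meaning = Meaning(
            pred_c, agent_c, patient_c if two_arg else NO_PATIENT
        )
        if meaning not in space:
            return None
    return entries, syn_terms, meaning, complete


def _cue_fills(cue: Meaning, pred_c, agent_c, patient_c, two_arg) -> bool:
    """True when the cue agrees with every constituent the rules specify."""
    if two_arg != cue.has_patient:
        return False
    if pred_c is not None and pred_c != cue.pred:
        return False
    if agent_c is not None and agent_c != cue.agent:
        return False
    if patient_c is not None and patient_c != cue.patient:
        return False
    return True


# ---------------------------------------------------------------------------
# Exchange, update, forgetting
# ---------------------------------------------------------------------------


class ExchangeOutcome:
    """Record of one utterance exchange."""

    __slots__ = (
        "success",
        "utterance",
        "intended",
        "understood",
        "cue_correct",
        "created",
        "speaker_chosen",
        "speaker_sets",
        "listener_chosen",
        "listener_sets",
    )

    def __init__(self, **kw):
        for name in self.__slots__:
            setattr(self, name, kw.get(name))


def update_after_exchange(
    speaker: Agent, listener: Agent, outcome: ExchangeOutcome,
    cfg: SimulationConfig,
) -> None:
    """Lateral inhibition after an exchange.

    On success both sides reward the rules, order rules, and association
    weights of their chosen set (+delta, capped at 1.0) and penalize items
    appearing only in competing sets (-delta); membership of the chosen set
    wins when an item sits in both.  On failure chosen-set items are
    penalized and competitors left alone.  Pruning runs afterwards.
    """
    delta = cfg.adjust_amount
    for agent, chosen, all_sets in (
        (speaker, outcome.speaker_chosen, outcome.speaker_sets),
        (listener, outcome.listener_chosen, outcome.listener_sets),
    ):
        if chosen is None:
            continue
        sign = 1.0 if outcome.success else -1.0
        chosen_rules = set(chosen.rules())
        chosen_syn = {syn for syn, _ in chosen.syn_terms}
        chosen_memberships = {
            (id(cat), rule) for _, pairs in chosen.syn_terms for cat, rule in pairs
        }
        for rule in chosen_rules:
            rule.strength = adjust_strength(rule.strength, sign * delta)
        for syn in chosen_syn:
            syn.strength = adjust_strength(syn.strength, sign * delta)
        for _, pairs in chosen.syn_terms:
            seen_pairs = set()
            for cat, rule in pairs:
                if (id(cat), rule) in seen_pairs:
                    continue
                seen_pairs.add((id(cat), rule))
                cat.members[rule] = adjust_strength(
                    cat.members[rule], sign * delta
                )
        if outcome.success:
            # Each competing item is penalized once, regardless of how many
            # competing sets it appears in; chosen-set membership wins.
            competing_rules: set[LexicalRule] = set()
            competing_syn: set[SyntacticRule] = set()
            competing_memberships: set = set()
            for other in all_sets:
                if other is chosen:
                    continue
                for rule, _roles in other.lex_entries:
                    competing_rules.add(rule)
                for syn, pairs in other.syn_terms:
                    competing_syn.add(syn)
                    for cat, rule in pairs:
                        competing_memberships.add((id(cat), cat, rule))
            for rule in competing_rules - chosen_rules:
                rule.strength = adjust_strength(rule.strength, -delta)
            for syn in competing_syn - chosen_syn:
                syn.strength = adjust_strength(syn.strength, -delta)
            for key, cat, rule in competing_memberships:
                if (key, rule) not in chosen_memberships and rule in cat.members:
                    cat.members[rule] = adjust_strength(
                        cat.members[rule], -delta
                    )
        agent.prune()


def run_exchange(
    speaker: Agent,
    listener: Agent,
    space: SemanticSpace,
    cfg: SimulationConfig,
    rng: random.Random,
) -> ExchangeOutcome:
    """One full utterance exchange: produce -> cue -> comprehend -> update."""
    meaning = space.random_meaning(rng)
    utterance, sp_chosen, sp_sets, created = produce(
        speaker, meaning, space, cfg, rng
    )
    if utterance is None:
        return ExchangeOutcome(success=False, intended=meaning, created=False,
                               speaker_sets=[], listener_sets=[])
    cue_meaning, cue_correct = generate_cue(
        meaning, space, rng, cfg.cue_reliability
    )
    li_sets = build_comprehension_sets(
        listener, utterance, cue_meaning, space, cfg.cue_strength
    )
    li_chosen = _choose_max(li_sets, rng)
    success = li_chosen.strength >= cfg.confidence_threshold - 1e-9
    outcome = ExchangeOutcome(
        success=success,
        utterance=utterance,
        intended=meaning,
        understood=li_chosen.meaning,
        cue_correct=cue_correct,
        created=created,
        speaker_chosen=sp_chosen,
        speaker_sets=sp_sets,
        listener_chosen=li_chosen,
        listener_sets=li_sets,
    )
    update_after_exchange(speaker, listener, outcome, cfg)
    if success:
        learn_from_mapping(listener, li_chosen.meaning, utterance, space)
    return outcome


def run_communication(
    speaker: Agent,
    listener: Agent,
    space: SemanticSpace,
    cfg: SimulationConfig,
    rng: random.Random,
) -> list[ExchangeOutcome]:
    """One communication: a fixed number of sequential utterance exchanges.

    Lexical extraction runs on every successful storage; category and
    word-order acquisition over the listener's updated STM runs once per
    communication.
    """
    if speaker is listener:
        raise ValueError("speaker and listener must differ")
    outcomes = [
        run_exchange(speaker, listener, space, cfg, rng)
        for _ in range(cfg.exchanges_per_communication)
    ]
    if any(o.success for o in outcomes):
        acquire_categories_and_syntax(listener, space)
    return outcomes


def exchange_record(outcome: ExchangeOutcome, space: SemanticSpace) -> dict:
    """One JSON-serializable log record for an utterance exchange."""
    fmt = space.format_meaning
    return {
        "intended": fmt(outcome.intended) if outcome.intended else None,
        "utterance": outcome.utterance,
        "understood": (
            fmt(outcome.understood) if outcome.understood else None
        ),
        "cue_correct": outcome.cue_correct,
        "created": bool(outcome.created),
        "success": bool(outcome.success),
        "chosen_strength": (
            round(outcome.listener_chosen.strength, 6)
            if outcome.listener_chosen is not None else None
        ),
    }


def write_exchange_log(outcomes, space: SemanticSpace, path) -> None:
    """Append exchange records to a JSON-lines file (opt-in logging)."""
    import json as _json

    with open(path, "a") as fh:
        for out in outcomes:
            fh.write(_json.dumps(exchange_record(out, space)) + "\n")


__all__ = [
    "CandidateSet",
    "ExchangeOutcome",
    "apply_forgetting",
    "build_comprehension_sets",
    "build_production_sets",
    "generate_cue",
    "exchange_record",
    "produce",
    "run_communication",
    "run_exchange",
    "update_after_exchange",
]
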