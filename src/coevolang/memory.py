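"""Linguistic knowledge and the bounded two-store memory system.

Agents carry a short-term memory (STM) of recently heard meaning-utterance
mappings and three long-term stores (LTM) of acquired knowledge: lexical
rules, syntactic rules, and categories.  Stores are bounded; STM evicts the
oldest mapping (FIFO) while LTM stores evict the weakest rule.  Rule strengths
and association weights live in (0, 1]: they are rewarded/penalized by +-0.1
in competition, decay by 0.01 under forgetting, are capped at 1.0, and any
value that falls to <= 0 marks its owner for removal at the next prune.

The lexical-LTM capacity is the heritable trait of the model; STM and the
syntactic/category LTMs are fixed at 40 units.
"""

from __future__ import annotations

import json
from collections import deque
from typing import Iterable, NamedTuple, Optional

from .semantics import Meaning

NEW_STRENGTH = 0.5

#: Thematic roles map onto syntactic roles: agent -> S, predicate -> V,
#: patient -> O (nominative-accusative; passive voice is excluded).
ROLE_S = "S"
ROLE_V = "V"
ROLE_O = "O"
ROLES = (ROLE_S, ROLE_V, ROLE_O)


class MUMapping(NamedTuple):
    """A meaning-utterance mapping, the unit of linguistic experience."""

    meaning: Meaning
    utterance: str
    arrival: int = 0


class LexicalRule:
    """A lexical rule: holistic (full meaning <-> whole utterance) or
    compositional (a set of 1-2 constituents <-> an utterance fragment).

    Compositional rules are role-free: an entity constituent may fill either
    the agent or the patient slot when the rule is used; predicates always
    fill the predicate slot.  ``birth`` is a per-agent monotone counter used
    to break eviction ties (oldest goes first).
    """

    __slots__ = ("meaning", "constituents", "utterance", "strength", "birth")

    def __init__(
        self,
        utterance: str,
        meaning: Optional[Meaning] = None,
        constituents: Optional[frozenset[int]] = None,
        strength: float = NEW_STRENGTH,
        birth: int = 0,
    ):
        if (meaning is None) == (constituents is None):
            raise ValueError("rule is either holistic or compositional")
        if not utterance:
            raise ValueError("utterance part must be non-empty")
        self.meaning = meaning
        self.constituents = constituents
        self.utterance = utterance
        self.strength = strength
        self.birth = birth

    @property
    def is_holistic(self) -> bool:
        return self.meaning is not None

    @property
    def key(self):
        """Identity for duplicate detection: exact meaning + utterance parts."""
        return (self.meaning, self.constituents, self.utterance)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        part = self.meaning if self.is_holistic else set(self.constituents)
        return f"LexicalRule({part}<->/{self.utterance}/, {self.strength:.2f})"


class SyntacticRule:
    """A local-order rule between two categories, identified by their roles.

    ``(first, second)`` means: utterance fragments of the *first* category's
    members come (not necessarily immediately) before those of the *second*.
    """

    __slots__ = ("first", "second", "strength", "birth")

    def __init__(
        self, first: str, second: str, strength: float = NEW_STRENGTH, birth: int = 0
    ):
        if first == second:
            raise ValueError("syntactic rule must connect two distinct roles")
        self.first = first
        self.second = second
        self.strength = strength
        self.birth = birth

    @property
    def key(self):
        return (self.first, self.second)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SyntacticRule({self.first}<<{self.second}, {self.strength:.2f})"


class Category:
    """A syntactic category: lexical members with association weights.

    The association weight gates how strongly the category's syntactic rules
    apply to a member.  At most one category per syntactic role exists in an
    agent (same-role categories are merged on sight).
    """

    __slots__ = ("role", "members", "birth")

    def __init__(self, role: str, birth: int = 0):
        if role not in ROLES:
            raise ValueError(f"unknown syntactic role {role!r}")
        self.role = role
        self.members: dict[LexicalRule, float] = {}
        self.birth = birth

    def add_member(self, rule: LexicalRule, weight: float = NEW_STRENGTH) -> None:
        if rule not in self.members:
            self.members[rule] = weight

    def mean_weight(self) -> float:
        if not self.members:
            return 0.0
        return sum(self.members.values()) / len(self.members)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Category({self.role}, {len(self.members)} members)"


def adjust_strength(value: float, delta: float) -> float:
    """Apply a competition/forgetting adjustment.

    Gains are capped at 1.0; losses are *not* clamped at zero -- a value
    <= 0 flags the owner for removal at the next prune.
    """
    return min(1.0, value + delta)


class Agent:
    """An artificial language user with bounded STM and LTM stores.

    ``lex_capacity`` (the evolving, heritable trait) bounds the lexical store;
    STM and the syntactic/category stores have fixed capacities.
    """

    STM_CAPACITY = 40
    SYN_CAPACITY = 40
    CAT_CAPACITY = 40

    def __init__(
        self,
        lex_capacity: int,
        stm_capacity: int = STM_CAPACITY,
        syn_capacity: int = SYN_CAPACITY,
        cat_capacity: int = CAT_CAPACITY,
    ):
        if lex_capacity < 1:
            raise ValueError("lexical LTM capacity must be positive")
        self.lex_capacity = lex_capacity
        self.stm_capacity = stm_capacity
        self.syn_capacity = syn_capacity
        self.cat_capacity = cat_capacity
        self.stm: deque[MUMapping] = deque()
        self.lexicon: list[LexicalRule] = []
        self.syn_rules: list[SyntacticRule] = []
        self.categories: list[Category] = []
        self.cs = 0.0
        self._arrival = 0
        self._birth = 0
        # Lexicon-membership version and duplicate index; occurrence caches
        # used by the learning module are invalidated via ``lex_version``.
        self.lex_version = 0
        self._lex_index: dict = {}
        self._occ_cache: dict = {}
        self._occ_version = 0
        self._const_index: dict[int, list[LexicalRule]] = {}
        self._lex_added: list[LexicalRule] = []
        self._lex_removed: list[LexicalRule] = []
        self._cat_by_role: dict[str, Category] = {}

    # -- counters -----------------------------------------------------------

    def next_arrival(self) -> int:
        self._arrival += 1
        return self._arrival

    def _next_birth(self) -> int:
        self._birth += 1
        return self._birth

    # -- STM ----------------------------------------------------------------

    def stm_insert(self, mapping: MUMapping) -> None:
        """Store a mapping; when full, the oldest (smallest arrival) leaves."""
        if len(self.stm) >= self.stm_capacity:
            self.stm.popleft()
        self.stm.append(mapping)

    # -- LTM insertion with lowest-strength eviction ------------------------

    def insert_lex(self, rule: LexicalRule) -> LexicalRule:
        """Insert a lexical rule unless an identical one exists.

        When the store is full the minimum-strength rule (ties: oldest birth)
        is evicted first.  Returns the stored rule (the existing duplicate,
        if any).
        """
        existing = self._lex_index.get(rule.key)
        if existing is not None:
            return existing
        if len(self.lexicon) >= self.lex_capacity:
            victim = self.lexicon[0]
            for r in self.lexicon:
                if r.strength < victim.strength or (
                    r.strength == victim.strength and r.birth < victim.birth
                ):
                    victim = r
            self._drop_lex(victim)
        rule.birth = self._next_birth()
        self.lexicon.append(rule)
        self._lex_index[rule.key] = rule
        self.lex_version += 1
        self._lex_added.append(rule)
        return rule

    def insert_syn(self, rule: SyntacticRule) -> SyntacticRule:
        for r in self.syn_rules:
            if r.key == rule.key:
                return r
        if len(self.syn_rules) >= self.syn_capacity:
            victim = min(self.syn_rules, key=lambda r: (r.strength, r.birth))
            self.syn_rules.remove(victim)
        rule.birth = self._next_birth()
        self.syn_rules.append(rule)
        return rule

    def insert_cat(self, cat: Category) -> Category:
        existing = self._cat_by_role.get(cat.role)
        if existing is not None:
            # Same-role categories are merged immediately.
            for rule, w in cat.members.items():
                existing.add_member(rule, w)
            return existing
        if len(self.categories) >= self.cat_capacity:
            victim = min(self.categories, key=lambda c: (c.mean_weight(), c.birth))
            self.categories.remove(victim)
            self._cat_by_role.pop(victim.role, None)
        cat.birth = self._next_birth()
        self.categories.append(cat)
        self._cat_by_role[cat.role] = cat
        return cat

    def category(self, role: str) -> Optional[Category]:
        return self._cat_by_role.get(role)

    def _drop_lex(self, rule: LexicalRule) -> None:
        self.lexicon.remove(rule)
        self._lex_index.pop(rule.key, None)
        self.lex_version += 1
        self._lex_removed.append(rule)
        for c in self.categories:
            c.members.pop(rule, None)

    # -- pruning ------------------------------------------------------------

    def prune(self) -> None:
        """Discard rules/associations at strength <= 0 and clean up.

        Categories left without members are discarded, and syntactic rules
        whose roles no longer have a category are dropped with them.
        """
        for rule in [r for r in self.lexicon if r.strength <= 0.0]:
            self._drop_lex(rule)
        self.syn_rules = [r for r in self.syn_rules if r.strength > 0.0]
        for c in self.categories:
            dead = [r for r, w in c.members.items() if w <= 0.0]
            for r in dead:
                del c.members[r]
        self.categories = [c for c in self.categories if c.members]
        self._cat_by_role = {c.role: c for c in self.categories}
        live_roles = set(self._cat_by_role)
        self.syn_rules = [
            r for r in self.syn_rules if r.first in live_roles and r.second in live_roles
        ]

    def forget(self, amount: float) -> None:
        """Deduct ``amount`` from every strength and association weight."""
        for r in self.lexicon:
            r.strength -= amount
        for r in self.syn_rules:
            r.strength -= amount
        for c in self.categories:
            for rule in list(c.members):
                c.members[rule] -= amount
        self.prune()

    # -- serialization / inspection ----------------------------------------

    def knowledge_snapshot(self):
        """A deep, hashable snapshot of all knowledge state.

        Used to verify that evaluation passes (e.g. communicative-success
        scoring) leave the agent bit-identical.
        """
        lex = tuple((r.meaning, r.constituents, r.utterance, r.strength)
                    for r in self.lexicon)
        syn = tuple((r.first, r.second, r.strength) for r in self.syn_rules)
        cats = tuple(
            (c.role, tuple(sorted(((m.key, w) for m, w in c.members.items()),
                                  key=lambda kv: repr(kv[0]))))
            for c in self.categories
        )
        stm = tuple(self.stm)
        return (lex, syn, cats, stm, self.lex_capacity)

    def to_json(self) -> str:
        """Dump the knowledge state to JSON (debugging and fixtures)."""
        lex_index = {r: i for i, r in enumerate(self.lexicon)}
        state = {
            "lex_capacity": self.lex_capacity,
            "lexicon": [
                {
                    "meaning": list(r.meaning) if r.is_holistic else None,
                    "constituents": (
                        sorted(r.constituents) if not r.is_holistic else None
                    ),
                    "utterance": r.utterance,
                    "strength": round(r.strength, 6),
                }
                for r in self.lexicon
            ],
            "syntactic_rules": [
                {"order": f"{r.first}<<{r.second}", "strength": round(r.strength, 6)}
                for r in self.syn_rules
            ],
            "categories": [
                {
                    "role": c.role,
                    "members": {
                        str(lex_index[m]): round(w, 6) for m, w in c.members.items()
                    },
                }
                for c in self.categories
            ],
            "stm": [
                {"meaning": list(m.meaning), "utterance": m.utterance}
                for m in self.stm
            ],
        }
        return json.dumps(state, indent=2)


def apply_forgetting(agents: Iterable[Agent], amount: float = 0.01) -> None:
    """Regular forgetting: every strength and weight decays by ``amount``."""
    for a in agents:
        a.forget(amount)
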