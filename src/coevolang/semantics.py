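"""Semantic space and signalling space.

The simulated language talks about a closed world of *integrated meanings*,
each a predicate-argument structure ``predicate<agent>`` or
``predicate<agent, patient>``.  Semantic constituents come in three kinds:

* entities -- animate things that can act or be acted upon; the same pool
  serves both the agent and the patient role,
* single-argument predicates -- actions with an agent only (``run<tiger>``),
* double-argument predicates -- actions with an agent and a distinct patient
  (``chase<tiger, fox>``); meanings with ``agent == patient`` are excluded.

With E entities, P1 single- and P2 double-argument predicates the space holds
``E*P1 + P2*E*(E-1)`` meanings, e.g. 64 for (4, 4, 4) from only 12
constituents -- the gap that makes compositional rules pay off.

Utterances are strings of syllables drawn from a fixed 30-symbol signalling
alphabet; internally one character per syllable.
"""

from __future__ import annotations

import random
from typing import NamedTuple

#: 30-symbol signalling space; one character per syllable.
ALPHABET = "abcdefghijklmnopqrstuvwxyz0123"

NO_PATIENT = -1


class Meaning(NamedTuple):
    """An integrated meaning: predicate<agent> or predicate<agent, patient>.

    Constituents are global integer ids assigned by :class:`SemanticSpace`.
    ``patient`` is :data:`NO_PATIENT` for single-argument meanings.
    """

    pred: int
    agent: int
    patient: int = NO_PATIENT

    @property
    def has_patient(self) -> bool:
        return self.patient != NO_PATIENT

    def constituents(self) -> tuple[int, ...]:
        if self.has_patient:
            return (self.pred, self.agent, self.patient)
        return (self.pred, self.agent)

    def entities(self) -> tuple[int, ...]:
        if self.has_patient:
            return (self.agent, self.patient)
        return (self.agent,)


class SemanticSpace:
    """Enumerated space of integrated meanings over typed constituents.

    Constituent ids are laid out contiguously: entities ``0..E-1``,
    single-argument predicates ``E..E+P1-1``, double-argument predicates
    ``E+P1..E+P1+P2-1``.  Enumeration order is canonical (predicate-major,
    then agent, then patient) so serialized runs are diffable.
    """

    def __init__(self, n_entities: int, n_single: int, n_double: int):
        if n_entities < 1:
            raise ValueError("need at least one entity constituent")
        if n_single < 0 or n_double < 0:
            raise ValueError("predicate counts must be non-negative")
        self.n_entities = n_entities
        self.n_single = n_single
        self.n_double = n_double
        self.entities = range(0, n_entities)
        self.single_preds = range(n_entities, n_entities + n_single)
        self.double_preds = range(
            n_entities + n_single, n_entities + n_single + n_double
        )
        meanings: list[Meaning] = []
        for p in self.single_preds:
            for a in self.entities:
                meanings.append(Meaning(p, a))
        for p in self.double_preds:
            for a in self.entities:
                for b in self.entities:
                    if b != a:
                        meanings.append(Meaning(p, a, b))
        self.meanings: tuple[Meaning, ...] = tuple(meanings)
        self._index = {m: i for i, m in enumerate(meanings)}

    # -- constituent typing -------------------------------------------------

    def is_entity(self, c: int) -> bool:
        return 0 <= c < self.n_entities

    def is_single_pred(self, c: int) -> bool:
        return self.n_entities <= c < self.n_entities + self.n_single

    def is_double_pred(self, c: int) -> bool:
        lo = self.n_entities + self.n_single
        return lo <= c < lo + self.n_double

    def is_pred(self, c: int) -> bool:
        return self.is_single_pred(c) or self.is_double_pred(c)

    @property
    def n_constituents(self) -> int:
        """Total number of semantic constituents (E + P1 + P2)."""
        return self.n_entities + self.n_single + self.n_double

    # -- queries ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.meanings)

    def __contains__(self, m: Meaning) -> bool:
        return m in self._index

    def random_meaning(self, rng: random.Random) -> Meaning:
        """Uniform draw over the enumerated meanings."""
        if not self.meanings:
            raise ValueError("semantic space is empty")
        return self.meanings[rng.randrange(len(self.meanings))]

    # -- rendering ----------------------------------------------------------

    def constituent_name(self, c: int) -> str:
        if self.is_entity(c):
            return f"e{c}"
        if self.is_single_pred(c):
            return f"p{c - self.n_entities}"
        return f"q{c - self.n_entities - self.n_single}"

    def format_meaning(self, m: Meaning) -> str:
        """Human-readable ``pred<agent>`` / ``pred<agent,patient>`` form."""
        name = self.constituent_name
        if m.has_patient:
            return f"{name(m.pred)}<{name(m.agent)},{name(m.patient)}>"
        return f"{name(m.pred)}<{name(m.agent)}>"


def build_semantic_space(
    n_entities: int, n_single: int, n_double: int
) -> SemanticSpace:
    """Build the canonical semantic space for the given constituent counts."""
    return SemanticSpace(n_entities, n_single, n_double)


def random_utterance(rng: random.Random, n_constituents: int) -> str:
    """A fresh holistic utterance for a meaning with ``n_constituents`` parts.

    Length is uniform on ``[2, 2 + 2*n_constituents]`` syllables, each drawn
    i.i.d. from the signalling alphabet.
    """
    length = rng.randint(2, 2 + 2 * n_constituents)
    return "".join(rng.choice(ALPHABET) for _ in range(length))
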