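"""Usage-based learning: pattern extraction, categories, and word order.

Lexical rules are extracted from recurrent patterns across meaning-utterance
mappings: when a new mapping shares semantic constituents and a common
syllable substring with a mapping already in STM, the shared constituents are
paired with the longest common contiguous substring as a new compositional
rule (strength 0.5).

Categories and syntactic rules are acquired from order evidence: when the
fragments of two or more lexical rules sharing a thematic role consistently
precede (or follow) the fragment of a rule with another role across STM
mappings, the same-role rules are associated into a category with the
corresponding syntactic role (agent -> S, predicate -> V, patient -> O) and a
local-order rule between the two categories is recorded.  Same-role
categories are merged immediately, so each agent holds at most one S, one V,
and one O category.
"""

from __future__ import annotations

from typing import Optional

from .memory import (
    Agent,
    Category,
    LexicalRule,
    MUMapping,
    NEW_STRENGTH,
    ROLE_O,
    ROLE_S,
    ROLE_V,
    SyntacticRule,
)
from .semantics import Meaning, SemanticSpace

#: A local order must be observed in at least this many STM mappings, with no
#: counterexample, to count as consistent.
ORDER_EVIDENCE = 2


from functools import lru_cache


@lru_cache(maxsize=65536)
def longest_common_substring(a: str, b: str) -> str:
    """Longest common contiguous substring; ties broken leftmost in ``a``.

    Cached: utterances are drawn from a small, heavily reused convention
    pool once a communal language forms.
    """
    if not a or not b:
        return ""
    best = ""
    # Strings are short (utterances of a few syllables); brute force is fine.
    for i in range(len(a)):
        for j in range(i + len(best) + 1, len(a) + 1):
            if a[i:j] in b:
                best = a[i:j]
            else:
                break
    return best


def shared_pattern(m1: Meaning, m2: Meaning) -> frozenset[int]:
    """Constituents shared by two meanings (entities match across slots).

    Reference form of the comparison inlined in
    :func:`extract_lexical_rules`; kept for tests and readability.
    """
    shared = set(m1.entities()) & set(m2.entities())
    if m1.pred == m2.pred:
        shared.add(m1.pred)
    return frozenset(shared)


def extract_lexical_rules(
    new_mapping: MUMapping, stm
) -> list[LexicalRule]:
    """Candidate rules from contrasting a new mapping with the STM contents.

    Called *before* the new mapping is inserted.  For every stored mapping
    sharing at least one constituent with the new one, the shared-constituent
    pattern is paired with the longest common contiguous substring of the two
    utterances.  Patterns specifying more than two constituents (same
    constituent set, permuted roles) are skipped; identical mappings reduce to
    the (duplicate) holistic rule.  Candidates are returned with strength 0.5
    and deduplicated by exact pattern identity.
    """
    candidates: list[LexicalRule] = []
    seen = set()
    m_new = new_mapping.meaning
    u_new = new_mapping.utterance
    pred_new, agent_new, patient_new = m_new
    chars_new = set(u_new)
    lcs = longest_common_substring
    for old in stm:
        m_old, u_old, _arrival = old
        pred_old, agent_old, patient_old = m_old
        n_shared = 0
        if pred_new == pred_old:
            first = pred_new
            n_shared = 1
        if agent_new == agent_old or agent_new == patient_old:
            if n_shared:
                second = agent_new
            else:
                first = agent_new
            n_shared += 1
        if patient_new >= 0 and (
            patient_new == agent_old or patient_new == patient_old
        ):
            if n_shared == 0:
                first = patient_new
            elif n_shared == 1:
                second = patient_new
            n_shared += 1
        if not n_shared:
            continue
        if m_new == m_old:
            if u_new == u_old:
                key = (m_new, None, u_new)
                if key not in seen:
                    seen.add(key)
                    candidates.append(LexicalRule(u_new, meaning=m_new))
            continue
        if n_shared > 2 or chars_new.isdisjoint(u_old):
            continue
        frag = lcs(u_new, u_old)
        if not frag:
            continue
        shared = (
            frozenset((first,)) if n_shared == 1
            else frozenset((first, second))
        )
        key = (None, shared, frag)
        if key not in seen:
            seen.add(key)
            candidates.append(LexicalRule(frag, constituents=shared))
    return candidates


def local_order(utterance: str, part_a: str, part_b: str) -> Optional[str]:
    """Local order of two fragments in an utterance (first occurrences).

    Returns ``"before"`` if ``part_a`` ends at or before ``part_b`` starts,
    ``"after"`` for the converse, and ``None`` when either part is absent,
    the parts coincide, or their occurrences overlap.
    """
    ia = utterance.find(part_a)
    ib = utterance.find(part_b)
    if ia < 0 or ib < 0 or part_a == part_b:
        return None
    if ia + len(part_a) <= ib:
        return "before"
    if ib + len(part_b) <= ia:
        return "after"
    return None


def _mapping_occurrences(agent: Agent, mapping: MUMapping):
    """Single-constituent-rule occurrences in one mapping, bucketed by role."""
    m = mapping.meaning
    u = mapping.utterance
    index = agent._const_index
    slots = [(m.pred, ROLE_V), (m.agent, ROLE_S)]
    if m.has_patient:
        slots.append((m.patient, ROLE_O))
    occ: dict[str, list] = {}
    for const, role in slots:
        for rule in index.get(const, ()):
            pos = u.find(rule.utterance)
            if pos >= 0:
                occ.setdefault(role, []).append(
                    (rule, pos, pos + len(rule.utterance))
                )
    return occ


def _sync_learning_caches(agent: Agent) -> None:
    """Fold lexicon-membership changes into the occurrence caches.

    ``insert_lex``/``_drop_lex`` record added and removed rules; here the
    constituent index and cached per-mapping occurrence buckets are updated
    incrementally instead of being rebuilt from scratch.
    """
    if agent._occ_version == agent.lex_version:
        return
    if len(agent._lex_added) + len(agent._lex_removed) > 2 * len(agent.lexicon):
        # Heavy churn (store at capacity): a rebuild is cheaper than
        # folding in every change.  Occurrence lists refill lazily.
        agent._occ_cache.clear()
        index = {}
        for rule in agent.lexicon:
            if not rule.is_holistic and len(rule.constituents) == 1:
                (c,) = rule.constituents
                index.setdefault(c, []).append(rule)
        agent._const_index = index
        agent._lex_added.clear()
        agent._lex_removed.clear()
        agent._occ_version = agent.lex_version
        return
    index = agent._const_index
    new_single = [
        r for r in agent._lex_added
        if not r.is_holistic and len(r.constituents) == 1
    ]
    for rule in new_single:
        (c,) = rule.constituents
        index.setdefault(c, []).append(rule)
    if new_single:
        for mapping, occ in agent._occ_cache.items():
            m = mapping.meaning
            slots = {m.pred: ROLE_V, m.agent: ROLE_S}
            if m.has_patient:
                slots[m.patient] = ROLE_O
            for rule in new_single:
                (c,) = rule.constituents
                role = slots.get(c)
                if role is None:
                    continue
                pos = mapping.utterance.find(rule.utterance)
                if pos >= 0:
                    occ.setdefault(role, []).append(
                        (rule, pos, pos + len(rule.utterance))
                    )
    if agent._lex_removed:
        gone = {id(r) for r in agent._lex_removed}
        for c, rules in list(index.items()):
            kept = [r for r in rules if id(r) not in gone]
            if len(kept) != len(rules):
                index[c] = kept
        for occ in agent._occ_cache.values():
            for role, entries in occ.items():
                entries[:] = [t for t in entries if id(t[0]) not in gone]
    agent._lex_added.clear()
    agent._lex_removed.clear()
    agent._occ_version = agent.lex_version


def acquire_categories_and_syntax(agent: Agent, space: SemanticSpace) -> None:
    """Build/extend categories and order rules from STM order evidence.

    For each ordered role pair (r1, r2): collect STM mappings in which a
    rule with role r1 appears entirely before a rule with role r2.  The
    order is consistent when observed in >= 2 mappings with no
    counterexample, and a category is only created when >= 2 distinct rules
    carry the leading role (one rule alone is no category evidence).  New
    memberships and order rules start at strength/weight 0.5; existing ones
    are left untouched, so re-running on an unchanged STM is a no-op.
    """
    if not agent.lexicon or len(agent.stm) < ORDER_EVIDENCE:
        return
    # Occurrence buckets are cached per mapping and updated incrementally as
    # the lexicon's membership changes (strength updates do not matter here).
    _sync_learning_caches(agent)
    cache = agent._occ_cache
    occurrences = []
    for mapping in agent.stm:
        occ = cache.get(mapping)
        if occ is None:
            occ = _mapping_occurrences(agent, mapping)
            cache[mapping] = occ
        occurrences.append(occ)
    if len(cache) > 4 * agent.stm_capacity:
        keep = set(agent.stm)
        stale = [k for k in cache if k not in keep]
        for k in stale:
            del cache[k]

    # Pairwise local-order evidence: for each ordered pair of rules (with
    # their thematic roles in the mapping), count mappings where the first
    # occurs entirely before the second.  Consistency is judged per pair --
    # support in >= 2 mappings with no reverse observation for that pair --
    # so a convention can nucleate locally even while global word order is
    # still random.
    before: dict[tuple, int] = {}
    for occ in occurrences:
        if len(occ) < 2:
            continue
        roles = list(occ.items())
        for i, (r1, ahead) in enumerate(roles):
            for r2, behind in roles[i + 1:]:
                for ra, sa, ea in ahead:
                    for rb, sb, eb in behind:
                        if ra is rb:
                            continue
                        if ea <= sb:
                            key = (ra, rb, r1, r2)
                        elif eb <= sa:
                            key = (rb, ra, r2, r1)
                        else:
                            continue
                        before[key] = before.get(key, 0) + 1

    # A pair is clean when observed in one order only; total clean evidence
    # across a pattern must reach ORDER_EVIDENCE mappings.
    clean = {
        key: n for key, n in before.items()
        if (key[1], key[0], key[3], key[2]) not in before
    }

    # Category creation: two or more distinct rules sharing a role, each
    # cleanly ordered on the same side of the same other rule (two leaders
    # before one target, or two followers after one leader).
    by_target: dict[tuple, set[LexicalRule]] = {}
    by_leader: dict[tuple, set[LexicalRule]] = {}
    for ra, rb, r1, r2 in clean:
        by_target.setdefault((rb, r1, r2), set()).add(ra)
        by_leader.setdefault((ra, r1, r2), set()).add(rb)

    def create(first_rules, second_rules, r1, r2):
        cat1 = agent.category(r1)
        if cat1 is None:
            cat1 = agent.insert_cat(Category(r1))
        for rule in first_rules:
            cat1.add_member(rule, NEW_STRENGTH)
        cat2 = agent.category(r2)
        if cat2 is None:
            cat2 = agent.insert_cat(Category(r2))
        for rule in second_rules:
            cat2.add_member(rule, NEW_STRENGTH)
        agent.insert_syn(SyntacticRule(r1, r2))

    for (rb, r1, r2), leaders in by_target.items():
        if len(leaders) >= 2:
            create(leaders, [rb], r1, r2)
    for (ra, r1, r2), followers in by_leader.items():
        if len(followers) >= 2:
            create([ra], followers, r1, r2)

    # Category extension: once an order between two categories exists, a
    # single rule cleanly ordered (in >= ORDER_EVIDENCE mappings) against a
    # member of the opposite category joins its own role's category.
    for (ra, rb, r1, r2), n in clean.items():
        if n < ORDER_EVIDENCE:
            continue
        cat1 = agent.category(r1)
        cat2 = agent.category(r2)
        if cat1 is None or cat2 is None:
            continue
        if not any(s.first == r1 and s.second == r2 for s in agent.syn_rules):
            continue
        if rb in cat2.members:
            cat1.add_member(ra, NEW_STRENGTH)
        if ra in cat1.members:
            cat2.add_member(rb, NEW_STRENGTH)


def learn_from_mapping(
    agent: Agent, meaning: Meaning, utterance: str, space: SemanticSpace
) -> None:
    """Lexical learning step for a listener that just stored an exchange.

    The new mapping is contrasted with the STM *before* insertion (pattern
    extraction), then inserted.  Category/order acquisition over the updated
    STM runs at communication granularity (see
    :func:`coevolang.communication.run_communication`).
    """
    mapping = MUMapping(meaning, utterance, agent.next_arrival())
    known = agent._lex_index
    for rule in extract_lexical_rules(mapping, agent.stm):
        if rule.key not in known:
            agent.insert_lex(rule)
    agent.stm_insert(mapping)
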