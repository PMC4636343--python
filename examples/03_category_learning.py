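"""Acquire categories and word order from short-term memory evidence.

Three stored mappings in which two entity fragments consistently precede
two predicate fragments yield an S category, a V category, and the shared
local order S << V.
"""

from coevolang import SemanticSpace
from coevolang.experiments import category_learning_agent
from coevolang.learning import acquire_categories_and_syntax

space = SemanticSpace(4, 4, 4)
agent = category_learning_agent(space)
print("STM:", [(space.format_meaning(m.meaning), m.utterance)
               for m in agent.stm])
acquire_categories_and_syntax(agent, space)
for cat in agent.categories:
    print(f"category {cat.role}:",
          sorted(f"/{r.utterance}/" for r in cat.members))
for syn in agent.syn_rules:
    print(f"order rule: {syn.first} << {syn.second} "
          f"(strength {syn.strength})")
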