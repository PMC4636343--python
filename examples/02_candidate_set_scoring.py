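"""Score a production candidate set: the worked three-rule example.

An S entity (strength 0.7), a V double-argument predicate (0.6) and an O
entity (0.5) combine with order rules S<<V (0.8) and S<<O (0.4).  Combined
strength = mean lexical strength + mean of (order strength x mean
association weight of the members it regulates).
"""

import random

from coevolang import SemanticSpace
from coevolang.communication import build_production_sets
from coevolang.experiments import worked_example_agent

space = SemanticSpace(4, 4, 4)
agent, meaning = worked_example_agent(space)
sets = build_production_sets(agent, meaning, space, random.Random(0))
s = sets[0]
print("meaning:         ", space.format_meaning(meaning))
print("lexical term:    ", round(s.lex_contribution, 4))   # 0.6
print("syntactic term:  ", round(s.syn_contribution, 4))   # 0.38
print("combined:        ", round(s.strength, 4))           # 0.98
orders = {build_production_sets(agent, meaning, space,
                                random.Random(k))[0].utterance
          for k in range(30)}
print("possible orders: ", sorted(orders))  # S first; V/O unordered
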