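"""One communication (20 utterance exchanges) between two initial agents.

Both agents start with the same eight holistic seed rules; meanings outside
the seeds need cue support or random creation, so early success is patchy.
"""

import random

from coevolang import SimulationConfig
from coevolang.communication import run_communication
from coevolang.experiments import initial_population

cfg = SimulationConfig()
population, space = initial_population(seed=3)
speaker, listener = population.agents[0], population.agents[1]
log = run_communication(speaker, listener, space, cfg, random.Random(5))
for i, out in enumerate(log):
    print(
        f"exchange {i:2d}: meaning={space.format_meaning(out.intended):>12}"
        f"  utterance={out.utterance or '-':>10}"
        f"  success={out.success}"
    )
print("successes:", sum(o.success for o in log), "/", len(log))
print("listener STM size:", len(listener.stm),
      "| new rules:", len(listener.lexicon) - 8)
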