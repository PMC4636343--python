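"""A reduced natural-selection condition with heritable, mutable capacity.

Initial capacities are Gaussian around 30 (sd 5); parents are chosen in
proportion to communicative success and offspring inherit (and occasionally
mutate) their parent's lexical-LTM capacity.  Expect UR to climb towards a
high plateau; mean capacity moves slowly at the mutation supply rate.
Takes a few minutes on one CPU.
"""

from coevolang import SimulationConfig
from coevolang.evolution import run_simulation
from coevolang.metrics import gen_statistic, peak_ur

cfg = SimulationConfig(
    initial_lex_capacity=30, capacity_sd=5.0,
    natural_selection=True, mutation=True,
    generations=80, sampling_points=17, seed=2,
)
trajectory = run_simulation(cfg)
for generation, ur, cap in trajectory.samples():
    print(f"gen {generation:3d}  UR {ur:5.2f}  mean capacity {cap:5.1f}")
print("peak UR:", round(peak_ur(trajectory), 3),
      "| Gen:", round(gen_statistic(trajectory), 3))
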