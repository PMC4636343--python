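"""Watch a communal language emerge (no selection, ample memory).

With lexical-LTM capacity 60 the understanding rate climbs from 0.125 (the
eight shared seed rules) towards ~1.0 within a few tens of generations as
compositional rules and a shared word order take over.  Takes a minute or
two on one CPU.
"""

from coevolang import SimulationConfig
from coevolang.evolution import run_simulation

cfg = SimulationConfig(
    initial_lex_capacity=60, capacity_sd=0.0,
    generations=25, sampling_points=26, seed=1,
)
trajectory = run_simulation(cfg)
for generation, ur, cap in trajectory.samples():
    bar = "#" * int(40 * ur)
    print(f"gen {generation:3d}  UR {ur:5.2f}  {bar}")
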