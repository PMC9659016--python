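"""Four-objective NSGA-II optimization over the surrogate.

Minimises drying time and energy use while maximising vitamin C and
rehydration capacity over the admissible blanching/drying conditions.
A reduced generation budget keeps this demo around ten seconds.
"""

from berryopt import NSGA2Config, run, surrogate_problem

problem = surrogate_problem()  # published network by default
config = NSGA2Config(generations_per_var=100, front_size=10, seed=3)
result = run(problem, config, seed=3)

front = result.to_frame(problem.var_names, problem.obj_names)
print(f"converged front of {len(front)} solutions "
      f"after {result.generations} generations:")
print(front.round(2).to_string(index=False))

# Every row is a nondominated trade-off: moving along the front swaps
# drying speed and energy against the two product-quality objectives.
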