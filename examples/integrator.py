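"""Integrator: a one-ensemble memory that accumulates its input.

The recurrent identity connection (filter tau) plus input transform tau*I
realize dx/dt = u.  A constant input of 0.5 for one second should charge
the state to 0.5, which then holds after the input switches off.
"""

from nefsim import build
from nefsim.examples import integrator_model

example = integrator_model(n_neurons=100, input_value=0.5, input_duration=1.0)
plan = build(example.model, dt=0.001, seed=0)
record = plan.run(1.5)[example.probes["decoded_state"]]

v = record.values[:, 0]
print(f"state at 0.5 s: {v[499]:.3f}  (ideal 0.25)")
print(f"state at 1.0 s: {v[999]:.3f}  (ideal 0.50)")
print(f"state at 1.5 s: {v[-1]:.3f}  (input off since 1.0 s; memory holds)")
print("(the ensemble ramps with the integral of its input and retains the"
      " value afterwards)")
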