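"""Lorenz attractor: chaotic dynamics from one recurrent ensemble.

2000 LIF neurons represent the three-dimensional state; the recurrent
connection decodes g(x) = tau*f(x) + x where f is the (shifted) Lorenz
vector field.  No input drives the network - baseline firing kicks the
state off the origin.
"""

import numpy as np

from nefsim import build
from nefsim.examples import LorenzParams, lorenz_model

example = lorenz_model(LorenzParams())
plan = build(example.model, dt=0.001, seed=0)
record = plan.run(6.0)[example.probes["decoded_state"]]
v = record.values

x0 = v[:, 0]
big = x0[np.abs(x0) > 0.5]
lobe_switches = int(np.sum(np.diff(np.sign(big)) != 0))
print(f"simulated {record.times[-1]:.0f} s; max state norm "
      f"{np.linalg.norm(v, axis=1).max():.1f} (radius 60)")
print(f"per-dimension std: {np.round(v.std(axis=0), 2)}")
print(f"sign changes of x: {lobe_switches}")
print("(the state stays on the attractor and hops between the two lobes of"
      " the butterfly)")
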