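"""Communication channel: route a band-limited noise signal unchanged.

A stimulus node drives ensemble A, which projects the identity f(x) = x to
ensemble B.  Tracking error is measured against the stimulus passed through
the same synaptic/probe filter cascade as the neural path.
"""

from nefsim import build
from nefsim.examples import NoiseSpec, communication_channel_model
from nefsim.metrics import lowpass_filter, rmse

example = communication_channel_model(
    n_neurons_per_ens=50, noise=NoiseSpec(duration=1.0, limit=5.0, rms=0.5, seed=0))
plan = build(example.model, dt=0.001, seed=0)
data = plan.run(1.0)

stim = data[example.probes["stim"]].values
target_a = lowpass_filter(stim, 0.001, 0.005)          # one 5 ms stage to A
target_b = lowpass_filter(target_a, 0.001, 0.005)      # a second stage to B
err_a = rmse(data[example.probes["decoded_A"]].values, target_a)
err_b = rmse(data[example.probes["decoded_B"]].values, target_b)
print(f"decoded A tracking RMSE: {err_a:.4f}")
print(f"decoded B tracking RMSE: {err_b:.4f}")
print("(both ensembles follow the 0-5 Hz stimulus; B adds one decode stage"
      " of error on top of A's)")
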