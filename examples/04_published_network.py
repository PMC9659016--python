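"""Evaluating the published trained network.

Loads the 3-8-4 network reconstructed from its printed weights and
evaluates it at the published optimal operating condition.
"""

from berryopt import forward, published_network

net = published_network()
print(net.provenance)
print(f"hidden neurons: {net.n_hidden}, activations: "
      f"{net.topology.hidden_activation}/{net.topology.output_activation}")

pred = forward(net, 93.0, 89.0, 1.2)
print("\nprediction at BT=93 s, T=89 degC, v=1.2 m/s:")
print(f"  DT  = {pred['dt_min']:.1f} min")
print(f"  SEC = {pred['sec_mj_kg']:.2f} MJ/kg")
print(f"  VC  = {pred['vc_mg_100g']:.2f} mg/100g")
print(f"  RC  = {pred['rc']:.2f}")

# The quality responses (VC, RC) reconstruct tightly; drying time is within
# a few percent and SEC only loosely, because the original normalization of
# the output layer was never published and is calibrated here by least
# squares against the published front (see docs/methods.md).
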