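"""The LTP/LTD balance that protects stored memories.

Drives one microcomplex with a fixed contextual input for 30 seconds of
simulated time while the climbing fibres stay at their baseline rate (no
teaching), and prints the mean parallel-fibre synaptic weight before and
after. The potentiation from every parallel-fibre spike is cancelled,
per spike, by the baseline depression it becomes eligible for — so the
stored input-output mapping survives activity without teaching, which is
what lets offline replay leave untrained pathways untouched.
"""

import numpy as np

from cbmsim.models import encode_mf, make_encoder
from cbmsim.network import MicrocomplexConfig, build_microcomplex

cfg = MicrocomplexConfig(n_mf=20)
net = build_microcomplex(cfg, seed=7)
enc = make_encoder(cfg.n_mf, [[-1, 1], [-1, 1]])
drive = encode_mf((0.2, -0.3), enc)
baseline = np.full(cfg.n_io, cfg.cf_baseline_hz)

w0 = net.pf_pc.weights.mean()
for _ in range(30_000):
    net.step_network(mf_drive=drive, cf_drive=baseline)
net.reset_to_baseline()
w1 = net.pf_pc.weights.mean()

print(f"mean PF-PC weight before: {w0:.8f}")
print(f"mean PF-PC weight after:  {w1:.8f}")
print(f"drift: {abs(w1 - w0):.2e}  (ceiling {cfg.w_max}; criterion 1e-4 x ceiling)")
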