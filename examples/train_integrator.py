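"""Train a small ring-integrator RNN and probe its stability.

The network receives the initial heading (as cos/sin) for 10 steps and a
scalar angular-velocity stream afterwards; it is trained to output the
cos/sin of the exactly integrated heading.  A well-trained integrator holds
its heading fixed when the velocity input is zeroed.
"""

import numpy as np

import headcode as hc
from headcode.rnn import forward, make_trial_batch

cfg = hc.RNNConfig(
    n_units=64, trial_len=300, n_trials=200, epochs=300,
    batch_size=50, rate_l2=1e-3, seed=0,
)
net = hc.train(cfg, verbose=False)
print(f"test NMSE per epoch: start {net.nmse_trace[0]:.1f} "
      f"-> epoch 50 {net.nmse_trace[50]:.1f} -> final {net.nmse_trace[-1]:.1f}"
      " (mean predictor scores 200)")

# stability probe: zero velocity after initialization -> heading should hold
probe = hc.RNNConfig(**{**cfg.__dict__, "sigma": 0.0, "trial_len": 110,
                        "zero_ahv_fraction": 0.0})
inp, tgt = make_trial_batch(probe, 20, seed=1)
y = forward(net, inp)
theta_hat = np.arctan2(y[..., 1], y[..., 0])
drift = np.abs(np.angle(np.exp(1j * (theta_hat[-1] - theta_hat[10]))))
print(f"median |drift| over 100 zero-velocity steps: {np.median(drift):.3f} rad")
# Drift well below 0.1 rad indicates a line/ring-attractor solution rather
# than decaying memory of the initial heading.
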