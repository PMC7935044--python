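"""Estimate a sparse effective-connectivity Jacobian from a noisy series.

Builds a 20-state Mexican-hat coupled system, simulates it, samples the
states at TR = 0.72 s with measurement noise, and recovers the directed
coupling matrix row by row with the variational GLM + Bayesian model
reduction pipeline.
"""

import numpy as np

from blanketrg import (estimate_jacobian, make_geometry, sample_jacobian,
                       simulate_latent)
from blanketrg.synthgen import TimeSeriesMatrix

geometry = make_geometry(10, 4.0, "grid", seed=1)
system = sample_jacobian(geometry, seed=101)
latent = simulate_latent(system, 720.0, dt=0.12, seed=201)

values = latent.values[::6]                         # decimate to TR
rng = np.random.default_rng(301)
noisy = values + rng.normal(0.0, values.std() / 3.0, values.shape)
series = TimeSeriesMatrix(values=noisy, sampling_interval=0.72)

posterior = estimate_jacobian(series, geometry)

true = system.jacobian
on = np.abs(true - np.diag(np.diag(true))) > 1e-9
est = posterior.support & ~np.eye(20, dtype=bool)
tp = int((est & on).sum())
print(f"true couplings: {int(on.sum())}, retained: {int(est.sum())}, "
      f"of which correct: {tp}")
print(f"on-support correlation with ground truth: "
      f"{np.corrcoef(posterior.mean[on], true[on])[0, 1]:.3f}")
print(f"total variational free energy: {posterior.free_energy:.1f} nats")
print("Each retained entry J_ij is the directed influence of state j on "
      "state i in Hz; the 3-nat reciprocal rule removed the rest.")
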