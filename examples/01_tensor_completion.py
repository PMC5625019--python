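"""Bayesian CP factorization: automatic rank recovery and tensor completion.

Simulates a low-rank 3-way tensor observed through Gaussian noise with 30%
of entries missing, fits the variational model from an overcomplete start,
and reports the recovered rank, the held-out completion error, and a
predictive distribution for one missing entry.
"""

import warnings

import numpy as np

import tffusion as tfn

warnings.filterwarnings("ignore", message="initial rank")

tensor, truth = tfn.gen_cp_tensor(
    shape=(40, 40, 5), rank=3, noise_precision=100.0,
    missing_fraction=0.30, seed=7,
)
state = tfn.fit(tensor, tfn.PriorConfig(r_init=10, seed=7))

held = ~tensor.mask
rmse = np.sqrt(np.mean(
    (tfn.reconstruct(state)[held] - truth.latent_tensor[held]) ** 2
))
idx = tuple(int(i) for i in np.argwhere(held)[0])
pred = tfn.predict(state, idx)

print(f"true rank {truth.true_rank}, recovered rank {state.rank} "
      f"(started from {10})")
print(f"held-out RMSE {rmse:.4f} vs noise std {truth.noise_precision**-0.5:.2f}")
print(f"missing entry {idx}: predicted {pred.mean:+.3f} +/- "
      f"{pred.variance**0.5:.3f}, truth {truth.latent_tensor[idx]:+.3f}")
print(f"ELBO rose monotonically over {len(state.lower_bound_trace)} sweeps: "
      f"{bool(np.all(np.diff(state.lower_bound_trace) >= 0))}")

# The recovered rank matching the planted rank shows the sparsity-inducing
# prior pruning unneeded components; an RMSE near the noise floor means the
# missing entries are recovered about as well as the noise allows.
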