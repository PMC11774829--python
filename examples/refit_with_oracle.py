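"""Refit a noise-free signature mixture and verify against the grid oracle.

Builds a two-signature mixture (70 % oxidative-damage C>A signature,
30 % clock-like), refits it by simulated annealing, and cross-checks the
objective against an exhaustive 0.01-step search over the 2-simplex.
"""

import numpy as np

from adenosig import AnnealingParams, refit_exposures, refit_oracle_grid
from adenosig.simulate import synthetic_signature_matrix

signatures = synthetic_signature_matrix().subset(["SBS18", "SBS1"])
truth = np.array([0.7, 0.3])
vector = signatures.probs @ truth

fit = refit_exposures(vector, signatures, AnnealingParams(seed=42))
oracle = refit_oracle_grid(vector, signatures, step=0.01)

print("true exposures:      SBS18=0.700  SBS1=0.300")
print(f"annealed exposures:  SBS18={fit['SBS18']:.3f}  SBS1={fit['SBS1']:.3f}")
print(f"annealed objective (Euclidean reconstruction error): {fit.reconstruction_error:.2e}")
print(f"grid-oracle optimum at step 0.01:                    {oracle.reconstruction_error:.2e}")
print()
print("The annealer should match the exhaustive optimum to ~1e-3; on a")
print("noise-free mixture both land at (numerically) zero reconstruction error.")
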