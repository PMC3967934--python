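"""Spike-time reliability of noisy-input ensembles at matched firing rate.

For each fractional exponent the constant drive is calibrated so the
noise-free model fires near 14 spikes/s, then repeated trials with
independent alpha-filtered Gaussian noise (sigma = 0.03 nA) are simulated.
The pairwise correlation measure R (0 = unreliable, 1 = perfectly repeatable
spike times) increases as alpha decreases: the memory trace locks spike
times to the shared input structure.
"""

from flif.protocols import reliability_vs_alpha

out = reliability_vs_alpha(alphas=(1.0, 0.6, 0.2), n_trials=10, seed=42)
for alpha, rec in out.items():
    print(f"alpha={alpha}: calibrated I={rec['I']:.3f} nA, "
          f"mean rate {rec['rate']:.1f} sp/s, reliability R={rec['R']:.3f}")
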