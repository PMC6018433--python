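"""Unit size from the periodicity of division-ring fluorescence.

Synthesizes noisy axial fluorescence profiles of filamentous cells with
rings spaced 8.3 um apart, then recovers the spacing from the averaged
power spectrum: the dominant peak at q* gives lambda = 1/q*, and the
unit size is l0 = lambda/2 because ring spacing doubles in long cells.
"""

import numpy as np

import sizechain as sc

cfg = sc.GeneratorConfig(lambda_profile=8.3, profile_noise=0.5, seed=9)
lengths = np.random.default_rng(10).uniform(25, 60, 165)
profiles = sc.generate_profiles(cfg, lengths)
print(f"{profiles['cell_id'].nunique()} cells, sampled every 0.065 um")

spec = sc.estimate_l0_spectral(profiles)
print(f"spectral peak:  q* = {spec.q_star:.3f} 1/um")
print(f"ring spacing:   lambda = 1/q* = {spec.lam:.1f} um")
print(f"unit size:      l0 = lambda/2 = {spec.l0:.1f} um")
print("Despite 50% multiplicative noise the averaged spectrum pins the")
print("septum spacing to within one frequency-grid step.")
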