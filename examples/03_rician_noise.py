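"""Add Rician noise at the standard levels and check its statistics.

Noise levels are fractions of the median cord intensity m_sc: the two
Gaussian channels have sigma = level * m_sc, and the magnitude image
NI = sqrt((I + n1)^2 + n2^2) is Rician-distributed.
"""

import numpy as np

from cordsim import (
    NoiseSpec,
    PhantomParams,
    add_rician_noise,
    generate_phantom,
    median_cord_intensity,
    noise_level_grid,
)

vol, mask, _ = generate_phantom(PhantomParams(seed=0))
m_sc = median_cord_intensity(vol, mask)
print(f"median cord intensity m_sc = {m_sc:.2f}")
print(f"{'level':>6} {'sigma':>7} {'cord SNR':>9}")
for level in noise_level_grid()[1:]:
    spec = NoiseSpec(level, m_sc, seed=42)
    noisy = add_rician_noise(vol, spec)
    cord = noisy.data[mask.data > 0]
    resid = (noisy.data - vol.data)[mask.data > 0]
    print(f"{level:6.0%} {spec.sigma:7.2f} {cord.mean() / resid.std():9.1f}")
# SNR inside the cord falls monotonically with the level; at 1% noise the
# cord is measured at roughly 100:1, at 8% at roughly 12:1.
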