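"""Rician noise model for magnitude MR images.

Magnitude reconstruction maps independent Gaussian noise in the real and
imaginary channels into a Rician distribution:

    NI = sqrt((I + n1)^2 + n2^2)

with n1, n2 independent zero-mean Gaussian fields of equal standard
deviation sigma. Noise levels are expressed as a fraction of the median
cord intensity m_sc, so sigma_l = n_l * m_sc: a "2% noise" image has
sigma equal to 2% of the median intensity inside the cord mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume3D

#: the standard noise-level grid, including the noise-free condition
DEFAULT_NOISE_LEVELS = (0.0, 0.01, 0.02, 0.04, 0.08)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise level, intensity reference, and seed for one Rician draw.

    ``level`` is the dimensionless fraction n_l (0.01 for 1%);
    ``median_cord_intensity`` is m_sc, measured on the noise-free volume
    inside the cord mask; the Gaussian channel standard deviation is their
    product, sigma_l = n_l * m_sc. ``antithetic`` negates both Gaussian
    fields of the seed's draw — pairing a draw with its antithetic twin is
    the standard Monte Carlo variance-reduction device for seed averages.
    """

    level: float
    median_cord_intensity: float
    seed: int = 0
    antithetic: bool = False

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError(f"noise level must be >= 0, got {self.level}")
        if self.median_cord_intensity < 0:
            raise ValueError("median cord intensity must be >= 0")

    @property
    def sigma(self) -> float:
        return self.level * self.median_cord_intensity


def add_rician_noise(vol: Volume3D, spec: NoiseSpec) -> Volume3D:
    """Return the magnitude image of ``vol`` with Rician noise added.

    Deterministic given the seed; a zero noise level returns a bit-equal
    copy. The output is nonnegative everywhere (it is a magnitude).
    """
    if spec.sigma == 0.0:
        return vol.with_data(vol.data.copy())
    rng = np.random.default_rng(spec.seed)
    n1 = rng.normal(0.0, spec.sigma, size=vol.shape)
    n2 = rng.normal(0.0, spec.sigma, size=vol.shape)
    if spec.antithetic:
        n1, n2 = -n1, -n2
    noisy = np.sqrt((vol.data + n1) ** 2 + n2**2)
    return vol.with_data(noisy)


def noise_level_grid() -> list[float]:
    """The standard ascending level grid {0, 1, 2, 4, 8}% as fractions."""
    return list(DEFAULT_NOISE_LEVELS)
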