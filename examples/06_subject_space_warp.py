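"""Carry synthetic volumes into a subject-like space with a warp field.

Template-space synthetics are mapped to subject space by applying a dense
displacement field (in practice the inverse warp produced by an external
registration toolbox; here a smooth synthetic field). The KS comparison
quantifies whether warping preserved the simulated atrophy signal.
"""

import numpy as np

from cordsim import (
    AtrophySpec,
    DeformationField,
    PhantomParams,
    SimulationRecipe,
    apply_warp,
    generate_phantom,
    invert_field,
    registration_impact,
    segments_from_landmarks,
    simulate_atrophy,
)

vol, mask, landmarks = generate_phantom(PhantomParams(seed=0, blur_mm=1.0))
ref, _, _ = simulate_atrophy(SimulationRecipe(vol, mask, AtrophySpec(0.0)))
segs = segments_from_landmarks(landmarks)

# a smooth synthetic "subject" deformation, displacements in mm
nx, ny, nz = vol.shape
x, y, z = np.mgrid[0:nx, 0:ny, 0:nz].astype(float)
d = np.zeros((*vol.shape, 3))
d[..., 0] = 0.3 * np.sin(2 * np.pi * x / nx) * np.cos(2 * np.pi * y / ny)
d[..., 1] = 0.3 * np.cos(2 * np.pi * y / ny) * np.sin(2 * np.pi * z / nz)
d[..., 2] = 0.15 * np.sin(2 * np.pi * z / nz)
field = DeformationField(d, vol.spacing)

inv = invert_field(field)
roundtrip = apply_warp(apply_warp(ref, field), inv)
err = np.abs(roundtrip.data - ref.data)[mask.data > 0]
print(
    "warp -> inverse-warp round trip: mean |error| in cord = "
    f"{err.mean():.3f} intensity units (cord ~ 100)"
)

pairs_t, pairs_w = {}, {}
for a in (2.0, 10.0):
    out, _, _ = simulate_atrophy(SimulationRecipe(vol, mask, AtrophySpec(a)))
    pairs_t[a] = (ref, out)
    pairs_w[a] = (apply_warp(ref, field), apply_warp(out, field))
print(registration_impact(pairs_t, pairs_w, mask, segs).to_string(index=False))
# D is small throughout and shrinks as the atrophy level grows: once the
# atrophy signal dominates the sub-voxel interpolation jitter, the warp
# carries it into subject space with essentially no distortion of its
# intensity signature.
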