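"""Synthetic cervical cord/canal template generator.

Emulates the inputs the simulation pipeline expects from a real spinal-cord
template (T1-weighted contrast, bright cord inside a dark CSF ring, canal
wall, vertebral-disc landmarks) so that every downstream stage is testable
without downloading imaging data. The phantom is deliberately simple — no
vertebral texture, lesions, bias fields or motion — because only the
cord/CSF geometry and contrast matter to the atrophy engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .volume import CordMask, Volume3D, write_nifti


@dataclass
class PhantomParams:
    """Parameters of the synthetic template.

    Defaults give a 32 x 32 x 60 mm cervical-cord-like field of view at
    0.5 x 0.5 x 1.0 mm voxels: a bright, mildly elliptical cord of ~4 mm
    equivalent radius inside a 6.5 mm CSF ring and a bony canal wall, with
    slice index increasing toward the head (C1 superior). The cord tapers,
    drifts and twists slowly along the stack, and every tissue carries
    smooth low-amplitude intensity texture — real cords are not constant-
    intensity cylinders, and perfectly symmetric phantoms phase-lock
    lattice discretization in a way no real image does.
    """

    shape: tuple[int, int, int] = (64, 64, 60)
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    #: equivalent circular radius: the elliptical cross-section has the
    #: same area as a disc of this radius
    cord_radius_mm: float = 4.0
    #: peak-to-peak amplitude of the smooth superior-inferior radius taper
    radius_variation_mm: float = 0.6
    #: minor/major axis ratio of the cord cross-section (1 = circle)
    ellipticity: float = 0.85
    #: amplitude of the smooth per-slice centerline drift
    center_drift_mm: float = 0.3
    #: total rotation of the ellipse orientation over the stack (radians)
    orientation_twist_rad: float = 1.0
    csf_radius_mm: float = 7.0
    wall_radius_mm: float = 8.5
    intensity_cord: float = 100.0
    intensity_csf: float = 30.0
    intensity_wall: float = 60.0
    intensity_background: float = 10.0
    #: in-plane Gaussian blur (mm) applied to intensities only, for
    #: partial-volume realism; never applied to the mask
    blur_mm: float = 0.3
    #: intra-tissue intensity texture: standard deviation (intensity units)
    #: and in-plane correlation length (mm) of a smooth random field added
    #: to the intensities; 0 disables it
    texture_sd: float = 3.0
    texture_corr_mm: float = 0.8
    #: disc landmarks as slice indices: C1 upper extremity, C2/C3 mid-disc,
    #: C5/C6 mid-disc (superior = higher slice index)
    landmark_c1: int = 55
    landmark_c2c3: int = 42
    landmark_c5c6: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ellipticity <= 1.0):
            raise ValueError("ellipticity must lie in (0, 1]")
        major = (
            self.cord_radius_mm + self.radius_variation_mm / 2
        ) / np.sqrt(self.ellipticity)
        if major + self.center_drift_mm >= self.csf_radius_mm:
            raise ValueError("cord (major axis + drift) must stay inside the CSF ring")
        if self.intensity_cord <= self.intensity_csf:
            raise ValueError("T1-w contrast requires cord intensity > CSF intensity")
        marks = (self.landmark_c5c6, self.landmark_c2c3, self.landmark_c1)
        if not (0 <= marks[0] < marks[1] < marks[2] < self.shape[2]):
            raise ValueError(
                "landmarks must be strictly increasing (C5/C6 < C2/C3 < C1) inside the grid"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("shape", "spacing"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def cord_radius_profile(params: PhantomParams) -> np.ndarray:
    """Cord radius (mm) per axial slice: a smooth cosine taper about the mean."""
    nz = params.shape[2]
    z = np.arange(nz)
    return params.cord_radius_mm + 0.5 * params.radius_variation_mm * np.cos(
        2 * np.pi * z / max(nz - 1, 1)
    )


def generate_phantom(
    params: PhantomParams,
) -> tuple[Volume3D, CordMask, pd.DataFrame]:
    """Build the synthetic template, its binary cord mask, and landmark table.

    The cord mask is the set of voxels whose centers lie inside the
    elliptical cord cross-section at each slice. The intensity volume is
    piecewise constant (background / wall / CSF / cord from outside in),
    plus seeded smooth intra-tissue texture, with an optional in-plane
    Gaussian blur for partial-volume realism; neither texture nor blur is
    ever applied to the mask. Deterministic given the seed.
    """
    nx, ny, nz = params.shape
    dx, dy, dz = params.spacing
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = (np.arange(nx) - cx) * dx
    y = (np.arange(ny) - cy) * dy
    rr = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)  # in-plane radius map, mm

    radii = cord_radius_profile(params)
    z = np.arange(nz)
    theta = params.orientation_twist_rad * z / max(nz - 1, 1)
    # smooth, slice-dependent centerline drift (two incommensurate waves)
    off_x = params.center_drift_mm * np.sin(2 * np.pi * z / nz * 1.7 + 0.3)
    off_y = params.center_drift_mm * np.cos(2 * np.pi * z / nz * 2.3 + 1.1)

    vol = np.full(params.shape, params.intensity_background, dtype=float)
    mask = np.zeros(params.shape, dtype=float)
    sqrt_e = np.sqrt(params.ellipticity)
    for k in range(nz):
        sl = vol[:, :, k]
        sl[rr <= params.wall_radius_mm] = params.intensity_wall
        sl[rr <= params.csf_radius_mm] = params.intensity_csf
        # area-preserving ellipse: semi-axes r/sqrt(e) and r*sqrt(e)
        a_ax = radii[k] / sqrt_e
        b_ax = radii[k] * sqrt_e
        xr = (x[:, None] - off_x[k]) * np.cos(theta[k]) + (
            y[None, :] - off_y[k]
        ) * np.sin(theta[k])
        yr = -(x[:, None] - off_x[k]) * np.sin(theta[k]) + (
            y[None, :] - off_y[k]
        ) * np.cos(theta[k])
        # strict inequality: centers exactly on the boundary (possible for
        # integer pixel radii) stay outside, keeping lattice counts closest
        # to the continuous area
        cord = (xr / a_ax) ** 2 + (yr / b_ax) ** 2 < 1.0
        sl[cord] = params.intensity_cord
        mask[:, :, k][cord] = 1.0

    if params.texture_sd > 0:
        rng = np.random.default_rng(params.seed)
        field = rng.normal(size=params.shape)
        sig_t = (params.texture_corr_mm / dx, params.texture_corr_mm / dy, 1.0)
        field = ndimage.gaussian_filter(field, sigma=sig_t)
        field *= params.texture_sd / field.std()
        vol = vol + field

    if params.blur_mm > 0:
        sig = (params.blur_mm / dx, params.blur_mm / dy, 0.0)
        vol = ndimage.gaussian_filter(vol, sigma=sig)

    landmarks = pd.DataFrame(
        {
            "label": ["C5C6", "C2C3", "C1"],
            "slice": [params.landmark_c5c6, params.landmark_c2c3, params.landmark_c1],
        }
    )
    landmarks["z_mm"] = landmarks["slice"] * dz

    affine = np.diag([dx, dy, dz, 1.0])
    return (
        Volume3D(vol, params.spacing, affine),
        CordMask(mask, params.spacing, affine),
        landmarks,
    )


def median_cord_intensity(vol: Volume3D, mask: CordMask) -> float:
    """Median intensity over the cord-mask voxels (mask > 0).

    This is the reference scale for noise levels: a noise level of n%
    means a Gaussian channel standard deviation of n% of this median.
    """
    sel = mask.data > 0
    if not sel.any():
        raise ValueError("cannot take the median over an empty mask")
    return float(np.median(vol.data[sel]))


def write_phantom(
    params: PhantomParams, out_dir: str | Path, stem: str = "phantom"
) -> dict[str, Path]:
    """Write template + mask NIfTIs, landmark TSV, and a labeled landmark NIfTI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol, mask, landmarks = generate_phantom(params)
    paths = {
        "template": out_dir / f"{stem}_t1.nii.gz",
        "mask": out_dir / f"{stem}_cordmask.nii.gz",
        "landmarks_tsv": out_dir / f"{stem}_landmarks.tsv",
        "landmarks_nii": out_dir / f"{stem}_landmarks.nii.gz",
    }
    write_nifti(vol, paths["template"])
    write_nifti(mask, paths["mask"])
    landmarks.to_csv(paths["landmarks_tsv"], sep="\t", index=False)

    # integer-labeled single-voxel landmarks on the cord centerline
    lab = np.zeros(params.shape, dtype=np.uint8)
    cx, cy = params.shape[0] // 2, params.shape[1] // 2
    for i, row in landmarks.iterrows():
        lab[cx, cy, int(row["slice"])] = i + 1
    nib.save(nib.Nifti1Image(lab, vol.affine), paths["landmarks_nii"])
    return paths
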