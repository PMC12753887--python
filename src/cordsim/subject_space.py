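"""Subject-space adapter: deformation fields and external-tool orchestration.

Carrying synthetic template-space images into a subject's native space
requires cord segmentation, vertebral labeling, and non-rigid template
registration — all external tools (the Spinal Cord Toolbox). This module
only *drives* those tools and applies their deformation fields; it never
re-implements segmentation or the registration optimizer. Warp application
and its validation are computed in-repo.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .evaluation import SegmentDef, ks_statistic
from .volume import CordMask, Volume3D


class ExternalToolError(RuntimeError):
    """An external executable is missing or exited nonzero."""


@dataclass
class DeformationField:
    """Dense voxel-wise displacement field in physical mm.

    ``displacements`` has shape (nx, ny, nz, 3): for each voxel, the mm
    offset added to its physical position to find where intensities are
    pulled from. ``direction`` labels whether this is the forward
    template-to-subject warp W or its inverse.
    """

    displacements: np.ndarray
    spacing: tuple[float, float, float]
    direction: Literal["forward", "inverse"] = "forward"

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[3] != 3:
            raise ValueError(
                f"displacement field must have shape (nx, ny, nz, 3), "
                f"got {self.displacements.shape}"
            )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]  # type: ignore[return-value]

    def matches(self, vol: Volume3D | CordMask) -> bool:
        return self.shape == vol.shape and np.allclose(self.spacing, vol.spacing)


def read_field(path: str | Path) -> DeformationField:
    """Load a displacement-field NIfTI (3 vector components, mm units)."""
    img = nib.load(Path(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)  # tolerate the common (nx, ny, nz, 1, 3) layout
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"{path}: expected a 3-component displacement field, got shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DeformationField(data, spacing)


def write_field(field: DeformationField, path: str | Path) -> None:
    img = nib.Nifti1Image(
        field.displacements.astype(np.float32), np.diag([*field.spacing, 1.0])
    )
    nib.save(img, Path(path))


def apply_warp(vol: Volume3D, field: DeformationField) -> Volume3D:
    """Trilinear pullback of intensities along the displacement field.

    output(x) = input(x + d(x)), with d in mm converted to voxel units per
    axis. Out-of-grid samples take the nearest boundary value, so constant
    volumes map to constant volumes and no artificial zeros enter the CSF.
    """
    if not field.matches(vol):
        raise ValueError("volume and deformation field must share one voxel grid")
    nx, ny, nz = vol.shape
    grid = np.mgrid[0:nx, 0:ny, 0:nz].astype(float)
    coords = [
        grid[ax] + field.displacements[..., ax] / vol.spacing[ax] for ax in range(3)
    ]
    out = ndimage.map_coordinates(
        vol.data.astype(float), coords, order=1, mode="nearest"
    )
    return vol.with_data(out)


def invert_field(field: DeformationField, n_iter: int = 30) -> DeformationField:
    """Numerically invert a displacement field by fixed-point iteration.

    Iterates d_inv(x) <- -d(x + d_inv(x)); converges for smooth,
    diffeomorphic-scale deformations (the regime template registration
    operates in).
    """
    d = field.displacements
    spacing = np.asarray(field.spacing)
    nx, ny, nz = field.shape
    grid = np.mgrid[0:nx, 0:ny, 0:nz].astype(float)
    d_inv = np.zeros_like(d)
    for _ in range(n_iter):
        coords = [grid[ax] + d_inv[..., ax] / spacing[ax] for ax in range(3)]
        sampled = np.stack(
            [
                ndimage.map_coordinates(d[..., ax], coords, order=1, mode="nearest")
                for ax in range(3)
            ],
            axis=-1,
        )
        d_inv = -sampled
    direction = "inverse" if field.direction == "forward" else "forward"
    return DeformationField(d_inv, field.spacing, direction)


def run_external_registration(
    subject_t1: str | Path,
    template: str | Path,
    out_dir: str | Path,
    sct_bin: str = "sct_register_to_template",
    extra_args: Sequence[str] = (),
    dry_run: bool = False,
) -> tuple[Path, Path] | list[str]:
    """Drive the external toolbox's segmentation + labeling + registration.

    Builds the command line for the toolbox's template-registration entry
    point (which internally runs cord detection, centerline computation,
    cropping, segmentation and vertebral labeling) and returns the paths of
    the forward and inverse warp files it produces. With ``dry_run=True``
    the exact command is returned without executing anything.

    Raises :class:`ExternalToolError` naming the missing executable if the
    toolbox is not installed — deliberately distinct from data errors.
    """
    out_dir = Path(out_dir)
    cmd = [
        sct_bin,
        "-i", str(subject_t1),
        "-t", str(template),
        "-ofolder", str(out_dir),
        *extra_args,
    ]
    if dry_run:
        return cmd
    if shutil.which(sct_bin) is None:
        raise ExternalToolError(
            f"external registration tool {sct_bin!r} not found on PATH; "
            "install the Spinal Cord Toolbox or pass dry_run=True"
        )
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        tail = "\n".join(proc.stderr.splitlines()[-20:])
        raise ExternalToolError(
            f"{sct_bin} exited with code {proc.returncode}:\n{tail}"
        )
    fwd = out_dir / "warp_template2anat.nii.gz"
    inv = out_dir / "warp_anat2template.nii.gz"
    for p in (fwd, inv):
        if not p.exists():
            raise ExternalToolError(f"expected warp file {p} was not produced")
    return fwd, inv


def registration_impact(
    template_pairs: dict[float, tuple[Volume3D, Volume3D]],
    warped_pairs: dict[float, tuple[Volume3D, Volume3D]],
    mask: CordMask,
    segments: dict[str, SegmentDef],
) -> pd.DataFrame:
    """KS comparison of atrophy-difference distributions across spaces.

    For each atrophy level, both dicts supply (atrophy-free, atrophied)
    volume pairs — one in template space, one after warping. Within each
    segment, the voxel-wise intensity differences (free minus atrophied)
    inside the cord mask are compared between spaces with the two-sample KS
    test. Small D throughout means the registration step preserves the
    simulated atrophy signal.
    """
    rows = []
    for level, (t_free, t_atr) in sorted(template_pairs.items()):
        if level not in warped_pairs:
            raise ValueError(f"missing warped pair for atrophy level {level}")
        w_free, w_atr = warped_pairs[level]
        for name, seg in segments.items():
            sel = mask.data[:, :, seg.slices] > 0
            d_template = (t_free.data - t_atr.data)[:, :, seg.slices][sel]
            d_warped = (w_free.data - w_atr.data)[:, :, seg.slices][sel]
            ks = ks_statistic(d_template, d_warped)
            rows.append(
                {
                    "segment": name,
                    "atrophy_percent": level,
                    "D": ks.D,
                    "p": ks.p,
                }
            )
    return pd.DataFrame(rows)
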