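"""Validation statistics for simulated cord atrophy.

Covers the quantities an atrophy-simulation study reports: per-segment
cross-sectional area (CSA) and the CSA-difference atrophy estimate,
boundary-ring integrity at the CSF/cord interface (pooled-variance t-test
plus Cohen's d), the two-sample Kolmogorov-Smirnov D statistic on intensity
distributions, paired intensity tables, and RMSE / Pearson agreement
between measurement series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .volume import CordMask, StructuringElement, Volume3D, boundary_ring

SEGMENT_NAMES = ("C1C5", "C1C2", "C2C5")


@dataclass(frozen=True)
class SegmentDef:
    """A named cervical segment as a half-open axial slice interval [lo, hi).

    Segments are anchored at mid-disc landmarks: C1C5 spans the upper C1
    extremity down to the C5/C6 disc, and is partitioned exactly into C1C2
    (above the C2/C3 disc) and C2C5 (below it).
    """

    name: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.name not in SEGMENT_NAMES:
            raise ValueError(f"segment name must be one of {SEGMENT_NAMES}")
        if not self.lo < self.hi:
            raise ValueError(f"empty slice interval [{self.lo}, {self.hi})")

    @property
    def slices(self) -> slice:
        return slice(self.lo, self.hi)


def segments_from_landmarks(landmarks: pd.DataFrame) -> dict[str, SegmentDef]:
    """Build the three standard segments from a landmark table.

    The table needs rows labeled C1, C2C3 and C5C6 with a ``slice`` column
    (slice index increasing toward the head). By construction
    C1C2 and C2C5 are disjoint and their union is C1C5.
    """
    pos = {row["label"]: int(row["slice"]) for _, row in landmarks.iterrows()}
    missing = {"C1", "C2C3", "C5C6"} - set(pos)
    if missing:
        raise ValueError(f"landmark table is missing labels: {sorted(missing)}")
    return {
        "C1C5": SegmentDef("C1C5", pos["C5C6"], pos["C1"]),
        "C1C2": SegmentDef("C1C2", pos["C2C3"], pos["C1"]),
        "C2C5": SegmentDef("C2C5", pos["C5C6"], pos["C2C3"]),
    }


@dataclass
class CSASeries:
    """Per-slice cord cross-sectional areas (mm^2) over one segment."""

    segment: str
    slice_areas_mm2: np.ndarray

    @property
    def mean_mm2(self) -> float:
        return float(np.mean(self.slice_areas_mm2))


def compute_csa(mask: CordMask, segment: SegmentDef | None = None) -> CSASeries:
    """CSA from a (binary or soft) mask: soft values count fractionally.

    Per-slice area = sum of mask values in the slice times the in-plane
    voxel area. This is the ground-truth backend: it reads the simulation's
    own mask, so it is unaffected by image noise.
    """
    sl = segment.slices if segment else slice(None)
    sub = mask.data[:, :, sl]
    if sub.shape[2] == 0:
        raise ValueError("segment interval lies outside the volume")
    pixel_area = mask.spacing[0] * mask.spacing[1]
    areas = sub.sum(axis=(0, 1)) * pixel_area
    return CSASeries(segment.name if segment else "ALL", np.asarray(areas, dtype=float))


def csa_from_image(
    vol: Volume3D,
    roi: CordMask,
    cord_intensity: float,
    csf_intensity: float,
    segment: SegmentDef | None = None,
    clip: bool = False,
) -> CSASeries:
    """Intensity-based CSA backend: partial-volume integration inside a ROI.

    Each ROI voxel contributes the fraction obtained by linearly ramping
    its intensity between the CSF and cord reference intensities — the
    integrated signal above the CSF floor, normalized to one full cord
    voxel. The unclipped default keeps the estimator linear in the image
    (zero-mean texture and noise cancel in expectation); ``clip=True``
    bounds fractions to [0, 1] at the cost of a clipping bias. This stands
    in for image-driven CSA tools: unlike :func:`compute_csa` it sees the
    image, so noise degrades it — which is the point when quantifying
    noise sensitivity.
    """
    if not vol.same_geometry(roi):
        raise ValueError("volume and ROI must share one voxel grid")
    if cord_intensity <= csf_intensity:
        raise ValueError("cord reference intensity must exceed the CSF reference")
    sl = segment.slices if segment else slice(None)
    sub_v = vol.data[:, :, sl]
    sub_r = roi.data[:, :, sl] > 0
    frac = (sub_v - csf_intensity) / (cord_intensity - csf_intensity)
    if clip:
        frac = np.clip(frac, 0.0, 1.0)
    frac = np.where(sub_r, frac, 0.0)
    pixel_area = vol.spacing[0] * vol.spacing[1]
    areas = frac.sum(axis=(0, 1)) * pixel_area
    return CSASeries(segment.name if segment else "ALL", np.asarray(areas, dtype=float))


def estimate_atrophy(baseline: CSASeries, followup: CSASeries) -> float:
    """Percent CSA loss between two time points: 100 (CSA_b - CSA_f) / CSA_b."""
    if baseline.segment != followup.segment:
        raise ValueError(
            f"segments differ: {baseline.segment!r} vs {followup.segment!r}"
        )
    if baseline.mean_mm2 == 0:
        raise ValueError("baseline CSA is zero")
    return 100.0 * (baseline.mean_mm2 - followup.mean_mm2) / baseline.mean_mm2


@dataclass
class RingStats:
    """Boundary-ring comparison between a reference and a test volume."""

    t: float
    p: float
    cohens_d: float
    n_ref: int
    n_test: int


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-standard-deviation standardized mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def ring_analysis(
    ref: Volume3D,
    test: Volume3D,
    mask: CordMask,
    test_mask: CordMask | None = None,
    variant: Literal["pooled", "welch"] = "pooled",
) -> RingStats:
    """Compare intensities on the 2-pixel CSF/cord boundary ring.

    The ring is dilate(mask, r=1) minus erode(mask, r=1) in each axial
    plane — the transition zone where compositing artifacts would appear.
    When the test volume carries a rescaled cord, pass its own (thresholded)
    mask as ``test_mask`` so each ring tracks its volume's transition zone;
    by default the reference ring is used for both. Returns the independent
    two-sample t statistic (pooled variance by default, Welch behind the
    flag), its p-value, and pooled Cohen's d.
    """
    if not (ref.same_geometry(test) and ref.same_geometry(mask)):
        raise ValueError("ring analysis inputs must share one voxel grid")
    ring = boundary_ring(mask, StructuringElement(1)).data > 0
    if test_mask is None:
        ring_b = ring
    else:
        ring_b = boundary_ring(test_mask, StructuringElement(1)).data > 0
    if not ring.any() or not ring_b.any():
        raise ValueError("boundary ring is empty")
    a = ref.data[ring]
    b = test.data[ring_b]
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return RingStats(float(t), float(p), cohens_d(a, b), len(a), len(b))


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov statistic D in [0, 1] and its p-value."""

    D: float
    p: float


def ks_statistic(sample_a: np.ndarray, sample_b: np.ndarray) -> KSResult:
    """Two-sample KS test: D is the sup-difference of the two ECDFs.

    D = 0 iff the empirical distributions coincide; D = 1 when supports are
    fully separated. P-values use the asymptotic Kolmogorov distribution.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue))


def intensity_pair_distribution(
    ref: Volume3D, test: Volume3D, mask: CordMask
) -> pd.DataFrame:
    """Paired intensities at mask voxels, with their voxel-wise difference.

    On a scatter of (reference, test), atrophy-free data lies on the
    diagonal; growing atrophy pulls pairs off it. The ``difference`` column
    (ref - test) feeds the KS comparisons.
    """
    if not (ref.same_geometry(test) and ref.same_geometry(mask)):
        raise ValueError("inputs must share one voxel grid")
    sel = mask.data > 0
    r = ref.data[sel]
    t = test.data[sel]
    return pd.DataFrame({"ref": r, "test": t, "difference": r - t})


@dataclass
class AgreementStats:
    """RMSE (same units as the inputs) and Pearson r between two series."""

    rmse: float
    pearson_r: float
    errors: np.ndarray


def agreement(measured: np.ndarray, reference: np.ndarray) -> AgreementStats:
    """RMSE and Pearson correlation between two equal-length series.

    ``errors`` is measured - reference per cell. Pearson r needs at least
    two points and nonzero variance in both series.
    """
    a = np.asarray(measured, dtype=float).ravel()
    b = np.asarray(reference, dtype=float).ravel()
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length series with n >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson r undefined for a zero-variance series")
    err = a - b
    rmse = float(np.sqrt(np.mean(err**2)))
    r, _ = stats.pearsonr(a, b)
    return AgreementStats(rmse, float(r), err)
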