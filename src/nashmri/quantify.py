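"""ROI-based signal quantification: relative liver enhancement (RLE),
dual-echo fat fraction (FF), and the clinical fibrosis scores.

Nine circular ROIs (emulating one per Couinaud segment, 4a/4b separate)
are placed inside the liver mask, per-sequence mean signal intensities are
measured, and

    RLE = (PostSI - PreSI) / PreSI
    FF  = (SIin - SIopp) / (2 * SIin) * 100   [percent]

are computed per ROI and averaged across ROIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort import MRStudy


class PlacementError(RuntimeError):
    """ROI placement infeasible for the given mask/constraints."""


@dataclass(frozen=True)
class ROI:
    """Circular ROI; a pixel (y, x) belongs to the disk iff
    (y-cy)^2 + (x-cx)^2 <= radius^2 (0-based indices)."""

    center: tuple[int, int]
    radius: int

    def pixel_mask(self, shape) -> np.ndarray:
        yy, xx = np.ogrid[0 : shape[0], 0 : shape[1]]
        cy, cx = self.center
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius**2


@dataclass(frozen=True)
class ROISignal:
    pre_si: float
    post_si: float
    si_in: float
    si_opp: float


@dataclass
class QuantResult:
    per_roi: list  # (ROI, ROISignal, rle, ff)
    rle_mean: float
    ff_mean: float


def rle(pre_si: float, post_si: float) -> float:
    """Relative liver enhancement (PostSI - PreSI) / PreSI."""
    if pre_si <= 0:
        raise ValueError("pre_si must be > 0")
    return (post_si - pre_si) / pre_si


def ff(si_in: float, si_opp: float) -> float:
    """Dual-echo chemical-shift fat fraction, percent:
    (SIin - SIopp) / (2 * SIin) * 100."""
    if si_in <= 0:
        raise ValueError("si_in must be > 0")
    return (si_in - si_opp) / (2.0 * si_in) * 100.0


def place_rois(
    mask: np.ndarray,
    n: int = 9,
    min_radius: int = 3,
    stream: np.random.Generator | None = None,
    max_attempts: int = 2000,
) -> list[ROI]:
    """Place ``n`` pairwise-disjoint disks of radius ``min_radius`` fully
    inside ``mask``, with centers biased toward high distance-to-boundary
    (far from vessels/boundary in the real-data analogue)."""
    stream = stream if stream is not None else np.random.default_rng(0)
    mask = mask.astype(bool)
    dist = ndimage.distance_transform_edt(mask)
    candidates = np.argwhere(dist >= min_radius + 1)
    if len(candidates) == 0:
        raise PlacementError(
            f"mask admits no disk of radius {min_radius} (interior too small)"
        )
    weights = dist[candidates[:, 0], candidates[:, 1]] ** 2
    weights = weights / weights.sum()
    placed: list[ROI] = []
    for _ in range(max_attempts * n):
        idx = stream.choice(len(candidates), p=weights)
        cy, cx = (int(v) for v in candidates[idx])
        if all(
            (cy - r.center[0]) ** 2 + (cx - r.center[1]) ** 2 > (2 * min_radius + 1) ** 2
            for r in placed
        ):
            placed.append(ROI(center=(cy, cx), radius=min_radius))
            if len(placed) == n:
                return placed
    raise PlacementError(
        f"could not place {n} disjoint disks of radius {min_radius} "
        f"after {max_attempts * n} draws ({len(placed)} placed)"
    )


def quantify_study(study: MRStudy, rois: list[ROI]) -> QuantResult:
    """Per-ROI sequence means, RLE and FF, plus their arithmetic means."""
    shape = study.liver_mask.shape
    per_roi = []
    for roi in rois:
        disk = roi.pixel_mask(shape)
        if not np.all(study.liver_mask[disk]):
            raise ValueError(f"ROI at {roi.center} extends outside the liver mask")
        sig = ROISignal(
            pre_si=float(study.t1_pre[disk].mean()),
            post_si=float(study.t1_hbp[disk].mean()),
            si_in=float(study.in_phase[disk].mean()),
            si_opp=float(study.opposed_phase[disk].mean()),
        )
        per_roi.append((roi, sig, rle(sig.pre_si, sig.post_si), ff(sig.si_in, sig.si_opp)))
    return QuantResult(
        per_roi=per_roi,
        rle_mean=float(np.mean([r for (_, _, r, _) in per_roi])),
        ff_mean=float(np.mean([f for (_, _, _, f) in per_roi])),
    )


@dataclass(frozen=True)
class LabPanel:
    """Laboratory inputs for the clinical fibrosis scores. Units: AST/ALT/
    GGT/ALP U/L, platelets 10^9/L, albumin g/L, bilirubin umol/L."""

    age: float
    bmi: float
    ast: float
    alt: float
    ast_uln: float
    platelets: float
    albumin: float
    bilirubin: float
    ifg_diabetes: int
    ggt: float = float("nan")
    alp: float = float("nan")


@dataclass(frozen=True)
class ClinicalScores:
    fib4: float
    nfs: float
    albi: float
    apri: float


def clinical_scores(labs: LabPanel) -> ClinicalScores:
    """FIB-4, NAFLD fibrosis score, ALBI and APRI from one lab panel.

    FIB-4 = age * AST / (platelets * sqrt(ALT));
    NFS = -1.675 + 0.037*age + 0.094*BMI + 1.13*IFG/diabetes
          + 0.99*AST/ALT - 0.013*platelets - 0.66*albumin[g/dL];
    ALBI = 0.66*log10(bilirubin[umol/L]) - 0.0852*albumin[g/L];
    APRI = (AST / AST upper limit of normal) * 100 / platelets.
    """
    for name in ("platelets", "alt", "ast_uln", "bilirubin"):
        if getattr(labs, name) <= 0:
            raise ValueError(f"{name} must be > 0")
    fib4 = labs.age * labs.ast / (labs.platelets * math.sqrt(labs.alt))
    nfs = (
        -1.675
        + 0.037 * labs.age
        + 0.094 * labs.bmi
        + 1.13 * labs.ifg_diabetes
        + 0.99 * labs.ast / labs.alt
        - 0.013 * labs.platelets
        - 0.66 * (labs.albumin / 10.0)  # g/L -> g/dL
    )
    albi = 0.66 * math.log10(labs.bilirubin) - 0.0852 * labs.albumin
    apri = (labs.ast / labs.ast_uln) * 100.0 / labs.platelets
    return ClinicalScores(fib4=fib4, nfs=nfs, albi=albi, apri=apri)
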