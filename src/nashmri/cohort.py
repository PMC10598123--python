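"""Synthetic NAFLD cohort generator.

Emulates a two-class liver-MRI cohort (simple steatosis vs NASH under the
SAF rule) with four co-registered 2D sequences per subject: unenhanced T1,
hepatobiliary-phase T1 (HBP), and the dual-echo chemical-shift pair
(in-phase / opposed-phase), plus a liver mask.

Generative model
----------------
* Histology grades are drawn from class-conditional categorical tables
  (defaults approximate the published grade frequencies of a 46-patient
  NAFLD derivation cohort) with rejection sampling until the SAF rule
  yields the intended class.
* Chemical shift: inside the mask, in-phase = (W+L), opposed = (W-L) with
  L/(W+L) = true_fat_fraction/100, so the dual-echo fat-fraction formula
  inverts the generator exactly at zero noise.
* Enhancement: t1_hbp = t1_pre_noiseless * (1 + true_rle) with
  true_rle = rle_base - rle_per_fibrosis*F - rle_per_inflammation*I, so
  relative liver enhancement inverts exactly at zero noise.
* Texture: zero-mean random fields whose second-order statistics depend on
  the histology grades (granularity grows with inflammation, sparse bright
  blobs with ballooning, anisotropic streaks with fibrosis; chemical-shift
  granularity tracks steatosis). Texture is applied multiplicatively to
  both members of each ratio (pre/HBP share one field; in/opposed share
  one field) so it carries class information without perturbing RLE or FF.
* Noise: additive Gaussian, truncated at zero.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

NASH = "NASH"
SIMPLE_STEATOSIS = "simple_steatosis"

_GRADE_RANGES = {"steatosis_grade": 3, "inflammation": 2, "ballooning": 2, "fibrosis": 4}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration cannot produce valid subjects."""


@dataclass(frozen=True)
class HistologyProfile:
    """SAF components: steatosis S (0-3), inflammation and ballooning
    activities A (0-2 each), fibrosis stage F (0-4)."""

    steatosis_grade: int
    inflammation: int
    ballooning: int
    fibrosis: int

    def __post_init__(self):
        for name, hi in _GRADE_RANGES.items():
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= hi):
                raise ValueError(f"{name}={v!r} outside closed range [0, {hi}]")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    histology: HistologyProfile
    nash_label: str
    true_fat_fraction: float
    true_rle: float

    def __post_init__(self):
        if self.nash_label != classify_saf(self.histology):
            raise ValueError("nash_label inconsistent with SAF rule")
        if not 0.0 <= self.true_fat_fraction < 100.0:
            raise ValueError("true_fat_fraction outside [0, 100)")
        if self.true_rle < -1.0:
            raise ValueError("true_rle below -1")


@dataclass
class MRStudy:
    """One subject's co-registered 2D slices plus liver mask."""

    t1_pre: np.ndarray
    t1_hbp: np.ndarray
    in_phase: np.ndarray
    opposed_phase: np.ndarray
    liver_mask: np.ndarray

    SEQUENCES = ("t1_pre", "t1_hbp", "in_phase", "opposed_phase")

    def __post_init__(self):
        shapes = {getattr(self, s).shape for s in self.SEQUENCES}
        shapes.add(self.liver_mask.shape)
        if len(shapes) != 1:
            raise ValueError("all five arrays must share one shape")
        if not self.liver_mask.any():
            raise ValueError("liver mask is empty")
        for s in self.SEQUENCES:
            a = getattr(self, s)
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise ValueError(f"{s} has non-finite or negative intensities")
        self.liver_mask = self.liver_mask.astype(bool)


# Class-conditional grade frequencies (simple steatosis n=18 / NASH n=28),
# normalised at sampling time.
_DEFAULT_GRADE_TABLES = {
    SIMPLE_STEATOSIS: {
        "steatosis_grade": [0.0, 11.0, 4.0, 3.0],
        "inflammation": [13.0, 5.0, 0.0],
        "ballooning": [14.0, 3.0, 1.0],
        "fibrosis": [9.0, 4.0, 4.0, 0.0, 1.0],
    },
    NASH: {
        "steatosis_grade": [0.0, 9.0, 5.0, 14.0],
        "inflammation": [0.0, 18.0, 10.0],
        "ballooning": [0.0, 21.0, 7.0],
        "fibrosis": [1.0, 11.0, 4.0, 8.0, 4.0],
    },
}


def _default_tables():
    return json.loads(json.dumps(_DEFAULT_GRADE_TABLES))


def _default_ff_bins():
    # Signal fat-fraction (percent) bins per steatosis grade 0..3. The
    # dual-echo formula saturates at 50%, hence the cap below it; bin
    # midpoints are equally spaced so expected FF is linear in grade.
    return [[0.5, 12.0], [12.0, 24.0], [24.0, 36.0], [36.0, 48.0]]


@dataclass
class CohortConfig:
    n_subjects: int = 46
    class_mix: float = 28.0 / 46.0
    image_size: int = 64
    noise_sd: float = 5.0
    # Signal model (intensity units follow typical T1 SI magnitudes).
    t1_base: float = 285.0
    csi_base: float = 300.0
    background: float = 20.0
    rle_base: float = 1.8
    rle_per_fibrosis: float = 0.132
    rle_per_inflammation: float = 0.144
    # Texture relative amplitudes (fraction of base signal).
    tex_inflammation: float = 0.10
    tex_ballooning: float = 0.10
    tex_fibrosis: float = 0.08
    tex_steatosis_csi: float = 0.08
    ff_bins: list = field(default_factory=_default_ff_bins)
    grade_tables: dict = field(default_factory=_default_tables)
    rng_seed: int = 0
    max_rejections: int = 10_000

    def validate(self):
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not 0.0 <= self.class_mix <= 1.0:
            raise ConfigurationError("class_mix must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        worst_rle = self.rle_base - 4 * self.rle_per_fibrosis - 2 * self.rle_per_inflammation
        if worst_rle <= -1.0:
            raise ConfigurationError("effect stacking drives HBP intensity negative")
        amp = self.tex_inflammation + self.tex_ballooning + self.tex_fibrosis
        if amp >= 0.5 or self.tex_steatosis_csi >= 0.5:
            raise ConfigurationError("texture amplitudes too large for nonnegative intensities")
        for g, (lo, hi) in enumerate(self.ff_bins):
            if not (0.0 <= lo < hi < 50.0):
                raise ConfigurationError(f"ff bin for grade {g} must satisfy 0 <= lo < hi < 50")
        return self


def null_effects(config: CohortConfig) -> CohortConfig:
    """Copy of ``config`` with every class-informative image effect removed
    (flat textures, no grade dependence of RLE or fat fraction)."""
    cfg = dataclasses.replace(
        config,
        tex_inflammation=0.0,
        tex_ballooning=0.0,
        tex_fibrosis=0.0,
        tex_steatosis_csi=0.0,
        rle_per_fibrosis=0.0,
        rle_per_inflammation=0.0,
    )
    cfg.ff_bins = [[5.0, 45.0]] * 4
    cfg.grade_tables = json.loads(json.dumps(config.grade_tables))
    return cfg


def classify_saf(profile: HistologyProfile) -> str:
    """SAF rule: NASH iff S >= 1 and inflammation >= 1 and ballooning >= 1,
    irrespective of fibrosis stage."""
    if (
        profile.steatosis_grade >= 1
        and profile.inflammation >= 1
        and profile.ballooning >= 1
    ):
        return NASH
    return SIMPLE_STEATOSIS


def sample_histology(
    config: CohortConfig, stream: np.random.Generator, intended_class: str | None = None
) -> HistologyProfile:
    """Draw one SAF profile; rejection-sample until the SAF rule produces
    the intended class (drawn from ``class_mix`` when not given)."""
    if intended_class is None:
        intended_class = NASH if stream.random() < config.class_mix else SIMPLE_STEATOSIS
    if intended_class not in config.grade_tables:
        raise ConfigurationError(f"no grade table for class {intended_class!r}")
    tables = config.grade_tables[intended_class]
    for _ in range(config.max_rejections):
        draws = {}
        for name, hi in _GRADE_RANGES.items():
            w = np.asarray(tables[name], dtype=float)
            if w.shape != (hi + 1,) or w.sum() <= 0 or (w < 0).any():
                raise ConfigurationError(f"invalid grade table for {name}")
            draws[name] = int(stream.choice(hi + 1, p=w / w.sum()))
        profile = HistologyProfile(**draws)
        if classify_saf(profile) == intended_class:
            return profile
    raise ConfigurationError(
        f"could not satisfy class {intended_class!r} in {config.max_rejections} draws"
    )


def _liver_blob(size: int, stream: np.random.Generator) -> np.ndarray:
    """Randomised convex-ish liver blob: perturbed rotated ellipse."""
    cy = size / 2 + stream.uniform(-0.04, 0.04) * size
    cx = size / 2 + stream.uniform(-0.04, 0.04) * size
    ry = stream.uniform(0.28, 0.36) * size
    rx = stream.uniform(0.28, 0.36) * size
    theta = stream.uniform(0, np.pi)
    amps = stream.uniform(-0.06, 0.06, size=3)
    phases = stream.uniform(0, 2 * np.pi, size=3)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    r = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    phi = np.arctan2(v / ry, u / rx)
    bound = 1.0 + sum(a * np.cos((m + 2) * phi + p) for m, (a, p) in enumerate(zip(amps, phases)))
    return r <= bound


def _unit_field(raw: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-std (over the mask) version of a random field."""
    sd = raw[mask].std()
    if sd == 0:
        return np.zeros_like(raw)
    out = raw / sd
    out = out - out[mask].mean()
    return out


def _texture_t1(profile, config, size, mask, stream):
    """Grade-parameterised zero-mean multiplicative texture for the T1 pair."""
    tau = np.zeros((size, size))
    if config.tex_inflammation > 0:
        g = ndimage.gaussian_filter(
            stream.standard_normal((size, size)), sigma=0.5 + 0.9 * profile.inflammation
        )
        tau += config.tex_inflammation * _unit_field(g, mask)
    if config.tex_ballooning > 0 and profile.ballooning > 0:
        density = 0.004 + 0.010 * profile.ballooning
        imp = (stream.random((size, size)) < density).astype(float)
        blobs = ndimage.gaussian_filter(imp, sigma=1.0)
        tau += config.tex_ballooning * (profile.ballooning / 2.0) * _unit_field(blobs, mask)
    if config.tex_fibrosis > 0 and profile.fibrosis > 0:
        streaks = ndimage.gaussian_filter(
            stream.standard_normal((size, size)), sigma=(0.5, 2.0 + profile.fibrosis)
        )
        tau += config.tex_fibrosis * (profile.fibrosis / 4.0) * _unit_field(streaks, mask)
    return np.clip(tau, -0.9, 0.9)


def _texture_csi(profile, config, size, mask, stream):
    if config.tex_steatosis_csi <= 0:
        return np.zeros((size, size))
    g = ndimage.gaussian_filter(
        stream.standard_normal((size, size)), sigma=0.5 + 0.7 * profile.steatosis_grade
    )
    return np.clip(config.tex_steatosis_csi * _unit_field(g, mask), -0.9, 0.9)


def _noisy(img: np.ndarray, sd: float, stream: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return img.copy()
    return np.clip(img + stream.normal(0.0, sd, size=img.shape), 0.0, None)


def true_rle_of(profile: HistologyProfile, config: CohortConfig) -> float:
    return (
        config.rle_base
        - config.rle_per_fibrosis * profile.fibrosis
        - config.rle_per_inflammation * profile.inflammation
    )


def render_study(
    record: SubjectRecord, config: CohortConfig, stream: np.random.Generator
) -> MRStudy:
    """Render the four sequences plus mask for one subject."""
    config.validate()
    size = config.image_size
    mask = _liver_blob(size, stream)
    while mask.sum() < 0.1 * size * size:  # degenerate blob: redraw
        mask = _liver_blob(size, stream)

    tau_t1 = _texture_t1(record.histology, config, size, mask, stream)
    tau_csi = _texture_csi(record.histology, config, size, mask, stream)

    bg = np.full((size, size), config.background)
    pre0 = np.where(mask, config.t1_base * (1.0 + tau_t1), bg)
    if (pre0 < 0).any():
        raise ConfigurationError("negative intended T1 intensity after effect stacking")
    hbp0 = np.where(mask, pre0 * (1.0 + record.true_rle), bg)
    f = record.true_fat_fraction / 100.0
    in0 = np.where(mask, config.csi_base * (1.0 + tau_csi), bg)
    opp0 = np.where(mask, config.csi_base * (1.0 - 2.0 * f) * (1.0 + tau_csi), bg)
    if (opp0 < 0).any() or (hbp0 < 0).any():
        raise ConfigurationError("negative intended intensity after effect stacking")

    sd = config.noise_sd
    return MRStudy(
        t1_pre=_noisy(pre0, sd, stream),
        t1_hbp=_noisy(hbp0, sd, stream),
        in_phase=_noisy(in0, sd, stream),
        opposed_phase=_noisy(opp0, sd, stream),
        liver_mask=mask,
    )


def generate_cohort(config: CohortConfig) -> list[tuple[SubjectRecord, MRStudy]]:
    """Generate ``n_subjects`` (record, study) pairs, reproducible from
    ``config.rng_seed``."""
    config.validate()
    stream = np.random.default_rng(config.rng_seed)
    cohort = []
    for i in range(config.n_subjects):
        intended = NASH if stream.random() < config.class_mix else SIMPLE_STEATOSIS
        profile = sample_histology(config, stream, intended)
        lo, hi = config.ff_bins[profile.steatosis_grade]
        record = SubjectRecord(
            subject_id=f"S{i + 1:04d}",
            histology=profile,
            nash_label=classify_saf(profile),
            true_fat_fraction=float(stream.uniform(lo, hi)),
            true_rle=true_rle_of(profile, config),
        )
        cohort.append((record, render_study(record, config, stream)))
    return cohort


def cohort_table(cohort) -> pd.DataFrame:
    rows = []
    for record, _ in cohort:
        h = record.histology
        rows.append(
            {
                "subject_id": record.subject_id,
                "steatosis_grade": h.steatosis_grade,
                "inflammation": h.inflammation,
                "ballooning": h.ballooning,
                "fibrosis": h.fibrosis,
                "nash_label": record.nash_label,
                "true_fat_fraction": record.true_fat_fraction,
                "true_rle": record.true_rle,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(outdir, cohort, config: CohortConfig):
    """Write per-subject NIfTI files per sequence, the cohort CSV, and a
    JSON config snapshot. Row-major pixel grid, 0-based indices."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for record, study in cohort:
        for seq in MRStudy.SEQUENCES:
            img = nib.Nifti1Image(
                getattr(study, seq).astype(np.float32), affine=np.eye(4)
            )
            nib.save(img, outdir / f"{record.subject_id}_{seq}.nii.gz")
        m = nib.Nifti1Image(study.liver_mask.astype(np.uint8), affine=np.eye(4))
        nib.save(m, outdir / f"{record.subject_id}_liver_mask.nii.gz")
    cohort_table(cohort).to_csv(outdir / "cohort.csv", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)


def read_cohort(indir) -> tuple[list[tuple[SubjectRecord, MRStudy]], CohortConfig]:
    """Read a cohort written by :func:`write_cohort`."""
    import nibabel as nib

    indir = Path(indir)
    with open(indir / "config.json") as fh:
        config = CohortConfig(**json.load(fh))
    table = pd.read_csv(indir / "cohort.csv")
    cohort = []
    for _, row in table.iterrows():
        profile = HistologyProfile(
            steatosis_grade=int(row.steatosis_grade),
            inflammation=int(row.inflammation),
            ballooning=int(row.ballooning),
            fibrosis=int(row.fibrosis),
        )
        record = SubjectRecord(
            subject_id=row.subject_id,
            histology=profile,
            nash_label=row.nash_label,
            true_fat_fraction=float(row.true_fat_fraction),
            true_rle=float(row.true_rle),
        )
        arrays = {
            seq: np.asarray(
                nib.load(indir / f"{row.subject_id}_{seq}.nii.gz").dataobj, dtype=float
            )
            for seq in MRStudy.SEQUENCES
        }
        mask = np.asarray(
            nib.load(indir / f"{row.subject_id}_liver_mask.nii.gz").dataobj
        ).astype(bool)
        cohort.append((record, MRStudy(liver_mask=mask, **arrays)))
    return cohort, config
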