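"""Synthetic phantom cohort with the statistical structure the analysis
assumes.

Each patient gets a planning-CT-like scan plus one MVCT-like scan per
treatment fraction.  Every slice holds an annular rectum on a flat
background: the filled rectum is a (slightly deformed, per-fraction
jittered) disc, and the 2-pixel wall band carries a spatially
correlated Gaussian texture field (smoothing length ``corr_length``)
on top of the base wall intensity.  Daily images are noisier than the
planning image (``sigma_mvct > sigma_ct``).

Texture effect model: patient i's wall-texture standard deviation is
``sigma_texture * exp(tau * z_i - tau^2/2)`` (log-normal between-patient
heterogeneity, ``tau = texture_spread``).  For endpoint-positive
patients the field *variance* is multiplied by ``1 + delta * ramp(week)``
from the onset week onwards, and the correlation length by
``1 + ell_effect * delta * ramp(week)``, where
``ramp(w) = min(1, max(0, (w - onset_week + 1) / 2))`` -- the signal
appears at the onset week and saturates one week later.  The planning
scan is week 0 (never affected).  ``delta = 0`` gives an exact null.

Generation is deterministic per (seed, patient index) and independent
across patients (seed-sequence spawning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import io as rio
from .io import CohortRecord, ContourPolygon, ScanSeries, SliceImage, ValidationError
from .temporal import fraction_to_week

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort-level generation parameters (defaults = study conditions)."""

    n_patients: int
    regimen_mix: tuple[float, float] = (0.59, 0.41)  # (74Gy_37F, 60Gy_20F)
    prevalence: float = 0.33
    slice_shape: tuple[int, int] = (64, 64)
    n_slices: int = 5
    radius_range: tuple[float, float] = (8.0, 14.0)  # px
    mu_wall: float = 10.0  # HU-like soft-tissue contrast over background
    mu_bg: float = 0.0
    sigma_ct: float = 4.0
    sigma_mvct: float = 8.0
    corr_length: float = 2.0  # px
    sigma_texture: float = 20.0
    texture_spread: float = 0.1  # between-patient log-SD of texture SD
    delta: float = 1.0  # effect size: wall-texture variance multiplier - 1
    onset_week: int = 1
    ell_effect: float = 0.25  # correlation-length coupling of the effect
    n_contour_vertices: int = 48
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValidationError("prevalence must be in (0, 1)")
        if self.sigma_mvct < self.sigma_ct:
            raise ValidationError("sigma_mvct must be >= sigma_ct")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        if self.onset_week < 1:
            raise ValidationError("onset_week must be >= 1")
        if self.radius_range[0] < 4.0:
            raise ValidationError("rectum radius must be >= 4 px")


def effect_ramp(week: int, onset_week: int) -> float:
    """0 before onset, 1/2 at onset, saturating at 1 one week later."""
    return float(min(1.0, max(0.0, (week - onset_week + 1) / 2.0)))


@dataclass
class PatientData:
    """In-memory bundle for one synthetic patient."""

    record: CohortRecord
    scans: list[ScanSeries]
    contours: dict[tuple[str, int | None], list[ContourPolygon]] = field(
        default_factory=dict
    )  # keyed by (modality, fraction_index)


@dataclass
class CohortData:
    """In-memory synthetic cohort."""

    spec: SyntheticCohortSpec
    patients: list[PatientData]

    @property
    def records(self) -> list[CohortRecord]:
        return [p.record for p in self.patients]


def _circle_vertices(center, radius, n, deform=None) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = np.full(n, radius)
    if deform is not None:
        amp, phase = deform
        r = r * (1.0 + amp * np.sin(2.0 * theta + phase))
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return np.stack([rows, cols], axis=1)


def _correlated_field(rng, shape, ell, support=None) -> np.ndarray:
    """Smoothed Gaussian field with unit empirical variance.

    Normalisation uses the field's standard deviation over ``support``
    (the wall band) so the painted texture variance is controlled
    exactly, rather than only in expectation; the smoothing leaves few
    effective degrees of freedom in a thin ring, and without this the
    realisation noise would dominate the variance parameter itself.
    """
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=ell, mode="reflect")
    sd = f[support].std() if support is not None else f.std()
    return f / (sd if sd > 0 else 1.0)


def generate_patient(
    spec: SyntheticCohortSpec,
    patient_index: int,
    regimen: str,
) -> PatientData:
    """Generate one patient's planning scan, MVCT series and contours.

    Deterministic per (spec.seed, patient_index); geometry that cannot
    fit the slice is regenerated with a shrunk radius (logged).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(int(spec.seed), int(patient_index)))
    )
    h, w = spec.slice_shape
    pid = f"P{patient_index:04d}"
    positive = bool(rng.random() < spec.prevalence)
    grade = int(rng.integers(1, 4)) if positive else 0
    record = CohortRecord(patient_id=pid, regimen=regimen, endpoint_grade=grade)

    radius = float(rng.uniform(*spec.radius_range))
    center = np.array([h / 2.0, w / 2.0]) + rng.uniform(-2.0, 2.0, size=2)
    # shrink until the annulus plus jitter fits well inside the slice
    max_r = min(center[0], center[1], h - 1 - center[0], w - 1 - center[1]) - 3.0
    if radius > max_r:
        logger.warning(
            "%s: rectum radius %.1f px does not fit; shrunk to %.1f",
            pid, radius, max_r,
        )
        radius = max_r
    # patient-level texture SD with log-normal between-patient spread
    tau = spec.texture_spread
    sd_texture = spec.sigma_texture * float(
        np.exp(tau * rng.standard_normal() - tau**2 / 2.0)
    )

    n_fractions = rio.REGIMEN_FRACTIONS[regimen]
    scans: list[ScanSeries] = []
    contours: dict[tuple[str, int | None], list[ContourPolygon]] = {}
    for fraction in [None] + list(range(1, n_fractions + 1)):
        if fraction is None:
            modality, sigma_noise, week = "planning_ct", spec.sigma_ct, 0
        else:
            modality, sigma_noise = "mvct", spec.sigma_mvct
            week = fraction_to_week(fraction, regimen)
        ramp = effect_ramp(week, spec.onset_week) if week >= 1 else 0.0
        var_mult = 1.0 + spec.delta * ramp if positive else 1.0
        ell = spec.corr_length * (
            1.0 + spec.ell_effect * spec.delta * ramp if positive else 1.0
        )
        # mild per-fraction deformation and centre jitter
        jitter = center + rng.uniform(-1.0, 1.0, size=2)
        deform = (float(rng.uniform(0.0, 0.04)), float(rng.uniform(0, 2 * np.pi)))
        slices, polys = [], []
        for s in range(spec.n_slices):
            verts = _circle_vertices(jitter, radius, spec.n_contour_vertices, deform)
            poly = ContourPolygon(slice_index=s, vertices=verts)
            mask = rio.rasterise_contour(poly, (h, w))
            ring = _wall_band(mask)
            img = np.full((h, w), spec.mu_bg, dtype=float)
            field = _correlated_field(rng, (h, w), ell, support=ring)
            img[ring] = (
                spec.mu_wall
                + field[ring] * sd_texture * np.sqrt(var_mult)
            )
            img += rng.standard_normal((h, w)) * sigma_noise
            slices.append(SliceImage(img, 1.0, 1.0, slice_index=s))
            polys.append(poly)
        scans.append(
            ScanSeries(
                patient_id=pid, modality=modality,
                fraction_index=fraction, slices=slices,
            )
        )
        contours[(modality, fraction)] = polys
    return PatientData(record=record, scans=scans, contours=contours)


def _wall_band(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    eroded2 = binary_erosion(mask, structure=np.ones((3, 3), bool), iterations=2,
                             border_value=0)
    return mask & ~eroded2


def regimen_assignment(spec: SyntheticCohortSpec) -> list[str]:
    """Deterministic regimen mix: round(mix * n) patients get 74 Gy."""
    n74 = int(np.round(spec.regimen_mix[0] * spec.n_patients))
    return ["74Gy_37F"] * n74 + ["60Gy_20F"] * (spec.n_patients - n74)


def generate_cohort(
    spec: SyntheticCohortSpec,
    out_dir=None,
    fractions_filter: set[int] | None = None,
) -> CohortData:
    """Generate the full cohort; optionally write it to ``out_dir`` in
    the standard on-disk formats (NIfTI + contour JSON + manifest CSV).

    ``fractions_filter`` keeps only the listed MVCT fractions (the
    planning scan is always kept); week averages then use the available
    fractions.  Returns the in-memory cohort either way.
    """
    regimens = regimen_assignment(spec)
    patients = []
    for k, regimen in enumerate(regimens):
        pdata = generate_patient(spec, k, regimen)
        if fractions_filter is not None:
            pdata.scans = [
                s for s in pdata.scans
                if s.modality == "planning_ct"
                or s.fraction_index in fractions_filter
            ]
        patients.append(pdata)
    cohort = CohortData(spec=spec, patients=patients)
    n_pos = sum(p.record.endpoint_binary for p in patients)
    logger.info(
        "generated %d patients (%d positive, %.0f%%; %d x 74Gy, %d x 60Gy)",
        spec.n_patients, n_pos, 100 * n_pos / spec.n_patients,
        regimens.count("74Gy_37F"), regimens.count("60Gy_20F"),
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: CohortData, out_dir) -> "Path":  # noqa: F821
    """Write every scan, contour set and the manifest CSV under out_dir."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pdata in cohort.patients:
        pid = pdata.record.patient_id
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        for scan in pdata.scans:
            tag = (
                "ct" if scan.modality == "planning_ct"
                else f"fx{scan.fraction_index:02d}"
            )
            img_path = pdir / f"{tag}.nii.gz"
            ctr_path = pdir / f"{tag}_rectum.json"
            rio.write_scan(scan, img_path)
            rio.write_contours(
                pdata.contours[(scan.modality, scan.fraction_index)], ctr_path
            )
            rows.append(
                {
                    "patient_id": pid,
                    "regimen": pdata.record.regimen,
                    "endpoint_grade": pdata.record.endpoint_grade,
                    "modality": scan.modality,
                    "fraction_index": (
                        "" if scan.fraction_index is None else scan.fraction_index
                    ),
                    "image_path": str(img_path.relative_to(out_dir)),
                    "contour_path": str(ctr_path.relative_to(out_dir)),
                }
            )
    manifest = out_dir / "manifest.csv"
    rio.write_cohort_manifest(rows, manifest)
    return manifest


def cohort_summary(cohort: CohortData) -> pd.DataFrame:
    recs = cohort.records
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in recs],
            "regimen": [r.regimen for r in recs],
            "endpoint_grade": [r.endpoint_grade for r in recs],
            "endpoint_binary": [r.endpoint_binary for r in recs],
        }
    )


def null_spec(spec: SyntheticCohortSpec) -> SyntheticCohortSpec:
    """The same cohort with the toxicity effect switched off."""
    return replace(spec, delta=0.0)
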