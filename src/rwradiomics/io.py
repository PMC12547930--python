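"""On-disk artefacts: image series, rectum contours, cohort manifests.

Conventions
-----------
* Pixel coordinates are (row, col), 0-based, with pixel centres at
  integer coordinates.  A pixel belongs to a rasterised polygon iff its
  centre lies inside the polygon or on its boundary.
* Image series are stored as NIfTI (``.nii``/``.nii.gz``) with pixels
  stacked along the third axis and spacings in the affine, or as the
  repo's raw-array container (``.npz``).  DICOM slice directories are
  readable.  Series metadata (patient id, modality, fraction index)
  travels in the NIfTI ``descrip`` field / npz payload.
* Contours use a small JSON dialect: one object per structure with a
  list of per-slice vertex lists in (row, col) pixel units.
* The cohort manifest is a CSV with one row per scan: ``patient_id,
  regimen, endpoint_grade, modality, fraction_index, image_path,
  contour_path``.  Paths are relative to the manifest's directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import shapely

logger = logging.getLogger(__name__)

REGIMEN_FRACTIONS = {"74Gy_37F": 37, "60Gy_20F": 20}
MODALITIES = ("planning_ct", "mvct")


class ValidationError(ValueError):
    """Raised for inputs that violate a documented contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SliceImage:
    """One 2D attenuation grid (HU-like, unitless) with pixel spacing in mm."""

    pixels: np.ndarray
    row_spacing: float = 1.0
    col_spacing: float = 1.0
    slice_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("pixels must be a non-empty 2D grid")
        if self.row_spacing <= 0 or self.col_spacing <= 0:
            raise ValidationError("spacings must be positive")


@dataclass
class ScanSeries:
    """Ordered slices of one scan (planning CT or one MVCT fraction)."""

    patient_id: str
    modality: str
    slices: list[SliceImage]
    fraction_index: int | None = None

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality: {self.modality}")
        if self.modality == "mvct":
            if self.fraction_index is None or self.fraction_index < 1:
                raise ValidationError("mvct series needs fraction_index >= 1")
        elif self.fraction_index is not None:
            raise ValidationError("planning_ct has no fraction_index")
        if not self.slices:
            raise ValidationError("series has no slices")
        shapes = {s.pixels.shape for s in self.slices}
        spacings = {(s.row_spacing, s.col_spacing) for s in self.slices}
        if len(shapes) > 1:
            raise ValidationError(f"mixed slice dimensions: {shapes}")
        if len(spacings) > 1:
            raise ValidationError("mixed slice spacings")

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].pixels.shape

    def stack(self) -> np.ndarray:
        return np.stack([s.pixels for s in self.slices])


@dataclass
class ContourPolygon:
    """Closed planar polygon in (row, col) pixel units; fractional allowed."""

    slice_index: int
    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be an (n, 2) array")
        if self.vertices.shape[0] < 3:
            raise ValidationError("polygon needs at least 3 vertices")


@dataclass
class CohortRecord:
    """Per-patient regimen and 2-year rectal bleeding endpoint."""

    patient_id: str
    regimen: str
    endpoint_grade: int
    endpoint_binary: int = field(init=False)

    def __post_init__(self):
        if self.regimen not in REGIMEN_FRACTIONS:
            raise ValidationError(f"unknown regimen: {self.regimen}")
        if not 0 <= int(self.endpoint_grade) <= 3:
            raise ValidationError(
                f"endpoint_grade must be 0..3, got {self.endpoint_grade}"
            )
        self.endpoint_grade = int(self.endpoint_grade)
        # grade >= 1 rectal bleeding defines the binary endpoint
        self.endpoint_binary = int(self.endpoint_grade >= 1)

    @property
    def expected_fractions(self) -> int:
        return REGIMEN_FRACTIONS[self.regimen]


# ---------------------------------------------------------------------------
# image series I/O
# ---------------------------------------------------------------------------


def _meta_string(series: ScanSeries) -> str:
    fx = "" if series.fraction_index is None else str(series.fraction_index)
    return f"pid={series.patient_id};mod={series.modality};fx={fx}"


def _parse_meta(text: str) -> dict:
    out = {"pid": "unknown", "mod": "planning_ct", "fx": ""}
    for part in text.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_scan(series: ScanSeries, path) -> Path:
    """Write a series as NIfTI (.nii/.nii.gz) or raw-array .npz."""
    path = Path(path)
    data = np.transpose(series.stack(), (1, 2, 0)).astype(np.float64)
    if path.suffix == ".npz":
        np.savez(
            path,
            pixels=data,
            spacing=np.array([series.slices[0].row_spacing,
                              series.slices[0].col_spacing]),
            meta=np.array(_meta_string(series)),
        )
        return path
    affine = np.diag(
        [series.slices[0].row_spacing, series.slices[0].col_spacing, 1.0, 1.0]
    )
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = _meta_string(series).encode()[:79]
    nib.save(img, str(path))
    return path


def _series_from_array(
    data: np.ndarray, row_sp: float, col_sp: float, meta: dict
) -> ScanSeries:
    slices = [
        SliceImage(data[:, :, k], row_sp, col_sp, slice_index=k)
        for k in range(data.shape[2])
    ]
    fx = meta.get("fx", "")
    return ScanSeries(
        patient_id=meta.get("pid", "unknown"),
        modality=meta.get("mod", "planning_ct"),
        fraction_index=int(fx) if fx else None,
        slices=slices,
    )


def read_scan(path, format_hint: str | None = None) -> ScanSeries:
    """Read NIfTI, raw-array ``.npz`` or a directory of DICOM slices."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"scan path does not exist: {path}")
    fmt = format_hint
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.suffix == ".npz":
            fmt = "npz"
        else:
            fmt = "nifti"
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            data = np.asarray(z["pixels"], dtype=float)
            row_sp, col_sp = (float(v) for v in z["spacing"])
            meta = _parse_meta(str(z["meta"]))
        return _series_from_array(data, row_sp, col_sp, meta)
    if fmt == "dicom":
        return _read_dicom_dir(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # noqa: BLE001 - report the offending path
        raise IOError(f"unreadable image file: {path}") from exc
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValidationError(f"expected a 2D/3D image in {path}")
    zooms = img.header.get_zooms()
    meta = _parse_meta(str(img.header["descrip"].item().decode(errors="ignore")))
    return _series_from_array(data, float(zooms[0]), float(zooms[1]), meta)


def _read_dicom_dir(path: Path) -> ScanSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise IOError(f"no DICOM slices in {path}")
    dsets = [pydicom.dcmread(str(p)) for p in files]

    def z_position(ds):
        if getattr(ds, "ImagePositionPatient", None) is not None:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    dsets.sort(key=z_position)
    arrays = [ds.pixel_array.astype(float) for ds in dsets]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValidationError(f"mixed slice dimensions in {path}: {shapes}")
    ds0 = dsets[0]
    spacing = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    modality = "planning_ct" if getattr(ds0, "Modality", "CT") == "CT" else "mvct"
    slices = [
        SliceImage(a, float(spacing[0]), float(spacing[1]), slice_index=k)
        for k, a in enumerate(arrays)
    ]
    return ScanSeries(
        patient_id=str(getattr(ds0, "PatientID", "unknown")),
        modality=modality,
        fraction_index=None if modality == "planning_ct" else 1,
        slices=slices,
    )


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------


def write_contours(polygons: list[ContourPolygon], path, structure="rectum") -> Path:
    path = Path(path)
    payload = {
        "structure": structure,
        "slices": [
            {"slice_index": int(p.slice_index), "vertices": p.vertices.tolist()}
            for p in polygons
        ],
    }
    path.write_text(json.dumps(payload))
    return path


def read_contours(path) -> list[ContourPolygon]:
    path = Path(path)
    if not path.exists():
        raise IOError(f"contour file does not exist: {path}")
    payload = json.loads(path.read_text())
    return [
        ContourPolygon(slice_index=int(s["slice_index"]), vertices=s["vertices"])
        for s in payload["slices"]
    ]


def rasterise_contour(polygon: ContourPolygon, grid_shape) -> np.ndarray:
    """Binary mask of pixels whose centre is inside or on the polygon.

    Raises :class:`ValidationError` for degenerate polygons (fewer than
    three vertices or zero area); a polygon covering no pixel centre
    yields an empty mask with a logged warning.
    """
    verts = polygon.vertices
    if verts.shape[0] < 3:
        raise ValidationError("polygon needs at least 3 vertices")
    poly = shapely.Polygon(verts)
    if poly.area == 0:
        raise ValidationError("polygon has zero area")
    if not poly.is_valid:
        raise ValidationError("polygon is self-intersecting")
    h, w = grid_shape
    mask = np.zeros((h, w), dtype=bool)
    # evaluate only the bounding box of the polygon
    rmin = max(0, int(np.floor(poly.bounds[0])))
    cmin = max(0, int(np.floor(poly.bounds[1])))
    rmax = min(h - 1, int(np.ceil(poly.bounds[2])))
    cmax = min(w - 1, int(np.ceil(poly.bounds[3])))
    if rmax < rmin or cmax < cmin:
        logger.warning("polygon lies outside the grid; empty mask")
        return mask
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
    )
    pts = shapely.points(np.stack([rr.ravel(), cc.ravel()], axis=1))
    inside = shapely.covers(poly, pts).reshape(rr.shape)
    mask[rmin : rmax + 1, cmin : cmax + 1] = inside
    if not mask.any():
        logger.warning("polygon on slice %d covers no pixel centre",
                       polygon.slice_index)
    return mask


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "patient_id",
    "regimen",
    "endpoint_grade",
    "modality",
    "fraction_index",
    "image_path",
    "contour_path",
]


@dataclass
class ManifestData:
    """Parsed cohort manifest: patient records plus the scan registry."""

    records: list[CohortRecord]
    registry: pd.DataFrame  # one row per scan, with resolved paths
    missing_fractions: dict[str, list[int]]


def write_cohort_manifest(rows: list[dict], path) -> Path:
    """Write manifest rows (dicts with :data:`MANIFEST_COLUMNS` keys)."""
    path = Path(path)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def read_cohort_manifest(path) -> ManifestData:
    """Read and validate a cohort manifest CSV.

    Referenced files must exist; per-regimen fraction completeness is
    checked and gaps are tolerated with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest does not exist: {path}")
    df = pd.read_csv(path)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"manifest missing columns: {sorted(missing_cols)}")
    base = path.parent
    records: dict[str, CohortRecord] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        regimens = grp["regimen"].unique()
        grades = grp["endpoint_grade"].unique()
        if len(regimens) > 1 or len(grades) > 1:
            raise ValidationError(f"inconsistent rows for patient {pid}")
        records[str(pid)] = CohortRecord(
            patient_id=str(pid),
            regimen=str(regimens[0]),
            endpoint_grade=int(grades[0]),
        )
    for col in ("image_path", "contour_path"):
        for rel in df[col].dropna():
            if not (base / str(rel)).exists():
                raise IOError(f"manifest references a missing file: {rel}")
    registry = df.copy()
    registry["image_path"] = [str(base / p) for p in registry["image_path"]]
    registry["contour_path"] = [str(base / p) for p in registry["contour_path"]]

    missing: dict[str, list[int]] = {}
    for pid, rec in records.items():
        rows = registry[registry["patient_id"].astype(str) == pid]
        n_ct = (rows["modality"] == "planning_ct").sum()
        if n_ct != 1:
            raise ValidationError(f"patient {pid} has {n_ct} planning scans")
        have = set(
            int(v) for v in rows.loc[rows["modality"] == "mvct", "fraction_index"]
        )
        expected = set(range(1, rec.expected_fractions + 1))
        gap = sorted(expected - have)
        extra = sorted(have - expected)
        if extra:
            raise ValidationError(f"patient {pid} has out-of-range fractions {extra}")
        if gap:
            missing[pid] = gap
            logger.warning(
                "patient %s is missing %d fraction(s): %s", pid, len(gap), gap
            )
    return ManifestData(
        records=list(records.values()), registry=registry, missing_fractions=missing
    )
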