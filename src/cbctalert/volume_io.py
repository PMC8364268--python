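"""Volume, mask and rigid-transform containers and I/O.

Coordinate convention (used by every module in this package):

* Arrays are indexed ``(slice, row, column)``, i.e. patient ``(z, y, x)``
  in an LPS-style frame. Index 0 is the first slice sorted by physical
  position.
* All physical quantities are millimetres. ``spacing`` and ``origin`` are
  stored in **array-axis order** ``(z, y, x)``; the physical position of
  voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``. Grids are
  axis-aligned (no direction-cosine matrix); oblique DICOM series are
  rejected at load time.
* Intensities are Hounsfield units (air ≈ -1000, water 0).

Two on-disk dialects are supported:

* a lightweight *research* format: ``<base>.raw`` (raw little-endian
  array) plus ``<base>.json`` (shape/dtype/spacing/origin sidecar), and a
  plain-text rigid-transform file — both diffable and trivially
  reproducible in tests;
* clinical DICOM: CT image series, RTSTRUCT external contours
  (rasterized per slice with even-odd polygon fill), and Spatial
  Registration objects (rigid only).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import FormatError, PreconditionError

__all__ = [
    "VolumeGrid",
    "RigidTransform",
    "MaskVolume",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_transform",
    "save_transform",
    "load_dicom_series",
    "load_dicom_registration",
    "rtstruct_to_mask",
    "mask_from_external",
    "resample_onto",
    "identity_transform",
]

_AIR_HU = -1000.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VolumeGrid:
    """A 3D scalar intensity field (HU) on an axis-aligned physical grid.

    Parameters
    ----------
    data
        3D array, axes ``(slice, row, column)`` = patient ``(z, y, x)``.
    spacing
        Per-axis voxel size in mm, order ``(z, y, x)``; all components > 0.
    origin
        Physical position (mm) of voxel ``(0, 0, 0)``, order ``(z, y, x)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise PreconditionError(f"volume data must be 3D, got {self.data.ndim}D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise PreconditionError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Physical mm position(s) of fractional voxel indices (…, 3)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of physical mm position(s) (…, 3)."""
        return (np.asarray(pos, dtype=float) - self.origin) / self.spacing

    def same_grid(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and bool(np.allclose(self.spacing, other.spacing, atol=tol))
            and bool(np.allclose(self.origin, other.origin, atol=tol))
        )

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class RigidTransform:
    """A rigid (rotation + translation) map between two patient frames.

    ``rotation`` is a 3×3 orthonormal matrix (det +1) and ``translation``
    a 3-vector in mm, both expressed in array-axis order ``(z, y, x)``.
    ``direction`` states which way the map goes: with
    ``"moving_to_reference"``, ``p_ref = R @ p_mov + t``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    direction: str = "moving_to_reference"

    _DIRECTIONS = ("moving_to_reference", "reference_to_moving")

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.direction not in self._DIRECTIONS:
            raise PreconditionError(f"unknown transform direction {self.direction!r}")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise PreconditionError(
                f"rotation is not orthonormal (max deviation {err:.2e})"
            )
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-6:
            raise PreconditionError(f"rotation determinant must be +1, got {det:.8f}")

    def inverse(self) -> "RigidTransform":
        other = (
            "reference_to_moving"
            if self.direction == "moving_to_reference"
            else "moving_to_reference"
        )
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation, other)

    def as_moving_to_reference(self) -> "RigidTransform":
        if self.direction == "moving_to_reference":
            return self
        return self.inverse()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (…, 3) through the transform in its stated direction."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= tol
            and np.abs(self.translation).max() <= tol
        )


def identity_transform() -> RigidTransform:
    return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class MaskVolume:
    """Boolean voxel mask on the same grid as a companion :class:`VolumeGrid`."""

    data: np.ndarray
    provenance: str = "supplied"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise PreconditionError(f"mask data must be 3D, got {self.data.ndim}D")
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# Research-format I/O (raw + JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(base: Path) -> tuple[Path, Path]:
    base = Path(base)
    if base.suffix in {".raw", ".json"}:
        base = base.with_suffix("")
    return base.with_suffix(".raw"), base.with_suffix(".json")


def save_volume(volume: VolumeGrid, base_path: str | Path) -> Path:
    """Write a volume as ``<base>.raw`` + ``<base>.json``.

    The raw file holds the array in C order with an explicit little-endian
    dtype recorded in the sidecar, so a save/load round trip is
    bit-stable for data, spacing and origin.
    """
    raw_path, json_path = _sidecar_path(Path(base_path))
    data = np.ascontiguousarray(volume.data)
    dtype = data.dtype.newbyteorder("<")
    data.astype(dtype, copy=False).tofile(raw_path)
    meta = {
        "format": "cbctalert-volume",
        "shape": list(data.shape),
        "dtype": dtype.str,
        "spacing_mm": [float(s) for s in volume.spacing],
        "origin_mm": [float(o) for o in volume.origin],
        "axes_order": "slice,row,column (z,y,x)",
    }
    json_path.write_text(json.dumps(meta, indent=1) + "\n")
    return json_path.with_suffix("")


def _load_research_volume(path: Path, allow_non_finite: bool) -> VolumeGrid:
    raw_path, json_path = _sidecar_path(path)
    if not json_path.exists():
        raise FormatError(f"sidecar not found: {json_path}")
    if not raw_path.exists():
        raise FormatError(f"raw file not found: {raw_path}")
    try:
        meta = json.loads(json_path.read_text())
        shape = tuple(int(s) for s in meta["shape"])
        dtype = np.dtype(meta["dtype"])
        spacing = meta["spacing_mm"]
        origin = meta["origin_mm"]
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"bad sidecar {json_path}: {exc}") from exc
    data = np.fromfile(raw_path, dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise FormatError(
            f"{raw_path}: expected {int(np.prod(shape))} elements, found {data.size}"
        )
    data = data.reshape(shape)
    if not allow_non_finite and data.dtype.kind == "f" and not np.isfinite(data).all():
        n_bad = int((~np.isfinite(data)).sum())
        raise FormatError(f"{raw_path}: {n_bad} non-finite voxels in loaded volume")
    return VolumeGrid(data, spacing, origin)


def load_volume(
    path: str | Path,
    format: str = "research",
    allow_non_finite: bool = False,
) -> VolumeGrid:
    """Load a volume from the research raw+sidecar pair or a DICOM series.

    Parameters
    ----------
    path
        Research format: the base path (or either half of the pair).
        ``dicom_series``: a directory of CT slice files.
    format
        ``"research"`` or ``"dicom_series"``.
    allow_non_finite
        Permit NaN voxels (used for stored gamma maps, never for CT data).
    """
    path = Path(path)
    if format == "research":
        return _load_research_volume(path, allow_non_finite)
    if format == "dicom_series":
        return load_dicom_series(path)
    raise FormatError(f"unknown volume format {format!r}")


def save_mask(mask: MaskVolume, grid: VolumeGrid, base_path: str | Path) -> Path:
    """Write a mask as the research pair with boolean dtype, on ``grid``."""
    vol = VolumeGrid(mask.data.astype(np.uint8), grid.spacing, grid.origin)
    raw_path, json_path = _sidecar_path(Path(base_path))
    np.ascontiguousarray(vol.data).tofile(raw_path)
    meta = {
        "format": "cbctalert-volume",
        "shape": list(vol.data.shape),
        "dtype": "bool",
        "spacing_mm": [float(s) for s in grid.spacing],
        "origin_mm": [float(o) for o in grid.origin],
        "axes_order": "slice,row,column (z,y,x)",
        "provenance": mask.provenance,
    }
    json_path.write_text(json.dumps(meta, indent=1) + "\n")
    return json_path.with_suffix("")


def load_mask(path: str | Path) -> tuple[MaskVolume, VolumeGrid]:
    """Load a boolean mask saved by :func:`save_mask`.

    Returns the mask and a :class:`VolumeGrid` carrying its grid geometry
    (the grid's data is the uint8 view of the mask).
    """
    raw_path, json_path = _sidecar_path(Path(path))
    if not json_path.exists():
        raise FormatError(f"sidecar not found: {json_path}")
    meta = json.loads(json_path.read_text())
    if meta.get("dtype") != "bool":
        raise FormatError(f"{json_path}: not a boolean mask (dtype={meta.get('dtype')})")
    shape = tuple(int(s) for s in meta["shape"])
    data = np.fromfile(raw_path, dtype=np.uint8)
    if data.size != int(np.prod(shape)):
        raise FormatError(f"{raw_path}: size mismatch for shape {shape}")
    data = data.reshape(shape)
    grid = VolumeGrid(data, meta["spacing_mm"], meta["origin_mm"])
    return MaskVolume(data.astype(bool), meta.get("provenance", "supplied")), grid


# ---------------------------------------------------------------------------
# Plain-text transform files
# ---------------------------------------------------------------------------

def save_transform(transform: RigidTransform, path: str | Path) -> None:
    """Write a rigid transform as diffable plain text (row-major, zyx axes)."""
    lines = ["# cbctalert rigid transform (axes z,y,x; translation mm)"]
    lines += [" ".join(f"{v:.17g}" for v in row) for row in transform.rotation]
    lines.append("translation: " + " ".join(f"{v:.17g}" for v in transform.translation))
    lines.append(f"direction: {transform.direction}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_transform(path: str | Path) -> RigidTransform:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"transform file not found: {path}")
    rows: list[list[float]] = []
    translation: list[float] | None = None
    direction: str | None = None
    for raw_line in path.read_text().splitlines():
        line = raw_line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("translation:"):
            translation = [float(v) for v in line.split(":", 1)[1].split()]
        elif line.startswith("direction:"):
            direction = line.split(":", 1)[1].strip()
        else:
            rows.append([float(v) for v in line.split()])
    if len(rows) != 3 or any(len(r) != 3 for r in rows) or translation is None:
        raise FormatError(f"{path}: expected 3x3 rotation rows and a translation line")
    if direction is None:
        direction = "moving_to_reference"
    try:
        return RigidTransform(np.array(rows), np.array(translation), direction)
    except PreconditionError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# DICOM readers
# ---------------------------------------------------------------------------

def _zyx(vec_xyz: Sequence[float]) -> np.ndarray:
    return np.asarray(vec_xyz, dtype=float)[::-1]


def load_dicom_series(directory: str | Path) -> VolumeGrid:
    """Read an axial CT/CBCT slice series into a :class:`VolumeGrid`.

    Slices are sorted by physical position along the slice normal; gaps or
    inconsistent in-plane spacing raise :class:`FormatError` naming the
    offending position. Intensities are rescaled to HU via RescaleSlope /
    RescaleIntercept. Only axis-aligned (identity-orientation) series are
    supported, matching the package-wide grid convention.
    """
    import pydicom

    directory = Path(directory)
    if not directory.exists():
        raise FormatError(f"DICOM directory not found: {directory}")
    slices = []
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:  # unreadable file in the directory
            raise FormatError(f"{f}: not readable as DICOM ({exc})") from exc
        if not hasattr(ds, "PixelData") or not hasattr(ds, "ImagePositionPatient"):
            raise FormatError(f"{f}: not a CT image slice")
        slices.append(ds)
    if len(slices) < 2:
        raise FormatError(f"{directory}: need at least 2 slices, found {len(slices)}")

    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    if not (np.allclose(iop[:3], [1, 0, 0], atol=1e-4) and np.allclose(iop[3:], [0, 1, 0], atol=1e-4)):
        raise FormatError(f"{directory}: non-axial orientation {iop.tolist()} unsupported")
    ps0 = np.asarray(slices[0].PixelSpacing, dtype=float)
    for ds in slices:
        if not np.allclose(np.asarray(ds.PixelSpacing, dtype=float), ps0, atol=1e-6):
            raise FormatError(f"{directory}: inconsistent in-plane spacing")
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, dtype=float), iop, atol=1e-6):
            raise FormatError(f"{directory}: inconsistent slice orientation")

    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    dz = np.diff(zs)
    if np.any(dz <= 0):
        raise FormatError(f"{directory}: duplicate slice positions at z={zs[np.argmin(dz)]}")
    if np.abs(dz - dz[0]).max() > 1e-3:
        i = int(np.abs(dz - dz[0]).argmax())
        raise FormatError(
            f"{directory}: slice gap between z={zs[i]:.3f} and z={zs[i + 1]:.3f} mm "
            f"(step {dz[i]:.3f} vs {dz[0]:.3f} mm) — missing slice?"
        )

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    data = np.stack(planes, axis=0)
    ipp0 = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    spacing = np.array([dz[0], ps0[0], ps0[1]])  # (z, row, col)
    origin = _zyx(ipp0)
    return VolumeGrid(data, spacing, origin)


def load_dicom_registration(path: str | Path) -> RigidTransform:
    """Read a rigid DICOM Spatial Registration object.

    Returns the first non-identity FrameOfReferenceTransformationMatrix as
    a moving-to-reference transform (the registered series' frame into the
    reference frame), converted to the package's zyx axis order.
    """
    import pydicom

    path = Path(path)
    if not path.exists():
        raise FormatError(f"registration file not found: {path}")
    ds = pydicom.dcmread(path)
    if not hasattr(ds, "RegistrationSequence"):
        raise FormatError(f"{path}: no RegistrationSequence — not a spatial registration")
    matrices = []
    for reg in ds.RegistrationSequence:
        for mreg in getattr(reg, "MatrixRegistrationSequence", []):
            for m in getattr(mreg, "MatrixSequence", []):
                vals = np.asarray(m.FrameOfReferenceTransformationMatrix, dtype=float)
                matrices.append(vals.reshape(4, 4))
    if not matrices:
        raise FormatError(f"{path}: no transformation matrix found")
    chosen = None
    for mat in matrices:
        if not np.allclose(mat, np.eye(4), atol=1e-9):
            chosen = mat
            break
    if chosen is None:
        chosen = matrices[0]
    r_xyz = chosen[:3, :3]
    t_xyz = chosen[:3, 3]
    # reverse axis order: zyx = P @ xyz with P the order-reversing permutation
    rot = r_xyz[::-1, ::-1]
    try:
        return RigidTransform(rot, t_xyz[::-1], "moving_to_reference")
    except PreconditionError as exc:
        raise FormatError(f"{path}: matrix is not rigid ({exc})") from exc


def rtstruct_to_mask(
    path: str | Path,
    grid: VolumeGrid,
    roi_name: str | None = None,
) -> MaskVolume:
    """Rasterize an RTSTRUCT contour (the external by default) onto ``grid``.

    Each planar contour is filled on its nearest slice with even-odd
    polygon filling; overlapping contours on one slice toggle (XOR), so
    holes are honoured. Contours between slices are not interpolated.
    """
    import pydicom

    path = Path(path)
    if not path.exists():
        raise FormatError(f"RTSTRUCT file not found: {path}")
    ds = pydicom.dcmread(path)
    if not hasattr(ds, "StructureSetROISequence"):
        raise FormatError(f"{path}: no StructureSetROISequence — not an RTSTRUCT")

    rois = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    target_number = None
    if roi_name is not None:
        for num, name in rois.items():
            if name.lower() == roi_name.lower():
                target_number = num
        if target_number is None:
            raise FormatError(f"{path}: ROI {roi_name!r} not found (have {sorted(rois.values())})")
    else:
        for num, name in rois.items():
            if name.lower() in {"external", "body", "skin", "outer contour"}:
                target_number = num
                break
        if target_number is None:
            target_number = sorted(rois)[0]

    mask = np.zeros(grid.shape, dtype=bool)
    filled_any = False
    for roi_contour in ds.ROIContourSequence:
        if int(roi_contour.ReferencedROINumber) != target_number:
            continue
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = float(np.mean(pts[:, 2]))
            k = int(round((z - grid.origin[0]) / grid.spacing[0]))
            if not 0 <= k < grid.shape[0]:
                continue
            rows = (pts[:, 1] - grid.origin[1]) / grid.spacing[1]
            cols = (pts[:, 0] - grid.origin[2]) / grid.spacing[2]
            plane = _fill_polygon(rows, cols, grid.shape[1:])
            mask[k] ^= plane  # even-odd across nested contours
            filled_any = True
    if not filled_any:
        raise FormatError(f"{path}: ROI {rois[target_number]!r} has no contours on the grid")
    return MaskVolume(mask, provenance=f"rtstruct:{rois[target_number]}")


def _fill_polygon(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd fill of one closed polygon on a pixel grid (centres tested)."""
    from matplotlib.path import Path as MplPath

    verts = np.column_stack([cols, rows])
    verts = np.vstack([verts, verts[:1]])  # explicit closing vertex
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([cc.ravel(), rr.ravel()])
    inside = MplPath(verts, closed=True).contains_points(pts)
    return inside.reshape(shape)


# ---------------------------------------------------------------------------
# Mask dilation and resampling
# ---------------------------------------------------------------------------

def mask_from_external(contour_mask: MaskVolume, spacing: np.ndarray, margin_mm: float = 10.0) -> MaskVolume:
    """Dilate an external-contour mask by a physical margin (default 1 cm).

    The structuring element is the set of voxel offsets whose centre lies
    within ``margin_mm`` of the origin voxel centre, measured in mm using
    ``spacing`` — an anisotropy-aware ball. The evaluation region for the
    gamma comparison is this dilated body, chosen to exclude image
    artifacts that occur outside the patient volume.
    """
    if margin_mm < 0:
        raise PreconditionError(f"margin_mm must be >= 0, got {margin_mm}")
    if contour_mask.count() == 0:
        raise PreconditionError("cannot dilate an empty external mask")
    if margin_mm == 0:
        return MaskVolume(contour_mask.data.copy(), provenance="dilated:0mm")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    radii = np.floor(margin_mm / spacing).astype(int)
    zz, yy, xx = np.mgrid[
        -radii[0] : radii[0] + 1, -radii[1] : radii[1] + 1, -radii[2] : radii[2] + 1
    ]
    dist2 = (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    element = dist2 <= margin_mm**2 + 1e-9
    out = ndimage.binary_dilation(contour_mask.data, structure=element)
    return MaskVolume(out, provenance=f"dilated:{margin_mm:g}mm")


def _snap_integer(coords: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Snap near-integer fractional indices so coincident grids interpolate exactly."""
    rounded = np.round(coords)
    return np.where(np.abs(coords - rounded) < tol, rounded, coords)


def resample_onto(
    moving: VolumeGrid,
    transform: RigidTransform | None,
    reference: VolumeGrid,
    fill_value: float = _AIR_HU,
    interpolation: str = "linear",
) -> VolumeGrid:
    """Resample ``moving`` onto the grid of ``reference`` under a rigid map.

    ``transform`` maps moving-frame coordinates into the reference frame
    (either direction is accepted and inverted as needed; ``None`` means
    identity). Interpolation is trilinear for intensities and
    nearest-neighbour (``interpolation="nearest"``) for masks; samples
    outside the moving extent take ``fill_value`` (default -1000 HU, air).
    An identity transform between coincident grids returns an exact copy.
    """
    if transform is None:
        transform = identity_transform()
    transform = transform.as_moving_to_reference()
    det = float(np.linalg.det(transform.rotation))
    if abs(det - 1.0) > 1e-6:
        raise PreconditionError(f"degenerate rotation (det={det})")
    if transform.is_identity(tol=1e-12) and moving.same_grid(reference, tol=1e-12):
        return VolumeGrid(moving.data.astype(float, copy=True), reference.spacing.copy(), reference.origin.copy())

    inv = transform.inverse()  # reference -> moving
    idx = np.indices(reference.shape, dtype=float).reshape(3, -1).T
    p_ref = reference.index_to_physical(idx)
    p_mov = inv.apply(p_ref)
    idx_mov = _snap_integer(moving.physical_to_index(p_mov))
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise PreconditionError(f"unknown interpolation {interpolation!r}")
    out = ndimage.map_coordinates(
        moving.data.astype(float),
        idx_mov.T,
        order=order,
        mode="constant",
        cval=float(fill_value),
        prefilter=False,
    )
    return VolumeGrid(out.reshape(reference.shape), reference.spacing.copy(), reference.origin.copy())
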