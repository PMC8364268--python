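"""Synthetic CBCT treatment courses with known anatomy-change ground truth.

The phantom is a head-and-neck-like ellipsoidal body (soft tissue ≈ 40
HU) in air, with a bone-like posterior insert (spine surrogate) and an
air-like anterior channel (airway surrogate). Anatomy change is modelled
as progressive *lateral recession* of the body surface — the dominant
clinical change (weight loss) — shrinking the two in-plane half-axes by
``regression_rate`` mm per fraction from ``onset_fraction`` onward, with
a saturation depth so the total loss stays clinically plausible. This
gives closed-form ground truth: the recession depth at fraction f is
``min(rate * max(0, f - onset), max_recession)`` exactly.

Each acquisition adds a random rigid setup offset (recorded as the true
registration transform, so online matching exactly undoes it), Gaussian
HU noise, and optionally ring-artifact texture placed strictly outside
the body-plus-margin region (so a correct evaluation mask excludes it).

Ground-truth labelling is a synthetic-cohort convention: a course is
*positive* when the total recession reaches ``clinical_change_mm``
(default 5 mm), and its re-CT fraction is the first fraction at which
that depth is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import PreconditionError
from .evaluation import CaseRecord, write_annotations
from .mqp_tracker import Acquisition, PlanManifest, write_plan_manifest
from .volume_io import (
    MaskVolume,
    RigidTransform,
    VolumeGrid,
    save_mask,
    save_transform,
    save_volume,
)

__all__ = [
    "PhantomSpec",
    "CourseSpec",
    "CourseData",
    "GroundTruth",
    "CohortRanges",
    "CohortCase",
    "Cohort",
    "generate_course",
    "generate_cohort",
    "split_plans",
    "cbct_fraction_schedule",
    "coarse_phantom_spec",
]

_AIR_HU = -1000.0
_EDGE_BLEND_MM = 1.5  # partial-volume-like soft edge on all structure surfaces


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging-texture parameters of the static phantom.

    ``shape``/``spacing`` follow the package grid convention (z, y, x).
    ``body_half_axes_mm`` is the external-contour ellipsoid; internal
    ``structures`` are (half_axes, centre offset, HU) ellipsoids. The
    default 64³ grid at 3 mm isotropic spacing is a deliberately
    coarsened stand-in for a clinical CBCT matrix.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_half_axes_mm: tuple[float, float, float] = (75.0, 60.0, 70.0)
    body_hu: float = 40.0
    structures: tuple[dict, ...] = (
        {"half_axes": (70.0, 12.0, 12.0), "center_offset": (0.0, 30.0, 0.0), "hu": 700.0},
        {"half_axes": (60.0, 9.0, 9.0), "center_offset": (0.0, -20.0, 0.0), "hu": -950.0},
    )
    noise_sigma: float = 20.0
    noise_correlation_vox: float = 0.8
    artifact_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise PreconditionError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        self.validate_clearance()

    def validate_clearance(self, margin_mm: float = 10.0) -> None:
        """Body must fit inside the grid with >= margin + 2 voxels to spare."""
        half_extent = (np.asarray(self.shape) - 1) / 2 * np.asarray(self.spacing)
        need = np.asarray(self.body_half_axes_mm) + margin_mm + 2 * np.asarray(self.spacing)
        if np.any(need > half_extent + 1e-9):
            raise PreconditionError(
                f"body {self.body_half_axes_mm} + {margin_mm} mm margin + 2 voxels does "
                f"not fit the grid (half extent {half_extent.tolist()} mm)"
            )

    def grid(self) -> VolumeGrid:
        """Empty grid centred on the origin of the patient frame."""
        shape = np.asarray(self.shape)
        spacing = np.asarray(self.spacing, dtype=float)
        origin = -(shape - 1) / 2.0 * spacing
        return VolumeGrid(np.zeros(self.shape), spacing, origin)


def coarse_phantom_spec() -> PhantomSpec:
    """A 48³ / 4 mm variant used for cohort-scale experiments."""
    return PhantomSpec(
        shape=(48, 48, 48),
        spacing=(4.0, 4.0, 4.0),
        body_half_axes_mm=(70.0, 56.0, 64.0),
    )


def cbct_fraction_schedule(n_fractions: int, schedule: str | Sequence[int]) -> list[int]:
    """Treatment fractions that receive a CBCT.

    ``"twice_weekly"`` images on the 1st and 4th day of each 5-fraction
    week (the departmental norm); ``"daily"`` images every fraction; a
    sequence of fraction numbers is used as-is.
    """
    if isinstance(schedule, str):
        if schedule == "daily":
            return list(range(1, n_fractions + 1))
        if schedule == "twice_weekly":
            return [f for f in range(1, n_fractions + 1) if (f - 1) % 5 in (0, 3)]
        raise PreconditionError(f"unknown CBCT schedule {schedule!r}")
    fracs = sorted(int(f) for f in schedule)
    if any(f < 1 or f > n_fractions for f in fracs):
        raise PreconditionError(f"schedule fractions outside 1..{n_fractions}: {fracs}")
    return fracs


@dataclass(frozen=True)
class CourseSpec:
    """One treatment course: imaging schedule, anatomy change, setup error.

    ``regression_rate`` is the lateral surface recession in mm per
    fraction starting at ``onset_fraction`` (``None`` for a stable
    course), saturating at ``max_recession_mm`` total. ``setup_jitter_mm``
    is the per-axis standard deviation of the random rigid setup
    translation; ``jitter_rotation_deg`` optionally adds a random axial
    rotation of that standard deviation, exercising rotational
    registrations.
    """

    n_fractions: int = 33
    cbct_schedule: str | tuple[int, ...] = "twice_weekly"
    onset_fraction: int | None = None
    regression_rate: float = 0.0
    max_recession_mm: float = 12.0
    setup_jitter_mm: float = 2.0
    jitter_rotation_deg: float = 0.0
    replan_fraction: int | None = None
    clinical_change_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.onset_fraction is not None and self.onset_fraction > self.n_fractions:
            raise PreconditionError(
                f"onset_fraction {self.onset_fraction} beyond course of {self.n_fractions}"
            )
        if self.regression_rate < 0:
            raise PreconditionError("regression_rate must be >= 0 (tissue never regrows)")

    def recession_at(self, fraction: int) -> float:
        """Total recession depth (mm) at a given fraction — the ground truth."""
        if self.onset_fraction is None or self.regression_rate == 0.0:
            return 0.0
        return min(
            self.regression_rate * max(0, fraction - self.onset_fraction),
            self.max_recession_mm,
        )


@dataclass
class GroundTruth:
    label: str
    onset_fraction: int | None
    regression_rate: float
    recession_by_fraction: dict[int, float]
    rect_fraction: int | None
    replan_fraction: int | None


@dataclass
class CourseData:
    acquisitions: list[Acquisition]
    external_mask: MaskVolume
    grid: VolumeGrid
    ground_truth: GroundTruth


def _smoothing_kernel_l2(corr_vox: float) -> float:
    """L2 norm of the Gaussian smoothing kernel (variance shrink factor)."""
    n = max(9, int(8 * corr_vox) | 1)
    impulse = np.zeros((n, n, n))
    impulse[n // 2, n // 2, n // 2] = 1.0
    from scipy.ndimage import gaussian_filter

    k = gaussian_filter(impulse, corr_vox)
    return float(np.sqrt((k**2).sum()))


def _acquisition_noise(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    sigma_hu: float,
    corr_vox: float,
) -> np.ndarray:
    """Spatially correlated Gaussian HU noise with marginal std ``sigma_hu``.

    CBCT reconstruction noise is correlated over roughly a voxel by the
    reconstruction kernel; white voxel noise would let trilinear
    resampling shrink the effective noise by up to half depending on the
    sub-voxel phase of the setup offset, which makes match quality swing
    with jitter phase instead of anatomy. Filtering white noise with a
    ``corr_vox``-voxel Gaussian (then renormalizing the marginal std)
    removes that artifact while keeping the stated noise level.
    """
    white = rng.normal(0.0, 1.0, size=shape)
    if corr_vox <= 0:
        return sigma_hu * white
    from scipy.ndimage import gaussian_filter

    return sigma_hu * gaussian_filter(white, corr_vox, mode="nearest") / _smoothing_kernel_l2(corr_vox)


def _structure_field(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: np.ndarray,
    half_axes: np.ndarray,
) -> np.ndarray:
    """Soft-edged occupancy (0..1) of an ellipsoid at the given voxel coords."""
    rho2 = sum(((c - ctr) / ax) ** 2 for c, ctr, ax in zip(coords, center, half_axes))
    rho = np.sqrt(rho2)
    a_min = float(np.min(half_axes))
    # approximate signed distance to the surface, blended over ~1 voxel
    d_mm = (1.0 - rho) * a_min
    return np.clip(d_mm / _EDGE_BLEND_MM + 0.5, 0.0, 1.0)


def _render(
    phantom: PhantomSpec,
    recession_mm: float,
    shift_mm: np.ndarray | None = None,
    rotation: np.ndarray | None = None,
) -> np.ndarray:
    """Render the phantom (HU, noise-free) with the body laterally receded.

    ``shift_mm``/``rotation`` place the anatomy in the acquired frame:
    an anatomy point q appears at ``p = R q + shift`` in the image.
    """
    grid = phantom.grid()
    axes = [grid.origin[i] + np.arange(grid.shape[i]) * grid.spacing[i] for i in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", copy=False)
    if rotation is not None or shift_mm is not None:
        shift = np.zeros(3) if shift_mm is None else np.asarray(shift_mm, dtype=float)
        rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        pts = np.stack([zz, yy, xx], axis=-1) - shift
        q = pts @ rot  # (R^T applied from the right) = R^{-1} p
        zz, yy, xx = q[..., 0], q[..., 1], q[..., 2]
    coords = (zz, yy, xx)

    body_axes = np.asarray(phantom.body_half_axes_mm, dtype=float).copy()
    body_axes[1] -= recession_mm
    body_axes[2] -= recession_mm
    if np.any(body_axes <= 0):
        raise PreconditionError(
            f"recession of {recession_mm} mm makes the body non-positive: {body_axes.tolist()}"
        )
    data = np.full(grid.shape, _AIR_HU)
    body = _structure_field(coords, np.zeros(3), body_axes)
    data += body * (phantom.body_hu - _AIR_HU)
    for struct in phantom.structures:
        occ = _structure_field(
            coords,
            np.asarray(struct["center_offset"], dtype=float),
            np.asarray(struct["half_axes"], dtype=float),
        )
        # internal structures replace body tissue where they occupy it
        occ = np.minimum(occ, body)
        data += occ * (float(struct["hu"]) - phantom.body_hu)
    return data


def _artifact_texture(phantom: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Ring texture confined to the region outside body + margin + setup slack."""
    grid = phantom.grid()
    axes = [grid.origin[i] + np.arange(grid.shape[i]) * grid.spacing[i] for i in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", copy=False)
    guard = np.asarray(phantom.body_half_axes_mm) + 10.0 + 8.0  # mask margin + jitter slack
    rho2 = (zz / guard[0]) ** 2 + (yy / guard[1]) ** 2 + (xx / guard[2]) ** 2
    outside = rho2 > 1.0
    r_xy = np.hypot(yy, xx)
    phase = rng.uniform(0, 2 * math.pi)
    rings = phantom.artifact_level * np.sin(2 * math.pi * r_xy / 15.0 + phase)
    return np.where(outside, rings, 0.0)


def _axial_rotation(angle_deg: float) -> np.ndarray:
    """Rotation about the z (slice) axis in zyx coordinates."""
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def generate_course(phantom: PhantomSpec, course: CourseSpec) -> CourseData:
    """Simulate one treatment course of CBCT acquisitions.

    Returns per-acquisition volumes with their fraction numbers and
    *true* rigid transforms (moving→reference, exactly undoing the setup
    jitter), the planning external-contour mask, and a ground-truth
    record. Deterministic: identical specs (including seeds) give
    bit-identical volumes.
    """
    rng = np.random.default_rng(course.seed)
    grid = phantom.grid()
    fractions = cbct_fraction_schedule(course.n_fractions, course.cbct_schedule)

    acquisitions: list[Acquisition] = []
    recession_by_fraction: dict[int, float] = {}
    for f in fractions:
        delta = course.recession_at(f)
        recession_by_fraction[f] = delta
        jitter = rng.normal(0.0, course.setup_jitter_mm, size=3) if course.setup_jitter_mm > 0 else np.zeros(3)
        angle = rng.normal(0.0, course.jitter_rotation_deg) if course.jitter_rotation_deg > 0 else 0.0
        rot = _axial_rotation(angle) if angle != 0.0 else None
        data = _render(phantom, delta, shift_mm=jitter, rotation=rot)
        if phantom.noise_sigma > 0:
            data = data + _acquisition_noise(
                rng, grid.shape, phantom.noise_sigma, phantom.noise_correlation_vox
            )
        if phantom.artifact_level > 0:
            data = data + _artifact_texture(phantom, rng)
        r = np.eye(3) if rot is None else rot
        transform = RigidTransform(r.T, -(r.T @ jitter), "moving_to_reference")
        acquisitions.append(
            Acquisition(
                fraction=f,
                volume=VolumeGrid(data, grid.spacing.copy(), grid.origin.copy()),
                transform=transform,
            )
        )

    # planning external contour: the unshrunk body in the plan frame
    body = _render(phantom, 0.0)
    # body occupancy >= 0.5 <=> inside the nominal surface
    plan_axes = [grid.origin[i] + np.arange(grid.shape[i]) * grid.spacing[i] for i in range(3)]
    zz, yy, xx = np.meshgrid(*plan_axes, indexing="ij", copy=False)
    rho2 = sum(
        (c / ax) ** 2 for c, ax in zip((zz, yy, xx), np.asarray(phantom.body_half_axes_mm))
    )
    external = MaskVolume(rho2 <= 1.0, provenance="synthetic external contour")

    total = course.recession_at(course.n_fractions)
    if total >= course.clinical_change_mm:
        label = "positive"
        rect = next(
            f
            for f in range(1, course.n_fractions + 1)
            if course.recession_at(f) >= course.clinical_change_mm
        )
    else:
        label, rect = "negative", None
    truth = GroundTruth(
        label=label,
        onset_fraction=course.onset_fraction,
        regression_rate=course.regression_rate,
        recession_by_fraction=recession_by_fraction,
        rect_fraction=rect,
        replan_fraction=course.replan_fraction,
    )
    return CourseData(acquisitions=acquisitions, external_mask=external, grid=grid, ground_truth=truth)


def split_plans(course_data: CourseData, plan_id: str) -> list[tuple[str, list[Acquisition]]]:
    """Split a course at its re-plan boundary into separately tracked plans.

    Acquisitions at fractions >= the re-plan fraction belong to the new
    plan, whose MQP series restarts from its own first usable CBCT.
    """
    boundary = course_data.ground_truth.replan_fraction
    if boundary is None:
        return [(plan_id, course_data.acquisitions)]
    before = [a for a in course_data.acquisitions if a.fraction < boundary]
    after = [a for a in course_data.acquisitions if a.fraction >= boundary]
    return [(f"{plan_id}-p1", before), (f"{plan_id}-p2", after)]


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortRanges:
    """Per-case sampling ranges for synthetic cohorts.

    Positives draw a recession onset and rate large enough to cross the
    5 mm clinical-change depth; negatives draw a mild sub-threshold rate
    (half of them drift a little, making borderline false alarms
    possible, as in real stable patients). Cohort experiments default to
    the coarser 48³ phantom grid for tractability.
    """

    phantom: PhantomSpec = field(default_factory=coarse_phantom_spec)
    n_fractions: int = 33
    cbct_schedule: str = "twice_weekly"
    onset_range: tuple[int, int] = (8, 16)
    rate_range_positive: tuple[float, float] = (0.6, 1.4)
    rate_range_negative: tuple[float, float] = (0.0, 0.12)
    setup_jitter_mm: float = 2.0
    clinical_change_mm: float = 5.0


@dataclass
class CohortCase:
    """One cohort member: specs plus ground-truth record; volumes on demand."""

    case_id: str
    phantom: PhantomSpec
    course: CourseSpec
    record: CaseRecord

    def generate(self) -> CourseData:
        return generate_course(self.phantom, self.course)


@dataclass
class Cohort:
    cases: list[CohortCase]
    ranges: CohortRanges

    def write(self, out_dir: str | Path) -> Path:
        """Write volumes, transforms, masks, manifests and annotations.

        Layout: ``<out>/<plan_id>/manifest.yaml`` (+ data files),
        ``<out>/annotations.tsv``, ``<out>/cohort.yaml``. Deterministic
        given the cohort seed: identical cohorts produce byte-identical
        manifests and annotations.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        plan_entries = []
        for case in self.cases:
            plan_dir = out / case.case_id
            plan_dir.mkdir(exist_ok=True)
            data = case.generate()
            save_mask(data.external_mask, data.grid, plan_dir / "mask")
            entries = []
            for acq in data.acquisitions:
                stem = f"f{acq.fraction:02d}"
                save_volume(acq.volume, plan_dir / stem)
                tfm_name = None
                if acq.transform is not None:
                    tfm_name = f"{stem}.tfm"
                    save_transform(acq.transform, plan_dir / tfm_name)
                entry = {"fraction": acq.fraction, "volume": f"{stem}.json", "usable": acq.usable}
                if tfm_name:
                    entry["transform"] = tfm_name
                entries.append(entry)
            manifest = PlanManifest(
                plan_id=case.case_id,
                external_mask="mask.json",
                acquisitions=entries,
                root=plan_dir,
            )
            write_plan_manifest(manifest, plan_dir / "manifest.yaml")
            plan_entries.append({"plan_id": case.case_id, "manifest": f"{case.case_id}/manifest.yaml"})
        (out / "cohort.yaml").write_text(yaml.safe_dump({"plans": plan_entries}, sort_keys=False))
        write_annotations(
            [c.record for c in self.cases],
            out / "annotations.tsv",
            header_note=(
                "synthetic cohort: positive = total lateral recession >= "
                f"{self.ranges.clinical_change_mm:g} mm (cohort convention); "
                "rect_fraction = first fraction reaching that depth"
            ),
        )
        return out


def generate_cohort(
    n_positive: int,
    n_negative: int,
    ranges: CohortRanges = CohortRanges(),
    seed: int = 0,
) -> Cohort:
    """Draw a cohort of independent synthetic courses.

    Deterministic given ``seed``; each case gets its own derived seed so
    cases are independent and individually reproducible.
    """
    if n_positive < 0 or n_negative < 0:
        raise PreconditionError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    cases: list[CohortCase] = []
    labels = ["positive"] * n_positive + ["negative"] * n_negative
    for i, intended in enumerate(labels):
        case_seed = int(rng.integers(0, 2**31 - 1))
        onset = int(rng.integers(ranges.onset_range[0], ranges.onset_range[1] + 1))
        onset = min(onset, ranges.n_fractions)  # short courses clamp the drawn onset
        if intended == "positive":
            rate = float(rng.uniform(*ranges.rate_range_positive))
        else:
            rate = float(rng.uniform(*ranges.rate_range_negative))
        course = CourseSpec(
            n_fractions=ranges.n_fractions,
            cbct_schedule=ranges.cbct_schedule,
            onset_fraction=onset if rate > 0 else None,
            regression_rate=rate,
            setup_jitter_mm=ranges.setup_jitter_mm,
            clinical_change_mm=ranges.clinical_change_mm,
            seed=case_seed,
        )
        phantom = replace(ranges.phantom, seed=case_seed)
        case_id = f"case{i:03d}"
        total = course.recession_at(course.n_fractions)
        label = "positive" if total >= ranges.clinical_change_mm else "negative"
        if label != intended:
            raise PreconditionError(
                f"{case_id}: sampled specs produce a {label} course but a {intended} "
                "one was requested — adjust the cohort ranges"
            )
        rect = None
        if label == "positive":
            rect = next(
                f
                for f in range(1, course.n_fractions + 1)
                if course.recession_at(f) >= ranges.clinical_change_mm
            )
        record = CaseRecord(plan_id=case_id, label=label, rect_fraction=rect)
        cases.append(CohortCase(case_id=case_id, phantom=phantom, course=course, record=record))
    return Cohort(cases=cases, ranges=ranges)
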