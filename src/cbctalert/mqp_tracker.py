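"""Match-quality-parameter (MQP) time series and alert triggering.

For each treatment plan, the earliest usable CBCT serves as the
reference. The gamma comparison between the first two usable CBCTs is
the *reference match*; the xth percentile of its failed-voxel gamma
values is ``gamma_ref`` (x = 80 by default). Every later acquisition i
is compared to the reference CBCT the same way, and

    MQP_i = gamma_ref - gamma_i

so MQP is 0 for the reference match by definition and goes negative as
the anatomy drifts away from its state at the start of the course. An
alert fires when ``consecutive_required`` consecutive usable
acquisitions (default 3) have MQP strictly below the threshold (default
-0.11). A re-plan starts a fresh series (MQP resets to zero), handled by
splitting the plan manifest at the re-plan boundary.

"Consecutive" counts usable CBCT acquisitions, not calendar fractions:
imaging is typically twice weekly, so gaps in fraction number within a
run are the norm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import FormatError, PreconditionError
from .gamma_engine import GammaCriteria, compute_gamma, failed_percentile
from .volume_io import (
    MaskVolume,
    RigidTransform,
    VolumeGrid,
    load_mask,
    load_transform,
    load_volume,
    mask_from_external,
    resample_onto,
)

__all__ = [
    "Acquisition",
    "AlertConfig",
    "AlertEvent",
    "MqpEntry",
    "MqpSeries",
    "compute_mqp",
    "build_series",
    "detect_alert",
    "alert_events",
    "series_at_percentile",
    "save_series",
    "load_series",
    "read_plan_manifest",
    "write_plan_manifest",
    "track_plan",
]


@dataclass
class Acquisition:
    """One CBCT acquisition of a plan: volume, registration, usability."""

    fraction: int
    volume: VolumeGrid
    transform: RigidTransform | None = None
    usable: bool = True


@dataclass(frozen=True)
class AlertConfig:
    """Trigger condition: ``consecutive_required`` MQP values < ``threshold``.

    ``mute_after_fraction`` optionally marks events at or beyond that
    fraction as suppressed (e.g. to silence alerts during the last week
    of treatment); suppression flags events, it never removes them.
    """

    threshold: float = -0.11
    consecutive_required: int = 3
    mute_after_fraction: int | None = None

    def __post_init__(self) -> None:
        if self.consecutive_required < 1:
            raise PreconditionError(
                f"consecutive_required must be >= 1, got {self.consecutive_required}"
            )


@dataclass
class MqpEntry:
    """One point of the MQP series (one usable acquisition after the first)."""

    acquisition_index: int
    fraction: int
    mqp: float
    gamma_x: float | None = None
    failed_values: np.ndarray | None = None


@dataclass
class MqpSeries:
    plan_id: str
    x: float
    gamma_ref: float
    entries: list[MqpEntry]

    def __post_init__(self) -> None:
        fracs = [e.fraction for e in self.entries]
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise PreconditionError(
                f"plan {self.plan_id}: entries must be strictly increasing in fraction"
            )
        if self.entries and self.entries[0].mqp != 0.0:
            raise PreconditionError(
                f"plan {self.plan_id}: reference-match MQP must be exactly 0"
            )

    @property
    def mqp_values(self) -> np.ndarray:
        return np.array([e.mqp for e in self.entries])


@dataclass
class AlertEvent:
    plan_id: str
    trigger_fraction: int
    trigger_acquisition: int
    contributing_entries: list[MqpEntry]
    is_followup: bool = False
    suppressed: bool = False


def compute_mqp(gamma_ref: float, gamma_i: float) -> float:
    """MQP for one acquisition: ``gamma_ref - gamma_i``.

    Negative values mean the current match has a higher failed-gamma
    percentile (a poorer match) than the reference match.
    """
    if not (math.isfinite(gamma_ref) and math.isfinite(gamma_i)):
        raise PreconditionError(
            f"gamma values must be finite, got ref={gamma_ref}, i={gamma_i}"
        )
    return gamma_ref - gamma_i


def build_series(
    acquisitions: Sequence[Acquisition],
    external_mask: MaskVolume,
    criteria: GammaCriteria = GammaCriteria(),
    x: float = 80.0,
    margin_mm: float = 10.0,
    plan_id: str = "plan",
    keep_failed_values: bool = True,
    mode: str = "subvoxel",
) -> MqpSeries:
    """Build the MQP series for one plan from its usable CBCTs.

    All volumes (including the reference) are resampled into the planning
    frame via their registration transforms, onto the grid of the first
    usable CBCT; the external mask lives on that grid and is dilated by
    ``margin_mm`` before gamma evaluation. Entry i (i >= 1) compares
    CBCT[0] with CBCT[i]; entry 1 is the reference match with MQP exactly
    0. When ``keep_failed_values`` is set every entry retains its failed
    gamma multiset, so percentiles for any other x can be recomputed
    without re-running gamma.
    """
    usable = [a for a in acquisitions if a.usable]
    if len(usable) < 2:
        raise PreconditionError(
            f"plan {plan_id}: need at least 2 usable CBCTs, got {len(usable)}"
        )
    ref_acq = usable[0]
    grid = ref_acq.volume
    if external_mask.shape != grid.shape:
        raise PreconditionError(
            f"plan {plan_id}: external mask shape {external_mask.shape} does not "
            f"match reference grid {grid.shape}"
        )
    mask = mask_from_external(external_mask, grid.spacing, margin_mm)

    ref_res = resample_onto(ref_acq.volume, ref_acq.transform, grid)
    gamma_ref: float | None = None
    entries: list[MqpEntry] = []
    for i, acq in enumerate(usable[1:], start=1):
        moved = resample_onto(acq.volume, acq.transform, grid)
        result = compute_gamma(ref_res, moved, mask, criteria, mode=mode)
        g_x = failed_percentile(result, x)
        if gamma_ref is None:
            gamma_ref = g_x
            mqp = 0.0
        else:
            mqp = compute_mqp(gamma_ref, g_x)
        entries.append(
            MqpEntry(
                acquisition_index=i,
                fraction=acq.fraction,
                mqp=mqp,
                gamma_x=g_x,
                failed_values=result.failed_values if keep_failed_values else None,
            )
        )
    assert gamma_ref is not None
    return MqpSeries(plan_id=plan_id, x=x, gamma_ref=gamma_ref, entries=entries)


def series_at_percentile(series: MqpSeries, x: float) -> MqpSeries:
    """Recompute a series at a different percentile from stored failed values.

    Requires ``failed_values`` on every entry (entry 1 carries the
    reference match's multiset, from which the new ``gamma_ref`` comes).
    """
    if any(e.failed_values is None for e in series.entries):
        raise PreconditionError(
            f"plan {series.plan_id}: failed values were not retained; "
            "rebuild the series with keep_failed_values=True"
        )
    gamma_ref = failed_percentile(series.entries[0].failed_values, x)
    new_entries = []
    for e in series.entries:
        g_x = failed_percentile(e.failed_values, x)
        mqp = 0.0 if e.acquisition_index == series.entries[0].acquisition_index else compute_mqp(gamma_ref, g_x)
        new_entries.append(replace(e, mqp=mqp, gamma_x=g_x))
    return MqpSeries(series.plan_id, x, gamma_ref, new_entries)


def detect_alert(series: MqpSeries, config: AlertConfig = AlertConfig()) -> AlertEvent | None:
    """First acquisition completing a run of sub-threshold MQP values, or None.

    The comparison is strict (< threshold): a value equal to the
    threshold does not count and resets the run, as does any value at or
    above it. Runs are counted over consecutive entries in acquisition
    order within one series; they never span a re-plan boundary because a
    re-plan starts a new series.
    """
    run: list[MqpEntry] = []
    for entry in series.entries:
        if entry.mqp < config.threshold:
            run.append(entry)
            if len(run) == config.consecutive_required:
                return AlertEvent(
                    plan_id=series.plan_id,
                    trigger_fraction=run[-1].fraction,
                    trigger_acquisition=run[-1].acquisition_index,
                    contributing_entries=list(run),
                )
        else:
            run = []
    return None


def alert_events(series: MqpSeries, config: AlertConfig = AlertConfig()) -> list[AlertEvent]:
    """All alert events: the first trigger plus follow-ups.

    After the initial trigger, every subsequent sub-threshold acquisition
    is reported as a follow-up event (flagged ``is_followup``), mirroring
    how repeated alerts arrive in practice while the anatomy stays
    changed. Events at or beyond ``mute_after_fraction`` are flagged
    ``suppressed`` but still listed.
    """
    first = detect_alert(series, config)
    if first is None:
        return []
    events = [first]
    for entry in series.entries:
        if entry.acquisition_index <= first.trigger_acquisition:
            continue
        if entry.mqp < config.threshold:
            events.append(
                AlertEvent(
                    plan_id=series.plan_id,
                    trigger_fraction=entry.fraction,
                    trigger_acquisition=entry.acquisition_index,
                    contributing_entries=[entry],
                    is_followup=True,
                )
            )
    if config.mute_after_fraction is not None:
        for ev in events:
            if ev.trigger_fraction >= config.mute_after_fraction:
                ev.suppressed = True
    return events


# ---------------------------------------------------------------------------
# Series persistence
# ---------------------------------------------------------------------------

def save_series(series: MqpSeries, base_path: str | Path) -> tuple[Path, Path]:
    """Write a series as ``<base>.mqp.tsv`` (plot-ready) + ``<base>.mqp.json``.

    The TSV carries (fraction, acquisition, mqp, gamma_x) — the axes of
    the per-patient MQP-vs-fraction plot. The JSON sidecar retains the
    full state including per-entry failed gamma values (when kept), so
    percentile re-scans can run without touching image data.
    """
    base = Path(base_path)
    tsv = base.with_suffix(".mqp.tsv")
    js = base.with_suffix(".mqp.json")
    lines = [
        f"# plan_id: {series.plan_id}",
        f"# x: {series.x:g}",
        f"# gamma_ref: {series.gamma_ref!r}",
        "fraction\tacquisition\tmqp\tgamma_x",
    ]
    for e in series.entries:
        gx = "" if e.gamma_x is None else f"{e.gamma_x!r}"
        lines.append(f"{e.fraction}\t{e.acquisition_index}\t{e.mqp!r}\t{gx}")
    tsv.write_text("\n".join(lines) + "\n")

    payload = {
        "plan_id": series.plan_id,
        "x": series.x,
        "gamma_ref": series.gamma_ref,
        "entries": [
            {
                "acquisition_index": e.acquisition_index,
                "fraction": e.fraction,
                "mqp": e.mqp,
                "gamma_x": e.gamma_x,
                "failed_values": None if e.failed_values is None else [float(v) for v in e.failed_values],
            }
            for e in series.entries
        ],
    }
    js.write_text(json.dumps(payload) + "\n")
    return tsv, js


def load_series(path: str | Path) -> MqpSeries:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"series file not found: {path}")
    try:
        payload = json.loads(path.read_text())
        entries = [
            MqpEntry(
                acquisition_index=int(e["acquisition_index"]),
                fraction=int(e["fraction"]),
                mqp=float(e["mqp"]),
                gamma_x=None if e.get("gamma_x") is None else float(e["gamma_x"]),
                failed_values=None
                if e.get("failed_values") is None
                else np.asarray(e["failed_values"], dtype=float),
            )
            for e in payload["entries"]
        ]
        return MqpSeries(
            plan_id=str(payload["plan_id"]),
            x=float(payload["x"]),
            gamma_ref=float(payload["gamma_ref"]),
            entries=entries,
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"{path}: bad series file ({exc})") from exc


# ---------------------------------------------------------------------------
# Plan manifests
# ---------------------------------------------------------------------------

@dataclass
class PlanManifest:
    """Disk-level description of one plan: paths, fractions, usability."""

    plan_id: str
    external_mask: str
    acquisitions: list[dict]  # fraction, volume, transform (optional), usable
    root: Path = field(default_factory=Path)


def write_plan_manifest(manifest: PlanManifest, path: str | Path) -> None:
    doc = {
        "plan_id": manifest.plan_id,
        "external_mask": manifest.external_mask,
        "acquisitions": manifest.acquisitions,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_plan_manifest(path: str | Path) -> PlanManifest:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"plan manifest not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
        acqs = doc["acquisitions"]
        plan_id = str(doc["plan_id"])
        mask = str(doc["external_mask"])
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise FormatError(f"{path}: bad plan manifest ({exc})") from exc
    for a in acqs:
        if "fraction" not in a or "volume" not in a:
            raise FormatError(f"{path}: acquisition entries need 'fraction' and 'volume'")
    return PlanManifest(plan_id=plan_id, external_mask=mask, acquisitions=acqs, root=path.parent)


def track_plan(
    manifest: PlanManifest,
    criteria: GammaCriteria = GammaCriteria(),
    x: float = 80.0,
    margin_mm: float = 10.0,
    keep_failed_values: bool = True,
) -> MqpSeries:
    """Load a plan's volumes per its manifest and build the MQP series."""
    root = manifest.root
    mask, _grid = load_mask(root / manifest.external_mask)
    acqs = []
    for a in manifest.acquisitions:
        vol = load_volume(root / a["volume"])
        tfm = load_transform(root / a["transform"]) if a.get("transform") else None
        acqs.append(
            Acquisition(
                fraction=int(a["fraction"]),
                volume=vol,
                transform=tfm,
                usable=bool(a.get("usable", True)),
            )
        )
    return build_series(
        acqs,
        mask,
        criteria,
        x=x,
        margin_mm=margin_mm,
        plan_id=manifest.plan_id,
        keep_failed_values=keep_failed_values,
    )
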