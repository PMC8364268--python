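"""Masked 3D global gamma comparison between serial CBCT volumes.

The gamma index, applied here to image intensities rather than dose,
scores each reference voxel ``r`` against the evaluated volume::

    gamma(r) = min over r' of sqrt( |r' - r|^2 / dta^2
                                    + (HU_eval(r') - HU_ref(r))^2 / dHU^2 )

with a *global* intensity criterion: the denominator ``dHU`` is a fixed
HU difference (default 30 HU), never a local percentage. ``dta`` is the
distance-to-agreement criterion (default 3 mm). gamma <= 1 is a pass,
gamma > 1 a failure. The minimisation runs over a bounded sphere of
candidate offsets; two discretizations are provided:

* ``mode="subvoxel"`` (default): candidate offsets on a regular mm
  lattice of pitch ``interp_step_mm`` with trilinear interpolation of the
  evaluated volume — standard distance-to-agreement practice;
* ``mode="integer"``: offsets restricted to whole-voxel displacements
  with no interpolation, which makes the search exactly reproducible by
  an exhaustive brute-force oracle.

Only voxels inside the supplied mask (the external contour dilated by a
margin) are evaluated; the multiset of failed gamma values feeds the
match-quality-parameter percentile downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import PreconditionError
from .volume_io import MaskVolume, VolumeGrid, save_volume

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "compute_gamma",
    "failed_percentile",
    "export_gamma",
    "export_failed_histogram",
]

logger = logging.getLogger(__name__)

_AIR_HU = -1000.0

try:  # optional fast path; the numpy search below is the reference implementation
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

_numba_kernel = None


def _get_numba_kernel():
    """Compile (once) the per-voxel gamma search kernel."""
    global _numba_kernel
    if _numba_kernel is not None:
        return _numba_kernel

    @_numba.njit(cache=False)
    def kernel(eva, idx, ref_vals, gamma2, offs_vox, dist_terms, inv_dhu2, fill):
        nz, ny, nx = eva.shape
        for p in range(idx.shape[0]):
            g = gamma2[p]
            z0, y0, x0 = idx[p, 0], idx[p, 1], idx[p, 2]
            rv = ref_vals[p]
            for o in range(offs_vox.shape[0]):
                t = dist_terms[o]
                if t >= g:
                    break  # offsets sorted by distance: no further improvement
                z = z0 + offs_vox[o, 0]
                y = y0 + offs_vox[o, 1]
                x = x0 + offs_vox[o, 2]
                iz = int(np.floor(z))
                iy = int(np.floor(y))
                ix = int(np.floor(x))
                fz = z - iz
                fy = y - iy
                fx = x - ix
                val = 0.0
                for dz in range(2):
                    wz = fz if dz else 1.0 - fz
                    if wz == 0.0:
                        continue
                    for dy in range(2):
                        wy = fy if dy else 1.0 - fy
                        if wy == 0.0:
                            continue
                        for dx in range(2):
                            wx = fx if dx else 1.0 - fx
                            if wx == 0.0:
                                continue
                            zz, yy, xx = iz + dz, iy + dy, ix + dx
                            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                                v = eva[zz, yy, xx]
                            else:
                                v = fill
                            val += wz * wy * wx * v
                d = val - rv
                c = t + d * d * inv_dhu2
                if c < g:
                    g = c
            gamma2[p] = g

    _numba_kernel = kernel
    return kernel


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma comparison criteria.

    Parameters
    ----------
    dta_mm
        Distance-to-agreement criterion in mm (> 0).
    delta_hu
        Global intensity-difference criterion in HU (> 0).
    search_radius_mm
        Maximum search distance for the minimisation; ``None`` defaults
        to ``3 * dta_mm``. Bounds the attainable gamma at voxels with no
        nearby intensity match, so it is part of the visible config.
    interp_step_mm
        Pitch of the subvoxel candidate lattice; ``None`` defaults to
        ``min(spacing) / 3`` at compute time. Must be <= min(spacing)/2.
    """

    dta_mm: float = 3.0
    delta_hu: float = 30.0
    search_radius_mm: float | None = None
    interp_step_mm: float | None = None

    def __post_init__(self) -> None:
        if self.dta_mm <= 0:
            raise PreconditionError(f"dta_mm must be > 0, got {self.dta_mm}")
        if self.delta_hu <= 0:
            raise PreconditionError(f"delta_hu must be > 0, got {self.delta_hu}")
        if self.search_radius_mm is not None and self.search_radius_mm < self.dta_mm:
            raise PreconditionError(
                f"search_radius_mm ({self.search_radius_mm}) must be >= dta_mm ({self.dta_mm})"
            )

    def resolved(self, spacing: np.ndarray) -> tuple[float, float]:
        """Resolve (search_radius_mm, interp_step_mm) for a given grid."""
        radius = self.search_radius_mm if self.search_radius_mm is not None else 3.0 * self.dta_mm
        step = self.interp_step_mm if self.interp_step_mm is not None else float(np.min(spacing)) / 3.0
        if step > float(np.min(spacing)) / 2.0 + 1e-12:
            raise PreconditionError(
                f"interp_step_mm ({step}) must be <= min(spacing)/2 ({float(np.min(spacing)) / 2})"
            )
        return float(radius), float(step)


@dataclass
class GammaResult:
    """Per-voxel gamma values within the mask plus the failed-value multiset.

    ``gamma`` is a full-shape float array, NaN outside the (effective)
    mask. ``failed_values`` holds exactly the gamma values > 1 inside the
    mask, sorted ascending. Voxels with non-finite intensities inside the
    supplied mask are excluded from evaluation and from ``n_evaluated``;
    their count is logged and kept in ``n_excluded``.
    """

    gamma: np.ndarray
    mask: MaskVolume
    failed_values: np.ndarray
    n_evaluated: int
    n_excluded: int = 0
    spacing: np.ndarray | None = None
    origin: np.ndarray | None = None

    @property
    def n_failed(self) -> int:
        return int(self.failed_values.size)

    @property
    def fail_fraction(self) -> float:
        return self.n_failed / self.n_evaluated if self.n_evaluated else 0.0


def _candidate_offsets(
    spacing: np.ndarray,
    radius_mm: float,
    step_mm: float,
    mode: str,
    in_plane: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate offsets (voxel units) and squared distance terms, sorted by distance.

    The zero offset is excluded (it seeds the minimisation separately).
    """
    if mode == "integer":
        nmax = np.floor(radius_mm / spacing).astype(int)
        grids = np.mgrid[
            -nmax[0] : nmax[0] + 1, -nmax[1] : nmax[1] + 1, -nmax[2] : nmax[2] + 1
        ]
        offs_vox = grids.reshape(3, -1).T.astype(float)
        offs_mm = offs_vox * spacing
    elif mode == "subvoxel":
        n = int(np.floor(radius_mm / step_mm))
        grids = np.mgrid[-n : n + 1, -n : n + 1, -n : n + 1]
        offs_mm = grids.reshape(3, -1).T.astype(float) * step_mm
        offs_vox = offs_mm / spacing
    else:
        raise PreconditionError(f"unknown gamma search mode {mode!r}")
    dist2 = np.einsum("ij,ij->i", offs_mm, offs_mm)
    keep = (dist2 <= radius_mm**2 + 1e-9) & (dist2 > 0)
    if in_plane:
        keep &= offs_mm[:, 0] == 0
    offs_vox, dist2 = offs_vox[keep], dist2[keep]
    order = np.argsort(dist2, kind="stable")
    return offs_vox[order], dist2[order]


def _search_numpy(
    eva: np.ndarray,
    idx: np.ndarray,
    ref_vals: np.ndarray,
    gamma2: np.ndarray,
    offs_vox: np.ndarray,
    dist_terms: np.ndarray,
    inv_dhu2: float,
    mode: str,
) -> None:
    """Reference vectorized search: offsets in distance order, active-set pruning.

    In-place minimisation of ``gamma2``. ``integer`` mode gathers whole-
    voxel candidates directly (out-of-bounds candidates skipped);
    ``subvoxel`` mode interpolates trilinearly with air fill.
    """
    shape = np.array(eva.shape)
    active = np.arange(ref_vals.size)
    coords0 = idx.astype(float)
    for off, dist_term in zip(offs_vox, dist_terms):
        sub = gamma2[active] > dist_term
        active = active[sub]
        if active.size == 0:
            break
        coords = coords0[active] + off
        if mode == "integer":
            ic = np.round(coords).astype(np.int64)
            inb = np.all((ic >= 0) & (ic < shape), axis=1)
            if not inb.any():
                continue
            tgt = active[inb]
            icb = ic[inb]
            vals = eva[icb[:, 0], icb[:, 1], icb[:, 2]]
            cand = dist_term + (vals - ref_vals[tgt]) ** 2 * inv_dhu2
            np.minimum(gamma2[tgt], cand, out=cand)
            gamma2[tgt] = cand
        else:
            vals = ndimage.map_coordinates(
                eva, coords.T, order=1, mode="constant", cval=_AIR_HU, prefilter=False
            )
            cand = dist_term + (vals - ref_vals[active]) ** 2 * inv_dhu2
            np.minimum(gamma2[active], cand, out=cand)
            gamma2[active] = cand


def compute_gamma(
    reference: VolumeGrid,
    evaluated: VolumeGrid,
    mask: MaskVolume,
    criteria: GammaCriteria = GammaCriteria(),
    mode: str = "subvoxel",
    in_plane: bool = False,
) -> GammaResult:
    """Compute the masked global gamma map of ``evaluated`` against ``reference``.

    Both volumes must share one grid (resample first). The minimisation
    visits candidate offsets in order of increasing distance and retires a
    voxel as soon as its current best gamma cannot be improved (the
    distance term alone already exceeds it), which keeps the search cheap
    wherever the images agree.

    In ``subvoxel`` mode, candidates falling outside the evaluated array
    sample air (-1000 HU); in ``integer`` mode out-of-bounds candidates
    are simply skipped, matching the brute-force oracle's convention.

    Set ``in_plane=True`` to restrict the search to each voxel's axial
    plane (2D-per-slice variant, useful for single-plane figures).
    """
    if not reference.same_grid(evaluated):
        raise PreconditionError("reference and evaluated volumes are not on the same grid")
    if mask.shape != reference.shape:
        raise PreconditionError(
            f"mask shape {mask.shape} does not match volume shape {reference.shape}"
        )
    if mask.count() == 0:
        raise PreconditionError("empty mask: nothing to evaluate")

    spacing = reference.spacing
    radius_mm, step_mm = criteria.resolved(spacing)
    ref = np.asarray(reference.data, dtype=float)
    eva = np.asarray(evaluated.data, dtype=float)

    finite = np.isfinite(ref) & np.isfinite(eva)
    eff_mask = mask.data & finite
    n_excluded = int(mask.count() - eff_mask.sum())
    if n_excluded:
        logger.info("gamma: excluding %d non-finite voxels inside the mask", n_excluded)
    if not eff_mask.any():
        raise PreconditionError("mask contains only non-finite voxels")
    # non-finite evaluated voxels must never win the minimisation
    if not np.isfinite(eva).all():
        eva = np.where(np.isfinite(eva), eva, 1e9)

    idx = np.argwhere(eff_mask)
    ref_vals = ref[eff_mask]
    n = ref_vals.size
    inv_dta2 = 1.0 / criteria.dta_mm**2
    inv_dhu2 = 1.0 / criteria.delta_hu**2

    # zero-offset seed: same-voxel intensity difference
    gamma2 = (eva[eff_mask] - ref_vals) ** 2 * inv_dhu2

    offs_vox, dist2_mm = _candidate_offsets(spacing, radius_mm, step_mm, mode, in_plane)
    dist_terms = dist2_mm * inv_dta2

    if mode == "subvoxel" and _numba is not None:
        kernel = _get_numba_kernel()
        kernel(
            np.ascontiguousarray(eva),
            idx.astype(np.float64),
            ref_vals,
            gamma2,
            np.ascontiguousarray(offs_vox),
            np.ascontiguousarray(dist_terms),
            inv_dhu2,
            _AIR_HU,
        )
    else:
        _search_numpy(eva, idx, ref_vals, gamma2, offs_vox, dist_terms, inv_dhu2, mode)

    gamma_vals = np.sqrt(gamma2)
    gamma_map = np.full(ref.shape, np.nan)
    gamma_map[eff_mask] = gamma_vals
    failed = np.sort(gamma_vals[gamma_vals > 1.0])
    return GammaResult(
        gamma=gamma_map,
        mask=MaskVolume(eff_mask, provenance="gamma-effective"),
        failed_values=failed,
        n_evaluated=n,
        n_excluded=n_excluded,
        spacing=spacing.copy(),
        origin=reference.origin.copy(),
    )


def failed_percentile(result: "GammaResult | np.ndarray", x: float = 80.0) -> float:
    """The xth empirical percentile of the failed-voxel gamma values.

    Uses linear interpolation between closest order statistics (the
    bin-free limit of a histogram percentile). If no voxel failed, the
    sentinel 1.0 — the pass/fail boundary — is returned, so a perfect
    match can never look worse than the reference match.
    """
    if not 0 < x < 100:
        raise PreconditionError(f"percentile x must be in (0, 100), got {x}")
    values = result.failed_values if isinstance(result, GammaResult) else np.asarray(result, dtype=float)
    if values.size == 0:
        return 1.0
    return float(np.percentile(values, x, method="linear"))


def export_gamma(result: GammaResult, base_path: str | Path) -> Path:
    """Write the gamma map as a research-format volume (NaN outside the mask)."""
    if result.spacing is None or result.origin is None:
        raise PreconditionError("gamma result carries no grid geometry")
    vol = VolumeGrid(result.gamma, result.spacing, result.origin)
    return save_volume(vol, base_path)


def export_failed_histogram(
    result: GammaResult, path: str | Path, bin_width: float = 0.05
) -> None:
    """Write the failed-value histogram as two-column text (bin centre, count)."""
    path = Path(path)
    vals = result.failed_values
    if vals.size == 0:
        path.write_text("# bin_center\tcount\n")
        return
    lo, hi = 1.0, float(vals.max()) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lines = ["# bin_center\tcount"]
    lines += [f"{c:.6g}\t{int(n)}" for c, n in zip(centers, counts)]
    path.write_text("\n".join(lines) + "\n")
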