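"""3D dose grids, diode-array detector geometries and the global gamma engine.

The gamma index compares a *reference* dose distribution (detector readings
for measurement-based QA, the original planned dose for calculation-based QA
— reference points are never interpolated) against an *evaluated* 3D dose
grid.  For reference point r with dose D_r,

    gamma(r) = min over evaluated positions e of
               sqrt(|r - e|^2 / DTA^2 + (D_e - D_r)^2 / (dd * D_norm / 100)^2)

with global normalization D_norm (maximum of the reference set by default).
Reference points below the dose threshold (10% of D_norm by default) are
excluded.  The gamma passing rate (GPR) is the percentage of evaluated
points with gamma <= 1.

The engine searches the evaluated grid on an upsampled displacement lattice
in shells of increasing distance with early termination (points whose
current best gamma cannot be improved by farther shells drop out).  When
several criteria are analysed together they share one candidate lattice, so
a more lenient criterion can never score worse than a stricter one on the
same dose pair — the GPR ordering across criteria is exact by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

#: The four acceptance criteria used throughout: (dose difference %, DTA mm).
STANDARD_CRITERIA: tuple[tuple[float, float], ...] = (
    (3.0, 3.0), (3.0, 2.0), (2.0, 2.0), (1.0, 1.0))

DEFAULT_THRESHOLD_PERCENT = 10.0


class DoseSamplingError(ValueError):
    """Detector points fall outside the dose-grid bounds."""


@dataclass(frozen=True)
class DoseGrid:
    """A 3D dose lattice: origin + isotropic-or-not spacing + Gy values."""

    origin: np.ndarray       # mm, (3,)
    spacing: np.ndarray      # mm, (3,), default use is 2.5 mm isotropic
    values: np.ndarray       # Gy, (nx, ny, nz)

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, float))
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if v.ndim != 3:
            raise ValueError("dose values must be a 3-D array")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("dose values must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
                     for i in range(3))

    def bounds(self) -> np.ndarray:
        """(2, 3) array of (min, max) mm per axis."""
        hi = self.origin + self.spacing * (np.array(self.shape) - 1)
        return np.stack([self.origin, hi])

    def save_npz(self, path: str | Path) -> None:
        np.savez(path, origin=self.origin, spacing=self.spacing,
                 values=self.values)

    @classmethod
    def load_npz(cls, path: str | Path) -> "DoseGrid":
        with np.load(path) as z:
            return cls(z["origin"], z["spacing"], z["values"])


def read_dicom_dose(path: str | Path) -> DoseGrid:
    """Read a DICOM-RT Dose file into a :class:`DoseGrid`.

    Axis order is converted to (x, y, z); spacing must be uniform along the
    frame-offset axis.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    scale = float(getattr(ds, "DoseGridScaling", 1.0))
    vol = ds.pixel_array.astype(float) * scale  # (z, rows=y, cols=x)
    offsets = np.asarray(ds.GridFrameOffsetVector, float)
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0]):
        raise ValueError(f"{path}: non-uniform frame offsets unsupported")
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    origin = np.asarray(ds.ImagePositionPatient, float)
    values = np.transpose(vol, (2, 1, 0))  # -> (x, y, z)
    spacing = np.array([col_sp, row_sp, float(dz[0]) if offsets.size > 1 else 1.0])
    return DoseGrid(origin=origin, spacing=spacing, values=values)


# ---------------------------------------------------------------------------
# detector layouts


@dataclass(frozen=True)
class DetectorLayout:
    """A set of detector sample points with stable ids."""

    kind: str                 # helical | cross | oblique_cross
    points: np.ndarray        # (n, 3) mm
    ids: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "points", np.asarray(self.points, float))
        if self.points.shape[0] != len(self.ids):
            raise ValueError("point/id count mismatch")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def subsample(self, step: int) -> "DetectorLayout":
        """Every ``step``-th detector (used for scaled-down cohort runs)."""
        return DetectorLayout(self.kind, self.points[::step],
                              tuple(self.ids[::step]))


def build_layout(kind: str, *, radius_mm: float = 105.0,
                 length_mm: float = 210.0, pitch_mm: float = 10.0,
                 plane_half_mm: float = 100.0, fine_pitch_mm: float = 5.0,
                 fine_half_mm: float = 30.0) -> DetectorLayout:
    """Construct a diode-array geometry.

    ``helical``
        Diodes on a cylinder surface (radius 105 mm, length 210 mm) in rings
        of 10 mm arc pitch stacked at 10 mm axial pitch — 66 diodes per ring
        x 21 rings; rings are staggered by half the angular pitch.  The real
        device's exact spiral pattern is approximated; diode count and radius
        are the modelled facts.
    ``cross``
        Two perpendicular 200 x 200 mm planes through the cylinder (z) axis
        with 5 mm pitch inside the central 60 x 60 mm and 10 mm outside;
        points shared by both planes (on the axis line) appear once.
    ``oblique_cross``
        The cross layout rotated 45 degrees about the cylinder axis.
    """
    if kind == "helical":
        # one ring per axial pitch slab, at the slab centre: 21 rings over 210 mm
        n_rings = int(round(length_mm / pitch_mm))
        circumference = 2.0 * np.pi * radius_mm
        n_per_ring = int(round(circumference / pitch_mm))
        zs = -length_mm / 2.0 + pitch_mm * (np.arange(n_rings) + 0.5)
        pts = []
        ids = []
        for ri, z in enumerate(zs):
            phase = (ri % 2) * np.pi / n_per_ring  # half-pitch stagger
            ang = phase + 2.0 * np.pi * np.arange(n_per_ring) / n_per_ring
            for ai, a in enumerate(ang):
                pts.append((radius_mm * np.cos(a), radius_mm * np.sin(a), z))
                ids.append(f"h{ri:02d}_{ai:02d}")
        return DetectorLayout("helical", np.array(pts), tuple(ids))

    if kind in ("cross", "oblique_cross"):
        coarse = np.arange(-plane_half_mm, plane_half_mm + 0.5, pitch_mm)
        fine = np.arange(-fine_half_mm, fine_half_mm + 0.5, fine_pitch_mm)
        plane_uv = [(u, z) for u in coarse for z in coarse
                    if max(abs(u), abs(z)) > fine_half_mm + 1e-9]
        plane_uv += [(u, z) for u in fine for z in fine]
        pts = []
        ids = []
        seen = set()
        for plane, (ex, ey) in (("p1", (1.0, 0.0)), ("p2", (0.0, 1.0))):
            for i, (uu, z) in enumerate(plane_uv):
                key = (round(uu * ex, 6), round(uu * ey, 6), round(z, 6))
                if abs(uu) < 1e-9 and key in seen:
                    continue  # axis line shared by both planes
                seen.add(key)
                pts.append((uu * ex, uu * ey, z))
                ids.append(f"{plane}_{i:03d}")
        pts = np.array(pts)
        if kind == "oblique_cross":
            c = np.cos(np.pi / 4.0)
            rot = np.array([[c, -c, 0.0], [c, c, 0.0], [0.0, 0.0, 1.0]])
            pts = pts @ rot.T
        return DetectorLayout(kind, pts, tuple(ids))

    raise ValueError(f"unknown detector layout kind {kind!r}")


# ---------------------------------------------------------------------------
# sampling and gamma


def _fractional_index(grid: DoseGrid, points: np.ndarray) -> np.ndarray:
    return (points - grid.origin[None, :]) / grid.spacing[None, :]


def sample_dose(grid: DoseGrid, layout: DetectorLayout) -> np.ndarray:
    """Trilinear interpolation of the calculated grid at the detector points.

    Only the calculated grid is ever interpolated; measured readings are used
    as-is by the gamma engine.  Out-of-bounds points raise, listing their ids.
    """
    idx = _fractional_index(grid, layout.points)
    hi = np.array(grid.shape) - 1
    bad = np.any((idx < -1e-9) | (idx > hi[None, :] + 1e-9), axis=1)
    if bad.any():
        names = [layout.ids[i] for i in np.nonzero(bad)[0][:10]]
        raise DoseSamplingError(
            f"{int(bad.sum())} detector point(s) outside the dose grid, "
            f"e.g. {names}")
    return ndimage.map_coordinates(grid.values, np.clip(idx, 0, hi).T,
                                   order=1, mode="nearest")


@dataclass(frozen=True)
class GammaResult:
    """Per-point gamma values and the passing rate at one criterion."""

    criterion: tuple[float, float]          # (dd %, dta mm)
    threshold_percent: float
    gamma_values: np.ndarray                # NaN for below-threshold points
    gpr: float                              # percent
    n_evaluated: int


def _shell_plan(dta_values: np.ndarray, step: float, radius_factor: float):
    """Shared displacement lattice grouped into distance shells.

    Returns (offsets sorted by distance, distances, shell slice boundaries).
    """
    r_max = radius_factor * float(np.max(dta_values))
    n = int(np.floor(r_max / step))
    ax = step * np.arange(-n, n + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    offsets = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    dist = np.linalg.norm(offsets, axis=1)
    keep = dist <= r_max + 1e-9
    offsets, dist = offsets[keep], dist[keep]
    order = np.argsort(dist)
    offsets, dist = offsets[order], dist[order]
    # group into shells of one step width
    edges = np.searchsorted(dist, step * np.arange(1, n + 2), side="left")
    starts = np.concatenate([[0], edges[:-1]])
    return offsets, dist, list(zip(starts, edges))


def gamma_analysis_multi(
    reference_points: np.ndarray,
    reference_doses: np.ndarray,
    evaluated: DoseGrid,
    criteria: tuple[tuple[float, float], ...] = STANDARD_CRITERIA,
    threshold_percent: float = DEFAULT_THRESHOLD_PERCENT,
    normalization: float | None = None,
    search_step_fraction: float = 10.0,
    search_radius_factor: float = 3.0,
) -> dict[tuple[float, float], GammaResult]:
    """Global 3D gamma of reference points against an evaluated grid.

    All criteria are evaluated on one shared displacement lattice with step
    ``min(DTA)/search_step_fraction`` and per-criterion search radius
    ``search_radius_factor * DTA`` (the radius only affects gamma values
    above ~``radius/DTA``; pass/fail at gamma = 1 needs radius >= DTA).

    ``normalization`` overrides the global normalization dose (default: max
    of the reference doses).
    """
    ref_pts = np.asarray(reference_points, float)
    ref_dose = np.asarray(reference_doses, float)
    if ref_pts.shape[0] != ref_dose.shape[0]:
        raise ValueError("reference point/dose count mismatch")
    d_norm = float(np.max(ref_dose)) if normalization is None else float(normalization)
    if d_norm <= 0:
        raise ValueError("normalization dose must be > 0")

    above = ref_dose >= threshold_percent / 100.0 * d_norm
    n_eval = int(above.sum())
    if n_eval == 0:
        raise ValueError("no evaluable points: all reference doses below threshold")

    dds = np.array([c[0] for c in criteria])
    dtas = np.array([c[1] for c in criteria])
    step = float(np.min(dtas)) / search_step_fraction
    offsets, dist, shells = _shell_plan(dtas, step, search_radius_factor)

    pts = ref_pts[above]
    dose = ref_dose[above]
    n_pts = pts.shape[0]
    n_crit = len(criteria)
    dd_abs = dds * d_norm / 100.0

    gamma2 = np.full((n_pts, n_crit), np.inf)
    best_off = np.zeros((n_pts, n_crit), dtype=np.int64)
    active = np.arange(n_pts)
    hi = np.array(evaluated.shape) - 1

    def _interp(candidates):
        """Trilinear dose at candidate positions; NaN outside the grid."""
        idx = (candidates - evaluated.origin) / evaluated.spacing
        inside = np.all((idx >= 0) & (idx <= hi), axis=-1)
        flat = idx.reshape(-1, 3)
        dval = ndimage.map_coordinates(
            evaluated.values, flat.T, order=1, mode="nearest"
        ).reshape(candidates.shape[:-1])
        return np.where(inside, dval, np.nan)

    for start, stop in shells:
        if active.size == 0:
            break
        shell_off = offsets[start:stop]
        shell_dist = dist[start:stop]
        # prune criteria columns that can no longer improve at this distance
        d_lo = shell_dist[0]
        dist_term_min = (d_lo / dtas[None, :]) ** 2          # (1, n_crit)
        improvable = gamma2[active] > dist_term_min          # (n_active, n_crit)
        keep = improvable.any(axis=1)
        active = active[keep]
        if active.size == 0:
            break
        within = shell_dist <= search_radius_factor * dtas.max() + 1e-9
        if not within.any():
            break
        cand = pts[active][:, None, :] + shell_off[None, :, :]  # (na, ns, 3)
        dval = _interp(cand)
        ddiff2 = (dval - dose[active][:, None]) ** 2            # (na, ns)
        for ci in range(n_crit):
            in_radius = np.nonzero(
                shell_dist <= search_radius_factor * dtas[ci] + 1e-9)[0]
            if in_radius.size == 0:
                continue
            g2 = (shell_dist[None, in_radius] / dtas[ci]) ** 2 \
                + ddiff2[:, in_radius] / dd_abs[ci] ** 2
            g2 = np.where(np.isnan(g2), np.inf, g2)
            loc = g2.argmin(axis=1)
            best = g2[np.arange(g2.shape[0]), loc]
            cur = gamma2[active, ci]
            upd = best < cur
            rows = active[upd]
            gamma2[rows, ci] = best[upd]
            best_off[rows, ci] = start + in_radius[loc[upd]]

    # local refinement around each point's best coarse offsets on a step/5
    # sub-lattice; every criterion is evaluated on the union of a point's
    # refinement neighbourhoods, so the lenient-criterion gamma remains
    # pointwise <= the strict one and the GPR ordering stays exact
    fine = step / 5.0
    ax = fine * np.arange(-4, 5)
    FX, FY, FZ = np.meshgrid(ax, ax, ax, indexing="ij")
    local = np.stack([FX.ravel(), FY.ravel(), FZ.ravel()], axis=1)
    cand_list, owner = [], []
    for p in range(n_pts):
        centers = np.unique(best_off[p])
        cand = (pts[p] + offsets[centers][:, None, :] + local[None, :, :]
                ).reshape(-1, 3)
        cand_list.append(cand)
        owner.append(np.full(cand.shape[0], p))
    cand = np.concatenate(cand_list)
    owner = np.concatenate(owner)
    dval = _interp(cand)
    cdist = np.linalg.norm(cand - pts[owner], axis=1)
    ddiff2 = (dval - dose[owner]) ** 2
    for ci in range(n_crit):
        ok = cdist <= search_radius_factor * dtas[ci] + 1e-9
        g2 = (cdist[ok] / dtas[ci]) ** 2 + ddiff2[ok] / dd_abs[ci] ** 2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        np.minimum.at(gamma2[:, ci], owner[ok], g2)

    results = {}
    for ci, crit in enumerate(criteria):
        g = np.sqrt(gamma2[:, ci])
        full = np.full(ref_pts.shape[0], np.nan)
        full[above] = g
        # tolerance absorbs float round-off for points exactly at gamma = 1
        gpr = 100.0 * float((g <= 1.0 + 1e-9).sum()) / n_eval
        results[crit] = GammaResult(criterion=crit,
                                    threshold_percent=threshold_percent,
                                    gamma_values=full, gpr=gpr,
                                    n_evaluated=n_eval)
    return results


def gamma_analysis(reference_points, reference_doses, evaluated: DoseGrid,
                   criterion: tuple[float, float],
                   threshold_percent: float = DEFAULT_THRESHOLD_PERCENT,
                   normalization: float | None = None,
                   search_step_fraction: float = 10.0,
                   search_radius_factor: float = 3.0) -> GammaResult:
    """Single-criterion convenience wrapper around :func:`gamma_analysis_multi`."""
    return gamma_analysis_multi(
        reference_points, reference_doses, evaluated, (criterion,),
        threshold_percent, normalization, search_step_fraction,
        search_radius_factor)[criterion]


# ---------------------------------------------------------------------------
# long-format GPR bookkeeping


def criterion_label(criterion: tuple[float, float]) -> str:
    return f"{criterion[0]:g}%/{criterion[1]:g}mm"


def gpr_table(records) -> pd.DataFrame:
    """Assemble long-format GPR rows (plan_id, system, criterion, gpr).

    ``records`` is an iterable of dicts with keys plan_id, system, criterion
    (label or (dd, dta) tuple), gpr (may be NaN), and optional status.  Rows
    with missing GPRs are kept and marked ``status='missing'``, never dropped
    silently; duplicate (plan, system, criterion) keys raise.
    """
    rows = []
    for rec in records:
        crit = rec["criterion"]
        if isinstance(crit, tuple):
            crit = criterion_label(crit)
        gpr = rec.get("gpr", np.nan)
        rows.append({
            "plan_id": rec["plan_id"],
            "system": rec["system"],
            "criterion": crit,
            "gpr": float(gpr) if gpr is not None else np.nan,
            "status": rec.get("status",
                              "ok" if gpr is not None and np.isfinite(gpr)
                              else "missing"),
        })
    df = pd.DataFrame(rows, columns=["plan_id", "system", "criterion",
                                     "gpr", "status"])
    dup = df.duplicated(subset=["plan_id", "system", "criterion"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate GPR record for plan={first.plan_id!r} "
            f"system={first.system!r} criterion={first.criterion!r}")
    return df
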