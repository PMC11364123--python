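"""Plan complexity metrics (PCMs) for sliding-window IMRT.

A plan's "complexity" is summarized by a registry of scalar metrics in three
families:

fluence/aperture
    Geometry of the MLC aperture per control point — modulation complexity
    score (MCS) with its leaf-sequence (LSV) and aperture-area (AAV)
    components, mean field area, small-aperture scores (SAS), edge area
    metric (EAM), converted aperture metric (CAM), aperture irregularity,
    plan modulation, and relatives.
MU
    Meterset bookkeeping — total MU, MU per prescribed Gy, beam-on time.
dynamics
    MLC motion — leaf travel (LT), mean/std leaf speed, and the modulation
    indices for speed (MI_s) and acceleration (MI_a) that integrate the
    weighted fraction of inter-control-point speed/acceleration variations
    exceeding multiples of the series' standard deviation.

Every metric is a named plugin carrying its family, its orientation (whether
a larger value indicates a more complex plan; 0 when no sign applies) and a
``fallback`` flag for metrics whose published formula is not fully specified
and which therefore ship with a documented surrogate definition (CAM, MAD).

Aggregation: metrics are computed per beam and combined to plan level as
MU-weighted means (totals like MU and summed leaf travel add instead).
Control-point weights are interval-averaged, ``w_j = (dMU_{j-1} + dMU_j)/2``,
which makes MU-weighted aperture statistics exactly invariant under
duplicating a control point with its meterset split in half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Callable

import numpy as np
from scipy import ndimage

from .rtplan_io import Beam, ControlPoint, Plan, CLOSED_TOL_MM
from .dynamics import (
    LeafKinematics,
    derive_kinematics,
    kinematic_summaries,
    MOVING_SPEED_TOL,
    DEFAULT_MAX_SPEED,
)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class MetricConfig:
    """Tunable parameters shared by the metric plugins.

    raster_px_mm:
        Pixel size for aperture rasterization (EAM/CAM).  The independent
        oracle in the test suite uses 0.1 mm.
    eam_margin_mm:
        Penumbra margin defining the "edge region" of an aperture.
    cam_kappa_mm:
        Decay length of the fallback converted-aperture kernel exp(-d/kappa).
    f_max, f_nodes:
        Integration range [0, f_max] and trapezoid grid size for MI_s/MI_a.
    weight_c:
        Variation-weighting slope: w(v) = 1 + weight_c * v / sigma.  The
        default 1/3 puts weights in ratio 1:2 on variations of sigma and
        5*sigma (e.g. 0.1 vs 0.5 cm/s when sigma = 0.1 cm/s).
    """

    raster_px_mm: float = 0.5
    eam_margin_mm: float = 5.0
    cam_kappa_mm: float = 5.0
    sas_thresholds_mm: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0)
    f_max: float = 1.0
    f_nodes: int = 1000
    weight_c: float = 1.0 / 3.0
    small_field_cm2: float = 10.0
    max_speed_cm_s: float = DEFAULT_MAX_SPEED
    moving_tol_cm_s: float = MOVING_SPEED_TOL

    @property
    def f_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.f_max, self.f_nodes)


DEFAULT_CONFIG = MetricConfig()


# ---------------------------------------------------------------------------
# aperture geometry


@dataclass(frozen=True)
class ApertureShape:
    """The open aperture of one control point.

    ``open_segments`` is an (n_pairs, 2) array of (low, high) mm intervals
    per leaf pair after jaw clipping; closed pairs (width below the closed
    tolerance) and pairs outside the y jaws have zero-width segments.
    ``heights`` are the jaw-clipped leaf-pair heights (mm).  Area is cm^2,
    perimeter cm.
    """

    open_segments: np.ndarray
    heights: np.ndarray
    leaf_boundaries: np.ndarray
    area: float
    perimeter: float

    @property
    def widths(self) -> np.ndarray:
        return self.open_segments[:, 1] - self.open_segments[:, 0]

    @property
    def open_mask(self) -> np.ndarray:
        return self.widths > CLOSED_TOL_MM


def _staircase_perimeter(segments: np.ndarray, heights: np.ndarray) -> float:
    """Perimeter (mm) of a stack of per-row rectangles (the MLC staircase)."""
    widths = segments[:, 1] - segments[:, 0]
    open_ = widths > CLOSED_TOL_MM
    if not open_.any():
        return 0.0
    perim = 0.0
    prev = None  # previous open row's segment, None when previous row closed
    for i in range(segments.shape[0]):
        if not open_[i]:
            if prev is not None:
                perim += prev[1] - prev[0]  # bottom edge of the block above
            prev = None
            continue
        lo, hi = segments[i]
        perim += 2.0 * heights[i]  # left + right edges
        if prev is None:
            perim += hi - lo  # top edge fully exposed
        else:
            ov = max(0.0, min(hi, prev[1]) - max(lo, prev[0]))
            perim += (hi - lo) + (prev[1] - prev[0]) - 2.0 * ov
        prev = (lo, hi)
    if prev is not None:
        perim += prev[1] - prev[0]  # bottom edge of last block
    return perim


def aperture_from_cp(cp: ControlPoint, boundaries: np.ndarray) -> ApertureShape:
    """Jaw-clipped open aperture of a control point.

    Per leaf pair the open interval is ``[max(b, jaw_x_lo), min(a, jaw_x_hi)]``
    clipped to non-negative width; pairs whose leaf-boundary strip does not
    intersect the y jaws are closed.  Area sums width x (jaw-clipped) leaf
    height; the perimeter traces the MLC staircase outline.
    """
    boundaries = np.asarray(boundaries, float)
    lo_y = np.maximum(boundaries[:-1], cp.jaw_y[0])
    hi_y = np.minimum(boundaries[1:], cp.jaw_y[1])
    heights = np.clip(hi_y - lo_y, 0.0, None)

    lo = np.maximum(cp.bank_b_positions, cp.jaw_x[0])
    hi = np.minimum(cp.bank_a_positions, cp.jaw_x[1])
    widths = np.clip(hi - lo, 0.0, None)
    closed = (widths <= CLOSED_TOL_MM) | (heights <= 0.0)
    segments = np.stack([lo, lo + widths], axis=1)
    segments[closed] = 0.0
    h = np.where(closed, 0.0, heights)

    area_mm2 = float(np.sum((segments[:, 1] - segments[:, 0]) * h))
    perim_mm = _staircase_perimeter(segments, h)
    return ApertureShape(
        open_segments=segments,
        heights=h,
        leaf_boundaries=boundaries,
        area=area_mm2 / 100.0,
        perimeter=perim_mm / 10.0,
    )


def _rasterize(ap: ApertureShape, cp: ControlPoint, px: float,
               bounds: tuple[float, float, float, float] | None = None):
    """Boolean open-aperture mask on a ``px``-mm grid.

    Returns (mask, px).  Rows follow the y (leaf-stacking) axis, columns x.
    ``bounds`` = (x0, x1, y0, y1) restricts the raster window (default: the
    jaw box).
    """
    if bounds is None:
        x0, x1 = cp.jaw_x
        y0, y1 = cp.jaw_y
    else:
        x0, x1, y0, y1 = bounds
    nx = max(1, int(round((x1 - x0) / px)))
    ny = max(1, int(round((y1 - y0) / px)))
    xc = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    yc = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
    mask = np.zeros((ny, nx), dtype=bool)
    lb = ap.leaf_boundaries
    row_pair = np.searchsorted(lb, yc, side="right") - 1
    valid = (row_pair >= 0) & (row_pair < ap.open_segments.shape[0])
    for i in np.nonzero(ap.open_mask)[0]:
        rows = valid & (row_pair == i)
        if not rows.any():
            continue
        lo, hi = ap.open_segments[i]
        cols = (xc >= lo) & (xc <= hi)
        mask[np.ix_(rows, cols)] = True
    return mask, px


def edge_and_cam_from_mask(mask: np.ndarray, px: float, margin_mm: float,
                           kappa_mm: float) -> tuple[float, float]:
    """EAM and fallback CAM of one aperture mask.

    Distances to the aperture edge are Euclidean distances on the rasterized
    mask (padded so the jaw box boundary counts as an edge), corrected by
    half a pixel so grid-aligned rectangles give exact band areas.
    """
    n_open = int(mask.sum())
    if n_open == 0:
        return 0.0, 0.0
    padded = np.pad(mask, 1, constant_values=False)
    d = ndimage.distance_transform_edt(padded, sampling=px)[1:-1, 1:-1]
    d_edge = np.clip(d[mask] - 0.5 * px, 0.0, None)
    eam = float((d_edge < margin_mm).mean())
    cam = float(np.exp(-d_edge / kappa_mm).mean())
    return eam, cam


# ---------------------------------------------------------------------------
# modulation indices


def _weighted_z_integral(variations: np.ndarray, sigma: float,
                         f_grid: np.ndarray, weight_c: float) -> float:
    """Integral over f of the weighted exceedance fraction Z(f).

    Z(f) = sum(w_i * [v_i > f*sigma]) / sum(w_i) with w(v) = 1 + c*v/sigma;
    integrated by the trapezoid rule on ``f_grid``.
    """
    if variations.size == 0 or sigma <= 0:
        return 0.0
    w = 1.0 + weight_c * variations / sigma
    thresholds = f_grid * sigma
    # sort variations once; exceedance weight = suffix sum of sorted weights
    order = np.argsort(variations)
    v_sorted = variations[order]
    w_sorted = w[order]
    suffix = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])
    idx = np.searchsorted(v_sorted, thresholds, side="right")
    z = suffix[idx] / w.sum()
    return float(np.trapezoid(z, f_grid))


def _speed_variations(k: LeafKinematics, moving_tol: float):
    """(variations, sigma_s): |delta speed| on moving leaf-interval pairs."""
    moving = k.speeds > moving_tol
    if not moving.any():
        return np.empty(0), 0.0
    sigma = float(k.speeds[moving].std())
    if k.n_intervals < 2:
        return np.empty(0), sigma
    dv = np.abs(np.diff(k.speeds, axis=1))
    mask = moving[:, :-1] | moving[:, 1:]
    return dv[mask], sigma


def _accel_variations(k: LeafKinematics, moving_tol: float):
    """(variations, sigma_a): |delta accel| on moving acceleration pairs."""
    moving = k.speeds > moving_tol
    if k.accelerations.shape[1] == 0 or not moving.any():
        return np.empty(0), 0.0
    mov_a = moving[:, :-1] | moving[:, 1:]
    if not mov_a.any():
        return np.empty(0), 0.0
    sigma = float(k.accelerations[mov_a].std())
    if k.accelerations.shape[1] < 2:
        return np.empty(0), sigma
    da = np.abs(np.diff(k.accelerations, axis=1))
    mask = mov_a[:, :-1] | mov_a[:, 1:]
    return da[mask], sigma


def mi_speed(k: LeafKinematics, f_grid: np.ndarray | None = None,
             weight_c: float = DEFAULT_CONFIG.weight_c,
             moving_tol: float = MOVING_SPEED_TOL) -> float:
    """Modulation index for MLC speed of one beam.

    Integrates, over f in the configured range, the weighted fraction of
    inter-control-point speed variations exceeding ``f * sigma_s`` where
    ``sigma_s`` is the standard deviation of the moving-leaf speeds.  Larger
    variations receive proportionally larger weight (``w = 1 + c*v/sigma``).
    All-equal speeds (sigma_s = 0) give 0 by convention.
    """
    if f_grid is None:
        f_grid = DEFAULT_CONFIG.f_grid
    v, sigma = _speed_variations(k, moving_tol)
    return _weighted_z_integral(v, sigma, np.asarray(f_grid, float), weight_c)


def mi_accel(k: LeafKinematics, f_grid: np.ndarray | None = None,
             weight_c: float = DEFAULT_CONFIG.weight_c,
             moving_tol: float = MOVING_SPEED_TOL) -> float:
    """Modulation index for MLC acceleration (as :func:`mi_speed` with the
    acceleration series and sigma_a)."""
    if f_grid is None:
        f_grid = DEFAULT_CONFIG.f_grid
    v, sigma = _accel_variations(k, moving_tol)
    return _weighted_z_integral(v, sigma, np.asarray(f_grid, float), weight_c)


# ---------------------------------------------------------------------------
# per-beam feature cache


def cp_mu_weights(beam: Beam) -> np.ndarray:
    """Interval-averaged MU weight per control point; sums to the meterset."""
    dmu = np.diff(beam.meterset_fractions) * beam.meterset
    w = np.zeros(beam.n_control_points)
    w[:-1] += 0.5 * dmu
    w[1:] += 0.5 * dmu
    return w


class BeamFeatures:
    """Lazy cache of everything the metric plugins need for one beam."""

    def __init__(self, beam: Beam, config: MetricConfig = DEFAULT_CONFIG):
        self.beam = beam
        self.config = config

    @cached_property
    def apertures(self) -> list[ApertureShape]:
        return [aperture_from_cp(cp, self.beam.leaf_boundaries)
                for cp in self.beam.control_points]

    @cached_property
    def cp_weights(self) -> np.ndarray:
        return cp_mu_weights(self.beam)

    @cached_property
    def areas(self) -> np.ndarray:
        return np.array([a.area for a in self.apertures])

    @cached_property
    def perimeters(self) -> np.ndarray:
        return np.array([a.perimeter for a in self.apertures])

    @cached_property
    def kin(self) -> LeafKinematics:
        return derive_kinematics(self.beam)

    @cached_property
    def ksum(self) -> dict:
        return kinematic_summaries(self.kin, self.config.moving_tol_cm_s,
                                   self.config.max_speed_cm_s)

    @cached_property
    def raster_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """(eam_cp, cam_cp) arrays from the rasterized apertures.

        The raster window is cropped to the open-aperture bounding box plus
        two pixels: every open cell's nearest background cell (the aperture
        edge, including closed rows and the segment ends) lies inside that
        window, so edge distances are exact while narrow sliding windows
        rasterize cheaply.  Identical control points share one computation.
        """
        cfg = self.config
        px = cfg.raster_px_mm
        eam = np.zeros(len(self.apertures))
        cam = np.zeros(len(self.apertures))
        cache: dict[bytes, tuple[float, float]] = {}
        lb = self.beam.leaf_boundaries
        for j, (ap, cp) in enumerate(zip(self.apertures, self.beam.control_points)):
            if ap.area <= 0:
                continue
            key = ap.open_segments.tobytes() + ap.heights.tobytes()
            if key in cache:
                eam[j], cam[j] = cache[key]
                continue
            open_i = np.nonzero(ap.open_mask)[0]
            seg = ap.open_segments[open_i]
            # snap outward to the pixel lattice so cells are exactly px wide
            x0 = np.floor((float(seg[:, 0].min()) - 2 * px) / px) * px
            x1 = np.ceil((float(seg[:, 1].max()) + 2 * px) / px) * px
            y0 = np.floor((float(lb[open_i.min()]) - 2 * px) / px) * px
            y1 = np.ceil((float(lb[open_i.max() + 1]) + 2 * px) / px) * px
            mask, _ = _rasterize(ap, cp, px, bounds=(x0, x1, y0, y1))
            eam[j], cam[j] = edge_and_cam_from_mask(
                mask, px, cfg.eam_margin_mm, cfg.cam_kappa_mm)
            cache[key] = (eam[j], cam[j])
        return eam, cam

    @cached_property
    def union_area(self) -> float:
        """Area (cm^2) of the union of all control-point apertures."""
        total_mm2 = 0.0
        n_pairs = self.beam.n_leaf_pairs
        for i in range(n_pairs):
            ivals = []
            h = 0.0
            for ap in self.apertures:
                if ap.open_mask[i]:
                    ivals.append(tuple(ap.open_segments[i]))
                    h = max(h, ap.heights[i])
            if not ivals:
                continue
            ivals.sort()
            merged_len = 0.0
            cur_lo, cur_hi = ivals[0]
            for lo, hi in ivals[1:]:
                if lo > cur_hi:
                    merged_len += cur_hi - cur_lo
                    cur_lo, cur_hi = lo, hi
                else:
                    cur_hi = max(cur_hi, hi)
            merged_len += cur_hi - cur_lo
            total_mm2 += merged_len * h
        return total_mm2 / 100.0

    @cached_property
    def lsv_aav(self) -> tuple[np.ndarray, np.ndarray]:
        """Leaf-sequence and aperture-area variability per control point."""
        n_cp = self.beam.n_control_points
        lsv = np.ones(n_cp)
        aav = np.zeros(n_cp)
        # per-pair maximal opening over the beam (jaw-clipped)
        seg = np.stack([a.open_segments for a in self.apertures])  # (cp, pair, 2)
        open_any = np.stack([a.open_mask for a in self.apertures]).any(axis=0)
        w_max = np.zeros(self.beam.n_leaf_pairs)
        heights = np.zeros(self.beam.n_leaf_pairs)
        for i in np.nonzero(open_any)[0]:
            mask_i = np.array([a.open_mask[i] for a in self.apertures])
            lo = seg[mask_i, i, 0].min()
            hi = seg[mask_i, i, 1].max()
            w_max[i] = hi - lo
            heights[i] = max(a.heights[i] for a in self.apertures)
        a_max_mm2 = float(np.sum(w_max * heights))

        for j, ap in enumerate(self.apertures):
            open_i = np.nonzero(ap.open_mask)[0]
            if open_i.size == 0:
                lsv[j] = 1.0
                aav[j] = 0.0
                continue
            factors = []
            for bank in (0, 1):  # 0: low edge (bank B), 1: high edge (bank A)
                pos = ap.open_segments[open_i, bank]
                if pos.size < 2:
                    factors.append(1.0)
                    continue
                pos_max = pos.max() - pos.min()
                if pos_max <= CLOSED_TOL_MM:
                    factors.append(1.0)
                    continue
                adj = np.abs(np.diff(pos))
                factors.append(float(np.sum(pos_max - adj) / (adj.size * pos_max)))
            lsv[j] = factors[0] * factors[1]
            aav[j] = (ap.area * 100.0) / a_max_mm2 if a_max_mm2 > 0 else 0.0
        return lsv, aav


# ---------------------------------------------------------------------------
# named metric operations


def mcs(obj: Beam | Plan, config: MetricConfig = DEFAULT_CONFIG) -> float:
    """Modulation complexity score: MU-weighted sum of LSV x AAV per CP.

    1 for a completely static open field, decreasing toward 0 with
    increasing leaf-sequence and aperture-area variability.
    """
    if isinstance(obj, Plan):
        vals = np.array([mcs(b, config) for b in obj.beams])
        mus = np.array([b.meterset for b in obj.beams])
        return float(np.sum(vals * mus) / mus.sum())
    feats = BeamFeatures(obj, config)
    lsv, aav = feats.lsv_aav
    if feats.areas.max() <= 0:
        warnings.warn(f"beam {obj.id!r}: zero-area beam, MCS = 0")
        return 0.0
    w = feats.cp_weights
    return float(np.sum(lsv * aav * w) / w.sum())


def _mu_weighted_cp_mean(values: np.ndarray, weights: np.ndarray,
                         valid: np.ndarray | None = None) -> float:
    if valid is not None:
        values, weights = values[valid], weights[valid]
    tot = weights.sum()
    return float(np.sum(values * weights) / tot) if tot > 0 else 0.0


def small_aperture_metrics(obj: Beam | Plan,
                           config: MetricConfig = DEFAULT_CONFIG) -> dict:
    """Small-field aperture scores of a beam or plan (MU-weighted over CPs).

    Returns ``sas_<x>`` (fraction of open leaf pairs with gap < x mm) for each
    configured threshold, ``mfa`` (mean field area, cm^2), ``eam`` (edge-region
    area fraction within the penumbra margin) and ``cam`` (fallback
    converted-aperture metric: mean over open aperture points of
    ``exp(-d/kappa)``, d = distance to the nearest aperture edge).
    Zero-area control points are excluded from the MU weighting with
    renormalization.
    """
    if isinstance(obj, Plan):
        per_beam = [small_aperture_metrics(b, config) for b in obj.beams]
        mus = np.array([b.meterset for b in obj.beams])
        return {k: float(np.sum([d[k] for d in per_beam] * mus) / mus.sum())
                for k in per_beam[0]}
    feats = BeamFeatures(obj, config)
    w = feats.cp_weights
    valid = feats.areas > 0
    out = {}
    gaps_frac = {x: np.zeros(len(feats.apertures)) for x in config.sas_thresholds_mm}
    for j, ap in enumerate(feats.apertures):
        if not valid[j]:
            continue
        open_gaps = ap.widths[ap.open_mask]
        for x in config.sas_thresholds_mm:
            gaps_frac[x][j] = float((open_gaps < x).mean())
    for x in config.sas_thresholds_mm:
        out[f"sas_{x:g}"] = _mu_weighted_cp_mean(gaps_frac[x], w, valid)
    out["mfa"] = _mu_weighted_cp_mean(feats.areas, w, valid)
    eam_cp, cam_cp = feats.raster_stats
    out["eam"] = _mu_weighted_cp_mean(eam_cp, w, valid)
    out["cam"] = _mu_weighted_cp_mean(cam_cp, w, valid)
    return out


def mu_metrics(plan: Plan, config: MetricConfig = DEFAULT_CONFIG) -> dict:
    """MU-family metrics: total MU, MU/Gy, beam irregularity, plan modulation.

    Beam irregularity is the MU-weighted mean over control points of
    ``perimeter^2 / (4 pi area)`` (1 for a disc); plan modulation is
    ``1 - sum_cp MU_cp A_cp / (MU_beam * A_union)`` per beam, both MU-weighted
    to plan level.
    """
    mus = np.array([b.meterset for b in plan.beams])
    irr = np.zeros(len(plan.beams))
    pmod = np.zeros(len(plan.beams))
    for bi, beam in enumerate(plan.beams):
        feats = BeamFeatures(beam, config)
        w = feats.cp_weights
        valid = feats.areas > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            cp_irr = np.where(valid, feats.perimeters ** 2
                              / (4.0 * np.pi * np.maximum(feats.areas, 1e-300)), 0.0)
        irr[bi] = _mu_weighted_cp_mean(cp_irr, w, valid)
        au = feats.union_area
        if au > 0:
            pmod[bi] = 1.0 - float(np.sum(w * feats.areas) / (w.sum() * au))
    total_mu = float(mus.sum())
    return {
        "mu_total": total_mu,
        "mu_per_gy": total_mu / plan.prescribed_dose,
        "beam_irregularity": float(np.sum(irr * mus) / total_mu),
        "plan_modulation": float(np.sum(pmod * mus) / total_mu),
    }


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class MetricDef:
    """One registered plan-complexity metric."""

    name: str
    category: str                      # fluence/aperture | MU | dynamics
    orientation: int                   # +1 larger=more complex, -1 opposite, 0 n/a
    fn: Callable[["PlanFeatures"], float]
    fallback: bool = False
    description: str = ""


@dataclass(frozen=True)
class PCMVector:
    """The evaluated metric vector of one plan."""

    plan_id: str
    values: dict[str, float]
    categories: dict[str, str]
    unavailable: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


class PlanFeatures:
    """Per-plan cache shared by the registry plugins."""

    def __init__(self, plan: Plan, config: MetricConfig = DEFAULT_CONFIG):
        self.plan = plan
        self.config = config
        self.beams = [BeamFeatures(b, config) for b in plan.beams]
        self.beam_mu = np.array([b.meterset for b in plan.beams])

    def mu_weighted(self, per_beam: Callable[[BeamFeatures], float]) -> float:
        vals = np.array([per_beam(bf) for bf in self.beams])
        return float(np.sum(vals * self.beam_mu) / self.beam_mu.sum())

    def summed(self, per_beam: Callable[[BeamFeatures], float]) -> float:
        return float(sum(per_beam(bf) for bf in self.beams))

    @cached_property
    def sam(self) -> dict:
        return small_aperture_metrics(self.plan, self.config)

    @cached_property
    def mum(self) -> dict:
        return mu_metrics(self.plan, self.config)

    @cached_property
    def mcs_value(self) -> float:
        return mcs(self.plan, self.config)

    def pooled_cp(self, fn: Callable[[BeamFeatures, int], float],
                  require_open: bool = True) -> float:
        """MU-weighted mean of a per-CP quantity pooled across beams."""
        num = den = 0.0
        for bf in self.beams:
            w = bf.cp_weights
            for j in range(len(bf.apertures)):
                if require_open and bf.areas[j] <= 0:
                    continue
                num += w[j] * fn(bf, j)
                den += w[j]
        return num / den if den > 0 else 0.0


def _gap_pool(pf: PlanFeatures) -> tuple[np.ndarray, np.ndarray]:
    """(gaps_mm, weights) over all open leaf pairs of all CPs of all beams."""
    gaps, wts = [], []
    for bf in pf.beams:
        w = bf.cp_weights
        for j, ap in enumerate(bf.apertures):
            g = ap.widths[ap.open_mask]
            if g.size:
                gaps.append(g)
                wts.append(np.full(g.size, w[j] / g.size))
    if not gaps:
        return np.empty(0), np.empty(0)
    return np.concatenate(gaps), np.concatenate(wts)


def _weighted_quantile(values, weights, q):
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cdf = np.cumsum(w) / w.sum()
    return float(np.interp(q, cdf, v))


def _speed_pool(pf: PlanFeatures) -> np.ndarray:
    pools = [bf.kin.speeds[bf.kin.speeds > pf.config.moving_tol_cm_s]
             for bf in pf.beams]
    pools = [p for p in pools if p.size]
    return np.concatenate(pools) if pools else np.empty(0)


def _accel_pool(pf: PlanFeatures) -> np.ndarray:
    pools = []
    for bf in pf.beams:
        k = bf.kin
        if k.accelerations.shape[1] == 0:
            continue
        moving = k.speeds > pf.config.moving_tol_cm_s
        mov_a = moving[:, :-1] | moving[:, 1:]
        if mov_a.any():
            pools.append(np.abs(k.accelerations[mov_a]))
    return np.concatenate(pools) if pools else np.empty(0)


def _mi(pf: PlanFeatures, which: str, weight_c: float, f_max: float) -> float:
    cfg = pf.config
    grid = np.linspace(0.0, f_max, cfg.f_nodes)
    fn = mi_speed if which == "s" else mi_accel
    return pf.mu_weighted(
        lambda bf: fn(bf.kin, grid, weight_c, cfg.moving_tol_cm_s))


def _area_std(pf: PlanFeatures) -> float:
    m = pf.pooled_cp(lambda bf, j: bf.areas[j])
    var = pf.pooled_cp(lambda bf, j: (bf.areas[j] - m) ** 2)
    return float(np.sqrt(var))


def default_registry(config: MetricConfig = DEFAULT_CONFIG) -> "MetricRegistry":
    """The 53-slot default metric registry."""
    r = MetricRegistry(config)
    A, M, D = "fluence/aperture", "MU", "dynamics"
    add = r.add

    # --- fluence / aperture (24) -------------------------------------------
    add("mcs", A, -1, lambda pf: pf.mcs_value,
        desc="modulation complexity score (LSV x AAV, MU-weighted)")
    add("lsv", A, 0, lambda pf: pf.mu_weighted(
        lambda bf: _mu_weighted_cp_mean(bf.lsv_aav[0], bf.cp_weights)),
        desc="leaf sequence variability")
    add("aav", A, -1, lambda pf: pf.mu_weighted(
        lambda bf: _mu_weighted_cp_mean(bf.lsv_aav[1], bf.cp_weights)),
        desc="aperture area variability")
    add("mfa", A, -1, lambda pf: pf.sam["mfa"], desc="mean field area (cm^2)")
    add("area_cp_std", A, +1, _area_std,
        desc="MU-weighted std of control-point aperture areas (cm^2)")
    add("area_cp_min", A, -1, lambda pf: min(
        float(bf.areas[bf.areas > 0].min()) if (bf.areas > 0).any() else 0.0
        for bf in pf.beams), desc="smallest open control-point area (cm^2)")
    add("union_area", A, 0, lambda pf: pf.mu_weighted(lambda bf: bf.union_area),
        desc="beam union aperture area (cm^2, MU-weighted over beams)")
    add("perimeter_mean", A, 0, lambda pf: pf.pooled_cp(
        lambda bf, j: bf.perimeters[j]), desc="mean aperture perimeter (cm)")
    add("beam_irregularity", A, +1, lambda pf: pf.mum["beam_irregularity"],
        desc="perimeter^2/(4 pi area), MU-weighted")
    add("plan_modulation", A, +1, lambda pf: pf.mum["plan_modulation"],
        desc="1 - MU-weighted aperture area over union area")
    add("eam", A, +1, lambda pf: pf.sam["eam"],
        desc="edge area metric: open-area fraction within the penumbra margin")
    add("cam", A, +1, lambda pf: pf.sam["cam"], fallback=True,
        desc="converted aperture metric (fallback: mean exp(-d/kappa) over "
             "open aperture points)")
    add("mad", A, +1, _mad, fallback=True,
        desc="mean aperture displacement (fallback: MU-weighted mean "
             "|pair midpoint - aperture centroid|, cm)")
    for x in config.sas_thresholds_mm:
        add(f"sas_{x:g}", A, +1, (lambda key: lambda pf: pf.sam[key])(f"sas_{x:g}"),
            desc=f"small aperture score: open-pair fraction with gap < {x:g} mm")
    add("gap_mean", A, -1, lambda pf: _gap_stat(pf, "mean"),
        desc="MU-weighted mean open leaf-pair gap (mm)")
    add("gap_std", A, +1, lambda pf: _gap_stat(pf, "std"),
        desc="MU-weighted std of open leaf-pair gaps (mm)")
    add("gap_p10", A, -1, lambda pf: _gap_stat(pf, "p10"),
        desc="10th percentile open gap (mm, MU-weighted)")
    add("esf_mean", A, -1, lambda pf: pf.pooled_cp(
        lambda bf, j: 4.0 * bf.areas[j] / bf.perimeters[j]
        if bf.perimeters[j] > 0 else 0.0),
        desc="Sterling equivalent-square field side 4A/P (cm)")
    add("small_field_mu_fraction", A, +1, _small_field_mu_fraction,
        desc=f"MU fraction delivered with aperture < {config.small_field_cm2:g} cm^2")
    add("open_pairs_mean", A, 0, lambda pf: pf.pooled_cp(
        lambda bf, j: float(bf.apertures[j].open_mask.sum())),
        desc="mean number of open leaf pairs")
    add("x_extent_mean", A, -1, lambda pf: pf.pooled_cp(_x_extent),
        desc="mean aperture x extent (cm)")

    # --- MU (8) -------------------------------------------------------------
    add("mu_total", M, +1, lambda pf: pf.mum["mu_total"], desc="total plan MU")
    add("mu_per_gy", M, +1, lambda pf: pf.mum["mu_per_gy"],
        desc="MU per prescribed Gy")
    add("mu_per_cp", M, +1, lambda pf: pf.plan.total_mu
        / sum(b.n_control_points for b in pf.plan.beams),
        desc="mean MU per control point")
    add("mu_per_beam_mean", M, +1, lambda pf: float(pf.beam_mu.mean()),
        desc="mean beam meterset (MU)")
    add("mu_per_beam_std", M, 0, lambda pf: float(pf.beam_mu.std()),
        desc="std of beam metersets (MU)")
    add("n_beams", M, 0, lambda pf: float(len(pf.plan.beams)),
        desc="number of treatment beams")
    add("n_cp_total", M, 0, lambda pf: float(
        sum(b.n_control_points for b in pf.plan.beams)),
        desc="total number of control points")
    add("beam_on_time_s", M, +1, lambda pf: pf.summed(
        lambda bf: bf.beam.meterset / bf.beam.dose_rate * 60.0),
        desc="total beam-on time at the planned dose rate (s)")

    # --- dynamics (21) -------------------------------------------------------
    add("mi_s", D, +1, lambda pf: _mi(pf, "s", config.weight_c, config.f_max),
        desc="modulation index for MLC speed (weighted)")
    add("mi_a", D, +1, lambda pf: _mi(pf, "a", config.weight_c, config.f_max),
        desc="modulation index for MLC acceleration (weighted)")
    add("mi_s_unweighted", D, +1, lambda pf: _mi(pf, "s", 0.0, config.f_max),
        desc="unweighted MI_s")
    add("mi_a_unweighted", D, 0, lambda pf: _mi(pf, "a", 0.0, config.f_max),
        desc="unweighted MI_a")
    add("mi_s_f2", D, +1, lambda pf: _mi(pf, "s", config.weight_c, 2.0),
        desc="MI_s integrated over f in [0, 2]")
    add("mi_a_f2", D, +1, lambda pf: _mi(pf, "a", config.weight_c, 2.0),
        desc="MI_a integrated over f in [0, 2]")
    add("lt_mean", D, +1, lambda pf: pf.mu_weighted(
        lambda bf: bf.ksum["lt_mean_cm"]),
        desc="leaf travel: mean total travel of moving leaves (cm)")
    add("lt_sum", D, +1, lambda pf: pf.summed(lambda bf: bf.ksum["lt_sum_cm"]),
        desc="leaf travel: summed over leaves and beams (cm)")
    add("lt_per_mu", D, +1, lambda pf: pf.mu_weighted(
        lambda bf: bf.ksum["lt_per_mu"]), desc="leaf travel per MU (cm/MU)")
    add("ls_mean", D, +1, lambda pf: pf.mu_weighted(
        lambda bf: bf.ksum["ls_mean"]), desc="mean moving-leaf speed (cm/s)")
    add("ls_std", D, +1, lambda pf: pf.mu_weighted(
        lambda bf: bf.ksum["ls_std"]), desc="std of moving-leaf speeds (cm/s)")
    add("la_mean", D, +1, lambda pf: float(np.mean(p)) if (p := _accel_pool(pf)).size
        else 0.0, desc="mean |acceleration| of moving leaves (cm/s^2)")
    add("la_std", D, +1, lambda pf: float(np.std(p)) if (p := _accel_pool(pf)).size
        else 0.0, desc="std of |acceleration| (cm/s^2)")
    add("speed_p90", D, +1, lambda pf: float(np.quantile(p, 0.9))
        if (p := _speed_pool(pf)).size else 0.0,
        desc="90th percentile moving-leaf speed (cm/s)")
    add("accel_p90", D, +1, lambda pf: float(np.quantile(p, 0.9))
        if (p := _accel_pool(pf)).size else 0.0,
        desc="90th percentile |acceleration| (cm/s^2)")
    add("speed_max", D, +1, lambda pf: float(p.max())
        if (p := _speed_pool(pf)).size else 0.0,
        desc="maximum observed leaf speed (cm/s)")
    add("frac_at_max_speed", D, 0, lambda pf: pf.mu_weighted(
        lambda bf: bf.ksum["frac_at_max_speed"]),
        desc="fraction of moving leaf-intervals at/above the speed ceiling")
    add("frac_moving", D, 0, lambda pf: pf.mu_weighted(
        lambda bf: float((bf.kin.speeds > config.moving_tol_cm_s).mean())),
        desc="fraction of leaf-intervals in motion")
    add("ltmcs", D, -1, lambda pf: pf.mcs_value * max(
        0.0, 1.0 - pf.mu_weighted(lambda bf: bf.ksum["lt_mean_cm"]) * 10.0 / 1000.0),
        desc="leaf-travel-modified MCS")
    add("speed_cv", D, +1, lambda pf: (
        lambda p: float(p.std() / p.mean()) if p.size and p.mean() > 0 else 0.0
    )(_speed_pool(pf)), desc="coefficient of variation of moving-leaf speeds")
    add("speed_change_mean", D, +1, _mean_speed_change,
        desc="mean |speed change| between adjacent intervals (cm/s)")

    assert len(r) == 53, f"registry has {len(r)} metrics, expected 53"
    return r


def _mad(pf: PlanFeatures) -> float:
    def per_cp(bf: BeamFeatures, j: int) -> float:
        ap = bf.apertures[j]
        open_i = ap.open_mask
        if not open_i.any():
            return 0.0
        mids = ap.open_segments[open_i].mean(axis=1)
        areas = ap.widths[open_i] * ap.heights[open_i]
        centroid = float(np.sum(mids * areas) / areas.sum())
        return float(np.abs(mids - centroid).mean()) / 10.0  # cm
    return pf.pooled_cp(per_cp)


def _x_extent(bf: BeamFeatures, j: int) -> float:
    ap = bf.apertures[j]
    if not ap.open_mask.any():
        return 0.0
    seg = ap.open_segments[ap.open_mask]
    return float(seg[:, 1].max() - seg[:, 0].min()) / 10.0  # cm


def _gap_stat(pf: PlanFeatures, stat: str) -> float:
    gaps, w = _gap_pool(pf)
    if gaps.size == 0:
        return 0.0
    if stat == "mean":
        return float(np.average(gaps, weights=w))
    if stat == "std":
        m = np.average(gaps, weights=w)
        return float(np.sqrt(np.average((gaps - m) ** 2, weights=w)))
    if stat == "p10":
        return _weighted_quantile(gaps, w, 0.10)
    raise ValueError(stat)


def _small_field_mu_fraction(pf: PlanFeatures) -> float:
    thr = pf.config.small_field_cm2
    num = den = 0.0
    for bf in pf.beams:
        w = bf.cp_weights
        num += float(np.sum(w[bf.areas < thr]))
        den += float(w.sum())
    return num / den if den > 0 else 0.0


def _mean_speed_change(pf: PlanFeatures) -> float:
    pools = []
    for bf in pf.beams:
        v, _ = _speed_variations(bf.kin, pf.config.moving_tol_cm_s)
        if v.size:
            pools.append(v)
    return float(np.concatenate(pools).mean()) if pools else 0.0


class MetricRegistry:
    """Named plugin registry mapping metric name -> plan-level evaluator."""

    def __init__(self, config: MetricConfig = DEFAULT_CONFIG):
        self.config = config
        self._defs: dict[str, MetricDef] = {}

    def add(self, name: str, category: str, orientation: int,
            fn: Callable[[PlanFeatures], float], fallback: bool = False,
            desc: str = "") -> None:
        if name in self._defs:
            raise ValueError(f"duplicate metric {name!r}")
        self._defs[name] = MetricDef(name, category, orientation, fn,
                                     fallback, desc)

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self):
        return iter(self._defs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    @property
    def names(self) -> list[str]:
        return list(self._defs)

    def get(self, name: str) -> MetricDef:
        return self._defs[name]

    def orientation(self, name: str) -> int:
        return self._defs[name].orientation

    def by_category(self, category: str) -> list[str]:
        return [d.name for d in self._defs.values() if d.category == category]


def compute_pcm_vector(plan: Plan, registry: MetricRegistry | None = None,
                       config: MetricConfig | None = None) -> PCMVector:
    """Evaluate every registered metric on one plan.

    Deterministic given (plan, config).  A metric that raises is recorded as
    unavailable with the error message instead of aborting the vector.
    """
    if registry is None:
        registry = default_registry(config or DEFAULT_CONFIG)
    pf = PlanFeatures(plan, registry.config)
    values: dict[str, float] = {}
    categories: dict[str, str] = {}
    unavailable: dict[str, str] = {}
    for mdef in registry:
        categories[mdef.name] = mdef.category
        try:
            values[mdef.name] = float(mdef.fn(pf))
        except Exception as exc:  # noqa: BLE001 - per-metric isolation
            unavailable[mdef.name] = f"{type(exc).__name__}: {exc}"
            values[mdef.name] = float("nan")
    return PCMVector(plan_id=plan.id, values=values, categories=categories,
                     unavailable=unavailable)
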