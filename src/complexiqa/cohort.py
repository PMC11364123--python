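"""Synthetic sliding-window IMRT QA cohort with a controllable complexity dial.

This module generates the full synthetic study the statistics stage analyses:

* site-stratified SW-IMRT plans whose single complexity dial ``m`` in [0, 1]
  maps to (mean leaf gap, gap variance, leaf stagger, meterset) — at ``m=0``
  the aperture is a near-static open field, at ``m=1`` a narrow erratic
  window sweeping the field;
* a deterministic "planned" dose per plan (fluence accumulation + Gaussian
  penumbra + mild depth attenuation; the beam axis is y, so the fluence
  plane (x, z) contains the detector-cylinder axis);
* a calculation-QA surrogate dose whose algorithmic mismatch (extra blur +
  output offset) grows with the plan's small-aperture content (SAS_5); and
* a measurement-QA surrogate reading set whose delivery jitter grows with
  leaf speed, plus i.i.d. detector noise.

The two error channels are deliberately orthogonal — aperture-driven for
calculation QA, speed-driven for measurement QA — so a weak calculation vs
measurement GPR correlation and the expected sign structure of the
complexity-GPR correlations are built into the cohort by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import ndimage

from .rtplan_io import Beam, ControlPoint, Plan, PlanValidationError
from .metrics import MetricConfig, DEFAULT_CONFIG, small_aperture_metrics
from .gamma import (
    DoseGrid,
    DetectorLayout,
    build_layout,
    sample_dose,
    gamma_analysis_multi,
    criterion_label,
    STANDARD_CRITERIA,
)

# Millennium-style 120-leaf MLC: 60 pairs, 10 outer 10 mm + 40 central 5 mm
# + 10 outer 10 mm, spanning -200..200 mm along the leaf-stacking axis.
MLC120_BOUNDARIES = np.concatenate([
    -200.0 + 10.0 * np.arange(10),
    -100.0 + 5.0 * np.arange(41),
    110.0 + 10.0 * np.arange(10),
])

SITE_PROFILES = {
    # site: (beam count range, field width x (mm) range, field height y (mm) range)
    "head_and_neck": ((7, 9), (90.0, 140.0), (90.0, 160.0)),
    "chest_and_abdomen": ((5, 7), (100.0, 160.0), (100.0, 180.0)),
    "pelvis": ((5, 7), (100.0, 160.0), (100.0, 180.0)),
    "limbs": ((2, 4), (60.0, 120.0), (60.0, 120.0)),
}

LINAC1_SYSTEMS = ("cqa_mc_helical", "cqa_mc_cross", "mqa_helical", "mqa_cross")
LINAC2_SYSTEMS = ("cqa_ccc_oblique", "mqa_oblique")
CQA_SYSTEMS = ("cqa_mc_helical", "cqa_mc_cross", "cqa_ccc_oblique")
MQA_SYSTEMS = ("mqa_helical", "mqa_cross", "mqa_oblique")


@dataclass(frozen=True)
class NoiseConfig:
    """Error-channel coefficients of the two QA surrogates.

    mlc_jitter_cm_per_speed:
        Random leaf-position jitter sigma (cm) per unit leaf speed (cm/s)
        in the measurement channel.
    systematic_offset_mm:
        Systematic per-bank leaf offset (mm, widens every gap) in the
        measurement channel.
    detector_noise_percent:
        i.i.d. relative detector noise (percent of reading).
    calc_blur_mm_per_small_aperture:
        Extra Gaussian blur sigma (mm) per unit SAS_5 in the calculation
        channel.
    calc_offset_per_small_aperture:
        Relative output offset per unit SAS_5 in the calculation channel.
    delivery_quality_sigma:
        Lognormal sigma of a per-plan delivery-quality factor scaling the
        MLC jitter — deliveries of equally complex plans differ in daily
        machine condition, which decorrelates the measurement channel from
        the (deterministic) calculation channel.
    ccc_dlg_mismatch_per_mm:
        Relative dose-output mismatch of the collapsed-cone surrogate per mm
        of |typical leaf gap - reference gap| (capped at 20 mm): a beam
        model tuned with a single leaf-gap correction misrenders plans whose
        gap content sits far from the calibration point (capped at
        ``ccc_dlg_cap_mm``).  Non-monotone in plan complexity by
        construction.
    """

    mlc_jitter_cm_per_speed: float = 0.06
    systematic_offset_mm: float = 0.2
    detector_noise_percent: float = 0.4
    calc_blur_mm_per_small_aperture: float = 8.0
    calc_offset_per_small_aperture: float = 0.05
    delivery_quality_sigma: float = 1.3
    ccc_dlg_mismatch_per_mm: float = 0.0005
    ccc_dlg_reference_gap_mm: float = 10.0
    ccc_dlg_cap_mm: float = 20.0

    def __post_init__(self):
        for name in ("mlc_jitter_cm_per_speed", "systematic_offset_mm",
                     "detector_noise_percent", "calc_blur_mm_per_small_aperture",
                     "calc_offset_per_small_aperture", "delivery_quality_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise coefficient {name} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of one synthetic cohort.

    ``n_per_site_linac1`` plans are verified by four QA systems (two
    calculation surrogates on the helical/cross phantom layouts plus the two
    corresponding measurement surrogates); ``n_per_site_linac2`` plans by two
    (oblique-cross calculation + measurement), all at the four standard
    criteria.  The same seed reproduces the cohort bitwise.
    """

    n_per_site_linac1: dict = field(default_factory=lambda: dict(
        head_and_neck=23, chest_and_abdomen=16, pelvis=32, limbs=4))
    n_per_site_linac2: dict = field(default_factory=lambda: dict(
        head_and_neck=61, chest_and_abdomen=32, pelvis=29, limbs=3))
    complexity_dial_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 2024
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    dose_rate: float = 400.0           # MU/min
    grid_spacing_mm: float = 2.5
    grid_half_extent_mm: float = 112.5
    n_cp: int = 60
    max_leaf_speed_cm_s: float = 2.5
    detector_subsample: int = 5        # scaled-down layouts for cohort runs
    gamma_step_fraction: float = 5.0   # candidate step = min(DTA)/this
    gamma_radius_factor: float = 1.5   # per-criterion search radius factor
    criteria: tuple = STANDARD_CRITERIA

    def __post_init__(self):
        for d in (self.n_per_site_linac1, self.n_per_site_linac2):
            for site, n in d.items():
                if site not in SITE_PROFILES or n < 0:
                    raise ValueError(f"bad site count {site}={n}")
        lo, hi = self.complexity_dial_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("complexity_dial_range must be within [0, 1]")

    @classmethod
    def study_counts(cls, **kw) -> "CohortConfig":
        """The clinical study's cohort structure: 152 + 252 = 404 plans."""
        return cls(
            n_per_site_linac1=dict(head_and_neck=46, chest_and_abdomen=32,
                                   pelvis=65, limbs=9),
            n_per_site_linac2=dict(head_and_neck=122, chest_and_abdomen=64,
                                   pelvis=59, limbs=7),
            **kw,
        )

    @property
    def n_plans(self) -> int:
        return sum(self.n_per_site_linac1.values()) + \
            sum(self.n_per_site_linac2.values())


# ---------------------------------------------------------------------------
# plan generation


def _smooth_noise(rng: np.random.Generator, shape, corr_cp: float) -> np.ndarray:
    """Zero-mean unit-variance noise, smoothed along the last axis.

    The series is generated with padding and cropped after filtering so the
    boundary samples have the same variance as the interior (edge-replicating
    filter modes would otherwise inflate them).
    """
    if np.isscalar(shape):
        shape = (shape,)
    pad = int(np.ceil(4 * corr_cp))
    raw = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    sm = ndimage.gaussian_filter1d(raw, sigma=corr_cp, axis=-1, mode="nearest")
    sm = sm[..., pad:pad + shape[-1]]
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _generate_beam(beam_id: str, site: str, m: float, rng: np.random.Generator,
                   fx: float, fy: float, beam_mu: float, n_cp: int,
                   dose_rate: float, max_speed: float) -> Beam:
    boundaries = MLC120_BOUNDARIES
    n_pairs = boundaries.size - 1
    centers = 0.5 * (boundaries[:-1] + boundaries[1:])
    active = (boundaries[1:] > -fy / 2.0) & (boundaries[:-1] < fy / 2.0)

    jaw_x = (-fx / 2.0 - 5.0, fx / 2.0 + 5.0)
    jaw_y = (-fy / 2.0, fy / 2.0)

    # mean gap interpolates log-linearly from the full field width
    # (near-static open aperture) at m=0 down to a 4 mm window at m=1,
    # so small-aperture content ramps in gradually over the upper dial range
    gap_mean = float(fx ** (1.0 - m) * 4.0 ** m)
    half_sweep = max(0.0, (fx - gap_mean) / 2.0)

    # meterset fractions: mildly uneven increments, rougher with m
    beam_time_s = beam_mu / dose_rate * 60.0
    # correlate the noise over ~2.5 s of delivery time at m=0, shortening to
    # ~1 s at m=1 — complex plans have rougher speed profiles — while staying
    # physical regardless of the control-point sampling density
    tau_s = 2.5 - 1.0 * m
    corr = max(2.0, tau_s / (beam_time_s / (n_cp - 1)))
    incr = np.exp(0.35 * m * _smooth_noise(rng, n_cp - 1, corr))
    cmf = np.concatenate([[0.0], np.cumsum(incr)])
    cmf /= cmf[-1]
    cmf[-1] = 1.0

    # window centre sweeps at constant speed in *time* (linear in meterset)
    base_center = -half_sweep + 2.0 * half_sweep * cmf

    n_active = int(active.sum())
    # multiplicative gap noise, rate-limited to ~12 mm amplitude
    gap_sigma = m * min(0.45, 12.0 / gap_mean)
    gap_noise = _smooth_noise(rng, (n_active, n_cp), corr) * gap_sigma
    stagger = _smooth_noise(rng, (n_active, n_cp), corr) * 6.0 * m

    gaps = gap_mean * np.exp(gap_noise)          # (n_active, n_cp) mm
    center = base_center[None, :] + stagger      # per-leaf window centre

    a = np.full((n_pairs, n_cp), jaw_x[0])
    b = np.full((n_pairs, n_cp), jaw_x[0])
    a_act = np.clip(center + gaps / 2.0, jaw_x[0], jaw_x[1])
    b_act = np.clip(center - gaps / 2.0, jaw_x[0], jaw_x[1])
    b_act = np.minimum(b_act, a_act)
    a[active] = a_act
    b[active] = b_act

    dt = np.diff(cmf) * beam_mu / dose_rate * 60.0
    peak_speed = float(np.max(np.abs(np.diff(a, axis=1)) / dt) / 10.0)
    peak_speed = max(peak_speed,
                     float(np.max(np.abs(np.diff(b, axis=1)) / dt) / 10.0))
    if peak_speed > max_speed:
        raise _SpeedCapExceeded(peak_speed)

    cps = tuple(
        ControlPoint(
            index=k,
            cumulative_meterset_fraction=float(cmf[k]),
            bank_a_positions=a[:, k].copy(),
            bank_b_positions=b[:, k].copy(),
            jaw_x=jaw_x,
            jaw_y=jaw_y,
        )
        for k in range(n_cp)
    )
    return Beam(id=beam_id, meterset=beam_mu, dose_rate=dose_rate,
                control_points=cps, leaf_boundaries=boundaries)


class _SpeedCapExceeded(RuntimeError):
    pass


def generate_plan(site: str, m: float, seed: int | np.random.Generator,
                  plan_id: str | None = None, n_cp: int = 60,
                  dose_rate: float = 400.0, prescribed_dose: float = 2.0,
                  max_speed: float = 2.5) -> Plan:
    """Generate one site-typical sliding-window plan at complexity ``m``.

    Both banks sweep unidirectionally left to right; the per-leaf gap process
    narrows in mean and gains variance (and inter-leaf stagger) as ``m``
    grows.  If a trajectory exceeds the physical leaf-speed cap it is
    regenerated with 50% more control points, up to five attempts.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"complexity dial m={m} outside [0, 1]")
    if site not in SITE_PROFILES:
        raise PlanValidationError(f"unknown site {site!r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    (b_lo, b_hi), (fx_lo, fx_hi), (fy_lo, fy_hi) = SITE_PROFILES[site]
    n_beams = int(rng.integers(b_lo, b_hi + 1))
    fx = float(rng.uniform(fx_lo, fx_hi))
    fy = float(rng.uniform(fy_lo, fy_hi))
    # MU grows with modulation at fixed prescription
    mu_per_gy = 250.0 * (1.0 + 0.8 * m) * float(np.exp(rng.normal(0, 0.05)))
    total_mu = prescribed_dose * mu_per_gy
    beam_mu = total_mu / n_beams + rng.uniform(-8.0, 8.0, n_beams)
    beam_mu = np.clip(beam_mu, 10.0, None)

    beams = []
    for bi in range(n_beams):
        cps = n_cp
        for attempt in range(5):
            try:
                beams.append(_generate_beam(
                    f"B{bi + 1}", site, m, rng, fx, fy, float(beam_mu[bi]),
                    cps, dose_rate, max_speed))
                break
            except _SpeedCapExceeded as exc:
                cps = int(cps * 1.5)
                last = exc
        else:
            raise PlanValidationError(
                f"beam B{bi + 1}: leaf speed {last.args[0]:.2f} cm/s exceeds "
                f"the {max_speed} cm/s cap after 5 regeneration attempts")
    return Plan(
        id=plan_id or f"{site[:2]}_{m:.3f}",
        site=site,
        prescribed_dose=prescribed_dose,
        beams=tuple(beams),
    )


# ---------------------------------------------------------------------------
# toy dose engine


def default_grid_spec(spacing: float = 2.5, half_extent: float = 112.5):
    """(origin, spacing, shape) of the standard QA-phantom grid."""
    n = int(round(2 * half_extent / spacing)) + 1
    origin = np.array([-half_extent] * 3)
    return origin, np.array([spacing] * 3), (n, n, n)


def toy_dose(plan: Plan, spacing: float = 2.5, half_extent: float = 112.5,
             penumbra_sigma_mm: float = 3.0, mu_att_per_mm: float = 0.002,
             _fluence_override=None) -> DoseGrid:
    """Deterministic planned dose of a plan on a phantom grid.

    Per-interval open-aperture fluence (indicator x interval MU, midpoint
    leaf positions) is accumulated in the (x, z) beam's-eye plane, convolved
    with an isotropic Gaussian penumbra kernel, extruded along the beam axis
    y with mild exponential attenuation, summed over beams and scaled so the
    grid-centre dose equals the prescription.
    """
    origin, sp, shape = default_grid_spec(spacing, half_extent)
    nx, ny, nz = shape
    xs = origin[0] + sp[0] * np.arange(nx)
    zs = origin[2] + sp[2] * np.arange(nz)

    if _fluence_override is not None:
        fluence = _fluence_override
    else:
        fluence = np.zeros((nx, nz))
        for beam in plan.beams:
            fluence += beam_fluence(beam, xs, zs)
    fluence = ndimage.gaussian_filter(fluence, sigma=penumbra_sigma_mm / spacing,
                                      mode="constant")

    ys = origin[1] + sp[1] * np.arange(ny)
    depth = np.exp(-(ys - ys[0]) * mu_att_per_mm)
    dose = fluence[:, None, :] * depth[None, :, None]

    centre = dose[nx // 2, ny // 2, nz // 2]
    ref = centre if centre > 0 else dose.max()
    if ref > 0:
        dose *= plan.prescribed_dose / ref
    return DoseGrid(origin=origin, spacing=sp, values=dose)


def beam_fluence(beam: Beam, xs: np.ndarray, zs: np.ndarray) -> np.ndarray:
    """MU-weighted open-aperture fluence of one beam on the (x, z) lattice.

    Cell coverage is fractional in both directions; interval apertures use
    midpoint leaf positions.
    """
    dx = xs[1] - xs[0]
    dz = zs[1] - zs[0]
    x_lo_edge = xs - dx / 2.0
    z_lo_edge = zs - dz / 2.0
    fl = np.zeros((xs.size, zs.size))
    dmu = np.diff(beam.meterset_fractions) * beam.meterset
    lb = beam.leaf_boundaries
    cps = beam.control_points
    jaw_x = cps[0].jaw_x
    jaw_y = cps[0].jaw_y

    # per-pair row coverage along z (constant over the beam)
    lo_z = np.maximum(lb[:-1], jaw_y[0])
    hi_z = np.minimum(lb[1:], jaw_y[1])
    row_cov = []
    for i in range(lb.size - 1):
        if hi_z[i] <= lo_z[i]:
            row_cov.append(None)
            continue
        cov = np.clip(
            (np.minimum(hi_z[i], z_lo_edge + dz) - np.maximum(lo_z[i], z_lo_edge))
            / dz, 0.0, 1.0)
        row_cov.append(cov)

    for n in range(len(cps) - 1):
        a_mid = 0.5 * (cps[n].bank_a_positions + cps[n + 1].bank_a_positions)
        b_mid = 0.5 * (cps[n].bank_b_positions + cps[n + 1].bank_b_positions)
        lo = np.maximum(b_mid, jaw_x[0])
        hi = np.minimum(a_mid, jaw_x[1])
        for i in np.nonzero(hi - lo > 1e-6)[0]:
            if row_cov[i] is None:
                continue
            col = np.clip(
                (np.minimum(hi[i], x_lo_edge + dx) - np.maximum(lo[i], x_lo_edge))
                / dx, 0.0, 1.0)
            fl += dmu[n] * np.outer(col, row_cov[i])
    return fl


# ---------------------------------------------------------------------------
# QA surrogates


def cqa_surrogate(plan: Plan, planned: DoseGrid, noise: NoiseConfig,
                  sas5: float | None = None, gap_mean_mm: float | None = None,
                  dlg_mismatch: bool = False,
                  metric_config: MetricConfig = DEFAULT_CONFIG) -> DoseGrid:
    """Calculation-QA surrogate: algorithmic mismatch growing with SAS_5.

    The planned dose is blurred in the fluence plane by an extra Gaussian of
    sigma ``calc_blur_mm_per_small_aperture * SAS_5`` and scaled by
    ``1 - calc_offset_per_small_aperture * SAS_5``.  With ``dlg_mismatch``
    (the collapsed-cone surrogate) an additional output offset grows with the
    distance of the plan's MU-weighted mean gap from the model's single
    leaf-gap calibration point.  Deterministic; identical to the planned dose
    for plans without small-aperture content (and, for the collapsed-cone
    variant, with gap content at the calibration point).
    """
    if sas5 is None:
        sas5 = small_aperture_metrics(plan, metric_config)["sas_5"]
    sigma_mm = noise.calc_blur_mm_per_small_aperture * sas5
    values = planned.values
    if sigma_mm > 0:
        sig = sigma_mm / planned.spacing[0]
        values = ndimage.gaussian_filter(values, sigma=(sig, 0.0, sig),
                                         mode="nearest")
    factor = 1.0 - noise.calc_offset_per_small_aperture * sas5
    if dlg_mismatch and noise.ccc_dlg_mismatch_per_mm > 0:
        if gap_mean_mm is None:
            from .metrics import compute_pcm_vector
            gap_mean_mm = compute_pcm_vector(plan).values["gap_mean"]
        dev = min(abs(gap_mean_mm - noise.ccc_dlg_reference_gap_mm),
                  noise.ccc_dlg_cap_mm)
        factor *= 1.0 - noise.ccc_dlg_mismatch_per_mm * dev
    return DoseGrid(planned.origin, planned.spacing, values * factor)


def perturb_delivery(plan: Plan, noise: NoiseConfig,
                     rng: np.random.Generator) -> Plan:
    """The 'as-delivered' plan: speed-proportional leaf positioning errors.

    Each leaf receives a *persistent* positional error for the whole beam
    (sigma proportional to its mean moving speed — fast leaves lag or
    overshoot consistently) plus *white* per-control-point jitter (sigma
    proportional to the instantaneous speed), and every bank is shifted
    outward by half the systematic offset (a gap-widening calibration
    error).  Deterministic given the generator state.
    """
    new_beams = []
    off = noise.systematic_offset_mm / 2.0
    quality = float(np.exp(rng.normal(0.0, noise.delivery_quality_sigma)))
    coeff_mm = noise.mlc_jitter_cm_per_speed * 10.0 * quality  # mm per (cm/s)
    for beam in plan.beams:
        cmf = beam.meterset_fractions
        dt = np.diff(cmf) * beam.meterset / beam.dose_rate * 60.0
        pos_a = np.stack([cp.bank_a_positions for cp in beam.control_points], axis=1)
        pos_b = np.stack([cp.bank_b_positions for cp in beam.control_points], axis=1)
        n_pairs, n_cp = pos_a.shape
        # cm/s speed per (leaf, interval) and per-leaf mean moving speed
        spd_a = np.abs(np.diff(pos_a, axis=1)) / dt[None, :] / 10.0
        spd_b = np.abs(np.diff(pos_b, axis=1)) / dt[None, :] / 10.0
        mean_a = spd_a.mean(axis=1)
        mean_b = spd_b.mean(axis=1)
        persist_a = rng.normal(0.0, 1.0, n_pairs) * coeff_mm * mean_a
        persist_b = rng.normal(0.0, 1.0, n_pairs) * coeff_mm * mean_b
        # instantaneous speed per CP: mean of adjacent intervals
        inst_a = np.zeros((n_pairs, n_cp))
        inst_b = np.zeros((n_pairs, n_cp))
        inst_a[:, :-1] += spd_a
        inst_a[:, 1:] += spd_a
        inst_a[:, 1:-1] /= 2.0
        inst_b[:, :-1] += spd_b
        inst_b[:, 1:] += spd_b
        inst_b[:, 1:-1] /= 2.0
        white_a = rng.normal(0.0, 1.0, (n_pairs, n_cp)) * coeff_mm * inst_a
        white_b = rng.normal(0.0, 1.0, (n_pairs, n_cp)) * coeff_mm * inst_b
        a = pos_a + off + persist_a[:, None] + white_a
        b = pos_b - off + persist_b[:, None] + white_b
        b = np.minimum(b, a)
        new_cps = tuple(
            ControlPoint(
                index=cp.index,
                cumulative_meterset_fraction=cp.cumulative_meterset_fraction,
                bank_a_positions=a[:, k], bank_b_positions=b[:, k],
                jaw_x=cp.jaw_x, jaw_y=cp.jaw_y)
            for k, cp in enumerate(beam.control_points))
        new_beams.append(Beam(id=beam.id, meterset=beam.meterset,
                              dose_rate=beam.dose_rate,
                              control_points=new_cps,
                              leaf_boundaries=beam.leaf_boundaries))
    return Plan(id=plan.id + "_delivered", site=plan.site,
                prescribed_dose=plan.prescribed_dose, beams=tuple(new_beams))


def mqa_surrogate(plan: Plan, planned: DoseGrid, layout: DetectorLayout,
                  noise: NoiseConfig, seed: int | np.random.Generator,
                  delivered_dose: DoseGrid | None = None) -> np.ndarray:
    """Measurement-QA surrogate readings at the detector points.

    Re-renders the dose with speed-proportional leaf jitter plus a
    systematic offset, samples it at the layout and applies i.i.d. relative
    detector noise.  ``delivered_dose`` lets several layouts share one
    perturbed delivery.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if delivered_dose is None:
        delivered_dose = render_delivery(plan, noise, rng,
                                         spacing=planned.spacing[0],
                                         half_extent=-planned.origin[0])
    readings = sample_dose(delivered_dose, layout)
    rel = noise.detector_noise_percent / 100.0
    if rel > 0:
        readings = readings * (1.0 + rng.normal(0.0, rel, readings.size))
    return np.clip(readings, 0.0, None)


def render_delivery(plan: Plan, noise: NoiseConfig, rng: np.random.Generator,
                    spacing: float = 2.5, half_extent: float = 112.5) -> DoseGrid:
    """Toy dose of the perturbed (as-delivered) plan."""
    if (noise.mlc_jitter_cm_per_speed == 0.0
            and noise.systematic_offset_mm == 0.0):
        delivered = plan
    else:
        delivered = perturb_delivery(plan, noise, rng)
    return toy_dose(delivered, spacing=spacing, half_extent=half_extent)


# ---------------------------------------------------------------------------
# study simulation


@dataclass(frozen=True)
class PlanSpec:
    plan_id: str
    site: str
    linac: int
    m: float
    seed: int


def study_roster(cfg: CohortConfig) -> list[PlanSpec]:
    """Deterministic plan roster (id, site, linac, dial, per-plan seed)."""
    ss = np.random.SeedSequence(cfg.seed)
    lo, hi = cfg.complexity_dial_range
    roster = []
    idx = 0
    for linac, counts in ((1, cfg.n_per_site_linac1), (2, cfg.n_per_site_linac2)):
        for site in SITE_PROFILES:
            for k in range(counts.get(site, 0)):
                child = ss.spawn(1)[0]
                rng = np.random.default_rng(child)
                m = float(rng.uniform(lo, hi))
                plan_seed = int(child.generate_state(1, np.uint32)[0] % (2 ** 31))
                roster.append(PlanSpec(
                    plan_id=f"p{idx:04d}_{site[:2]}_l{linac}",
                    site=site, linac=linac, m=m, seed=plan_seed))
                idx += 1
    return roster


def systems_for_linac(linac: int) -> tuple[str, ...]:
    return LINAC1_SYSTEMS if linac == 1 else LINAC2_SYSTEMS


def enumerate_qa_records(roster: Iterable[PlanSpec],
                         criteria=STANDARD_CRITERIA) -> list[dict]:
    """The (plan, system, criterion) bookkeeping grid of the study design."""
    records = []
    for spec in roster:
        for system in systems_for_linac(spec.linac):
            for crit in criteria:
                records.append({"plan_id": spec.plan_id, "system": system,
                                "criterion": criterion_label(crit)})
    return records


def simulate_study(cfg: CohortConfig,
                   metric_config: MetricConfig = DEFAULT_CONFIG,
                   progress: bool = False):
    """Run the full synthetic study.

    Returns ``(plans, table)`` where ``table`` is a
    :class:`~complexiqa.stats.QACohortTable` holding the long-format GPR rows,
    the per-plan PCM vectors and the site/linac metadata.
    """
    from .metrics import compute_pcm_vector, default_registry
    from .stats import QACohortTable
    import pandas as pd

    registry = default_registry(metric_config)
    roster = study_roster(cfg)
    layouts = {
        "helical": build_layout("helical").subsample(cfg.detector_subsample),
        "cross": build_layout("cross").subsample(cfg.detector_subsample),
        "oblique_cross": build_layout("oblique_cross").subsample(cfg.detector_subsample),
    }

    gpr_records = []
    pcm_records = []
    meta_records = []
    plans = []
    for i, spec in enumerate(roster):
        plan = generate_plan(spec.site, spec.m, spec.seed,
                             plan_id=spec.plan_id, n_cp=cfg.n_cp,
                             dose_rate=cfg.dose_rate,
                             max_speed=cfg.max_leaf_speed_cm_s)
        plans.append(plan)
        vec = compute_pcm_vector(plan, registry)
        for name, value in vec.values.items():
            pcm_records.append({"plan_id": spec.plan_id, "metric": name,
                                "value": value})
        meta_records.append({"plan_id": spec.plan_id, "site": spec.site,
                             "linac": spec.linac, "m": spec.m})

        planned = toy_dose(plan, spacing=cfg.grid_spacing_mm,
                           half_extent=cfg.grid_half_extent_mm)
        cqa_grid = cqa_surrogate(plan, planned, cfg.noise,
                                 sas5=vec.values["sas_5"],
                                 gap_mean_mm=vec.values["gap_mean"],
                                 dlg_mismatch=(spec.linac == 2))
        mqa_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 7, spec.seed]))
        delivered = render_delivery(plan, cfg.noise, mqa_rng,
                                    spacing=cfg.grid_spacing_mm,
                                    half_extent=cfg.grid_half_extent_mm)

        if spec.linac == 1:
            pairs = [("cqa_mc_helical", "cqa", layouts["helical"]),
                     ("cqa_mc_cross", "cqa", layouts["cross"]),
                     ("mqa_helical", "mqa", layouts["helical"]),
                     ("mqa_cross", "mqa", layouts["cross"])]
        else:
            pairs = [("cqa_ccc_oblique", "cqa", layouts["oblique_cross"]),
                     ("mqa_oblique", "mqa", layouts["oblique_cross"])]

        for system, mode, layout in pairs:
            if mode == "cqa":
                ref_dose = sample_dose(planned, layout)
                evaluated = cqa_grid
            else:
                ref_dose = mqa_surrogate(plan, planned, layout, cfg.noise,
                                         mqa_rng, delivered_dose=delivered)
                evaluated = planned
            results = gamma_analysis_multi(
                layout.points, ref_dose, evaluated, cfg.criteria,
                search_step_fraction=cfg.gamma_step_fraction,
                search_radius_factor=cfg.gamma_radius_factor)
            for crit, res in results.items():
                gpr_records.append({"plan_id": spec.plan_id, "system": system,
                                    "criterion": crit, "gpr": res.gpr})
        if progress and (i + 1) % 20 == 0:
            print(f"  simulated {i + 1}/{len(roster)} plans")

    from .gamma import gpr_table as _gpr_table
    table = QACohortTable(
        gpr=_gpr_table(gpr_records),
        pcm=pd.DataFrame(pcm_records),
        meta=pd.DataFrame(meta_records),
        registry=registry,
    )
    return plans, table
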