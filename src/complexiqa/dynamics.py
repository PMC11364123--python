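"""Per-leaf kinematics of dynamic MLC delivery.

At a fixed dose rate the cumulative meterset fraction defines the time axis:
interval n lasts ``dt_n = dcmf_n * meterset / dose_rate`` (minutes -> here
converted to seconds).  Leaf speed over an interval is displacement / time;
acceleration is the speed change between consecutive intervals divided by the
centred time step.  These series feed the dynamics family of complexity
metrics (modulation indices for speed and acceleration, leaf travel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rtplan_io import Beam, PlanValidationError

#: cm/s below which a leaf-interval counts as stationary.
MOVING_SPEED_TOL = 1e-4

#: Physical leaf-speed ceiling used for the "at maximum speed" summary (cm/s).
DEFAULT_MAX_SPEED = 2.5


@dataclass(frozen=True)
class LeafKinematics:
    """Per-leaf time/speed/acceleration series for one beam.

    ``speeds`` has shape (n_leaves, n_intervals) with both banks stacked along
    the leaf axis (bank A first); ``accelerations`` has one fewer column.
    Units: seconds, cm/s, cm/s^2, cm, MU.
    """

    beam_id: str
    times: np.ndarray            # (n_cp,) cumulative seconds, starts at 0
    speeds: np.ndarray           # (2*n_pairs, n_cp-1) cm/s, >= 0
    accelerations: np.ndarray    # (2*n_pairs, n_cp-2) cm/s^2, signed
    travel: np.ndarray           # (2*n_pairs,) cm
    interval_mu: np.ndarray      # (n_cp-1,) MU

    @property
    def n_leaves(self) -> int:
        return self.speeds.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.speeds.shape[1]

    @property
    def dt(self) -> np.ndarray:
        return np.diff(self.times)


def derive_kinematics(beam: Beam) -> LeafKinematics:
    """Convert a beam's control-point track into leaf kinematics.

    Zero-meterset intervals (``dcmf == 0``) are degenerate — they would give
    infinite speed for any leaf motion and an undefined time axis — and are
    rejected rather than merged.
    """
    cmf = beam.meterset_fractions
    dcmf = np.diff(cmf)
    zero = np.nonzero(dcmf <= 0)[0]
    if zero.size:
        raise PlanValidationError(
            f"beam {beam.id!r}: zero-meterset interval at control point "
            f"{int(zero[0])} -> {int(zero[0]) + 1}; degenerate time axis"
        )
    dt = dcmf * beam.meterset / beam.dose_rate * 60.0  # seconds
    times = np.concatenate([[0.0], np.cumsum(dt)])

    pos_a = np.stack([cp.bank_a_positions for cp in beam.control_points], axis=1)
    pos_b = np.stack([cp.bank_b_positions for cp in beam.control_points], axis=1)
    pos = np.vstack([pos_a, pos_b]) / 10.0  # mm -> cm; (2*n_pairs, n_cp)

    disp = np.abs(np.diff(pos, axis=1))      # cm per interval
    speeds = disp / dt[None, :]
    travel = disp.sum(axis=1)

    # centred acceleration over interval midpoints
    mid_dt = 0.5 * (dt[:-1] + dt[1:])
    accel = np.diff(speeds, axis=1) / mid_dt[None, :]

    return LeafKinematics(
        beam_id=beam.id,
        times=times,
        speeds=speeds,
        accelerations=accel,
        travel=travel,
        interval_mu=dcmf * beam.meterset,
    )


def kinematic_summaries(k: LeafKinematics, moving_threshold: float = MOVING_SPEED_TOL,
                        max_speed: float = DEFAULT_MAX_SPEED) -> dict:
    """Scalar summaries of one beam's kinematics.

    Returns a dict with:

    ``ls_mean``, ``ls_std``
        Mean/std (cm/s) over *moving* leaf-intervals, i.e. entries with speed
        above ``moving_threshold``; parked closed leaves do not dilute the
        mean.  An all-static beam gives 0 and ``all_static=True``.
    ``frac_at_max_speed``
        Fraction of moving leaf-intervals at or above ``max_speed``.
    ``lt_mean_cm``, ``lt_sum_cm``
        Leaf travel aggregated over leaves that move at least once: the mean
        and the sum of per-leaf total travel.
    ``lt_per_mu``
        ``lt_mean_cm`` divided by the beam meterset (cm/MU).
    """
    mu = float(k.interval_mu.sum())
    moving = k.speeds > moving_threshold
    any_moving = bool(moving.any())
    if any_moving:
        sel = k.speeds[moving]
        ls_mean = float(sel.mean())
        ls_std = float(sel.std())
        frac_max = float((sel >= max_speed).mean())
    else:
        ls_mean = ls_std = frac_max = 0.0

    leaf_moves = moving.any(axis=1)
    if leaf_moves.any():
        trav = k.travel[leaf_moves]
        lt_mean = float(trav.mean())
        lt_sum = float(trav.sum())
    else:
        lt_mean = lt_sum = 0.0

    return {
        "ls_mean": ls_mean,
        "ls_std": ls_std,
        "frac_at_max_speed": frac_max,
        "lt_mean_cm": lt_mean,
        "lt_sum_cm": lt_sum,
        "lt_per_mu": lt_mean / mu if mu > 0 else 0.0,
        "all_static": not any_moving,
        "beam_mu": mu,
    }
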