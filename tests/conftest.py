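"""Shared fixtures and plan builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from complexiqa import (
    Beam,
    ControlPoint,
    Plan,
    CohortConfig,
    simulate_study,
)


def make_cp(index, cmf, bank_a, bank_b, jaw_x=None, jaw_y=None):
    bank_a = np.asarray(bank_a, float)
    bank_b = np.asarray(bank_b, float)
    if jaw_x is None:
        jaw_x = (float(bank_b.min()) - 5.0, float(bank_a.max()) + 5.0)
    if jaw_y is None:
        jaw_y = (-100.0, 100.0)
    return ControlPoint(index=index, cumulative_meterset_fraction=cmf,
                        bank_a_positions=bank_a, bank_b_positions=bank_b,
                        jaw_x=jaw_x, jaw_y=jaw_y)


def make_beam(positions_a, positions_b, cmf=None, meterset=100.0,
              dose_rate=400.0, boundaries=None, jaw_x=None, jaw_y=None,
              beam_id="B1"):
    """Beam from (n_cp, n_pairs) position arrays for the two banks."""
    positions_a = np.atleast_2d(np.asarray(positions_a, float))
    positions_b = np.atleast_2d(np.asarray(positions_b, float))
    n_cp, n_pairs = positions_a.shape
    if cmf is None:
        cmf = np.linspace(0.0, 1.0, n_cp)
    if boundaries is None:
        boundaries = np.linspace(-5.0 * n_pairs, 5.0 * n_pairs, n_pairs + 1)
    cps = [make_cp(j, float(cmf[j]), positions_a[j], positions_b[j],
                   jaw_x=jaw_x, jaw_y=jaw_y)
           for j in range(n_cp)]
    return Beam(id=beam_id, meterset=meterset, dose_rate=dose_rate,
                control_points=tuple(cps), leaf_boundaries=boundaries)


def open_field_beam(n_pairs=10, half_width=25.0, n_cp=2, meterset=100.0,
                    jaw_y=None):
    """Static fully open rectangular field (every CP identical)."""
    a = np.full((n_cp, n_pairs), half_width)
    b = np.full((n_cp, n_pairs), -half_width)
    if jaw_y is None:
        jaw_y = (-2.5 * n_pairs, 2.5 * n_pairs)
    return make_beam(a, b, jaw_x=(-half_width, half_width), jaw_y=jaw_y)


def open_field_plan(n_pairs=10, half_width=25.0, prescribed_dose=2.0):
    return Plan(id="open_field", site="pelvis", prescribed_dose=prescribed_dose,
                beams=(open_field_beam(n_pairs, half_width),))


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded 200-plan synthetic study (shared across tests)."""
    plans, table = simulate_study(CohortConfig())
    return plans, table
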