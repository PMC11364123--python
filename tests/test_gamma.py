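"""Detector geometries, dose sampling and the gamma engine."""

import numpy as np
import pytest

from complexiqa import (
    DoseGrid,
    build_layout,
    gamma_analysis,
    gamma_analysis_multi,
    gpr_table,
    sample_dose,
)
from complexiqa.gamma import (
    DoseSamplingError,
    STANDARD_CRITERIA,
    read_dicom_dose,
)


def make_grid(values, spacing=2.5, origin=None):
    values = np.asarray(values, float)
    if origin is None:
        origin = -spacing * (np.array(values.shape) - 1) / 2.0
    return DoseGrid(origin=np.asarray(origin, float),
                    spacing=np.full(3, spacing), values=values)


class TestLayouts:
    def test_helical_diode_count_and_radius(self):
        lay = build_layout("helical")
        assert lay.n_points == 1386  # 66 per ring x 21 rings
        r = np.hypot(lay.points[:, 0], lay.points[:, 1])
        assert np.allclose(r, 105.0, atol=1e-9)
        assert np.abs(lay.points[:, 2]).max() <= 105.0

    def test_cross_symmetric_under_quarter_turn(self):
        lay = build_layout("cross")
        pts = {tuple(np.round(p, 6)) for p in lay.points}
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        rotated = {tuple(np.round(p, 6)) for p in lay.points @ rot.T}
        assert pts == rotated

    def test_oblique_cross_is_rotated_cross(self):
        cross = build_layout("cross")
        obl = build_layout("oblique_cross")
        c = np.cos(np.pi / 4)
        rot = np.array([[c, -c, 0.0], [c, c, 0.0], [0.0, 0.0, 1.0]])
        expect = {tuple(np.round(p, 6)) for p in cross.points @ rot.T}
        got = {tuple(np.round(p, 6)) for p in obl.points}
        assert got == expect

    def test_cross_pitch_structure(self):
        lay = build_layout("cross")
        in_plane = lay.points[np.abs(lay.points[:, 1]) < 1e-9]
        u = np.unique(np.round(in_plane[:, 0], 6))
        central = u[np.abs(u) <= 30.0 + 1e-9]
        outer = u[np.abs(u) > 30.0 + 1e-9]
        assert np.allclose(np.diff(central), 5.0)
        assert np.all(np.abs(np.diff(outer)[np.abs(np.diff(outer)) < 70]) >= 10.0 - 1e-9)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown detector layout"):
            build_layout("spiral")

    def test_subsample_keeps_geometry(self):
        lay = build_layout("helical").subsample(5)
        r = np.hypot(lay.points[:, 0], lay.points[:, 1])
        assert np.allclose(r, 105.0)
        assert lay.n_points == int(np.ceil(1386 / 5))


class TestSampling:
    def test_uniform_grid(self):
        grid = make_grid(np.full((9, 9, 9), 1.7), spacing=30.0)
        lay = build_layout("helical")
        assert np.allclose(sample_dose(grid, lay), 1.7)

    def test_trilinear_exact_on_linear_field(self):
        n = 11
        ax = np.arange(n) * 25.0 - 125.0
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        grid = DoseGrid(origin=[-125.0] * 3, spacing=[25.0] * 3,
                        values=2.0 + 0.003 * X + 0.001 * Y - 0.002 * Z + 1.0)
        lay = build_layout("cross")
        got = sample_dose(grid, lay)
        p = lay.points
        expect = 3.0 + 0.003 * p[:, 0] + 0.001 * p[:, 1] - 0.002 * p[:, 2]
        assert np.allclose(got, expect, atol=1e-9)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        grid = make_grid(rng.random((6, 7, 8)), spacing=40.0)
        pts = rng.uniform(-80, 80, (25, 3))
        from complexiqa.gamma import DetectorLayout
        lay = DetectorLayout("helical", pts, tuple(f"d{i}" for i in range(25)))
        got = sample_dose(grid, lay)
        for i, p in enumerate(pts):
            f = (p - grid.origin) / grid.spacing
            i0 = np.floor(f).astype(int)
            t = f - i0
            acc = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((t[0] if dx else 1 - t[0])
                             * (t[1] if dy else 1 - t[1])
                             * (t[2] if dz else 1 - t[2]))
                        acc += w * grid.values[min(i0[0] + dx, 5),
                                               min(i0[1] + dy, 6),
                                               min(i0[2] + dz, 7)]
            assert got[i] == pytest.approx(acc, rel=1e-12)

    def test_out_of_bounds_lists_ids(self):
        grid = make_grid(np.ones((5, 5, 5)), spacing=10.0)
        from complexiqa.gamma import DetectorLayout
        lay = DetectorLayout("cross", np.array([[0, 0, 0], [500.0, 0, 0]]),
                             ("ok", "far_away"))
        with pytest.raises(DoseSamplingError, match="far_away"):
            sample_dose(grid, lay)


def brute_force_gamma(ref_pts, ref_dose, grid, dd, dta, d_norm,
                      step=0.1, radius_factor=3.0):
    """Exhaustive dense-search oracle at a 0.1 mm displacement step."""
    from scipy.ndimage import map_coordinates

    n = int(np.floor(radius_factor * dta / step))
    ax = step * np.arange(-n, n + 1)
    DX, DY, DZ = np.meshgrid(ax, ax, ax, indexing="ij")
    off = np.stack([DX.ravel(), DY.ravel(), DZ.ravel()], axis=1)
    dist = np.linalg.norm(off, axis=1)
    keep = dist <= radius_factor * dta + 1e-9
    off, dist = off[keep], dist[keep]
    hi = np.array(grid.shape) - 1
    out = np.empty(len(ref_pts))
    for i, (p, dr) in enumerate(zip(ref_pts, ref_dose)):
        cand = p[None, :] + off
        idx = (cand - grid.origin) / grid.spacing
        inside = np.all((idx >= 0) & (idx <= hi), axis=1)
        dval = map_coordinates(grid.values, idx[inside].T, order=1)
        g2 = (dist[inside] / dta) ** 2 + \
            ((dval - dr) / (dd * d_norm / 100.0)) ** 2
        out[i] = np.sqrt(g2.min())
    return out


class TestGammaEngine:
    def _random_case(self, seed):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        n = 14
        base = 2.0 * np.exp(-((np.arange(n) - n / 2) ** 2) / 40.0)
        vals = np.einsum("i,j,k->ijk", base, base, base) / 4.0
        # multiplicative noise smoothed by the 3 mm penumbra scale (1.2
        # voxels): the roughness of physically realistic dose
        noise = gaussian_filter(rng.standard_normal(vals.shape), 1.2)
        vals = vals * (1.0 + 0.10 * noise)
        grid = make_grid(np.clip(vals, 0, None), spacing=2.5)
        pts = rng.uniform(-8, 8, (12, 3))
        ref = np.clip(
            vals[n // 2, n // 2, n // 2]
            * np.exp(-np.linalg.norm(pts, axis=1) ** 2 / 900.0)
            * (1.0 + 0.03 * rng.standard_normal(12)), 0.01, None)
        return pts, ref, grid

    def test_identical_fields_pass_everywhere(self):
        rng = np.random.default_rng(0)
        grid = make_grid(1.0 + rng.random((12, 12, 12)), spacing=2.5)
        lay_pts = rng.uniform(-10, 10, (40, 3))
        from complexiqa.gamma import DetectorLayout
        lay = DetectorLayout("cross", lay_pts,
                             tuple(f"d{i}" for i in range(40)))
        ref = sample_dose(grid, lay)
        res = gamma_analysis_multi(lay_pts, ref, grid)
        for crit, r in res.items():
            assert r.gpr == 100.0
            assert np.nanmax(r.gamma_values) <= 0.3

    def test_pure_dose_difference_boundary(self):
        # flat evaluated field at (1 + dd%) x reference -> gamma = 1 exactly
        for dd, dta in STANDARD_CRITERIA:
            grid = make_grid(np.full((15, 15, 15), 1.0 * (1 + dd / 100.0)),
                             spacing=2.5)
            pts = np.zeros((1, 3))
            res = gamma_analysis(pts, np.array([1.0]), grid, (dd, dta),
                                 normalization=1.0)
            assert res.gamma_values[0] == pytest.approx(1.0, abs=1e-9)
            assert res.gpr == 100.0

    def test_threshold_excludes_low_dose_points(self):
        grid = make_grid(np.ones((9, 9, 9)), spacing=5.0)
        pts = np.zeros((4, 3))
        pts[:, 0] = [-10, -5, 5, 10]
        dose = np.array([1.0, 0.05, 1.0, 0.04])  # two below 10% of max
        res = gamma_analysis(pts, dose, grid, (3.0, 3.0))
        assert res.n_evaluated == 2
        assert np.isnan(res.gamma_values[1]) and np.isnan(res.gamma_values[3])

    def test_all_below_threshold_raises(self):
        grid = make_grid(np.ones((5, 5, 5)), spacing=5.0)
        with pytest.raises(ValueError, match="no evaluable"):
            gamma_analysis(np.zeros((2, 3)), np.array([0.01, 0.02]), grid,
                           (3.0, 3.0), normalization=1.0)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_brute_force_oracle(self, seed):
        pts, ref, grid = self._random_case(seed)
        d_norm = ref.max()
        for dd, dta in ((3.0, 3.0), (2.0, 2.0)):
            res = gamma_analysis(pts, ref, grid, (dd, dta),
                                 threshold_percent=0.0)
            oracle = brute_force_gamma(pts, ref, grid, dd, dta, d_norm)
            got = res.gamma_values
            cap = 1.5  # both searches truncate far gammas differently
            mask = (oracle < cap) | (got < cap)
            assert np.all(np.abs(got[mask] - oracle[mask]) <= 0.02)

    def test_criterion_ordering_on_random_pairs(self):
        for seed in range(6):
            pts, ref, grid = self._random_case(seed)
            res = gamma_analysis_multi(pts, ref, grid, STANDARD_CRITERIA,
                                       threshold_percent=0.0)
            gprs = [res[c].gpr for c in STANDARD_CRITERIA]
            assert gprs[0] >= gprs[1] >= gprs[2] >= gprs[3]

    def test_global_scale_invariance(self):
        pts, ref, grid = self._random_case(42)
        res1 = gamma_analysis(pts, ref, grid, (2.0, 2.0), threshold_percent=0.0)
        grid2 = DoseGrid(grid.origin, grid.spacing, grid.values * 3.5)
        res2 = gamma_analysis(pts, ref * 3.5, grid2, (2.0, 2.0),
                              threshold_percent=0.0)
        assert np.allclose(res1.gamma_values, res2.gamma_values, atol=1e-9)


class TestGprTable:
    def test_row_counts(self):
        recs = [{"plan_id": "p1", "system": "s", "criterion": c, "gpr": 99.0}
                for c in STANDARD_CRITERIA]
        df = gpr_table(recs)
        assert len(df) == 4
        assert set(df.status) == {"ok"}

    def test_duplicate_key_rejected(self):
        recs = [{"plan_id": "p1", "system": "s", "criterion": "3%/3mm", "gpr": 99.0}] * 2
        with pytest.raises(ValueError, match="duplicate"):
            gpr_table(recs)

    def test_missing_marked_not_dropped(self):
        df = gpr_table([
            {"plan_id": "p1", "system": "s", "criterion": "3%/3mm", "gpr": 98.0},
            {"plan_id": "p2", "system": "s", "criterion": "3%/3mm", "gpr": None},
        ])
        assert len(df) == 2
        assert df.loc[df.plan_id == "p2", "status"].item() == "missing"


class TestDoseIO:
    def test_npz_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        grid = make_grid(rng.random((5, 6, 7)))
        grid.save_npz(tmp_path / "d.npz")
        back = DoseGrid.load_npz(tmp_path / "d.npz")
        assert np.array_equal(back.values, grid.values)
        assert np.array_equal(back.origin, grid.origin)

    def test_dicom_dose_round_trip(self, tmp_path):
        import pydicom
        from pydicom.dataset import Dataset, FileDataset
        from pydicom.uid import generate_uid, ExplicitVRLittleEndian

        rng = np.random.default_rng(2)
        vals = rng.random((4, 5, 6))  # (x, y, z)
        scaling = 1e-3
        pix = np.round(np.transpose(vals, (2, 1, 0)) / scaling).astype(np.uint32)

        meta = Dataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.UID(
            "1.2.840.10008.5.1.4.1.1.481.2")
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset("d", {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Modality = "RTDOSE"
        ds.DoseGridScaling = scaling
        ds.ImagePositionPatient = [-10.0, -20.0, -30.0]
        ds.PixelSpacing = [2.5, 2.5]
        ds.GridFrameOffsetVector = [2.5 * k for k in range(6)]
        ds.Rows, ds.Columns, ds.NumberOfFrames = 5, 4, 6
        ds.BitsAllocated = 32
        ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = pix.tobytes()
        path = tmp_path / "dose.dcm"
        ds.save_as(str(path), enforce_file_format=True)

        grid = read_dicom_dose(path)
        assert grid.shape == (4, 5, 6)
        assert np.allclose(grid.values, np.round(vals / scaling) * scaling)
        assert np.allclose(grid.spacing, 2.5)
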