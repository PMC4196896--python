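"""Hills parsing, bias summation, FES reconstruction, state labeling."""

import numpy as np
import pandas as pd
import pytest

from gpcrswitch import (
    FESGrid,
    GpcrSwitchError,
    HillsLog,
    HillsParseError,
    bias_potential,
    crystal_point,
    evaluate_cvs,
    label_states,
    read_hills,
    reconstruct_fes,
    write_hills,
)
from gpcrswitch.switches import distance_series
from gpcrswitch.synth import component_rng, gen_switch_bundle


def _log_from_rows(rows, gamma=10.0):
    df = pd.DataFrame(
        rows,
        columns=["time_ps", "cv1", "cv2", "sigma1", "sigma2", "height",
                 "biasfactor", "walker"],
    )
    return HillsLog(records=df, gamma=gamma)


def _random_log(rng, n=40, gamma=10.0):
    rows = [
        (
            4.0 * (i + 1),
            rng.uniform(7, 12),
            rng.uniform(7, 12),
            rng.uniform(0.05, 0.3),
            rng.uniform(0.05, 0.3),
            rng.uniform(0.01, 0.1),
            gamma,
            int(rng.integers(0, 6)),
        )
        for i in range(n)
    ]
    return _log_from_rows(rows, gamma)


class TestReadHills:
    def _write_walker_files(self, tmp_path, n_files=6, hills_per_file=3):
        paths = []
        for w in range(n_files):
            p = tmp_path / f"HILLS.{w}"
            with open(p, "w") as fh:
                fh.write("#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf\n")
                for i in range(hills_per_file):
                    t = 4.0 * (i + 1)
                    fh.write(f"{t} {9.0 + 0.1 * w} {10.0} 0.1 0.1 0.1 10.0\n")
            paths.append(p)
        return paths

    def test_merge_sorts_by_time_then_walker(self, tmp_path):
        paths = self._write_walker_files(tmp_path)
        log = read_hills(paths, temperature=300.0)
        assert len(log) == 18
        assert log.gamma == 10.0
        times = log.records["time_ps"].to_numpy()
        assert (np.diff(times) >= 0).all()
        first_block = log.records.iloc[:6]
        assert list(first_block["walker"]) == list(range(6))

    def test_single_sorted_file_is_identity(self, tmp_path):
        paths = self._write_walker_files(tmp_path, n_files=1)
        log = read_hills(paths, gamma=10.0)
        assert list(log.records["time_ps"]) == [4.0, 8.0, 12.0]

    def test_malformed_line_reports_position(self, tmp_path):
        p = tmp_path / "HILLS.bad"
        p.write_text("4.0 9.0 10.0 0.1 0.1 0.1 10\n4.0 9.0 10.0\n")
        with pytest.raises(HillsParseError, match="2"):
            read_hills([p], gamma=10.0)

    def test_negative_width_rejected(self, tmp_path):
        p = tmp_path / "HILLS.neg"
        p.write_text("4.0 9.0 10.0 -0.1 0.1 0.1 10\n")
        with pytest.raises(HillsParseError):
            read_hills([p], gamma=10.0)

    def test_write_read_roundtrip(self, tmp_path):
        log = _random_log(component_rng(3, "hills-roundtrip"))
        p = tmp_path / "HILLS"
        write_hills(log, p)
        back = read_hills([p], temperature=300.0)
        np.testing.assert_allclose(
            back.records[["time_ps", "cv1", "cv2", "height"]].to_numpy(),
            log.records[["time_ps", "cv1", "cv2", "height"]].to_numpy(),
            rtol=1e-6,
        )


class TestBiasPotential:
    def test_empty_log_is_zero(self):
        log = _log_from_rows([])
        assert bias_potential(log, np.array([9.0, 9.0])) == 0.0

    def test_single_hill_center_value(self):
        """A deposited hill contributes exactly its height at its center."""
        log = _log_from_rows([(4.0, 10.0, 10.0, 0.1, 0.1, 0.1, 10.0, 0)])
        assert bias_potential(log, np.array([10.0, 10.0])) == pytest.approx(0.1)

    def test_one_sigma_off_center(self):
        log = _log_from_rows([(4.0, 10.0, 10.0, 0.1, 0.1, 0.1, 10.0, 0)])
        v = bias_potential(log, np.array([10.1, 10.0]))
        assert v == pytest.approx(0.1 * np.exp(-0.5), rel=1e-12)

    def test_additive_over_concatenation(self):
        rng = component_rng(5, "bias-additivity")
        log_a = _random_log(rng, n=25)
        log_b = _random_log(rng, n=17)
        merged = HillsLog.concat([log_a, log_b])
        pts = rng.uniform(7, 12, size=(50, 2))
        np.testing.assert_allclose(
            bias_potential(merged, pts),
            bias_potential(log_a, pts) + bias_potential(log_b, pts),
            atol=1e-12,
        )


class TestReconstructFES:
    def test_single_hill_prefactor(self):
        """With γ=10 the estimator applies the 10/9 prefactor."""
        log = _log_from_rows([(4.0, 10.0, 10.0, 0.1, 0.1, 0.1, 10.0, 0)])
        axes = np.array([9.8, 10.0, 10.2])
        fes = reconstruct_fes(log, axes, axes, reference=False)
        assert fes.values[1, 1] == pytest.approx(-(10.0 / 9.0) * 0.1, rel=1e-12)

    def test_matches_closed_form_everywhere(self):
        """Reconstruction equals -(γ/(γ-1))·(analytic Gaussian sum) to 1e-9."""
        rng = component_rng(6, "fes-closed-form")
        log = _random_log(rng, n=60)
        ax1 = np.linspace(6.0, 14.0, 41)
        ax2 = np.linspace(6.0, 14.0, 37)
        fes = reconstruct_fes(log, ax1, ax2, reference=False)
        r = log.records
        X, Y = np.meshgrid(ax1, ax2, indexing="ij")
        analytic = np.zeros_like(X)
        for row in r.itertuples():
            analytic += row.height * np.exp(
                -((X - row.cv1) ** 2) / (2 * row.sigma1**2)
                - ((Y - row.cv2) ** 2) / (2 * row.sigma2**2)
            )
        np.testing.assert_allclose(fes.values, -(10.0 / 9.0) * analytic, atol=1e-9)

    def test_empty_log_is_flat_zero(self):
        log = _log_from_rows([])
        fes = reconstruct_fes(log, np.linspace(6, 14, 10), np.linspace(6, 14, 10))
        assert (fes.values == 0).all()

    def test_referencing_sets_min_to_zero(self):
        log = _random_log(component_rng(7, "fes-ref"))
        fes = reconstruct_fes(log)
        assert fes.values.min() == pytest.approx(0.0, abs=1e-15)

    def test_uniform_background_does_not_change_shape(self):
        """Free energy is defined up to a constant: adding a constant-height
        background everywhere shifts, never reshapes, the referenced FES."""
        rng = component_rng(8, "fes-background")
        log = _random_log(rng, n=30)
        fes = reconstruct_fes(log)
        shifted = FESGrid(
            fes.cv1_axis, fes.cv2_axis, fes.values + 3.21, fes.gamma
        ).reference()
        np.testing.assert_allclose(shifted.values, fes.values, atol=1e-12)

    def test_gamma_at_most_one_rejected(self):
        df = pd.DataFrame(
            [(4.0, 10.0, 10.0, 0.1, 0.1, 0.1, 1.0, 0)],
            columns=["time_ps", "cv1", "cv2", "sigma1", "sigma2", "height",
                     "biasfactor", "walker"],
        )
        with pytest.raises(GpcrSwitchError):
            HillsLog(records=df, gamma=1.0)


def _gaussian_basin_fes(centers, depths, axes=None):
    if axes is None:
        axes = np.linspace(6.0, 14.0, 161)
    X, Y = np.meshgrid(axes, axes, indexing="ij")
    F = np.zeros_like(X)
    for (cx, cy), depth in zip(centers, depths):
        F -= depth * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * 0.3**2))
    return FESGrid(axes, axes, F - F.min(), gamma=10.0)


class TestLabelStates:
    def test_single_minimum_in_active_region(self):
        fes = _gaussian_basin_fes([(8.0, 8.0)], [2.0])
        states = label_states(fes)
        assert states["active"]["argmin"] == pytest.approx((8.0, 8.0))
        assert states["active"]["min_free_energy"] == pytest.approx(0.0)

    def test_flat_surface_has_equal_minima(self):
        axes = np.linspace(6.0, 14.0, 33)
        fes = FESGrid(axes, axes, np.zeros((33, 33)), gamma=10.0)
        states = label_states(fes)
        vals = [v["min_free_energy"] for v in states.values()]
        assert vals == pytest.approx([0.0] * 4)

    def test_double_well_fixture(self):
        fes = _gaussian_basin_fes([(10.5, 10.5), (8.5, 8.5)], [1.0, 2.0])
        states = label_states(fes)
        assert states["inactive"]["argmin"] == pytest.approx((10.5, 10.5))
        assert states["active"]["argmin"] == pytest.approx((8.5, 8.5))

    def test_grid_must_span_threshold(self):
        axes = np.linspace(10.0, 14.0, 17)
        fes = FESGrid(axes, axes, np.zeros((17, 17)), gamma=10.0)
        with pytest.raises(GpcrSwitchError):
            label_states(fes)


class TestCrystalPoint:
    def test_matches_distance_series_on_frame(self, small_bundle):
        traj, top, _ = small_bundle
        d1, d2 = crystal_point(top, traj.coords[0])
        from gpcrswitch.metad import CV_DEFINITIONS

        for val, (sa, sb) in zip((d1, d2), CV_DEFINITIONS):
            ref = distance_series(traj, sa.resolve(top), sb.resolve(top))[0]
            assert val == pytest.approx(ref, abs=1e-12)

    def test_swapping_cv_definitions_swaps_outputs(self, small_bundle):
        traj, top, _ = small_bundle
        d1, d2 = evaluate_cvs(top, traj.coords[0])
        # evaluating the definitions in reverse order reverses the tuple
        from gpcrswitch.metad import CV_DEFINITIONS
        from gpcrswitch.structure import Trajectory

        t = Trajectory(coords=traj.coords[:1], times=np.array([0.0]))
        rev = [
            distance_series(t, sa.resolve(top), sb.resolve(top))[0]
            for sa, sb in reversed(CV_DEFINITIONS)
        ]
        assert (rev[0], rev[1]) == pytest.approx((d2, d1))
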